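"""Time binning: contiguous year intervals used for longitudinal comparison."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TimeBinning:
    """An ordered list of inclusive ``[start_year, end_year]`` intervals.

    Bins must be non-overlapping and ascending so every record year maps to
    at most one bin. The conventional choice for a 20-year corpus is four
    5-year spans, e.g. ``TimeBinning.from_spec("1993-1997,1998-2002,...")``.
    """

    bins: tuple[tuple[int, int], ...]

    def __post_init__(self):
        prev_end = None
        for start, end in self.bins:
            if end < start:
                raise ValueError(f"bin ({start}, {end}) has end < start")
            if prev_end is not None and start <= prev_end:
                raise ValueError("bins must be ascending and non-overlapping")
            prev_end = end

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def index_of(self, year: int) -> int | None:
        """Bin index containing ``year``, or None if outside all bins."""
        for i, (start, end) in enumerate(self.bins):
            if start <= year <= end:
                return i
        return None

    def labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in self.bins]

    @classmethod
    def from_spec(cls, spec: str) -> "TimeBinning":
        """Parse ``"1993-1997,1998-2002"`` style bin specifications."""
        bins = []
        for part in spec.split(","):
            a, b = part.strip().split("-")
            bins.append((int(a), int(b)))
        return cls(tuple(bins))

    @classmethod
    def uniform(cls, start: int, end: int, width: int) -> "TimeBinning":
        """Equal-width bins covering [start, end]."""
        bins = []
        y = start
        while y <= end:
            bins.append((y, min(y + width - 1, end)))
            y += width
        return cls(tuple(bins))
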