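"""Domain types shared across the pipeline stages.

A :class:`PaperRecord` is one cleaned bibliographic record; a
:class:`CleaningReport` is the exact ledger of what each cleaning stage
removed or merged; a :class:`SynonymMap` maps variant keyword spellings to
their canonical (standard) names.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path


@dataclass
class PaperRecord:
    """One bibliographic record (an article's metadata).

    Keywords are author-supplied free-text terms; after cleaning they are
    lowercased, accent-folded and deduplicated within the record.
    ``countries`` holds canonical country names derived from the affiliation
    strings.
    """

    record_id: str
    title: str
    year: int
    authors: list[str] = field(default_factory=list)
    affiliations: list[str] = field(default_factory=list)
    countries: set[str] = field(default_factory=set)
    keywords: list[str] = field(default_factory=list)
    doi: str | None = None
    journal: str | None = None
    citation_count: int | None = None
    funding_text: str | None = None

    def copy(self) -> "PaperRecord":
        return replace(
            self,
            authors=list(self.authors),
            affiliations=list(self.affiliations),
            countries=set(self.countries),
            keywords=list(self.keywords),
        )


@dataclass
class CleaningReport:
    """Ledger of a cleaning run.

    Invariant: ``n_read == n_retained + n_invalid_removed +
    n_duplicates_removed`` (skipped unparseable rows are counted inside
    ``n_invalid_removed`` under rule ``"unreadable_row"``).
    """

    n_read: int = 0
    n_retained: int = 0
    n_invalid_removed: int = 0
    n_duplicates_removed: int = 0
    n_keyword_variants_merged: int = 0
    per_rule_counts: dict[str, int] = field(default_factory=dict)

    def bump(self, rule: str, n: int = 1) -> None:
        self.per_rule_counts[rule] = self.per_rule_counts.get(rule, 0) + n

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        out = CleaningReport(
            n_read=self.n_read or other.n_read,
            n_retained=other.n_retained,
            n_invalid_removed=self.n_invalid_removed + other.n_invalid_removed,
            n_duplicates_removed=self.n_duplicates_removed + other.n_duplicates_removed,
            n_keyword_variants_merged=self.n_keyword_variants_merged
            + other.n_keyword_variants_merged,
            per_rule_counts=dict(self.per_rule_counts),
        )
        for rule, n in other.per_rule_counts.items():
            out.bump(rule, n)
        return out


class SynonymMap:
    """Canonical keyword -> variant spellings.

    Invariants enforced at construction: no variant is claimed by two
    canonicals, and no canonical appears as a variant of another canonical.
    """

    def __init__(self, entries: dict[str, list[str]] | None = None):
        entries = entries or {}
        self.entries: dict[str, list[str]] = {}
        self._variant_to_canonical: dict[str, str] = {}
        for canonical, variants in entries.items():
            self.add(canonical, variants)

    def add(self, canonical: str, variants: list[str]) -> None:
        canonical = canonical.strip().lower()
        for v in variants:
            v = v.strip().lower()
            if v == canonical:
                continue
            owner = self._variant_to_canonical.get(v)
            if owner is not None and owner != canonical:
                raise ValueError(
                    f"variant {v!r} claimed by both {owner!r} and {canonical!r}"
                )
            if v in self.entries:
                raise ValueError(
                    f"canonical {v!r} also listed as a variant of {canonical!r}"
                )
            if canonical in self._variant_to_canonical:
                raise ValueError(
                    f"canonical {canonical!r} is already a variant of "
                    f"{self._variant_to_canonical[canonical]!r}"
                )
            self._variant_to_canonical[v] = canonical
            self.entries.setdefault(canonical, []).append(v)
        self.entries.setdefault(canonical, self.entries.get(canonical, []))

    def canonical(self, keyword: str) -> str:
        """Map a keyword to its canonical form (identity if unmapped)."""
        return self._variant_to_canonical.get(keyword, keyword)

    def __len__(self) -> int:
        return len(self._variant_to_canonical)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymMap":
        """Read a two-column CSV ``canonical,variant`` (header optional)."""
        m = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            for i, row in enumerate(reader):
                if not row or len(row) < 2:
                    continue
                canonical, variant = row[0].strip(), row[1].strip()
                if i == 0 and canonical.lower() == "canonical":
                    continue
                m.add(canonical, [variant])
        return m
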