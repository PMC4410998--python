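"""Longitudinal trend statistics for keywords and keyword pairs.

Two statistics drive the analysis:

*Relative growth* of a frequency series ``f_1 .. f_n`` (per-bin relative
frequencies, in percent of papers) is the summed period-to-period relative
increment, expressed as a percentage::

    Growth = 100 * sum_{i=1}^{n-1} (f_{i+1} - f_i) / f_i

The ratio is undefined where ``f_i = 0``; such terms are skipped and the
number of terms actually summed is reported. Growth is scale-invariant
(multiplying every ``f_i`` by a positive constant changes nothing), so it
isolates a subject's trajectory from overall corpus growth.

*Z-score significance*: each subject's growth value ``X`` is standardised
against the population of growth values of all subjects in the same
analysis run, ``z = (X - mean) / sd`` (sample sd), and converted to a
one-sided normal tail probability — upper tail for above-mean growth,
lower tail otherwise. A subject is flagged significant when the tail
probability is below alpha (default 0.01).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from coword.binning import TimeBinning
from coword.records import PaperRecord

Subject = str | tuple[str, str]

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_TOTAL_FREQUENCY = 20


def _canonical_subject(subject: Subject) -> Subject:
    if isinstance(subject, tuple):
        a, b = subject
        return (a, b) if a <= b else (b, a)
    return subject


@dataclass
class FrequencySeries:
    """Per-bin relative frequencies of a keyword or unordered keyword pair.

    ``f[i]`` is the percentage of papers in bin ``i`` containing the
    subject (both keywords, for a pair).
    """

    subject: Subject
    f: np.ndarray

    def __post_init__(self):
        self.subject = _canonical_subject(self.subject)
        self.f = np.asarray(self.f, dtype=float)


@dataclass
class GrowthResult:
    """Growth and significance of one subject."""

    subject: Subject
    growth_pct: float
    n_terms_used: int
    z: float = math.nan
    p_tail: float = math.nan
    significant: bool = False


def bin_paper_counts(records: list[PaperRecord], binning: TimeBinning) -> np.ndarray:
    counts = np.zeros(len(binning), dtype=int)
    for rec in records:
        i = binning.index_of(rec.year)
        if i is not None:
            counts[i] += 1
    return counts


def relative_frequency_series(
    records: list[PaperRecord], subject: Subject, binning: TimeBinning
) -> FrequencySeries:
    """Percentage of papers per bin containing ``subject``.

    For a pair, containment means both keywords present in the same paper.
    Empty bins contribute a frequency of 0.
    """
    subject = _canonical_subject(subject)
    n_bins = len(binning)
    hits = np.zeros(n_bins, dtype=int)
    totals = np.zeros(n_bins, dtype=int)
    for rec in records:
        i = binning.index_of(rec.year)
        if i is None:
            continue
        totals[i] += 1
        kws = set(rec.keywords)
        if isinstance(subject, tuple):
            contained = subject[0] in kws and subject[1] in kws
        else:
            contained = subject in kws
        if contained:
            hits[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals > 0, 100.0 * hits / np.maximum(totals, 1), 0.0)
    return FrequencySeries(subject=subject, f=f)


def growth(series: FrequencySeries | np.ndarray | list[float]) -> tuple[float, int]:
    """Relative growth (percent) of a frequency series.

    Returns ``(growth_pct, n_terms_used)``. Terms whose denominator ``f_i``
    is zero are skipped. When every denominator is zero the growth is
    undefined and returned as NaN (not 0).
    """
    f = series.f if isinstance(series, FrequencySeries) else np.asarray(series, dtype=float)
    if f.size < 2:
        raise ValueError("growth needs a series of length >= 2")
    denom = f[:-1]
    increments = np.diff(f)
    usable = denom > 0
    n_used = int(usable.sum())
    if n_used == 0:
        return math.nan, 0
    value = 100.0 * float(np.sum(increments[usable] / denom[usable]))
    return value, n_used


def growth_zscore(
    population: np.ndarray | list[float],
    subject_growth: float,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[float, float, bool]:
    """Standardise one growth value against a population of growth values.

    ``z = (X - mean) / s`` with sample standard deviation (ddof=1); the tail
    probability is upper-tail for ``X >= mean``, lower-tail otherwise, so it
    is at most 0.5. Returns ``(z, p_tail, significant)``; z is NaN (never
    significant) when the population sd is zero.
    """
    pop = np.asarray(population, dtype=float)
    pop = pop[np.isfinite(pop)]
    if pop.size < 2:
        raise ValueError("population must contain at least 2 finite values")
    mean = float(pop.mean())
    sd = float(pop.std(ddof=1))
    if sd == 0 or not math.isfinite(subject_growth):
        return math.nan, math.nan, False
    z = (subject_growth - mean) / sd
    p_tail = float(stats.norm.sf(z) if z >= 0 else stats.norm.cdf(z))
    return z, p_tail, bool(p_tail < alpha)


def _subject_totals(
    records: list[PaperRecord], binning: TimeBinning, subjects: str
) -> Counter:
    """Total paper counts per subject over all bins (binary per paper)."""
    totals: Counter = Counter()
    for rec in records:
        if binning.index_of(rec.year) is None:
            continue
        kws = sorted(set(rec.keywords))
        if subjects == "pairs":
            totals.update(combinations(kws, 2))
        else:
            totals.update(kws)
    return totals


def analyze_growth(
    records: list[PaperRecord],
    binning: TimeBinning,
    subjects: str = "keywords",
    min_total_frequency: int = DEFAULT_MIN_TOTAL_FREQUENCY,
    alpha: float = DEFAULT_ALPHA,
    use_counts: bool = False,
) -> list[GrowthResult]:
    """Growth + z-score for every subject passing the frequency filter.

    ``subjects`` is ``"keywords"`` or ``"pairs"``. The z-score population is
    the set of growth values of all subjects in this run. ``use_counts``
    switches the series from per-bin percentages to raw paper counts.
    """
    if subjects not in ("keywords", "pairs"):
        raise ValueError("subjects must be 'keywords' or 'pairs'")
    totals = _subject_totals(records, binning, subjects)
    eligible = [s for s, c in totals.items() if c >= min_total_frequency]

    n_bins = len(binning)
    hits = {s: np.zeros(n_bins, dtype=int) for s in eligible}
    bin_totals = np.zeros(n_bins, dtype=int)
    eligible_set = set(eligible)
    for rec in records:
        i = binning.index_of(rec.year)
        if i is None:
            continue
        bin_totals[i] += 1
        kws = sorted(set(rec.keywords))
        iterable = combinations(kws, 2) if subjects == "pairs" else kws
        for s in iterable:
            if s in eligible_set:
                hits[s][i] += 1

    results: list[GrowthResult] = []
    for s in eligible:
        if use_counts:
            f = hits[s].astype(float)
        else:
            f = np.where(bin_totals > 0, 100.0 * hits[s] / np.maximum(bin_totals, 1), 0.0)
        g, n_used = growth(f)
        results.append(GrowthResult(subject=s, growth_pct=g, n_terms_used=n_used))

    finite = [r.growth_pct for r in results if math.isfinite(r.growth_pct)]
    if len(finite) >= 2 and np.std(finite, ddof=1) > 0:
        for r in results:
            if math.isfinite(r.growth_pct):
                r.z, r.p_tail, r.significant = growth_zscore(finite, r.growth_pct, alpha)
    return results


def rank_by_growth(
    records: list[PaperRecord],
    binning: TimeBinning,
    subjects: str = "keywords",
    min_total_frequency: int = DEFAULT_MIN_TOTAL_FREQUENCY,
    direction: str = "up",
    alpha: float = DEFAULT_ALPHA,
    top: int | None = None,
) -> list[GrowthResult]:
    """Subjects ranked by growth, descending for "up", ascending for "down".

    Ties are broken lexicographically on the subject; undefined (NaN) growth
    values sort last in either direction.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    results = analyze_growth(records, binning, subjects, min_total_frequency, alpha)
    sign = -1.0 if direction == "up" else 1.0

    def key(r: GrowthResult):
        g = r.growth_pct
        return (not math.isfinite(g), sign * (g if math.isfinite(g) else 0.0), r.subject)

    ranked = sorted(results, key=key)
    return ranked[:top] if top else ranked


def growth_table(
    results: list[GrowthResult],
    records: list[PaperRecord],
    binning: TimeBinning,
) -> pd.DataFrame:
    """Result table shaped like the classic trend tables: subject, per-bin
    percentages, growth % and tail probability."""
    labels = binning.labels()
    rows = []
    for r in results:
        series = relative_frequency_series(records, r.subject, binning)
        subj = " & ".join(r.subject) if isinstance(r.subject, tuple) else r.subject
        row = {"subject": subj}
        row.update({f"{lab} (%)": round(float(v), 2) for lab, v in zip(labels, series.f)})
        row["growth_pct"] = round(r.growth_pct, 2) if math.isfinite(r.growth_pct) else math.nan
        row["p_tail"] = r.p_tail
        row["significant"] = r.significant
        rows.append(row)
    return pd.DataFrame(rows)
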