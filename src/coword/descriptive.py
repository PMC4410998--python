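"""Corpus-level descriptive statistics per time bin.

Answers the first-phase questions of a bibliometric study: how many papers
per period, how many authors per paper, how much international
collaboration, which countries and keywords dominate.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from coword.binning import TimeBinning
from coword.records import PaperRecord


@dataclass
class BinSummary:
    """Descriptive summary for one time bin.

    A paper is *international* iff its authors span at least two countries.
    Country counts use full counting (each distinct country credited once
    per paper). Keyword counts are binary per paper.
    """

    bin: tuple[int, int]
    n_papers: int
    mean_authors_per_paper: float  # NaN when the bin is empty
    n_international: int
    pct_international: float
    country_counts: dict[str, int] = field(default_factory=dict)
    top_keywords: list[tuple[str, int]] = field(default_factory=list)


def records_in_bin(records: list[PaperRecord], bin_: tuple[int, int]) -> list[PaperRecord]:
    start, end = bin_
    return [r for r in records if start <= r.year <= end]


def summarize_bin(
    records: list[PaperRecord], bin_: tuple[int, int], k: int = 20
) -> BinSummary:
    """Summarise one time bin; ``k`` is the top-keyword list size.

    An empty bin yields zero counts with the mean flagged as NaN.
    """
    in_bin = records_in_bin(records, bin_)
    n = len(in_bin)
    n_intl = sum(1 for r in in_bin if len(r.countries) >= 2)
    country_counts: Counter = Counter()
    kw_counts: Counter = Counter()
    total_authors = 0
    for rec in in_bin:
        total_authors += len(rec.authors)
        country_counts.update(rec.countries)
        kw_counts.update(set(rec.keywords))
    top = sorted(kw_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return BinSummary(
        bin=bin_,
        n_papers=n,
        mean_authors_per_paper=(total_authors / n) if n else math.nan,
        n_international=n_intl,
        pct_international=(100.0 * n_intl / n) if n else 0.0,
        country_counts=dict(country_counts),
        top_keywords=top,
    )


def summarize(
    records: list[PaperRecord], binning: TimeBinning, k: int = 20
) -> list[BinSummary]:
    return [summarize_bin(records, b, k) for b in binning]


def keyword_occurrence_totals(records: list[PaperRecord]) -> tuple[int, float]:
    """Total keyword occurrences and mean keywords per paper.

    Total is the sum of per-record keyword-list lengths (records are assumed
    cleaned, so lists hold no within-record duplicates). The mean is NaN for
    an empty corpus.
    """
    total = sum(len(r.keywords) for r in records)
    n = len(records)
    return total, (total / n) if n else math.nan


def summary_table(summaries: list[BinSummary]) -> pd.DataFrame:
    """Per-bin summary as a DataFrame (CSV-writable)."""
    return pd.DataFrame(
        {
            "bin": [f"{a}-{b}" for a, b in (s.bin for s in summaries)],
            "n_papers": [s.n_papers for s in summaries],
            "mean_authors_per_paper": [s.mean_authors_per_paper for s in summaries],
            "n_international": [s.n_international for s in summaries],
            "pct_international": [s.pct_international for s in summaries],
        }
    )


def top_keyword_table(summaries: list[BinSummary]) -> pd.DataFrame:
    """Long-format top-keyword table: bin, rank, keyword, paper count."""
    rows = []
    for s in summaries:
        for rank, (kw, cnt) in enumerate(s.top_keywords, start=1):
            rows.append({"bin": f"{s.bin[0]}-{s.bin[1]}", "rank": rank,
                         "keyword": kw, "n_papers": cnt})
    return pd.DataFrame(rows)
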