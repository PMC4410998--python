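"""Gene-word (stem keyword) extraction.

A *gene-word* is a high-frequency stem that forms many other keywords by
compounding, prefixing or suffixing ("insulin" -> "insulin resistance",
"~tomy" -> "gastrectomy"). Three rules gate a candidate:

1. the stem itself is frequent (over 100 appearances) and ranks in the
   top-100 keywords;
2. it has at least 10 derived keywords each appearing more than 10 times,
   whose aggregate frequency exceeds 20% of the family total;
3. it represents a priority issue of the domain — inherently editorial,
   so supplied as a curated priority list.

Pattern syntax: a plain stem (``insulin``) matches any keyword containing
it; ``~stem`` matches keywords with a word *ending* in the stem;
``stem~`` matches keywords with a word *starting* with the stem. Matching
is case-insensitive on canonical keywords and the bare stem itself is
never its own derivative. Families may overlap: a keyword can derive from
two gene-words.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from coword.binning import TimeBinning
from coword.ingest import canonical_keyword

#: Gene-word stems commonly found in obesity-research corpora; the default
#: priority list for rule 3.
DEFAULT_PRIORITY_PATTERNS = [
    "obesity", "diabetes", "insulin", "adipose", "metabolism", "metabolic",
    "child", "surgery", "cardio~", "weight", "hyper~", "risk", "lipid",
    "blood", "disease", "diet", "food", "hypo~", "~tomy",
]


@dataclass
class GeneWordReport:
    """One gene-word family and its appearance statistics."""

    gene_word: str
    derived_keywords: list[str] = field(default_factory=list)
    n_derived: int = 0
    freq_per_bin: list[int] = field(default_factory=list)
    total_freq: int = 0
    avg_freq_per_derived: float = 0.0
    rules_passed: tuple[bool, bool, bool] = (False, False, False)


def _pattern_regex(pattern: str) -> re.Pattern:
    if pattern.startswith("~"):
        return re.compile(re.escape(pattern[1:]) + r"\b")
    if pattern.endswith("~"):
        return re.compile(r"\b" + re.escape(pattern[:-1]))
    return re.compile(re.escape(pattern))


def stem_of(pattern: str) -> str:
    return pattern.strip("~")


def find_derived(pattern: str, keyword_universe) -> list[str]:
    """Keywords in the universe derived from ``pattern`` (sorted).

    The bare stem itself is excluded. Raises ValueError on an empty
    pattern.
    """
    stem = stem_of(pattern)
    if not stem:
        raise ValueError("empty gene-word pattern")
    canon = canonical_keyword(stem)
    if pattern.startswith("~"):
        rx = _pattern_regex("~" + canon)
    elif pattern.endswith("~"):
        rx = _pattern_regex(canon + "~")
    else:
        rx = _pattern_regex(canon)
    out = []
    for kw in keyword_universe:
        k = canonical_keyword(kw)
        if k == canon:
            continue
        if rx.search(k):
            out.append(k)
    return sorted(set(out))


def extract_genewords(
    freq_table: dict[str, int],
    candidate_patterns: list[str],
    priority_list: list[str] | None = None,
    per_bin_freq: dict[str, list[int]] | None = None,
    n_bins: int = 0,
    stem_freq_threshold: int = 100,
    stem_rank_threshold: int = 100,
    min_derived: int = 10,
    derived_freq_threshold: int = 10,
    family_share_threshold: float = 0.20,
    share_mode: str = "family",
) -> list[GeneWordReport]:
    """Apply the three gene-word rules to candidate patterns.

    ``freq_table`` maps keyword -> total appearance count; ``per_bin_freq``
    (optional) maps keyword -> per-bin counts for the report columns.

    Rule 1 tests the bare stem's own frequency (> ``stem_freq_threshold``)
    and rank (<= ``stem_rank_threshold``, ties included). Affix patterns
    (``~stem`` / ``stem~``) have no standalone keyword; for those the rule
    is tested on the family's most frequent derived keyword, which anchors
    the family in the top of the distribution.

    Rule 2 requires >= ``min_derived`` derived keywords each with frequency
    > ``derived_freq_threshold``, and an aggregate derived frequency above
    ``family_share_threshold`` of the family-plus-stem total
    (``share_mode="family"``, default) or of the whole corpus
    (``share_mode="corpus"``).

    Rule 3 keeps only candidates on ``priority_list`` (None disables it).
    Reports for passing candidates are sorted by average frequency per
    derived keyword, descending.
    """
    for name, value in [
        ("stem_freq_threshold", stem_freq_threshold),
        ("stem_rank_threshold", stem_rank_threshold),
        ("min_derived", min_derived),
        ("derived_freq_threshold", derived_freq_threshold),
        ("family_share_threshold", family_share_threshold),
    ]:
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    if share_mode not in ("family", "corpus"):
        raise ValueError("share_mode must be 'family' or 'corpus'")

    freqs = sorted(freq_table.values(), reverse=True)
    corpus_total = sum(freq_table.values())

    def rank_of(freq: int) -> int:
        return 1 + sum(1 for f in freqs if f > freq)

    priority = None
    if priority_list is not None:
        priority = {p.strip().lower() for p in priority_list}

    reports = []
    for pattern in candidate_patterns:
        stem = canonical_keyword(stem_of(pattern))
        derived = find_derived(pattern, freq_table.keys())
        derived_freqs = {k: freq_table.get(k, 0) for k in derived}
        total = sum(derived_freqs.values())
        stem_freq = freq_table.get(stem, 0)
        is_affix = pattern.startswith("~") or pattern.endswith("~")
        anchor_freq = (
            max(derived_freqs.values(), default=0) if (is_affix and stem not in freq_table)
            else stem_freq
        )
        r1 = anchor_freq > stem_freq_threshold and rank_of(anchor_freq) <= stem_rank_threshold
        n_qualifying = sum(1 for f in derived_freqs.values() if f > derived_freq_threshold)
        denom = corpus_total if share_mode == "corpus" else total + stem_freq
        r2 = n_qualifying >= min_derived and denom > 0 and total > family_share_threshold * denom
        r3 = True if priority is None else pattern.strip().lower() in priority

        if not (r1 and r2 and r3):
            continue
        per_bin = [0] * n_bins
        if per_bin_freq is not None:
            for k in derived:
                for i, c in enumerate(per_bin_freq.get(k, [])):
                    if i < len(per_bin):
                        per_bin[i] += c
        n_derived = len(derived)
        reports.append(
            GeneWordReport(
                gene_word=pattern,
                derived_keywords=derived,
                n_derived=n_derived,
                freq_per_bin=per_bin,
                total_freq=total,
                avg_freq_per_derived=total / n_derived if n_derived else 0.0,
                rules_passed=(r1, r2, r3),
            )
        )
    reports.sort(key=lambda r: (-r.avg_freq_per_derived, r.gene_word))
    return reports


def geneword_table(reports: list[GeneWordReport], binning: TimeBinning | None = None) -> pd.DataFrame:
    """Gene-word summary table: family size, per-bin and total frequency,
    and average frequency per derived keyword (2 decimals)."""
    labels = binning.labels() if binning is not None else None
    rows = []
    for r in reports:
        row: dict[str, object] = {
            "gene_word": r.gene_word,
            "n_derived": r.n_derived,
        }
        if labels:
            for lab, f in zip(labels, r.freq_per_bin):
                row[f"freq {lab}"] = f
        row["total_freq"] = r.total_freq
        row["avg_freq_per_derived"] = round(r.avg_freq_per_derived, 2)
        rows.append(row)
    return pd.DataFrame(rows)
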