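"""Hierarchical categorisation of keywords via a MeSH-style vocabulary.

Medical Subject Headings (MeSH) descriptors carry *tree numbers* such as
``E04.210.338``; the dot-separated components define a root-anchored path
through the category hierarchy. A keyword is categorised by looking it up
in the descriptor (and optionally entry-term) index and keeping the top
two levels of every path it sits on — the broad category and its first
refinement.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from coword.binning import TimeBinning
from coword.ingest import canonical_keyword
from coword.records import PaperRecord


@dataclass
class CategoryTree:
    """Descriptor hierarchy: tree-number -> name plus a term index.

    ``term_index`` maps a canonical term to the list of tree numbers (paths)
    of the descriptor(s) carrying it. ``version`` records which vocabulary
    release was loaded; it is echoed into output tables because category
    results are version-dependent.
    """

    names: dict[str, str] = field(default_factory=dict)
    term_index: dict[str, list[str]] = field(default_factory=dict)
    version: str = "unspecified"

    def name_of(self, tree_number: str) -> str:
        """Descriptor name at a tree number; the number itself if unnamed."""
        return self.names.get(tree_number, tree_number)

    def top_two_levels(self, tree_number: str) -> tuple[str, str | None]:
        parts = tree_number.split(".")
        level1 = self.name_of(parts[0])
        level2 = self.name_of(".".join(parts[:2])) if len(parts) >= 2 else None
        return level1, level2


@dataclass
class CategoryAssignment:
    """Top-two-level categories of one keyword (empty when unindexed)."""

    keyword: str
    categories: list[tuple[str, str | None]] = field(default_factory=list)


def load_tree(
    xml_path: str | Path,
    include_entry_terms: bool = False,
    version: str = "unspecified",
) -> CategoryTree:
    """Parse a MeSH descriptor XML file into a :class:`CategoryTree`.

    Reads ``DescriptorRecord`` elements: the descriptor name indexes every
    tree number in its ``TreeNumberList``; with ``include_entry_terms`` the
    concept entry terms (synonyms) index the same paths. Malformed XML
    raises :class:`lxml.etree.XMLSyntaxError` with line context.
    """
    tree = CategoryTree(version=version)
    root = etree.parse(str(xml_path)).getroot()
    for rec in root.iter("DescriptorRecord"):
        name_el = rec.find("DescriptorName/String")
        if name_el is None or not name_el.text:
            continue
        name = name_el.text.strip()
        numbers = [
            tn.text.strip()
            for tn in rec.findall("TreeNumberList/TreeNumber")
            if tn.text and tn.text.strip()
        ]
        if not numbers:
            continue
        terms = {canonical_keyword(name)}
        if include_entry_terms:
            for term_el in rec.findall("ConceptList/Concept/TermList/Term/String"):
                if term_el.text:
                    terms.add(canonical_keyword(term_el.text))
        for tn in numbers:
            tree.names[tn] = canonical_keyword(name)
        for term in terms:
            tree.term_index.setdefault(term, [])
            for tn in numbers:
                if tn not in tree.term_index[term]:
                    tree.term_index[term].append(tn)
    return tree


def load_overrides(csv_path: str | Path) -> dict[str, list[tuple[str, str | None]]]:
    """Read a category override file (CSV: keyword,level1,level2)."""
    overrides: dict[str, list[tuple[str, str | None]]] = {}
    with open(csv_path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or len(row) < 2:
                continue
            if i == 0 and row[0].strip().lower() == "keyword":
                continue
            kw = canonical_keyword(row[0])
            l1 = canonical_keyword(row[1])
            l2 = canonical_keyword(row[2]) if len(row) > 2 and row[2].strip() else None
            overrides.setdefault(kw, []).append((l1, l2))
    return overrides


def categorize_keyword(
    keyword: str,
    tree: CategoryTree,
    overrides: dict[str, list[tuple[str, str | None]]] | None = None,
) -> CategoryAssignment:
    """Top-two-level category pairs of a keyword (pure function).

    A keyword on several tree positions yields several (deduplicated)
    pairs; an unindexed keyword yields an empty assignment, never an error.
    Overrides, when supplied, replace the tree lookup for that keyword.
    """
    kw = canonical_keyword(keyword)
    if overrides and kw in overrides:
        return CategoryAssignment(keyword=kw, categories=list(overrides[kw]))
    pairs: list[tuple[str, str | None]] = []
    for tn in tree.term_index.get(kw, []):
        pair = tree.top_two_levels(tn)
        if pair not in pairs:
            pairs.append(pair)
    return CategoryAssignment(keyword=kw, categories=pairs)


def category_distribution(
    records: list[PaperRecord],
    tree: CategoryTree,
    binning: TimeBinning,
    top_n_keywords: int = 650,
    overrides: dict[str, list[tuple[str, str | None]]] | None = None,
) -> pd.DataFrame:
    """Per-category keyword frequency and share, per time bin.

    Only the ``top_n_keywords`` most frequent keywords are categorised. A
    keyword's per-bin paper counts are credited once to *each* of its
    category pairs (multi-path keywords therefore inflate category totals;
    with single-path keywords category and keyword sums agree exactly).
    Shares are normalised within each bin over the credited totals.
    """
    totals: Counter = Counter()
    for rec in records:
        if binning.index_of(rec.year) is not None:
            totals.update(set(rec.keywords))
    top = [kw for kw, _ in sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n_keywords]]

    n_bins = len(binning)
    per_kw_bin: dict[str, list[int]] = {kw: [0] * n_bins for kw in top}
    top_set = set(top)
    for rec in records:
        i = binning.index_of(rec.year)
        if i is None:
            continue
        for kw in set(rec.keywords):
            if kw in top_set:
                per_kw_bin[kw][i] += 1

    cat_bin: dict[tuple[str, str | None], list[int]] = {}
    for kw in top:
        assignment = categorize_keyword(kw, tree, overrides)
        for pair in assignment.categories:
            acc = cat_bin.setdefault(pair, [0] * n_bins)
            for i in range(n_bins):
                acc[i] += per_kw_bin[kw][i]

    labels = binning.labels()
    rows = []
    bin_sums = [sum(v[i] for v in cat_bin.values()) for i in range(n_bins)]
    for (l1, l2), freqs in sorted(cat_bin.items(), key=lambda kv: (-sum(kv[1]), kv[0])):
        row: dict[str, object] = {"level1": l1, "level2": l2, "vocabulary_version": tree.version}
        for i, lab in enumerate(labels):
            row[f"{lab} freq"] = freqs[i]
            row[f"{lab} share"] = freqs[i] / bin_sums[i] if bin_sums[i] else 0.0
        row["total freq"] = sum(freqs)
        rows.append(row)
    return pd.DataFrame(rows)
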