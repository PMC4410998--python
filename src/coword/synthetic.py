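"""Synthetic bibliographic corpora with known ground truth.

Emulates the kind of corpus a Scopus keyword query returns over a 20-year
window: per-period corpus growth (publication counts roughly doubling each
5-year span), author keyword sets of about five keywords per paper, keyword
relative-frequency trajectories with planted growth or decline, block
(community) co-occurrence structure, gene-word families (a stem plus
derived compounds), and the messiness real exports carry — accented
spellings, hyphenated variants, duplicate rows and records with missing
essential fields. Every injection is ledgered so the cleaning pipeline can
be checked against exact counts, and the planted structure is emitted as a
ground-truth file so trend, network and gene-word recovery are testable
without any download.

Given a fixed seed the emitted CSV is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coword.binning import TimeBinning

_SCOPUS_HEADER = [
    "Authors", "Title", "Year", "Author Keywords", "Affiliations",
    "DOI", "Source title", "Cited by", "Funding Details",
]

_COUNTRY_POOL = [
    "United States", "United Kingdom", "Australia", "China", "Germany",
    "France", "Italy", "Japan", "Brazil", "India", "Canada", "Spain",
]

#: Default gene-word families planted in the vocabulary. Derived keywords
#: are compounds of the stem, as in real author-keyword lists.
DEFAULT_FAMILIES = {
    "insulin": [
        "insulin resistance", "insulin sensitivity", "insulin secretion",
        "insulin therapy", "insulin signaling", "insulin receptor",
        "hyperinsulinemia", "insulin analogues", "insulin pump",
        "insulin clearance", "insulin tolerance", "insulin index",
    ],
    "lipid": [
        "dyslipidemia", "hyperlipidemia", "phospholipids", "plasma lipids",
        "lipid profile", "lipid metabolism", "lipid peroxidation",
        "lipid oxidation", "serum lipids", "lipid droplets",
        "lipid storage", "blood lipids",
    ],
}


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus.

    Defaults describe the emulated study conditions: four 5-year bins
    (1993-2012), paper counts doubling per bin, a Zipf-like keyword
    vocabulary, about five keywords per paper (Poisson, minimum one), and
    modest noise rates.
    """

    bins: TimeBinning = field(
        default_factory=lambda: TimeBinning.from_spec("1993-1997,1998-2002,2003-2007,2008-2012")
    )
    papers_per_bin: tuple[int, ...] = (250, 500, 1000, 2000)
    n_vocab: int = 120
    keywords_per_paper: float = 5.0
    #: keyword -> per-bin multiplicative factors applied to its base probability
    trend_map: dict[str, tuple[float, ...]] = field(default_factory=dict)
    #: base keyword probabilities: "zipf" (rank-skewed, realistic) or
    #: "uniform" (exchangeable keywords, for null calibration studies)
    prob_model: str = "zipf"
    #: number of community blocks the vocabulary is partitioned into
    n_blocks: int = 4
    #: probability mass drawn from the paper's own block (vs the global pool)
    p_intra_block: float = 0.7
    geneword_families: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FAMILIES.items()}
    )
    #: fraction of papers with affiliations from two countries
    international_rate: float = 0.2
    duplicate_rate: float = 0.0
    hyphen_variant_rate: float = 0.0
    accent_variant_rate: float = 0.0
    missing_field_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.papers_per_bin) != len(self.bins):
            raise ValueError("papers_per_bin length must match number of bins")
        if self.n_vocab < max(10, int(self.keywords_per_paper) + 1):
            raise ValueError("vocabulary too small for keywords_per_paper")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    vocabulary: list[str] = field(default_factory=list)
    relative_frequency: dict[str, list[float]] = field(default_factory=dict)
    trending_keywords: list[str] = field(default_factory=list)
    blocks: list[list[str]] = field(default_factory=list)
    geneword_families: dict[str, list[str]] = field(default_factory=dict)
    categories: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_papers_clean: int = 0
    n_duplicates_injected: int = 0
    n_hyphen_variants_injected: int = 0
    n_accent_variants_injected: int = 0
    n_invalid_injected: int = 0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1, default=list)
        return path


@dataclass
class GeneratedCorpus:
    csv_path: Path
    ground_truth: GroundTruth
    mesh_xml_path: Path
    ground_truth_path: Path


def _build_vocabulary(spec: CorpusSpec) -> list[str]:
    """Family stems + derived keywords first, then generic topic keywords."""
    vocab: list[str] = []
    for stem, derived in spec.geneword_families.items():
        vocab.append(stem)
        vocab.extend(derived)
    i = 0
    while len(vocab) < spec.n_vocab:
        name = f"topic {i:03d}"
        if name not in vocab:
            vocab.append(name)
        i += 1
    return vocab[: spec.n_vocab]


def _bin_block_probs(spec: CorpusSpec, vocab: list[str], blocks: list[list[str]]):
    """Per-(bin, block) keyword sampling distributions.

    Base probabilities are Zipf-like over the vocabulary; each bin applies
    the planted trend factors; each block mixes an intra-block boost with
    the global distribution.
    """
    n = len(vocab)
    idx = {kw: i for i, kw in enumerate(vocab)}
    if spec.prob_model == "uniform":
        base = np.ones(n)
    else:
        base = 1.0 / (np.arange(n) + 2.0)
    n_bins = len(spec.bins)
    out = []
    for b in range(n_bins):
        p = base.copy()
        for kw, factors in spec.trend_map.items():
            if kw in idx:
                p[idx[kw]] = base[idx[kw]] * factors[b]
        p /= p.sum()
        per_block = []
        for block in blocks:
            mask = np.zeros(n)
            for kw in block:
                mask[idx[kw]] = 1.0
            intra = p * mask
            intra = intra / intra.sum() if intra.sum() > 0 else p
            q = spec.p_intra_block * intra + (1 - spec.p_intra_block) * p
            per_block.append(q / q.sum())
        out.append(per_block)
    return out


def _accent(kw: str) -> str:
    """Deterministic accented variant (first 'a' or 'e' gains an accent)."""
    for ch, repl in (("a", "á"), ("e", "é")):
        if ch in kw:
            return kw.replace(ch, repl, 1)
    return kw


def _hyphen(kw: str) -> str:
    """Deterministic hyphenated variant: split the longest word in two."""
    words = kw.split(" ")
    longest = max(words, key=len)
    if len(longest) < 6:
        return kw
    cut = len(longest) // 2
    hyphenated = longest[:cut] + "-" + longest[cut:]
    return " ".join(hyphenated if w == longest else w for w in words)


def generate(spec: CorpusSpec, out_dir: str | Path) -> GeneratedCorpus:
    """Generate the corpus CSV, ground-truth JSON and mini category XML.

    Clean papers are generated first (ground truth is defined on them);
    noise is then layered on: keyword spelling variants replace occurrences
    in-place (always leaving at least one clean occurrence so the
    conservative hyphen-merge rule can fire), duplicate rows are appended
    copies sharing the DOI, and invalid rows (missing essential fields) are
    appended junk. The cleaning pipeline therefore recovers the ledger
    counts exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    vocab = _build_vocabulary(spec)
    n = len(vocab)

    # contiguous blocks over the vocabulary
    cuts = np.linspace(0, n, spec.n_blocks + 1).astype(int)
    blocks = [vocab[cuts[i]: cuts[i + 1]] for i in range(spec.n_blocks)]
    block_of = {}
    for bi, block in enumerate(blocks):
        for kw in block:
            block_of[kw] = bi

    probs = _bin_block_probs(spec, vocab, blocks)
    vocab_arr = np.array(vocab, dtype=object)
    if spec.prob_model == "uniform":
        block_weights = np.array([float(len(b)) for b in blocks])
    else:
        block_weights = np.array(
            [sum(1.0 / (vocab.index(kw) + 2.0) for kw in b) for b in blocks]
        )
    block_weights /= block_weights.sum()

    gt = GroundTruth(
        vocabulary=list(vocab),
        trending_keywords=sorted(spec.trend_map),
        blocks=[list(b) for b in blocks],
        geneword_families={k: list(v) for k, v in spec.geneword_families.items()},
    )

    papers = []  # (year, title, keywords, countries)
    pid = 0
    hits = {kw: [0] * len(spec.bins) for kw in vocab}
    for b, ((y0, y1), n_papers) in enumerate(zip(spec.bins, spec.papers_per_bin)):
        for _ in range(n_papers):
            k = max(1, rng.poisson(spec.keywords_per_paper))
            k = min(k, n - 1)
            blk = int(rng.choice(spec.n_blocks, p=block_weights))
            kws = list(rng.choice(vocab_arr, size=k, replace=False, p=probs[b][blk]))
            year = int(rng.integers(y0, y1 + 1))
            if rng.random() < spec.international_rate:
                countries = list(rng.choice(_COUNTRY_POOL, size=2, replace=False))
            else:
                countries = [str(rng.choice(_COUNTRY_POOL))]
            papers.append(
                {
                    "pid": pid,
                    "year": year,
                    "bin": b,
                    "keywords": kws,
                    "countries": countries,
                    "n_authors": 1 + int(rng.poisson(3)),
                }
            )
            for kw in kws:
                hits[kw][b] += 1
            pid += 1
    gt.n_papers_clean = len(papers)
    for kw in vocab:
        gt.relative_frequency[kw] = [
            100.0 * hits[kw][b] / spec.papers_per_bin[b] for b in range(len(spec.bins))
        ]

    # --- keyword spelling noise (in-place, guarded) --------------------
    plain_left = {kw: sum(hits[kw]) for kw in vocab}
    n_hyphen = n_accent = 0
    for paper in papers:
        noisy = []
        for kw in paper["keywords"]:
            if (
                spec.hyphen_variant_rate > 0
                and plain_left[kw] > 1
                and _hyphen(kw) != kw
                and rng.random() < spec.hyphen_variant_rate
            ):
                noisy.append(_hyphen(kw))
                plain_left[kw] -= 1
                n_hyphen += 1
            elif (
                spec.accent_variant_rate > 0
                and _accent(kw) != kw
                and rng.random() < spec.accent_variant_rate
            ):
                noisy.append(_accent(kw))
                n_accent += 1
            else:
                noisy.append(kw)
        paper["noisy_keywords"] = noisy
    gt.n_hyphen_variants_injected = n_hyphen
    gt.n_accent_variants_injected = n_accent

    # --- row-level noise ------------------------------------------------
    rows = [_paper_row(p, rng) for p in papers]
    n_dup = 0
    if spec.duplicate_rate > 0:
        dup_rows = []
        for row in rows:
            if rng.random() < spec.duplicate_rate:
                dup_rows.append(list(row))
                n_dup += 1
        rows.extend(dup_rows)
    gt.n_duplicates_injected = n_dup

    n_invalid = 0
    if spec.missing_field_rate > 0:
        n_invalid = int(rng.binomial(len(papers), spec.missing_field_rate))
        for j in range(n_invalid):
            year = int(rng.integers(spec.bins.bins[0][0], spec.bins.bins[-1][1] + 1))
            rows.append(
                ["", f"Invalid record {j}", str(year), "", "", "", "Journal of Synthetic Research", "", ""]
            )  # no authors, no keywords -> removed by the validity filter
    gt.n_invalid_injected = n_invalid

    csv_path = out_dir / "corpus.csv"
    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(_SCOPUS_HEADER) + "\r\n")
        for row in rows:
            fh.write(",".join(_quote(c) for c in row) + "\r\n")

    gt.categories = {
        kw: (f"category {block_of[kw]}", f"subcategory {block_of[kw]}.0") for kw in vocab
    }
    xml_path = write_mini_mesh_xml(vocab, block_of, out_dir / "mesh_mini.xml")
    gt_path = gt.to_json(out_dir / "ground_truth.json")
    return GeneratedCorpus(
        csv_path=csv_path, ground_truth=gt, mesh_xml_path=xml_path, ground_truth_path=gt_path
    )


def _quote(cell: str) -> str:
    cell = str(cell)
    if any(c in cell for c in ',"\n'):
        return '"' + cell.replace('"', '""') + '"'
    return cell


def _paper_row(paper: dict, rng: np.random.Generator) -> list[str]:
    pid = paper["pid"]
    authors = "; ".join(f"Author {pid}.{i}" for i in range(paper["n_authors"]))
    affils = "; ".join(
        f"Department of Research, University {pid % 40}, City, {country}"
        for country in paper["countries"]
    )
    title = f"A study of {paper['keywords'][0]} (paper {pid})"
    return [
        authors,
        title,
        str(paper["year"]),
        "; ".join(paper.get("noisy_keywords", paper["keywords"])),
        affils,
        f"10.9999/synth.{pid}",
        "Journal of Synthetic Research",
        str(int(rng.poisson(10))),
        "",
    ]


def write_mini_mesh_xml(vocab: list[str], block_of: dict[str, int], path: str | Path) -> Path:
    """Emit a small category tree in MeSH descriptor XML schema.

    Each community block becomes a level-1 category with one level-2
    subcategory; every vocabulary keyword is a descriptor beneath its
    block's subcategory.
    """
    from lxml import etree

    root = etree.Element("DescriptorRecordSet")
    n_blocks = max(block_of.values()) + 1 if block_of else 0

    def add_descriptor(name: str, tree_numbers: list[str]):
        rec = etree.SubElement(root, "DescriptorRecord")
        dn = etree.SubElement(etree.SubElement(rec, "DescriptorName"), "String")
        dn.text = name
        tnl = etree.SubElement(rec, "TreeNumberList")
        for tn in tree_numbers:
            etree.SubElement(tnl, "TreeNumber").text = tn

    for b in range(n_blocks):
        add_descriptor(f"category {b}", [f"C{b:02d}"])
        add_descriptor(f"subcategory {b}.0", [f"C{b:02d}.100"])
    for i, kw in enumerate(vocab):
        b = block_of[kw]
        add_descriptor(kw, [f"C{b:02d}.100.{i:03d}"])

    path = Path(path)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    return path
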