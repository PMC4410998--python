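"""Reading, cleaning and persisting bibliographic records.

The cleaning pipeline mirrors standard bibliometric practice in three
stages: a validity filter (records missing essential fields are dropped),
duplicate removal (by DOI, then by normalised title), text normalisation
(accent folding, lowercasing, country canonicalisation) and keyword-variant
merging (punctuation variants and a user-supplied synonym map). Every
removal and merge is counted in a :class:`~coword.records.CleaningReport`
so synthetic-corpus ledgers can be checked exactly.
"""

from __future__ import annotations

import csv
import logging
import re
import sqlite3
import unicodedata
from collections import Counter
from pathlib import Path

from coword._countries import canonical_country
from coword.records import CleaningReport, PaperRecord, SynonymMap

logger = logging.getLogger(__name__)

#: Default Scopus CSV export column names -> record fields.
DEFAULT_COLUMNS = {
    "authors": "Authors",
    "title": "Title",
    "year": "Year",
    "keywords": "Author Keywords",
    "affiliations": "Affiliations",
    "doi": "DOI",
    "journal": "Source title",
    "citation_count": "Cited by",
    "funding_text": "Funding Details",
}

#: Scopus multi-value field separator.
DEFAULT_SEPARATOR = "; "

_WS = re.compile(r"\s+")
_PUNCT = re.compile(r"[^\w\s]")


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


def _split_multi(value: str, separator: str) -> list[str]:
    if not value:
        return []
    return [part.strip() for part in value.split(separator.strip()) if part.strip()]


def read_records(
    csv_paths: list[str | Path],
    columns: dict[str, str] | None = None,
    separator: str = DEFAULT_SEPARATOR,
    report: CleaningReport | None = None,
) -> list[PaperRecord]:
    """Read Scopus-dialect CSV exports into raw :class:`PaperRecord` objects.

    Multi-value fields (authors, keywords, affiliations) are split on
    ``separator`` and trimmed. Rows whose year cell cannot be parsed are
    skipped and counted under the ``unreadable_row`` rule. Rows are kept in
    file order; the record id is ``<file-stem>:<row-number>``.

    Raises
    ------
    FormatError
        If a file lacks the required header columns.
    """
    columns = {**DEFAULT_COLUMNS, **(columns or {})}
    records: list[PaperRecord] = []
    for path in csv_paths:
        path = Path(path)
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise FormatError(f"{path}: empty file, no header row")
            required = {columns["title"], columns["year"]}
            missing = required - set(reader.fieldnames)
            if missing:
                raise FormatError(f"{path}: missing header column(s) {sorted(missing)}")
            for i, row in enumerate(reader):
                year_raw = (row.get(columns["year"]) or "").strip()
                try:
                    year = int(float(year_raw))
                except ValueError:
                    logger.debug("%s row %d: unreadable year %r, skipped", path, i, year_raw)
                    if report is not None:
                        report.n_read += 1
                        report.n_invalid_removed += 1
                        report.bump("unreadable_row")
                    continue
                cites_raw = (row.get(columns["citation_count"]) or "").strip()
                try:
                    cites = int(float(cites_raw)) if cites_raw else None
                except ValueError:
                    cites = None
                records.append(
                    PaperRecord(
                        record_id=f"{path.stem}:{i}",
                        title=(row.get(columns["title"]) or "").strip(),
                        year=year,
                        authors=_split_multi(row.get(columns["authors"]) or "", separator),
                        affiliations=_split_multi(
                            row.get(columns["affiliations"]) or "", separator
                        ),
                        keywords=_split_multi(row.get(columns["keywords"]) or "", separator),
                        doi=(row.get(columns["doi"]) or "").strip() or None,
                        journal=(row.get(columns["journal"]) or "").strip() or None,
                        citation_count=cites,
                        funding_text=(row.get(columns["funding_text"]) or "").strip() or None,
                    )
                )
                if report is not None:
                    report.n_read += 1
    return records


def filter_invalid(
    records: list[PaperRecord],
    year_range: tuple[int, int] | None = None,
) -> tuple[list[PaperRecord], CleaningReport]:
    """Drop records missing essential fields (title, authors, year, keywords).

    Optionally also drops records outside ``year_range`` (inclusive); the
    query-time language/document-type filters are assumed done upstream.
    """
    report = CleaningReport(n_read=len(records))
    kept: list[PaperRecord] = []
    for rec in records:
        rule = None
        if not rec.title.strip():
            rule = "missing_title"
        elif not rec.authors:
            rule = "missing_authors"
        elif not rec.keywords:
            rule = "missing_keywords"
        elif year_range is not None and not (year_range[0] <= rec.year <= year_range[1]):
            rule = "year_out_of_range"
        if rule:
            report.n_invalid_removed += 1
            report.bump(rule)
        else:
            kept.append(rec)
    report.n_retained = len(kept)
    logger.info("validity filter: %d read, %d removed", report.n_read, report.n_invalid_removed)
    return kept, report


def _normalized_title(title: str) -> str:
    t = _strip_accents(title).lower()
    t = _PUNCT.sub(" ", t)
    return _WS.sub(" ", t).strip()


def deduplicate(records: list[PaperRecord]) -> tuple[list[PaperRecord], CleaningReport]:
    """Remove duplicate records; the first occurrence wins.

    Records sharing a DOI (exact, case-insensitive) are duplicates. Among
    DOI-less records, records sharing a normalised title (lowercased,
    punctuation and extra whitespace stripped) are duplicates. DOI matching
    takes precedence over title matching.
    """
    report = CleaningReport(n_read=len(records))
    seen_doi: set[str] = set()
    seen_title: set[str] = set()
    kept: list[PaperRecord] = []
    for rec in records:
        if rec.doi:
            key = rec.doi.strip().lower()
            if key in seen_doi:
                report.n_duplicates_removed += 1
                report.bump("duplicate_doi")
                continue
            seen_doi.add(key)
        else:
            key = _normalized_title(rec.title)
            if key in seen_title:
                report.n_duplicates_removed += 1
                report.bump("duplicate_title")
                continue
            seen_title.add(key)
        kept.append(rec)
    report.n_retained = len(kept)
    logger.info("dedup: %d removed", report.n_duplicates_removed)
    return kept, report


def _strip_accents(text: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFKD", text) if not unicodedata.combining(c)
    )


def canonical_keyword(keyword: str) -> str:
    """Canonical keyword form: lowercase, accent-folded, whitespace-collapsed."""
    k = _strip_accents(keyword).lower().strip()
    return _WS.sub(" ", k)


def normalize_text(
    record: PaperRecord,
    country_aliases: dict[str, str] | None = None,
) -> PaperRecord:
    """Fold accents, lowercase keywords and derive canonical countries.

    Keywords are put into canonical form (lowercase, accents folded, e.g.
    ``café-au-lait`` -> ``cafe-au-lait``); affiliations keep their case but
    lose accents. Countries are extracted from the last comma-separated
    token of each affiliation string via the canonical country vocabulary
    and alias table (``Brasil`` -> ``Brazil``); unmatched tokens yield no
    country. Occurrence counts are untouched (pure renaming).
    """
    rec = record.copy()
    rec.keywords = [canonical_keyword(k) for k in rec.keywords]
    rec.affiliations = [_WS.sub(" ", _strip_accents(a)).strip() for a in rec.affiliations]
    countries: set[str] = set()
    for aff in rec.affiliations:
        token = aff.rsplit(",", 1)[-1]
        c = canonical_country(token, country_aliases)
        if c:
            countries.add(c)
    rec.countries = countries
    return rec


def merge_keyword_variants(
    records: list[PaperRecord],
    synonyms: SynonymMap | None = None,
) -> tuple[list[PaperRecord], CleaningReport]:
    """Collapse punctuation variants and apply the synonym map.

    A hyphenated keyword (``hyper-tension``) is merged into its dashless
    form only when that form already occurs in the corpus — a conservative
    rule that avoids false merges. Synonym-map variants are replaced by
    their canonical name. Within-record duplicates produced by merging are
    collapsed (the only way total keyword-occurrence count changes).
    """
    synonyms = synonyms or SynonymMap()
    report = CleaningReport(n_read=len(records), n_retained=len(records))

    vocab = {k for rec in records for k in rec.keywords}
    out: list[PaperRecord] = []
    for rec in records:
        rec = rec.copy()
        merged: list[str] = []
        for kw in rec.keywords:
            new = kw
            if "-" in new:
                dashless = _WS.sub(" ", new.replace("-", " ")).strip()
                joined = new.replace("-", "")
                if joined in vocab:
                    new = joined
                elif dashless in vocab:
                    new = dashless
            mapped = synonyms.canonical(new)
            if mapped != new:
                new = mapped
            if new != kw:
                report.n_keyword_variants_merged += 1
                report.bump("variant_merged")
            merged.append(new)
        deduped: list[str] = []
        seen: set[str] = set()
        for kw in merged:
            if kw in seen:
                report.bump("within_record_duplicate_collapsed")
                continue
            seen.add(kw)
            deduped.append(kw)
        rec.keywords = deduped
        out.append(rec)
    logger.info("variant merge: %d occurrences renamed", report.n_keyword_variants_merged)
    return out, report


def clean(
    records: list[PaperRecord],
    synonyms: SynonymMap | None = None,
    year_range: tuple[int, int] | None = None,
    country_aliases: dict[str, str] | None = None,
) -> tuple[list[PaperRecord], CleaningReport]:
    """Full cleaning pipeline: validity filter -> dedup -> normalise -> merge.

    Idempotent: applying the pipeline to its own output is the identity (up
    to a report with zero removals).
    """
    records, rep1 = filter_invalid(records, year_range=year_range)
    records, rep2 = deduplicate(records)
    records = [normalize_text(r, country_aliases) for r in records]
    records, rep3 = merge_keyword_variants(records, synonyms)
    report = rep1.merge(rep2).merge(rep3)
    report.n_read = rep1.n_read
    report.n_retained = len(records)
    return records, report


# ---------------------------------------------------------------------------
# Relational store (single-file SQLite)

_SCHEMA = """
CREATE TABLE papers (
    record_id TEXT PRIMARY KEY, title TEXT NOT NULL, year INTEGER NOT NULL,
    doi TEXT, journal TEXT, citation_count INTEGER, funding_text TEXT
);
CREATE TABLE authors (
    record_id TEXT REFERENCES papers(record_id), position INTEGER, name TEXT
);
CREATE TABLE keywords (keyword_id INTEGER PRIMARY KEY, keyword TEXT UNIQUE);
CREATE TABLE paper_keyword (
    record_id TEXT REFERENCES papers(record_id), position INTEGER,
    keyword_id INTEGER REFERENCES keywords(keyword_id)
);
CREATE TABLE affiliations (
    record_id TEXT REFERENCES papers(record_id), position INTEGER, affiliation TEXT
);
CREATE TABLE paper_country (record_id TEXT REFERENCES papers(record_id), country TEXT);
"""


def persist(records: list[PaperRecord], store_path: str | Path) -> Path:
    """Write records to a single-file relational store (SQLite).

    The store is normalised: papers, authors, keywords (unique), a
    paper-keyword link table, affiliations and derived countries, joined by
    relational keys. An existing file at ``store_path`` is replaced.
    """
    store_path = Path(store_path)
    if store_path.exists():
        store_path.unlink()
    con = sqlite3.connect(store_path)
    try:
        con.executescript(_SCHEMA)
        kw_ids: dict[str, int] = {}
        for rec in records:
            con.execute(
                "INSERT INTO papers VALUES (?,?,?,?,?,?,?)",
                (rec.record_id, rec.title, rec.year, rec.doi, rec.journal,
                 rec.citation_count, rec.funding_text),
            )
            con.executemany(
                "INSERT INTO authors VALUES (?,?,?)",
                [(rec.record_id, i, a) for i, a in enumerate(rec.authors)],
            )
            con.executemany(
                "INSERT INTO affiliations VALUES (?,?,?)",
                [(rec.record_id, i, a) for i, a in enumerate(rec.affiliations)],
            )
            con.executemany(
                "INSERT INTO paper_country VALUES (?,?)",
                [(rec.record_id, c) for c in sorted(rec.countries)],
            )
            for i, kw in enumerate(rec.keywords):
                if kw not in kw_ids:
                    cur = con.execute("INSERT INTO keywords (keyword) VALUES (?)", (kw,))
                    kw_ids[kw] = cur.lastrowid
                con.execute(
                    "INSERT INTO paper_keyword VALUES (?,?,?)",
                    (rec.record_id, i, kw_ids[kw]),
                )
        con.commit()
    finally:
        con.close()
    return store_path


def load(store_path: str | Path) -> list[PaperRecord]:
    """Load records from a store written by :func:`persist` (lossless)."""
    con = sqlite3.connect(store_path)
    try:
        recs: dict[str, PaperRecord] = {}
        for row in con.execute("SELECT * FROM papers"):
            rid, title, year, doi, journal, cites, funding = row
            recs[rid] = PaperRecord(
                record_id=rid, title=title, year=year, doi=doi,
                journal=journal, citation_count=cites, funding_text=funding,
            )
        for rid, _, name in con.execute("SELECT * FROM authors ORDER BY record_id, position"):
            recs[rid].authors.append(name)
        for rid, _, aff in con.execute(
            "SELECT * FROM affiliations ORDER BY record_id, position"
        ):
            recs[rid].affiliations.append(aff)
        for rid, country in con.execute("SELECT * FROM paper_country"):
            recs[rid].countries.add(country)
        for rid, _, kw in con.execute(
            "SELECT pk.record_id, pk.position, k.keyword FROM paper_keyword pk "
            "JOIN keywords k ON k.keyword_id = pk.keyword_id "
            "ORDER BY pk.record_id, pk.position"
        ):
            recs[rid].keywords.append(kw)
        return list(recs.values())
    finally:
        con.close()


def keyword_occurrences(records: list[PaperRecord]) -> Counter:
    """Corpus-wide keyword -> number of papers containing it (binary per paper)."""
    counts: Counter = Counter()
    for rec in records:
        counts.update(set(rec.keywords))
    return counts
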