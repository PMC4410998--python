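"""Reading, cleaning and persisting bibliographic records."""

import pytest

from coword import ingest
from coword.records import CleaningReport, SynonymMap
from tests.conftest import make_record

HEADER = "Authors,Title,Year,Author Keywords,Affiliations,DOI,Source title,Cited by,Funding Details\n"


def write_csv(tmp_path, rows, name="export.csv", header=HEADER):
    path = tmp_path / name
    path.write_text(header + "".join(rows), encoding="utf-8")
    return path


class TestReadRecords:
    def test_header_only_yields_empty_list(self, tmp_path):
        path = write_csv(tmp_path, [])
        assert ingest.read_records([path]) == []

    def test_multivalue_fields_split_and_trimmed(self, tmp_path):
        path = write_csv(
            tmp_path,
            ['Smith J.; Doe A.,T,2001,Obesity; Leptin,"Uni, Brazil",10.1/x,J,3,\n'],
        )
        (rec,) = ingest.read_records([path])
        assert rec.keywords == ["Obesity", "Leptin"]
        assert rec.authors == ["Smith J.", "Doe A."]
        assert rec.year == 2001
        assert rec.doi == "10.1/x"

    def test_row_with_missing_year_skipped_and_counted(self, tmp_path):
        rows = [
            "A.,T1,2001,k1,,,,,\n",
            "B.,T2,,k2,,,,,\n",  # no year -> unreadable
            "C.,T3,2003,k3,,,,,\n",
        ]
        path = write_csv(tmp_path, rows)
        report = CleaningReport()
        records = ingest.read_records([path], report=report)
        assert [r.title for r in records] == ["T1", "T3"]
        assert report.per_rule_counts["unreadable_row"] == 1

    def test_missing_header_is_format_error(self, tmp_path):
        path = write_csv(tmp_path, ["a,b\n"], header="Foo,Bar\n")
        with pytest.raises(ingest.FormatError):
            ingest.read_records([path])


class TestFilterInvalid:
    def test_all_valid_is_identity(self):
        records = [make_record(i, keywords=["k"]) for i in range(3)]
        kept, report = ingest.filter_invalid(records)
        assert kept == records
        assert report.n_invalid_removed == 0

    def test_empty_authors_removed(self):
        records = [make_record(i, keywords=["k"]) for i in range(3)] + [
            make_record(9, keywords=["k"], authors=()),
            make_record(10, keywords=["k"], authors=()),
        ]
        kept, report = ingest.filter_invalid(records)
        assert len(kept) == 3
        assert report.per_rule_counts["missing_authors"] == 2

    def test_empty_keywords_removed(self):
        kept, report = ingest.filter_invalid([make_record(1, keywords=())])
        assert kept == []
        assert report.per_rule_counts["missing_keywords"] == 1

    def test_ledger_balances(self):
        records = [make_record(1, keywords=["k"]), make_record(2, keywords=())]
        kept, report = ingest.filter_invalid(records)
        assert report.n_read == report.n_retained + report.n_invalid_removed


class TestDeduplicate:
    def test_same_doi_keeps_first(self):
        a = make_record(1, keywords=["k"], doi="10.1/X")
        b = make_record(2, keywords=["k"], doi="10.1/x")
        kept, report = ingest.deduplicate([a, b])
        assert kept == [a]
        assert report.n_duplicates_removed == 1

    def test_distinct_records_untouched(self):
        records = [make_record(i, title=f"T{i}", keywords=["k"]) for i in range(4)]
        kept, report = ingest.deduplicate(records)
        assert kept == records and report.n_duplicates_removed == 0

    def test_punctuation_stripped_but_no_word_substitution(self):
        # "&" is stripped, not rewritten to "and": the two titles differ
        a = make_record(1, title="Obesity & Diabetes", keywords=["k"])
        b = make_record(2, title="obesity and diabetes", keywords=["k"])
        kept, _ = ingest.deduplicate([a, b])
        assert len(kept) == 2
        # whereas pure punctuation/case variants do merge
        c = make_record(3, title="Obesity, diabetes!", keywords=["k"])
        d = make_record(4, title="obesity diabetes", keywords=["k"])
        kept, _ = ingest.deduplicate([c, d])
        assert len(kept) == 1

    def test_no_two_survivors_share_doi_or_title(self):
        records = [
            make_record(1, title="Alpha", keywords=["k"], doi="10/a"),
            make_record(2, title="Alpha", keywords=["k"]),
            make_record(3, title="alpha.", keywords=["k"]),
            make_record(4, title="Beta", keywords=["k"], doi="10/a"),
        ]
        kept, _ = ingest.deduplicate(records)
        dois = [r.doi for r in kept if r.doi]
        titles = [r.title.lower().strip(".") for r in kept if not r.doi]
        assert len(dois) == len(set(dois)) and len(titles) == len(set(titles))


class TestNormalizeText:
    def test_accents_folded_in_keywords(self):
        rec = make_record(1, keywords=["Café-au-lait"])
        assert ingest.normalize_text(rec).keywords == ["cafe-au-lait"]

    def test_country_alias_brasil(self):
        rec = make_record(1, keywords=["k"],
                          affiliations=["Universidade, Sao Paulo, Brasil"])
        assert ingest.normalize_text(rec).countries == {"Brazil"}

    def test_ascii_record_unchanged(self):
        rec = make_record(1, keywords=["obesity"], affiliations=["Uni, Australia"])
        out = ingest.normalize_text(rec)
        assert out.keywords == ["obesity"] and out.countries == {"Australia"}

    def test_unmatched_country_token_yields_nothing(self):
        rec = make_record(1, keywords=["k"], affiliations=["Somewhere, Atlantis"])
        assert ingest.normalize_text(rec).countries == set()

    def test_occurrence_count_conserved(self):
        rec = make_record(1, keywords=["á", "b", "é"])
        assert len(ingest.normalize_text(rec).keywords) == 3


class TestMergeKeywordVariants:
    def test_hyphen_variant_merged_when_dashless_exists(self):
        records = [
            make_record(1, keywords=["hypertension"]),
            make_record(2, keywords=["hyper-tension"]),
        ]
        out, report = ingest.merge_keyword_variants(records)
        assert out[1].keywords == ["hypertension"]
        assert report.n_keyword_variants_merged == 1

    def test_hyphen_kept_when_dashless_absent(self):
        records = [make_record(1, keywords=["cafe-au-lait"])]
        out, report = ingest.merge_keyword_variants(records)
        assert out[0].keywords == ["cafe-au-lait"]
        assert report.n_keyword_variants_merged == 0

    def test_synonym_map_applied(self):
        syn = SynonymMap({"calcifediol": ["25-hydroxy vitamin d"]})
        records = [make_record(1, keywords=["25-hydroxy vitamin d"])]
        out, _ = ingest.merge_keyword_variants(records, syn)
        assert out[0].keywords == ["calcifediol"]

    def test_empty_map_no_variants_is_identity(self):
        records = [make_record(1, keywords=["obesity", "leptin"])]
        out, report = ingest.merge_keyword_variants(records)
        assert out[0].keywords == ["obesity", "leptin"]
        assert report.n_keyword_variants_merged == 0

    def test_merge_collapse_accounted_in_ledger(self):
        # merging creates a within-record duplicate, which is collapsed
        syn = SynonymMap({"obesity": ["adiposity"]})
        records = [make_record(1, keywords=["obesity", "adiposity"])]
        out, report = ingest.merge_keyword_variants(records, syn)
        assert out[0].keywords == ["obesity"]
        before = 2
        collapsed = report.per_rule_counts.get("within_record_duplicate_collapsed", 0)
        assert sum(len(r.keywords) for r in out) == before - collapsed == 1


class TestSynonymMapInvariants:
    def test_variant_under_two_canonicals_rejected(self):
        with pytest.raises(ValueError):
            SynonymMap({"a": ["x"], "b": ["x"]})

    def test_canonical_listed_as_variant_rejected(self):
        with pytest.raises(ValueError):
            SynonymMap({"a": ["b"], "b": ["c"]})

    def test_from_csv(self, tmp_path):
        path = tmp_path / "syn.csv"
        path.write_text("canonical,variant\ncalcifediol,calcidiol\n")
        m = SynonymMap.from_csv(path)
        assert m.canonical("calcidiol") == "calcifediol"


class TestCleanPipeline:
    def test_idempotent(self):
        records = [
            make_record(1, keywords=["Hypertension"]),
            make_record(2, keywords=["hyper-tension", "Léptin"]),
            make_record(3, keywords=["leptin"], doi="10/a"),
            make_record(4, keywords=["x"], doi="10/a"),
            make_record(5, keywords=()),
        ]
        once, rep1 = ingest.clean(records)
        twice, rep2 = ingest.clean([r.copy() for r in once])
        assert [r.keywords for r in twice] == [r.keywords for r in once]
        assert rep2.n_invalid_removed == rep2.n_duplicates_removed == 0
        assert rep2.n_keyword_variants_merged == 0

    def test_report_balances(self):
        records = [make_record(1, keywords=["k"]), make_record(2, keywords=()),
                   make_record(3, keywords=["k"], title="Paper 1")]
        _, report = ingest.clean(records)
        assert report.n_read == (report.n_retained + report.n_invalid_removed
                                 + report.n_duplicates_removed)


class TestPersistence:
    def test_round_trip_is_lossless(self, tmp_path, small_corpus):
        store = tmp_path / "corpus.db"
        ingest.persist(small_corpus, store)
        loaded = sorted(ingest.load(store), key=lambda r: r.record_id)
        original = sorted(small_corpus, key=lambda r: r.record_id)
        assert loaded == original

    def test_empty_store(self, tmp_path):
        store = ingest.persist([], tmp_path / "empty.db")
        assert ingest.load(store) == []

    def test_keyword_and_link_table_shapes(self, tmp_path):
        import sqlite3

        records = [
            make_record(1, keywords=["a", "b", "c"]),
            make_record(2, keywords=["a", "b", "c"]),
        ]
        store = ingest.persist(records, tmp_path / "s.db")
        con = sqlite3.connect(store)
        assert con.execute("SELECT COUNT(*) FROM keywords").fetchone()[0] == 3
        assert con.execute("SELECT COUNT(*) FROM paper_keyword").fetchone()[0] == 6
        con.close()
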