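import pytest

from coword.binning import TimeBinning
from coword.records import PaperRecord


def make_record(rid, year=2000, title=None, keywords=(), authors=("Author A.",),
                countries=(), doi=None, affiliations=()):
    return PaperRecord(
        record_id=str(rid),
        title=title or f"Paper {rid}",
        year=year,
        authors=list(authors),
        affiliations=list(affiliations),
        countries=set(countries),
        keywords=list(keywords),
        doi=doi,
    )


@pytest.fixture
def four_bins():
    return TimeBinning.from_spec("1993-1997,1998-2002,2003-2007,2008-2012")


@pytest.fixture
def small_corpus():
    """Six papers across two bins with a known co-occurrence pattern."""
    return [
        make_record(1, 1995, keywords=["obesity", "leptin"], countries={"United States"}),
        make_record(2, 1996, keywords=["obesity", "diabetes", "leptin"],
                    countries={"United States", "United Kingdom"}),
        make_record(3, 1997, keywords=["diabetes"], countries={"Australia"}),
        make_record(4, 1999, keywords=["obesity", "insulin resistance"],
                    countries={"Brazil"}),
        make_record(5, 2000, keywords=["leptin", "insulin resistance"],
                    countries={"China"}),
        make_record(6, 2001, keywords=["obesity"], countries={"China", "India"}),
    ]
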