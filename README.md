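# coword

Co-word analysis of bibliographic metadata: a library and CLI for exploring
how the knowledge structure of a research field evolves, using nothing but
the metadata a bibliographic database (Scopus-style CSV export) already
provides — titles, author keywords, affiliations, years.

It is aimed at bibliometricians, domain scientists and policy analysts who
want longitudinal answers from a keyword corpus: which topics are growing
or dying, how topics group into sub-domains, which topics are studied
together, and which stem terms ("gene-words") spawn whole keyword families.

## What it computes

Papers are grouped into time bins (conventionally four 5-year spans). For a
keyword (or keyword pair) with per-bin relative frequencies
*f*<sub>1</sub> … *f*<sub>n</sub> (percent of papers in the bin containing
it), its **relative growth** is

    Growth = 100 · Σ_{i=1}^{n-1} (f_{i+1} − f_i) / f_i   [%]

with zero-denominator terms skipped. Growth values are standardised against
the population of all analysed subjects, *z* = (X − X̄)/s, and converted to
a one-sided normal tail probability; subjects with *p* < 0.01 are flagged
as significantly rising or falling.

Around this core the package provides:

- **ingest** — Scopus-dialect CSV reading, a three-stage cleaning pipeline
  (validity filter → DOI/title dedup → accent/country normalisation →
  keyword-variant and synonym merging) with an exact ledger of every
  removal, and a single-file SQLite relational store;
- **descriptive** — per-bin paper counts, authors per paper, international
  collaboration (papers with authors from ≥ 2 countries), country and
  top-keyword tables;
- **categorize** — keyword → broad-category mapping through a MeSH-style
  descriptor XML hierarchy, keeping the top two tree levels;
- **network** — per-bin keyword co-occurrence graphs (edge weight = papers
  containing both keywords), the five summary statistics (edges, average
  weighted degree = mean edge weight, density, modularity of a detected
  community partition, average clustering coefficient), a knowledge-map
  layout with a 0–2 blue→green→red density score, and GraphML / Pajek /
  VOSviewer export;
- **geneword** — extraction of stem keywords by the three gene-word rules
  (frequency > 100 and top-100 rank; ≥ 10 derived keywords each with
  frequency > 10 and a dominant aggregate share; membership of a curated
  priority list), with family statistics tables;
- **synthetic** — a corpus generator with planted trends, community blocks,
  gene-word families and ledgered noise, so every stage is testable with
  known ground truth.

## Worked example

Generate a synthetic corpus with one keyword whose selection probability
triples every bin, clean it, and rank keywords by growth:

```bash
cat > spec.yaml <<'YAML'
papers_per_bin: [150, 300, 600, 1200]
n_vocab: 60
trend_map:
  'topic 030': [1.0, 3.0, 9.0, 27.0]
YAML
coword simulate --spec spec.yaml --seed 5 --out sim   # corpus.csv + ground truth
coword ingest sim/corpus.csv --store corpus.db
coword trend --store corpus.db --bins 1993-1997,1998-2002,2003-2007,2008-2012
```

The top of `trend_out/growth_keywords_up.csv` then reads:

```
subject,1993-1997 (%),1998-2002 (%),2003-2007 (%),2008-2012 (%),growth_pct,p_tail,significant
topic 030,2.0,9.67,9.5,25.33,548.28,2.263970780634762e-05,True
```

The planted riser ranks first: its relative frequency climbs from 2% to
25% of papers, the summed period-to-period increments give a growth of
about +548%, and its tail probability is far below the 0.01 significance
gate. Keywords without a planted trend fall off quickly down the ranking
and most carry `significant,False`.

The same store feeds the other stages, e.g.

```bash
coword network --store corpus.db --bin 2008-2012 --min-freq 5 --export graphml,vos
coword geneword --store corpus.db --bins 1993-1997,1998-2002,2003-2007,2008-2012
```

which print the five network statistics as JSON and write the gene-word
family table.

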