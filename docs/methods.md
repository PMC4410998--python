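# Methods

This note documents the statistical and algorithmic choices behind the
package: what each stage computes, the assumptions it makes, the defaults
and why, and what the synthetic-corpus tests do and do not demonstrate
about real bibliographic data.

## Cleaning model

The ingest pipeline assumes a Scopus-style CSV export: one row per
article; multi-value fields (authors, keywords, affiliations) joined with
`"; "`; column names remappable through a configuration mapping. Cleaning
runs in a fixed order — validity filter, duplicate removal, text
normalisation, keyword-variant merging — because each stage's rules assume
the previous stage's invariants (e.g. variant merging operates on
accent-folded lowercase keywords).

Specific rules and their rationale:

- **Validity.** Records missing a title, author list, year or keyword list
  are dropped; these fields are what every later stage consumes.
  Language/document-type filters are assumed applied at query time; an
  optional year-range filter handles incompletely indexed boundary years.
- **Duplicates.** Exact case-insensitive DOI match wins over normalised
  title match (lowercase, punctuation and repeated whitespace stripped);
  the first occurrence is kept. Title normalisation deliberately performs
  no word substitution ("&" is stripped, never rewritten to "and"): false
  merges are more damaging than missed ones at corpus scale.
- **Keyword canonical form.** Lowercase, Unicode accents folded to ASCII
  (NFKD), whitespace collapsed. Hyphenated variants are merged only when
  the dashless form already occurs in the corpus — a conservative rule
  that cannot invent new keywords. Synonym merging is driven entirely by a
  user-supplied two-column map; no fuzzy matching is attempted, because
  near-miss merging of biomedical terms needs domain review.
- **Countries.** The last comma-separated token of each affiliation is
  matched against a canonical country vocabulary plus an alias table
  (`Brasil → Brazil`, `UK → United Kingdom`, …). Unmatched tokens yield no
  country rather than a guess; international-collaboration shares are
  therefore lower bounds when affiliations are malformed.

Every removal or merge increments a named counter, and the report
satisfies `n_read = n_retained + n_invalid + n_duplicates` exactly; the
synthetic-corpus tests check these ledgers against the generator's
injection counts with equality, not tolerance.

## Growth and significance

Keyword frequencies are **relative per-bin percentages** (share of the
bin's papers containing the keyword), which normalises out corpus growth —
essential when publication counts double every bin. Counting is binary per
paper. A raw-count mode exists behind a flag for sensitivity checks.

Growth sums period-to-period relative increments. The ratio is undefined
where `f_i = 0`; such terms are **skipped** (and the number of summed
terms reported) rather than treated as 0 or infinity. Skipping keeps the
statistic finite for keywords that appear mid-period — the common case for
emerging topics — at the price of understating their early growth; the
alternative (dropping such keywords) would hide exactly the topics the
analysis is for. Consequences that the property tests pin down: constant
series give 0, uniform positive rescaling changes nothing, and a series
starting at zero contributes only its nonzero suffix.

The z-score needs a reference population; the package uses **the growth
values of all subjects passing the frequency filter in the same run**,
with sample standard deviation (ddof = 1) and a one-sided tail in the
direction of the deviation. Note the implication: flagging at α = 0.01
marks |z| > 2.33, which under a perfectly normal population flags 2% of
subjects (1% per tail), not 1%. The growth statistic is a sum of ratios
of binomial proportions and is slightly heavy-tailed at finite counts, so
null calibration runs a little above 2% (the acceptance suite bounds the
mean over 20 null corpora at 3%). Significance here is a screening device,
not a formal test: the population mixes genuinely trending and flat
subjects, and no multiple-testing correction is applied beyond the single
α gate.

Defaults: α = 0.01; minimum total frequency 20 papers over the full
window (subjects below it produce unstable ratios); both configurable.
Keyword pairs run through identical machinery with containment defined as
both keywords in the same paper.

## Categorisation

The category vocabulary is a MeSH-style descriptor XML file: descriptors
carry dot-separated tree numbers whose components give a root-anchored
path. A keyword is matched exactly on canonical form against descriptor
names (entry-term matching is optional, off by default — entry terms are
noisier), and every matching path contributes its **top two levels**.
Multi-path keywords are credited to every category they sit on; this
inflates category totals relative to keyword totals and is documented
rather than hidden, because any single-assignment rule would be arbitrary.
A CSV override file replaces tree lookups for hand-checked keywords. The
vocabulary release is a required configuration field echoed into outputs,
since category results are version-dependent. By default only the most
frequent 650 keywords are categorised.

## Co-occurrence networks

Edge weight between two keywords is the number of papers containing both;
keywords under a per-bin frequency floor are excluded before pairing.
The five statistics:

- **Average weighted degree** is the mean edge weight over edges present —
  the co-word-analysis reading, fixed by the three-node worked example
  (10 and 20 average to 15). The graph-theoretic reading (mean node
  strength, which gives 20 on the same example) is available via
  `mode="node_mean"`.
- **Density** and **average clustering** are unweighted; nodes of degree
  < 2 contribute clustering 0 (the convention of common network tools),
  with exclusion available behind a flag.
- **Modularity** is Newman's weighted Q. **Community detection** solves
  graphs of ≤ 8 nodes exactly by dynamic programming over node subsets
  (3ⁿ submask pairs — milliseconds at that size; greedy heuristics are
  least reliable precisely on tiny dense graphs, where agglomeration
  cannot un-merge a bad early move). Larger graphs use seeded
  Louvain with 10 restarts, keeping the best partition; all results are
  deterministic given the seed.

## Knowledge map

Edge similarity is the association strength `a_ij = 2W·w_ij/(s_i·s_j)`
(W total edge weight, s weighted degree), target distances are shortest
paths over edge lengths `1/a_ij` (disconnected pairs sit at 1.5× the
largest finite distance), and positions minimise uniform-weight stress by
iterative majorization (Guttman transform) from a seeded random start,
stopping at a 1e-12 relative stress decrease or 500 iterations. This is a
deliberately simple VOS-like layout, not a replication of VOSviewer's
algorithm; VOSviewer-compatible map/network files are exported so the map
can be rebuilt in that tool. The density score is a Gaussian-kernel node
density (bandwidth = mean nearest-neighbour distance) with neighbours
weighted by their co-occurrence strength, min–max scaled onto [0, 2] and
coloured blue (0) → green (1) → red (2).

## Gene-words

Pattern syntax: a plain stem matches any keyword containing it; `~stem`
matches a word ending in the stem (`~tomy` → gastrectomy); `stem~` a word
starting with it (`hyper~` → hypertension). The bare stem is never its own
derivative and families may overlap. The three rules use thresholds
frequency > 100 with rank ≤ 100 (ties included), ≥ 10 derived keywords
each with frequency > 10, and membership of a curated priority list (the
"priority issue" judgement is editorial and is externalised rather than
approximated). Two readings of the aggregate-share clause are
implemented: derived-family share of the family-plus-stem total > 20%
(default) and share of the whole corpus (flag) — the former because a
single family cannot plausibly hold 20% of all keyword occurrences in a
large corpus. Affix patterns have no standalone stem keyword, so rule 1
is anchored on the family's most frequent derived keyword for them.

## Synthetic corpora

The generator emulates the study conditions of a 20-year keyword corpus:
four 5-year bins with paper counts doubling per bin (default 250 → 2000),
Poisson(5) keywords per paper (minimum 1, matching ~5 author keywords per
article), a Zipf-like vocabulary of 120 keywords (uniform mode for
exchangeable-null studies), planted per-bin multiplicative trend factors,
4 community blocks with 70% intra-block selection mass, two planted
gene-word families, 20% international papers, and ledgered noise:
duplicate rows (appended copies sharing the DOI), hyphen and accent
spelling variants (guarded so at least one clean occurrence survives,
keeping the conservative merge rule applicable), and invalid rows with
missing essential fields. Ground truth records the realised clean-corpus
frequency series, the planted structure and exact injection counts; with
a fixed seed the CSV is byte-identical across runs.

What passing tests show — and what they do not: recovery of planted
trends, blocks, families and ledgers demonstrates the pipeline's
correctness, power at the planted effect sizes (a ×3-per-bin trend at
2000 papers/bin is recovered as rank 1 and significant in ≥ 90% of
seeds), and null calibration. The generator does not model correlated
author behaviour, drifting keyword vocabularies, journal- or
citation-structure, misspellings beyond accents/hyphens, or genuinely
ambiguous synonymy, so real exports will need a curated synonym map and
may clean less exactly than the ledger tests suggest.

## Problem sizes and numerical choices

Test and acceptance runs use corpora of 1,500–8,000 papers per corpus,
20 seeds for stochastic claims, 200 random graphs (n ≤ 8) for the
exhaustive network oracles, and 500-keyword vocabularies for null
calibration. Tolerances: exact equality for combinatorial counts and
ledgers; 1e-9 for closed-form statistics; 1% relative for growth values
recomputed from 2-decimal printed inputs (the residual is input
rounding). Degenerate inputs are flagged, not silently zeroed: empty
bins, all-zero series, zero population standard deviation and edgeless
graphs yield NaN plus a flag where a number is expected.

## Known limitations

- The z-score reference population conflates trending and flat subjects;
  strong planted outliers inflate the estimated spread and can mask
  moderate trends (visible in the recovery tests as occasional
  significance of runner-up keywords).
- Country extraction trusts the trailing affiliation token; consortium
  affiliations and free-text addresses degrade it.
- The layout is not VOSviewer and figure geometry will differ from maps
  produced by that tool, though neighbourhood structure agrees on planted
  two-block graphs.
- Gene-word matching is purely lexical (no stemming/lemmatisation), so
  morphological variants outside the pattern syntax are missed.
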