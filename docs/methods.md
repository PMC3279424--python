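# Methods

## Model

The unit of analysis is an experimentally observed human protein–protein
interaction, keyed by an unordered canonical protein pair. Integration maps
every source record's endpoints to canonical protein representatives
(splice forms are not considered) with at least one gene identifier each,
drops records with unmappable endpoints, excludes genetic-interaction
records, and collapses duplicate pairs across sources into one interaction
whose evidence bundle is the set-union of studies (PubMed ids), normalized
detection-technique keys, source labels and PSI-MI interaction-type codes.
Ortholog evidence — the same pair observed between orthologs in a non-human
species — attaches only to interactions that already have human
experimental support; ortholog-only pairs are discarded. The default
species list (Bos taurus, Caenorhabditis elegans, Canis familiaris,
Drosophila melanogaster, Gallus gallus, Mus musculus, Rattus norvegicus,
Saccharomyces cerevisiae, Sus scrofa) is user-extensible.

Each interaction's confidence is

    S = w_s·s(n_s; a_s) + w_o·s(n_o; a_o) + w_t·s(n_t; a_t),
    s(n; a) = 1 − e^(−a·n),   w_s + w_o + w_t = 1,

with n_s the number of distinct studies, n_o the number of ortholog
species, and n_t the technique mass: the sum of curated reliability scores
over *distinct* techniques. The saturating form satisfies s(0) = 0 and
s(∞) = 1 with a_i controlling steepness; it is injected as a strategy so
alternatives (e.g. n/(n+a)) can be swapped for sensitivity analyses.
A technique used in several studies counts once in n_t — the study count
separately rewards repetition — while several techniques within one study
all count. Records without a PubMed id contribute techniques but no study
count. Unknown techniques score 0 and log a warning rather than inheriting
a parent term's score: silent generosity is worse than a loud zero.

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| a_s | study-subscore steepness | 2.3 | per study |
| a_o | organism-subscore steepness | 1.6 | per species |
| a_t | technique-subscore steepness | 0.2 | per technique-score point |
| w_s, w_o, w_t | subscore weights | 0.6, 0.1, 0.3 | dimensionless, simplex |

Under the defaults a single-study interaction with one average (score-5)
technique scores ≈ 0.7295, just below the 0.73 high-confidence boundary;
any second study, or one ortholog species, crosses it. The packaged
technique table holds 125 curated methods with scores in
{0, 1, 2, 2.5, 3, 5, 6, 7, 7.5, 9, 10}; lookups resolve by PSI-MI code
first, then by normalized name (case-folded, hyphens/slashes collapsed to
spaces), because source datasets mix spellings.

## Parameter selection

The six parameters are chosen by exhaustive grid search: a_i over [0, 3]
and w_i over the simplex, both at step 0.1 (31³ × 66 = 1,966,206
combinations). Each candidate is scored by leave-one-study-out
reproducibility on a reference dataset with explicit study–interaction
associations. Holding out study j removes its evidence (an interaction
disappears only if nothing experimental remains), rescores the reduced
dataset, and measures

    dev_j = (n_high_j + 0.5) / (0.25·|overlap_j| + 0.5)

where overlap_j is the set of PPIs shared between study j and the reduced
dataset, n_high_j counts those rescoring at or above the reduced dataset's
upper quartile Q3, and 0.25·|overlap_j| is the random expectation (Q3 puts
a quarter of the reduced dataset in the high stratum by construction). The
0.5 pseudocounts keep log(dev) finite at zero observed. The objective

    f = exp( Σ_j v_j·log dev_j / Σ_j v_j ),   v_j = |overlap_j|

is the overlap-weighted geometric mean of the deviations; any strictly
increasing outer function leaves the argmax unchanged, and the exponential
puts f on a natural scale (f = 1 when every holdout matches random
expectation). Eligible holdout studies have ≥ 10 interactions and more than
2 multi-study PPIs. Q3 is recomputed per holdout on the reduced dataset,
matching the procedure's order of operations.

The winner maximizes f; ties (grouped after rounding to 9 decimals, since
exact mathematical ties accumulate float noise) break to the largest
interquartile range of the full-reference score distribution — preferring
parameter sets that spread scores widely — and residual ties to the
lexicographically smallest parameter tuple. Combinations inducing fewer
than 20 distinct score values on the reference (configurable) are excluded
as degenerate; w_t = 0 is the canonical casualty, since technique scores
contribute most of the score's granularity.

The grid search evaluates holdout enrichment through a vectorized path:
the per-holdout evidence-count matrices and overlap indices are
parameter-independent and computed once, so each grid point costs only a
vectorized rescoring. A test asserts bit-level agreement between this fast
path and the plain per-study implementation. Evaluation is a sequential
loop by design — determinism over parallel speed.

## Numerical conventions

- **Quartiles** use the nearest-rank convention (the ceil(0.75·n)-th order
  statistic), never interpolation: thresholds are always observed scores
  and identical across platforms. High-confidence membership is
  score ≥ threshold, ties included.
- **Fisher's exact test** for recall differences is one-sided
  ("greater") on the table [[overlap_high, detectable_high],
  [overlap_low, detectable_low]] — each stratum's overlap count paired
  with its detectable-set size. p-values are reported in scientific
  notation at 3 significant digits.
- **Flat-file scores** are printed at 2 decimals (round-half-even);
  comparisons always use full precision in memory.
- Scores saturate to exactly 1.0 in double precision once a·n ≳ 37; the
  mathematical bound S < 1 holds everywhere floats can express it.

## File formats

PSI-MI TAB 2.5 is read and written with the standard 15-column layout,
`-` missing tokens and pipe-separated multi-values; extra columns from
later MITAB versions are ignored on read. Methods or source labels without
a PSI-MI code are emitted as `psi-mi:"MI:0000"(label)` — the cv cell
grammar requires a code and several curated methods come from
source-specific vocabularies — and MI:0000 maps back to "no code" on read.
Genetic interactions are flagged via interaction type MI:0208, which is
carried as a boolean rather than a type code so the flag round-trips.

The scored flat file has six columns: UniProt id and Entrez Gene id of each
partner, score, and an evidence comment of semicolon-separated classes with
comma-separated members: `experiments:…;pmids:…;sources:…`, plus an
`organisms:` class written only when ortholog evidence exists (rescoring
from a flat file would otherwise silently lose the organism subscore).
A protein encoded by duplicated genomic loci maps to several genes; such
interactions expand to one line per gene combination and collapse again on
read. Interaction-type codes are not representable in the flat dialect and
round-trip through MITAB instead.

## Subnetworks

Layer 0 keeps interactions with both endpoints in the query set; layer 1
admits one non-query endpoint but does not add edges among the new
partners. Thresholding keeps score ≥ min_score. The interaction-type filter
matches on any annotated code (union semantics, since sources disagree on
annotation completeness); **untyped interactions are dropped whenever a
filter is active**, which on sparsely annotated inputs can remove most of
the network. Neighborhood expansion iterates layer-1 extraction with
thresholding at each step and refuses more than 3 layers by default
(combinatorial growth).

## Synthetic fixtures

The generator emulates the statistical structure the scoring model assumes,
with defaults chosen once as the standard conditions: 300 proteins, 800
interactions, study multiplicities {1: 0.65, 2: 0.18, 3: 0.10, 4: 0.05,
5: 0.02} (most PPIs single-study, a reproducible minority), 24 studies over
3 source datasets, ~1% of records with no technique assigned, a technique
pool dominated by mid-reliability affinity/complementation methods with a
thin structure-grade tail, per-species ortholog evidence at 2%, 10%
gene-ambiguous proteins, 5% genetic records, 2% unmappable endpoints and 2%
ortholog-only distractor pairs. A pair's technique repertoire is drawn once
and shared across its studies, so technique diversity does not proxy for
study count — the two evidence axes stay separable. Every generated dataset
ships with a ground-truth ledger recording exactly what integration and
scoring must recompute; conservation is asserted end to end.

Fixtures for parameter-recovery properties use a heavier multi-study tail
{1: 0.40, 2: 0.25, 3: 0.20, 4: 0.10, 5: 0.05} (a planted
strong-reproducibility signal) at 150 proteins / 250 interactions / 16
studies, searched on a coarse grid (a step 1.0, w step 0.2). Generation is
bit-reproducible under a fixed seed, and synthetic study ids start at
900,000,000, far above real PubMed ids, so fixture studies can never be
conflated with real literature.

What passing tests on these fixtures do **not** show: real source databases
have skewed degree distributions, correlated technique usage across related
pairs, curation errors and identifier drift, none of which the generator
models. Published snapshot-bound quantities (total network size,
per-source sizes, the concrete optimum of the published search, the number
of eligible reference studies) depend on 2009–2010 database contents that
are not shipped and are therefore covered by property-level checks —
objective invariances, oracle-equivalent statistics, recovery of the
planted signal's direction — rather than by value reproduction.

## Known limitations

- The precedence question between a database's copy of a PPI and the same
  PPI's primary-publication copy is resolved by plain evidence union — the
  conservative reading; no deduplication of a study counted through two
  sources is attempted beyond PubMed-id set semantics.
- Reading a flat file reconstructs technique provenance only coarsely (all
  techniques attributed to one study), so leave-one-study-out optimization
  should run on record-level inputs (MITAB or the source dialect), not on
  re-read flat files.
- The full 1.97M-point grid at reference scale is computationally heavy in
  pure Python; the packaged search is meant for reduced grids or moderate
  references. Problem sizes used by the shipped tests and acceptance script
  (≤ 800 interactions, coarse grids, 20-seed sweeps) were chosen to keep a
  full run in the minutes range on one CPU.
- Self-interactions flow through scoring unchanged; no homodimer-specific
  treatment.
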