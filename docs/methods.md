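# Methods

This note documents the model, the default parameters and the numerical
choices behind `plasticitome`, and what the synthetic-data generator
does and does not emulate.

## Rank normalization

Two platform-specific rules convert expression to within-sample
percentile rank scores.

*RNA-Seq.* Counts are converted to TPM
(`TPM_g = (c_g/l_g) / Σ_j(c_j/l_j) × 10⁶`, always summing to one
million). Genes with zero counts are pinned to rank 0 — absence of
evidence of expression is treated as a distinct state, not as the lowest
rank. The N nonzero genes are ranked ascending and scored
`P = n/N × 100`, so the top untied gene scores exactly 100.

*Microarray.* Signals have no natural zero, so all N genes are sorted
ascending and divided into 100 equal parts; ordinal i scores
`ceil(i × 100/N)`. The ceiling form was chosen over floor variants
because it reproduces the `n/N × 100` grid when N is a multiple of 100
and attains the endpoint 100.

*Ties.* The ordinal-rank formula is undefined under ties; tied values
receive the mean of their positional ranks (fractional ranks allowed).
This makes both rules invariant under permutation of the input order and
under strictly increasing transformations of the values.

*Sample QC.* RNA-Seq samples pass when protein-coding reads total
≥ 500,000, make up strictly more than 50 % of all reads, and ≥ 10,000
protein-coding genes are detected. The strict inequality on the
fraction and the inclusive bounds on the other two mirror the usual
phrasing of these criteria ("more than half", "at least"). Marker-based
QC (e.g. CD79A/CD79B for B cells) requires every marker of the declared
cell type to reach a configurable rank, default 70; there is no
canonical published value for this cutoff, so it is surfaced in the
configuration and recorded in reports rather than hidden.

## Plasticity scores

For each gene across the samples of one cell type: ARS is the mean
rank; GPL (IQR) is Q3 − Q1; GPL (absolute) is max − min. Quartiles use
linear interpolation between order statistics (the numpy default,
"type 7"); the convention only affects the IQR score — the absolute
score, which all screens use, is convention-free. The absolute score is
monotone under adding samples, which formalizes the intuition that more
experimental conditions can only reveal more plasticity.

The polarized-gene screen keeps genes with absolute GPL ≥ 50 on *both*
platforms and maximum rank ≥ 90 on *both* platforms: highly plastic
genes that can reach the top decile of expression.

## Virtual sorting

The target gene's values across samples are split by **exact**
one-dimensional 2-means: the optimal two-cluster partition in one
dimension is a cut in sorted order, so scanning the n − 1 cut points
minimizes the within-cluster sum of squares exactly and removes random
initialization (and the need for a seed) entirely. The higher-mean
cluster is g1. Constant target vectors are rejected ("gene not plastic
in these samples"), and targets are required to have absolute GPL ≥ 50
across the supplied samples unless explicitly overridden.

Filters (defaults): correlated genes need δ ≥ 20 and Pearson r ≥ 0.5;
anticorrelated genes need δ ≤ −10, r < 0 (strict) and cosine
similarity ≤ 0.1. The asymmetric δ thresholds reflect that negative
partners are systematically harder to detect — mutual exclusion
produces a weaker rank signal than co-activation. δ, Pearson and cosine
are all computed on percentile-rank vectors by default; rank vectors
are the platform-comparable representation used throughout, and for
RNA-Seq they retain genuine zeros (zero-count ⇒ rank 0), which is what
makes the cosine-orthogonality filter for mutual exclusion meaningful.
Computing the metrics on raw values instead is supported as an option.

A zero vector has no direction; its cosine against anything is defined
as 0 with a warning — a never-expressed gene is vacuously exclusive.
Pearson against a constant vector is undefined (NaN) and never passes
either filter.

## Coexistence statistics

Presence is defined by detection calls (microarray), by TPM ≥ cutoff
(bulk RNA-Seq; the conventional cutoff series 1, 2, 3, 4, 5, 10, 20 is
emitted side by side because no single value is canonical), or by
UMI > 0 (single cell). Coexistence + APA = 1 holds exactly by
construction, and `sc_pp_rate(A,B) ≤ min(expressed_fraction(A),
expressed_fraction(B))` is asserted as a property.

The single-cell evaluation of a virtual-sorting result reports per-gene
Pearson and PP rate against the target over cells, the class medians,
and a one-sided Wilcoxon rank-sum p-value for correlated >
anticorrelated. The rank-sum test is descriptive — the gene sets were
selected on related data, so it is reported as a summary of separation,
not as confirmatory inference.

## Immunophenotype grammar

A phenotype string is a concatenation of units, each a marker followed
by a tag from the closed vocabulary `+ − hi lo int bright dim mid
medium high`. Unicode minus and superscript markup (`^+^`) are
normalized before parsing. Parsing is total-or-fail with memoized
backtracking: tags bind at the earliest position where the remainder
still parses (`CD25hi` → CD25 + hi, never CD2 + 5hi), and longer tags
beat their prefixes (`CD4high` takes `high`, not `hi`). The hyphen is
ambiguous — negative tag versus part of a compound marker name
(HLA-DRA) — and defaults to the tag reading; a caller-supplied
known-marker lexicon (typically the alias-table keys) lets recognized
compounds win. `high`/`hi` and `medium`/`mid` are kept distinct at
parse time; state enumeration uses only the binary `+`/`−` states.

Canonical keys sort units by (marker, tag), so phenotypes written in
different unit orders deduplicate. Layer-k children are the C(n, k)
unit subsets; corpus statistics deduplicate children globally by
canonical key. Alias normalization is idempotent (standard symbols
resolve to themselves); markers that cannot be resolved are kept
verbatim and flagged rather than dropped, so extraction noise is
visible instead of silently discarded.

## Preranked enrichment

Genes are ranked by descending absolute GPL with ties broken by gene id
(fully deterministic lists). The running statistic is the classic
weighted Kolmogorov–Smirnov walk: hits add `|score|^w` normalized over
the set, misses subtract `1/(N−k)`; ES is the signed maximum deviation.
The weight defaults to 1 (the standard weighted statistic); weight 0
retains the symmetric unweighted form, for which reversing the list
negates ES. Because the walk is piecewise monotone between hits, only
the 2k deviations immediately before/after hits need to be examined,
which makes the permutation null cheap to vectorize.

The null resamples random gene sets of the same size from the list —
the only permutation scheme available for preranked input. NES is
ES / mean(|null ES| of the same sign); the p-value is add-one
corrected, `(1 + #{|ES_null| ≥ |ES|}) / (n_perm + 1)`. On lists of ≤ 8
genes the permutation p-value is checked against the exhaustive
gene-set null in the test suite.

## Synthetic data

The generator plants the structure the pipeline is designed to detect,
with one latent on/off state per driver per sample driving both
platforms:

| class | default n | expression |
|---|---|---|
| housekeeping | 30 | 100 units, every sample |
| silent | 30 | 0.05 units |
| drivers | 5 | 200 on / 0.2 off, on with prob 0.5 per sample |
| correlated / driver | 20 | follow the driver's state |
| anticorrelated / driver | 20 | high exactly when the driver is off |
| noise | 50 | per-gene constant baseline, log-uniform 1–60 |

Defaults: 60 samples, 400 cells, log-normal noise σ = 0.25,
negative-binomial dispersion α = 0.1 (var = m + αm²), single-cell
dropout 0.3, ~4000 expected UMI per cell. The on/off fold separation
defaults to 1000×: the driver and block genes being emulated
(cytokines, activation antigens) swing between silence and strong
expression, and mutual exclusion in particular means *not expressed* —
an "off" state that is merely low would not be mutually exclusive in
the cosine sense, on real data or simulated. Gene lengths are drawn
from 1000–3000 bp and count means are length-weighted so TPM recovers
the planted profile; the simulated depth puts housekeeping genes far
from the zero-count regime while off-state genes remain mostly
undetected.

Array detection calls are `P` iff signal exceeds a fixed noise floor.
Single-cell matrices redraw the driver states per cell and thin counts
by independent Bernoulli dropout, reproducing the heavy zero inflation
of droplet data while keeping PP-rate expectations analytically
tractable.

What the generator does **not** emulate: batch effects, library-size
confounding, gene–gene correlation beyond the planted blocks,
cell-type mixtures, or real marker-gene biology. Passing recovery
tests therefore demonstrate that the pipeline's statistics detect the
structure they are defined to detect at realistic noise levels — not
that any particular biological claim about real cells holds.

Two emergent behaviours are worth knowing. First, housekeeping genes
show non-trivial rank plasticity (absolute GPL up to ~40) purely from
measurement noise, because many genes share one expression band and
their within-band order reshuffles every sample; this is faithful to
real rank-normalized data and is why the polarized screen requires both
platforms to agree. Second, a driver whose drawn states happen to be
all-on carries no planted variation and scores far below switching
drivers, but not near zero — the same within-band reshuffling sets a
noise floor for rank-based plasticity.

The phenotype-corpus generator emits 300 phenotype strings over 171
synthetic markers (159 planted plastic — chosen so the planted fraction
is a two-decimal percentage, 92.98 %), with a unit-count distribution
putting 83 % of phenotypes at ≤ 3 units and 30 % of marker mentions
written as aliases to exercise normalization.

## Problem sizes

The default study is 315 genes × 60 samples per platform, 400 cells,
and 20 independent seeds for recovery statistics; enrichment
calibration uses lists of 800–5000 genes with 200–1000 permutations.
These sizes give stable recovery estimates (100 driver-level
replicates) while keeping the full suite fast to iterate on.

## Known limitations

- The IQR plasticity score depends mildly on the quartile convention;
  only the convention-free absolute score feeds the screens.
- The 2-means gate assumes an approximately bimodal target; graded
  (continuum) targets get an arbitrary but WSS-optimal cut.
- The phenotype parser cannot resolve hyphenated compound markers
  without a lexicon, and treats tag words embedded in marker names as
  tags when a valid parse results.
- Detection-call generation upstream of `coexist_calls` (e.g.
  MAS5-style calling) is out of scope; calls are an input.
- Expression-recovery imputation for single-cell matrices is out of
  scope; `evaluate_vsort_sc` accepts a pre-imputed matrix as an
  alternative input.
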