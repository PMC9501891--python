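# Methods

This note documents the statistical procedures implemented in `immunosig`,
the choices made where the underlying workflow is conventionally
under-specified, and what the synthetic cohorts do and do not emulate.

## Normalization

Targeted-panel counts are normalized by housekeeping scaling, the
documented convention for nCounter-style instruments: for sample *j*,
`g_j` is the geometric mean of the housekeeping counts (after adding a
pseudocount), the scale factor is `mean_j(g_j) / g_j`, and reported values
are `log2(scale_j · (count + pseudocount))`. After scaling, the
housekeeping geometric mean is equal across samples by construction
(verified to 1e-9 relative tolerance in tests).

Choices:

- **Anchor = cohort mean.** Anchoring to the cohort mean (rather than a
  fixed reference level) makes normalized values comparable within a
  cohort but means a global rescaling of one sample shifts the anchor:
  the result changes only by one constant common to every value in the
  cohort, and within-sample contrasts are exactly preserved. Validation
  cohorts are normalized independently with their own factors (switchable
  in `SignatureDiscoveryResults.apply`).
- **Pseudocount 1** before both the geometric mean and the log2, avoiding
  log(0) on sparse panels. At typical panel counts (tens to thousands) the
  distortion is negligible.
- Gene identifiers are matched case-sensitively after whitespace trimming;
  duplicates are errors, never averaged.
- A best tumor-size change of exactly 0% classifies as non-responder
  (responders are defined by *any* regression; the boundary case is
  assigned conservatively).

## Immune cell-type scores

A cell type's score is the arithmetic mean of its marker genes' log2
values; markers absent from the panel are dropped with a warning (a cell
type with no marker present is skipped). Scores are compared between
responders and non-responders with the two-sided Wilcoxon rank-sum test.
No multiple-testing correction is applied across the dozen predefined cell
types — raw p < 0.05 — matching common practice for small fixed marker
panels; this is deliberate and documented rather than statistically ideal.
The packaged 12-cell-type marker list follows the established
tumor-immune marker-gene convention and is fully replaceable via a
two-column TSV.

The Wilcoxon implementation is exact (full enumeration of the rank-sum
null by dynamic programming) whenever the pooled sample is untied with
n ≤ 20 — which covers pilot-sized cohorts — and otherwise uses the normal
approximation with tie correction and a 0.5 continuity correction. The
exact two-sided p is the null probability of a rank sum at least as far
from its mean as observed.

## Gene-set enrichment

Genes are ranked by signal-to-noise association with response:
`(μ_r − μ_n) / (σ_r + σ_n)` with each group standard deviation floored at
`max(0.2·|μ|, 0.2)` — the floor keeps near-constant genes from dominating
small-sample rankings. A difference-of-means metric is available for
groups too small for variances (< 2 samples). Metric ties break
lexicographically by gene id so rankings are deterministic.

The enrichment score is the classic weighted (p = 1) Kolmogorov–Smirnov
running sum: walking the ranked list, set members add `|r_i|^p / N_R`
(`N_R` the sum of in-set weights) and non-members subtract `1/(N − N_h)`;
ES is the running-sum value of maximal absolute deviation (first
occurrence on exact ties), and the leading edge is the set members at or
before the peak (positive ES) or at or after the trough (negative ES).

Significance:

- **Null: random gene sets by default.** With 8-vs-4-sized phenotype
  groups there are too few label permutations for a usable phenotype null,
  so the default null draws random same-size gene sets against the fixed
  ranking; phenotype shuffling is available by flag for larger cohorts.
  Same-size sets share one null distribution, which is cached.
- **NES and nominal p are sign-stratified**: NES = ES divided by the mean
  |null ES| of the same sign; p = (1 + #{same-sign nulls ≥ |ES|}) /
  (1 + #same-sign), the add-one form that cannot return zero. The nominal
  p therefore has a floor of ~1/(n_same + 1); with 1,000 permutations the
  smallest attainable p is about 0.002.
- **FDR is Benjamini–Hochberg within each ES sign stratum**, a simpler and
  provably monotone substitute for the NES-histogram FDR of the original
  enrichment tool; q < 0.1 flags significance. Results are sorted by
  nominal p, then |NES|, then name.
- Note that the random-set null ES is *not* symmetric about zero in
  general: the weighted statistic conditions on the observed |metric|
  profile, and only a reversal-symmetric profile gives a symmetric null.
  All inference is within-sign, so this asymmetry does not bias p-values.

Sets are restricted to the measured panel; sets with fewer than 3 members
(configurable) or spanning the whole panel are discarded.

## Signature derivation and scoring

The top k = 3 pathways by nominal p (ties: larger |NES|, then name) define
the signature: a core gene is one appearing in ≥ 2 of the top pathways'
gene lists. "Appearing" defaults to **leading-edge membership** — the
genes actually driving each enrichment — with full-set membership as an
automatic fallback when the leading edges share no gene. The per-sample
signature score is the arithmetic mean of the core genes' log2 values; a
missing core gene is an error, never a silent drop, because a frozen
signature must not shrink per cohort.

Cohorts are dichotomized at the **median score**; samples strictly above
go high, ties at the median go low. Both strata must be nonempty. A fixed
cutoff (e.g. carried over from a derivation cohort) is supported.

A frozen six-gene reference signature (PSMB10, PSMB9, LAG3, CCL5, IFI35,
SH2D1A) ships with the package for scoring new cohorts. Its per-gene
pathway provenance is not part of the public record, so the provenance
column is empty and the "≥ 2 contributing pathways" invariant is enforced
only for signatures derived by the package itself.

## Survival and discrimination

- **Kaplan–Meier**: product-limit estimator; at tied times events are
  processed before censorings (a subject censored at an event time is
  still at risk for that event). Median survival is the first time S(t) ≤
  0.5 and is reported as "not reached", never interpolated, when the curve
  stays above 0.5.
- **Log-rank**: Mantel–Haenszel sums of observed minus
  hypergeometric-expected events over pooled distinct event times,
  chi-square with 1 df. Symmetric under group swap.
- **Hazard ratio**: single-binary-covariate Cox partial likelihood with
  Efron tie handling, maximized by damped Newton–Raphson (tolerance 1e-8,
  max 100 iterations), Wald 95% CI on the log scale. Complete separation
  of events (monotone likelihood) is reported as non-convergence with a
  direction flag, not as a number.
- **ROC/AUC**: thresholds at distinct scores; trapezoidal area, which
  equals the Mann–Whitney probability with ties half-counted (asserted
  internally on every call). The 95% CI is DeLong's placement-value
  normal-approximation interval, clipped to [0, 1]; zero placement
  variance (e.g. perfect separation) collapses the CI to the point
  estimate and is flagged.

The comparison test, HR estimator and CI method are the field-standard
choices for this workflow; all are cross-checked in the test suite against
independent implementations (lifelines, scikit-learn, R `survival`-derived
hand values) and brute-force oracles (grid-search likelihood maximization,
stratified bootstrap).

## TMB

TMB counts missense, nonsense, splice-site, inframe and frameshift
variants per sample, divided by the panel footprint in Mb. The footprint
is a required input — per-Mb values are meaningless without it, and no
default is assumed. Effect prediction is out of scope: variants arrive
pre-classified (TSV) or with a SnpEff/VEP-style annotation field (VCF
adapter; unrecognized consequence terms map to `other`, which never
counts toward TMB).

## Synthetic cohorts

The generator emulates a ~289-gene tumor-immune panel cohort:

- per-gene log2 baselines ~ Normal(6.0, 1.5) (≈ 64 counts median, spread
  chosen to span the dynamic range of a targeted panel), negative-binomial
  counts with a single shared dispersion (size 10) for nCounter-like
  overdispersion;
- 10 housekeeping genes drawn identically across phenotype groups and
  never planted;
- default cohort: 12 samples with 8/12 responders (the pilot-cohort
  setting this package targets); responder best-change percentages are
  negative, non-responder positive;
- planted genes shift responder means by 2^log2FC;
- the latent signature score is the per-sample mean of the planted genes'
  true log2 means, standardized across the cohort; PFS is exponential
  with hazard `hazard_base · exp(hazard_log_hr_per_score · score)`
  (defaults 0.1 events/month and −0.7 per SD, i.e. protective), censoring
  uniform on (0, T_max) with T_max solved numerically so the expected
  censoring fraction equals `censor_rate` (default 0.2);
- filler genes are named after the packaged immune marker genes first, so
  synthetic panels carry the cell-type markers and the frozen six-gene
  signature genes like the real assay; the planted-scenario helper places
  all six core genes (named after the reference signature by default) in
  every one of three planted pathway sets, with disjoint null fillers so
  only core genes can recur across pathways, plus 20 random background
  sets.

What the synthetic cohorts do **not** emulate: FFPE degradation and batch
effects, gene–gene correlation beyond the planted structure,
copy-number/fusion events, non-exponential hazards, informative
censoring, and the true (unknown) effect sizes and dispersions of any
real panel. Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover known planted truth under realistic
noise — not that any particular signature generalizes to patients.

## Problem sizes and numerical choices

Simulation-based tests use derivation cohorts of n = 30 (15/15), 500–1,000
permutations, and 25–200 replicates or seeds per property; the Cox
recovery check uses n = 200/200 with a true HR of 0.25; bootstrap
comparison of the DeLong CI uses 10,000 stratified resamples on an n = 40
fixture. Newton iterations stop at 1e-8; ES ties resolve to the first
extremum; the batched permutation-null ES resolves exact peak/trough
magnitude ties to the positive side (a measure-zero event for continuous
metrics). All randomness flows from explicit seeds; identical
config + seed reproduces every output byte for byte.

## Known limitations

- The enrichment FDR differs by design from the NES-histogram FDR of the
  original GSEA tool; q-values agree in ordering but not numerically.
- The nominal-p permutation floor means very strong enrichments tie at
  the smallest attainable p; the |NES| tie-break orders them.
- Exact Wilcoxon requires untied data; panel log2 values are effectively
  continuous, but heavily rounded inputs silently fall back to the
  normal approximation.
- The two-group Cox model has no covariate adjustment (deliberately —
  the validation contract is a univariate stratum comparison).
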