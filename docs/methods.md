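# Methods

## Model and procedure

The pipeline infers ordered cell-type pairs whose relative abundance shifts
with a phenotype, using only bulk expression and marker gene sets.  The core
idea: if cell type Y is depleted in cases while X is not, then for any
X-marker g_i and Y-marker g_j the per-sample log ratio g_i/g_j rises in
cases.  The pipeline therefore tests all ordered marker pairs, keeps the
significant ones as directed gene edges (direction = higher in cases), and
asks whether edges concentrate from X-markers to Y-markers more than the
overall significant-pair rate predicts.

Assumptions worth keeping in mind:

* Marker genes are expressed predominantly in their own cell type, so their
  bulk signal is roughly proportional to that type's mixing fraction.
* Each marker belongs to exactly one analyzed type.  Markers listed under
  multiple types are removed from all sets by default (a keep-in-first
  option exists); markers absent from the expression matrix are dropped, and
  a type retaining fewer than `min_markers` (default 3) is excluded.
* Inference is about *relative* composition.  A pair X→Y can fire because Y
  shrinks, X grows, or both; the method cannot separate these without an
  absolute anchor.

### Stage contracts and numerical choices

**Log-ratio scale.**  Ratios are log2.  For linear-scale input the value is
log2(x_i + c) − log2(x_j + c) with pseudocount c (default 1.0; c = 0 is
allowed only when the matrix has no zeros).  For declared log2 input the
value is a plain difference.  Antisymmetry value(i→j) = −value(j→i) is exact
in floating point because both entries are differences of the same two
numbers.  Rows are generated in blocks (`iter_mgp_blocks`) so M ≈ 2,000
markers (≈4M rows) streams in constant memory; correctness tests run at
M ≤ 60.

**Group test.**  Welch t by default (robust to unequal variances; a pooled
flag exists).  Rows constant in both groups get statistic 0 and p = 1 with a
warning.  The `linear_model` method fits per-row OLS on an intercept, a
case indicator, and covariates (categoricals one-hot with a dropped
reference level; samples with missing covariates dropped listwise with a
warning).  Moderation — on by default for `linear_model` only — shrinks
residual variances toward a scaled-F prior fitted by the method of moments
on log s² (the limma empirical-Bayes scheme, including the cap of total df
at the pooled df); the implementation reproduces Bioconductor limma's
moderated t and p to ~1e-14 and the suite keeps a live limma cross-check.

**Severity test.**  Per-row Spearman rho with average ranks on ties.  p uses
the t approximation for n ≥ 10 and an exact full-permutation null below
that (all n! orderings; ties handled by permuting the tied ranks as-is).
A constant severity vector is an error; constant rows get rho 0, p 1.

**FDR.**  Benjamini–Hochberg step-up with enforced monotonicity, implemented
directly and cross-checked against statsmodels and a brute-force step-up
reference.

**Network.**  Gate default: q ≤ 0.05 (metric and threshold configurable;
the reciprocal rows of a pair share the same p, hence the same q).  Only the
positive-statistic direction is kept; reciprocal exclusivity is re-verified
on every run and a violation raises.

**Cell-pair enrichment.**  The background universe for the rate f and the
Fisher margins is all M(M−1) ordered pairs of retained uniquely-typed
markers, including within-type pairs (a `cross_only_background` flag
restricts both N_sig and the universe to cross-type pairs).  Within-type
cell pairs X→X are not tested (6 types → 30 ordered pairs, 19 → 342).
Expected = L_X·L_Y·f; ER = observed/expected, reported as 0 when observed
is 0 (keeps concordance vectors complete) and NA only for an empty network.
The one-sided "greater" Fisher p is the hypergeometric upper tail
P(X ≥ observed) on (N = M(M−1), K = N_sig, n = L_X·L_Y); a two-sided option
calls the standard conditional exact test.  BH across the T(T−1) rows.

**Hierarchy.**  Significant CCIs (default q ≤ 0.05) give each type an in-
and out-degree; layer rank orders types by descending out−in, ties broken by
higher out-degree then name.  Rank 1 = net sender; a depleted type collects
in-edges and sinks to the bottom.

**Concordance.**  Spearman correlation of ER vectors over the shared ordered
cell pairs of two runs, NA ERs dropped pairwise, ≥ 4 finite pairs required.
Spearman (not Pearson) is used everywhere ERs from different datasets are
compared, for consistency and robustness to scale.

**Region stratification.**  With a region column the entire analysis reruns
independently per region, including per-region FDR (regions differ in n and
composition; pooling q-values across regions would let a well-powered region
mask the others).

## Signature scores

The per-sample score is a BASE-style weighted running sum: sort the sample's
genes by descending expression; walking down the list, add
w_g = x_g / Σ_markers x for each marker gene and subtract 1/(G − m) for each
non-marker; the raw score is the signed extreme of this excursion.  Because
the signed extreme of a weighted excursion has positive expectation even for
random marker labels, the raw score is centered on the mean over `n_perm`
(default 200) random same-size marker sets and scaled by their mean absolute
centered deviation.  The null marker positions depend only on (seed, set),
not on the data, and are shared across samples: the Monte-Carlo error of the
normalization is then common-mode and cancels from between-sample
comparisons, and editing one sample can never change another's score.
Ties in expression use average ranks for weighting and a deterministic
gene-id tie-break for ordering.  The default weights follow expression
magnitude; a `variant="rank"` option uses the average ranks as weights and
is exactly invariant to any monotone transform of a sample's expression.
One-sided (up-only) marker sets are assumed.

Scores compare across groups with a two-sided rank-sum test (exact
distribution when ≤ 60 samples and no ties) or against severity with
Spearman; raw p-values by default, BH optional.

## Synthetic cohorts

`simulate_cohort` emulates the structure the inference assumes: per type a
signature profile (markers at `marker_fold`, default 8, elsewhere 1;
background genes 1 everywhere), per sample mixing fractions drawn
Dirichlet(concentration × tilted baseline), expression = fraction-weighted
profile mixture times 2^N(0, noise_sd) log-normal noise (noise_sd default
0.4 on log2 scale).  Defaults: 6 types named neu/ast/oli/mic/opc/end with a
cortex-like baseline (0.40/0.20/0.20/0.10/0.05/0.05 — neurons the largest
pool, glia intermediate, OPCs and endothelium small), 10 markers per type,
500 background genes, Dirichlet concentration 50 (fraction sd ≈ 0.04 for a
0.4 baseline, a realistic person-to-person spread), 50 cases and 50
controls.  In group mode a per-type multiplicative `effect_map` tilts the
case baseline; in severity mode samples get a Uniform(0,1) severity s and
the tilt scales linearly, reaching the full effect at s = 1.  Tilted
baselines are renormalized to sum to 1, so halving one type does not halve
its *expected* fraction exactly — the analytic expectation e_Y·b_Y/Σ(b∘e)
is exposed as `expected_case_fractions` and is what tests assert against.

What the generator does **not** emulate: transcriptome-wide gene-gene
covariance, platform/batch effects, probe-level artifacts, library-size
variation, or markers with graded cross-type expression.  Passing tests
therefore demonstrate that the statistics and bookkeeping are correct and
that the method recovers clean planted composition shifts; they do not
certify performance on real tissue, where marker impurity and correlated
noise will blur the signal.

## Known limitations

* **Fisher calibration under a global null.**  MGP rows sharing a gene are
  strongly correlated, so chance-outlier genes make significant pairs
  radiate in bursts; the Fisher test's independence assumption then fails
  and its p-values are anti-conservative under a global null (empirically
  ~13% of null cell pairs reach p < 0.05 at a nominal MGP gate, vs ~2.5%
  under an idealized independent null where the test is conservative due to
  discreteness).  The gene-label permutation p available via
  `cci_enrichment(..., n_permutations=...)` respects the edge structure and
  is statistically consistent with nominal calibration on the same null
  cohorts; for calibration-sensitive claims, prefer it.  Fisher remains the
  primary, fast test and ranks pairs well — planted effects are recovered
  with the reverse direction never significant.
* Under the default q < 0.05 MGP gate, a global-null cohort typically yields
  an empty network (all Fisher p = 1): conservative, but it means the
  enrichment stage is only informative once some MGPs pass the gate.
* Rank-based signature scores saturate for very dominant cell types (all
  markers already at the top ranks), compressing between-sample contrast.
* The severity exact-permutation path enumerates n! orderings and is only
  used below n = 10 by design.

## Scale of the shipped analyses

The test suite and `scripts/acceptance.py` run the pipeline at M = 60
markers (3,540 ordered pairs), cohorts of 40–200 samples, 10–20 simulation
seeds per property, and 100–200 permutations for signature normalization —
sizes chosen so each property is measured with comfortable statistical
margin while a complete run stays in the minutes range on a laptop.
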