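# Methods

## The estimand and the crossnobis estimator

For two conditions $i, j$ with activity patterns $u_i, u_j$ over the $P$
voxels of a region, the quantity of interest is the squared Mahalanobis
distance $\delta^\top \Sigma^{-1} \delta$, $\delta = \mu_i - \mu_j$, under
the voxel noise covariance $\Sigma$. Patterns are estimated independently
in $M$ run partitions and noise-normalized ("prewhitened") by
$\Sigma^{-1/2}$; the cross-validated estimator

$$d_{i,j} = \sum_{l,m;\,l\neq m}^{M}
  \frac{(u_i^m-u_j^m)^\top (u_i^l-u_j^l)}{M(M-1)}$$

multiplies the pattern difference of one run with that of every *other*
run, so run-specific noise (independent across runs) cancels in
expectation. Consequences the tests verify:

* **Unbiasedness / meaningful zero.** $E[d] = 0$ when the true patterns
  coincide; individual estimates may be negative. Group inference can
  therefore test distances against zero with one-sample t-tests.
* **Symmetry and a hard zero diagonal**, by construction.
* **Equivalence to the double-loop formula** to 1e-10 on random
  instances (the production implementation is the vectorized identity
  $\sum_{l\neq m}\langle x_m, x_l\rangle = \|\sum_m x_m\|^2 - \sum_m
  \|x_m\|^2$).

No division by the voxel count is applied (matching the distance
definition used upstream); `normalize_voxels=True` enables the common
$d/P$ convention for cross-region comparability. The summation symbol in
some printed versions of the formula is ambiguous between "transpose"
and "number of time points"; it is the vector transpose (an inner
product over voxels) here.

## Noise covariance and prewhitening

Run-wise GLM residuals give a sample covariance (divisor: residual dof),
shrunk toward the diagonal of sample variances with the closed-form
Schäfer–Strimmer weight minimizing the expected squared error of the
off-diagonal entries; the result is positive definite whenever the
shrinkage weight is positive, including when voxels outnumber
timepoints. On truly white noise the diagonal target equals the truth
and the optimal weight approaches one — that regime is expected, not a
defect. The inverse square root uses a symmetric eigendecomposition with
an eigenvalue floor of 1e-10 times the largest eigenvalue.

Two whitening modes exist: per-run (each run's own covariance — the
strict reading of run-separate normalization) and pooled (dof-weighted
average covariance shared by all runs), the default, because short runs
make individual covariances noisy.

With an *estimated* covariance, $E[d] =
\frac{\nu}{\nu-P-1}\,\delta^\top\Sigma^{-1}\delta$ (Wishart identity,
$\nu$ = pooled residual dof): the plug-in precision matrix is biased
upward. `prewhiten(..., bias_correction=True)` multiplies the covariance
by $\nu/(\nu-P-1)$ before inversion, making the implied precision
unbiased; the parameter-recovery study uses this (with shrinkage fixed
at 0 and $\nu \gg P$) so its check is a genuine unbiasedness test rather
than a loose tolerance.

## Experimental designs

Three event-related designs are generated exactly at their published
trial counts:

| | Exp 1 | Exp 2 | Exp 3 |
|---|---|---|---|
| conditions | 24 (imagery only) | 16 (8 buildings × 2 domains) | 24 (6 buildings + 6 faces × 2 domains) |
| scans | 5 | 3 | 5 |
| experimental / null / question per scan | 120 / 5 / 9 | 96 / 12 / 6 | 120 / 5 / 9 |
| presentations per condition per scan | 5 | 6 | 5 |

Experimental and null trials last 2 s followed by a 2 s fixation;
question trials last 4 s. Stimulus order is a continuous carry-over
sequence: a seeded Eulerian circuit over the union of $k$ arc-disjoint
random permutation digraphs when the trial count is $k$ times the item
count (every item occurs exactly $k$ times and no ordered successor pair
repeats), otherwise a chained circuit on the complete digraph with
self-loops truncated to length (pair counts differ by at most one).
Self-successions are balanced along with hetero pairs, standard
carry-over practice. Null and question trials are inserted at seeded
uniform positions *after* sequence construction, keeping the stimulus
balance exact; whether the original studies balanced them inside the
sequence is not stated, and the analysis is insensitive to it because
null trials are unmodeled baseline and question trials are a pooled
nuisance. Per-scan volume counts are derived from trial durations plus a
16 s rest tail, not from the published volume numbers, which encode
scanner dead time the trial-level text does not determine.

## GLM

The canonical HRF is the SPM-convention double gamma (response gamma
peaking at 6 s, undershoot at 16 s, ratio 1/6, 32 s window), normalized
to unit peak. Event regressors are boxcars on a 0.1 s microtime grid,
convolved and sampled at volume midpoints (TR default 2 s) — fine enough
that 2 s events are not aliased. Framewise displacement is the sum of
absolute temporal derivatives of the six rigid-body parameters, with
rotations converted to arc length on a 50 mm sphere (the conversion
radius is configurable; the source text states no unit convention), and
FD[0] = 0. A constant-motion run yields an all-zero FD column, which is
dropped rather than left to break the design rank. Question trials form
one pooled nuisance regressor; motion parameters themselves are not
included (only FD is described). No temporal prewhitening is applied in
the GLM — noise correlation is handled spatially at the crossnobis
stage; the residual temporal autocorrelation inflates no group-level
test because inference operates on per-subject distances, not on GLM
statistics.

## Synthetic data

Ground-truth condition means are sums of seeded random unit-norm
component vectors — one per category, domain and quadrant plus one per
condition — scaled by the named effect sizes, so the true RDM is
available in closed form. Noise defaults: exchangeable spatial
correlation ρ = 0.3 with unit variance (strong enough that prewhitening
demonstrably matters) and AR(1) temporal autocorrelation φ = 0.4 in
time-series mode; both configurable. Head motion is a seeded random walk
(rotations two orders of magnitude below translations); it feeds the FD
regressor but does not corrupt the signal — FD is exercised as a
nuisance, not as an artifact model. Between-subject variability is a
seeded Gaussian perturbation of the true patterns (default scale 0.3
pattern units) in whole-study simulations; note that this gives every
subject small nonzero true distances even under a "null" profile, which
is realistic heterogeneity but *not* an exact null — the calibration
studies therefore use a multiplicative per-subject gain on the signal
difference instead, so their null regions are exactly null.

What the generator does not emulate: physiological noise, scanner
drift, susceptibility artifacts, spatial ROI anatomy, task-correlated
motion. Passing tests demonstrate the correctness and calibration of
the *analysis*, not the realism of any particular effect-size regime;
no published effect sizes exist for these data (figure axis ranges are
not reproducible quantities), so the synthetic separations are free
parameters with defaults chosen to put single-study power in a
realistic 0.8–1.0 band.

## Cell averaging and outlier exclusion

RDM cells are selected by same/different/ignore predicates on the three
factors, optionally restricted to categories/domains; selections are
unordered pairs and never include the diagonal. Quadrant predicates are
applied within a single category (categories are never mixed across a
quadrant comparison). Exclusion masks cell values strictly beyond ±2
pooled SDs (pooling subjects and stimulus pairs of the selection, per
region — RDMs are region-specific, and the original region scoping is
not stated), *before* within-subject averaging; a value exactly at the
boundary is retained. Trimming a right-skewed null distribution pulls
the post-exclusion mean slightly negative; this is a property of the
published rule, visible in the null-study test, and accepted. If every
cell of a subject's selection is excluded the subject's value is absent
and the subject drops listwise from any comparison using it (recorded
in the audit trail). Subjects who took part in two experiments
contribute the arithmetic mean of their two values.

## Inference

All "higher than zero" and directional comparisons are one-tailed — the
printed (t, p) pairs (t=2.49, df=18 → p=0.0112; t=1.94 → 0.0341)
reconstruct only under the one-tailed convention, which calibrates the
implementation. Stage-1 gates run per region at alpha = 0.05 divided by
the hemisphere-resolved seed count (8 or 12). Stage-2 tests run only in
regions whose required gates all passed, at the published explicit
thresholds where available (0.0056, 0.0125, 0.05/6, 0.025, 0.05/3) or
at 0.05 / (regions actually tested) otherwise; the 0.0056 threshold is
kept as an explicit fixture because its implied divisor (9) does not
match the listed eligible-region count (8). Two-sample comparisons use
pooled variance with df = n_a + n_b − 2 computed from the data (printed
df subscripts are not trusted: some published "t_27" values pair with
group sizes implying larger dfs). ANOVAs are one-way between-groups, per
the published wording; a repeated-measures variant would be defensible
for the equal-n imagery categories but is not what the text describes.
Significance is strict inequality p < alpha. Gate discipline — no
stage-2 result for an ineligible region — is asserted on every fit.

Under an exactly null geometry the one-sample gate's type-I rate sits
slightly *below* the corrected alpha at small region sizes (the
per-subject null distance is right-skewed, which makes the t statistic's
upper tail conservative; an independent 200k-test simulation gives a
true rate of ≈0.0037 at 20 voxels × 4 runs versus ≈0.0049–0.0054 at
100–200 voxels × 5 runs against a nominal 0.00625). The calibration
studies therefore use 5 runs and 100 voxels — the scan count of the
five-run experiments and a realistic ROI size — where the gate is close
to nominal; the residual mild conservativeness is inherent to t-tests
on skewed distance estimates at n = 16 subjects.

The power study's effect size is fixed *a priori* by a noncentral-t
power analysis targeting 95% power at alpha = 0.05/8, using the
closed-form replicate variance of the estimator under white noise,
$\mathrm{Var}(d) \approx 4D\tau^2/M + 2P\tau^4/(M(M-1))$ with
$\tau^2 = 2\sigma^2$, plus the between-subject variance implied by the
multiplicative gain $g_s \sim N(1, 0.25^2)$.

## Problem sizes

The simulation studies use deliberately compact sizes: null
unbiasedness at 2 conditions × 100 voxels × 5 runs × 1000 replicates;
full-pipeline recovery at 12 voxels × 4 runs × 16 trials per run × 200
replicates (pooled dof ≈ 150 ≫ P, where the Wishart correction is
essentially exact); gate calibration at 8 regions × 16 subjects × 500
replicate studies. These reproduce the asymptotic behaviour the larger
published study relies on while keeping any replication run in the
minutes range.

## Known limitations

* ROIs are opaque labels: no spatial structure, surface analysis or
  mask arithmetic (real-data ROIs enter as voxel index sets).
* Only the crossnobis dissimilarity is implemented; correlation
  distances, decoding accuracies and model-based RDM regression are out
  of scope.
* The GLM assumes temporally white noise; with the default AR(1)
  simulation noise the betas remain unbiased but are not minimum
  variance, which the distance cross-validation tolerates by design.
* Multiple-comparison policy is Bonferroni only, mirroring the analysis
  being reproduced; no FDR or permutation alternatives.
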