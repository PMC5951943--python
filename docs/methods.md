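# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical conventions, and the design choices behind `seedgc`, in the spirit
of the model documentation of packages like statsmodels or msprime.

## Signed-path-coefficient Granger causality

Effective connectivity between the seed mean series `X_t` and each voxel
series `Y_t` is the pair of lag-1 signed path coefficients from the two OLS
regressions

```
Y_t = A1 X_{t-1} + B1 Y_{t-1} + C Z_t + e_t
X_t = A1' Y_{t-1} + B1' X_{t-1} + C' Z_t + e'_t        t = 2..T
```

with intercepts, on mean-centered series. The model order is fixed at one
lag (one TR = 2.5 s at the emulated acquisition). Conventions:

- **No variance standardization.** Series are centered but not z-scored, so
  coefficients keep regression scale: doubling `Y` doubles `A1` and halves
  `A1'` exactly. Z-scoring would make the coefficients scale-free; since the
  inferential results (signs, t-maps, correlations) are unaffected, the
  regression scale was kept and the choice is exposed here rather than as an
  option.
- **Exogenous covariates default to empty.** The nine nuisance covariates
  are already regressed out of the data during preprocessing; carrying them
  again as `Z_t` would be a double regression. The `C Z_t` term is
  implemented for callers who skip nuisance preprocessing.
- Both regressions share the predictor set `{X_{t-1}, Y_{t-1}, Z_t, 1}`, so
  whole-brain maps are computed by assembling one Gram matrix per voxel
  (batched 3x3 or (3+q)x(3+q) solves) with two right-hand sides. A spot-check
  test verifies map values equal the single-pair fit voxel-by-voxel.
- Zero-variance voxels and voxels whose lag column is numerically collinear
  with the common design (e.g. a voxel identical to the seed mean under a
  single-voxel seed) are flagged and given coefficient 0 rather than fitted.

Estimator recovery: with `T = 230` and a planted coefficient of 0.5 over
white noise, the mean estimate over 200 replicates is within 0.02 of truth
and the reverse-direction coefficient is unbiased (both recomputed by
`scripts/acceptance.py`).

A caveat worth knowing: band-pass filtering before a lag-1 fit biases the
coefficients toward zero and redistributes variance onto the autoregressive
term, because filtering breaks the Markov structure of the generating
recursion (the filtered innovations correlate with the lagged regressors).
Group-difference signs, t-maps and correlation signs survive; absolute
coefficient recovery does not. The recovery checks in the test suite
therefore run the fit on unfiltered (discard + detrend + nuisance-regressed)
data, while the full pipeline keeps the conventional band-pass.

## Preprocessing

Order of operations: discard the first 10 volumes; 6-mm FWHM isotropic
Gaussian smoothing (sigma = FWHM / (2 sqrt(2 ln 2)) per axis, zero-padded
boundaries, no renormalization, applied volume-wise); per-voxel OLS removal
of intercept + linear trend; ideal frequency-domain band-pass retaining DFT
bins with 0.01 Hz <= f <= 0.08 Hz inclusive (exactly idempotent); regression
of nine nuisance covariates (CSF mean, WM mean, global mean over the brain
mask, six motion parameters), all mean-centered, from every voxel. Tissue
masks are taken as supplied (no internal erosion). Zero-variance nuisance
columns are dropped; exactly redundant columns are dropped inside the
pipeline (and raise, with names, in the standalone `regress_nuisance`).

Motion files follow the realignment-parameter dialect: three translations in
mm, three rotations in radians. The exclusion rule converts rotations to
degrees and flags a subject when any parameter's maximum absolute excursion
reaches 1.5 mm or 1.5 deg (inclusive). Flagged subjects are excluded and
listed in the pipeline report.

Global-signal regression constrains the voxel series to sum to ~0 at each
timepoint, which leaves a tiny negative offset (order 0.003) in the
brain-wide mean of the EC maps. This is a known property of global-signal
regression, two orders of magnitude below the planted effects, and is
accounted for in the null-construction tests.

## Group inference

**GLM t-maps.** Per voxel, OLS of the EC value on
`[intercept, group indicator, centered covariates]`; `t` = contrast estimate
over its standard error; `df = n - rank`. Intercept-only designs reproduce
the one-sample t-test formula exactly. Rank-deficient designs raise with the
colliding column names. Voxels with (numerically) zero residual variance get
`t = 0`.

**Smoothness estimation.** The first-difference variance-ratio (Forman-style)
estimator per axis, applied to the GLM residual maps after per-voxel variance
standardization, and averaged across maps. The neighbor correlation is
estimated as `rho_hat = 1 - Var(Delta)/(4 Var)` — the sqrt(2)-normalized
increment convention of the resting-state toolbox lineage — and mapped to
FWHM through the Gaussian autocorrelation model
`FWHM = d sqrt(-2 ln 2 / ln rho_hat)`. Two consequences, both intentional:

- unsmoothed iid noise reports an intrinsic smoothness of sqrt(2) voxels
  (about 1.41, i.e. 4.25 mm at 3 mm voxels), not zero;
- the estimate refers to the *studentized* residual field, which is what the
  thresholded t-map inherits. Standardization matters at low group sizes:
  the raw residual variance varies strongly across voxels (planted regions,
  near-seed voxels), and an unstandardized estimate understates the
  smoothness of the field on which clusters actually form, making the
  cluster-extent correction anticonservative.

**Cluster-extent Monte Carlo.** Per iteration: white noise on the mask grid,
smoothed by the Gaussian kernel that *inverts* the estimator above (so the
simulated field reproduces the requested estimated FWHM; FWHM at or below the
sqrt(2)-voxel floor means no smoothing), standardized in-mask, thresholded at
the two-sided Gaussian `voxel_p` quantile, positive and negative parts
clustered separately at 26-connectivity, maximum component size recorded.
The returned extent is the smallest `k` with
`(1 + #{max >= k}) / (1 + n_iterations) <= cluster_p` (add-one estimator;
a `cluster_p` below `1/(1+n_iterations)` raises, reporting the attainable
floor). Default 1000 iterations gives a threshold stable to about one voxel
at the default geometry; the calibration analyses use 500.

The voxel threshold `P < 0.001` is interpreted two-sided (`|t| >=
t_{1-0.0005, df}`), since both excitatory and inhibitory influences are read
from the same maps. Connectivity defaults to 26 neighbors (edge/corner
touching), the AFNI/DPABI-lineage default; 6 and 18 are available.

**TFCE.** `TFCE(v) = sum_h extent(v,h)^E h^H dh` with `H = 2`, `E = 0.5`,
heights at the midpoints of `n_steps = 100` equal steps of `dh =
max|map|/n_steps`; negative values are enhanced on the negated map and
re-negated. The permutation test compares the observed TFCE map against the
max-|TFCE| distribution over group-label permutations (two-sample) or sign
flips (one-sample), with the add-one corrected p
`(1 + #{perm max >= obs}) / (1 + n_perm)`; ties count against rejection.
When fewer distinct relabelings exist than requested permutations the test
enumerates all of them and reports that it did.

Nuisance covariates in the two-sample permutation are handled by simple
label permutation (covariates stay attached to their subjects); a
residual-forming (Freedman-Lane) scheme is a documented extension point, not
implemented.

**Calibration.** On 200 null synthetic datasets (16^3 grid, 12 vs 12
subjects, 200 permutations, TFCE at 25 steps — the max-statistic FWE
guarantee holds for any monotone statistic, so the step count only trades
resolution for runtime), the TFCE family-wise rejection rate at 0.05 falls
inside the binomial band [0.02, 0.08], and the cluster-extent procedure's
family-wise false-positive rate stays below twice the nominal cluster-level
alpha (it is conservative in practice). These problem sizes are the
package's standard desk-scale calibration settings.

## ROI statistics

"6-mm-diameter" spheres are read literally: radius 3 mm with inclusive
boundary, i.e. the center voxel plus its six face neighbors on a 3 mm grid
(7 voxels). Many papers mean radius 6 mm instead; the diameter is a
parameter. Per-subject ROI values are arithmetic means over the sphere.
Pearson correlations use the exact t-based two-sided p with n-2 df, computed
within the patient group by default (a flag selects the control group). No
correction is applied across the several ROI-scale pairs; p-values are
reported raw — a deliberate mirror of common practice and a caveat for users
screening many ROIs. The chi-square for 2x2 sex tables is Pearson's without
continuity correction (the Yates-corrected variant gives visibly larger p on
tables of this size). Group scalar comparisons use the pooled-variance
two-sample t.

## Synthetic data generator

The generator emulates a two-group resting-state study: default 16^3 voxels
at 3 mm, 240 volumes at TR 2.5 s (230 analyzed after discard), 12 + 12
subjects. Three disjoint 3^3 regions are planted:

- **seed**: voxels share a latent AR(1) signal `X_t` (autoregression
  `b = 0.3`, innovations scaled for unit variance);
- **forward target**: each voxel follows `Y_t = a X_{t-1} + b Y_{t-1} +
  N(0, 1)` with independent innovations per voxel; the subject-level `a` is
  the group value (default 0.0 patients / 0.4 controls) plus N(0, 0.05)
  jitter, giving the ROI-correlation stage a continuous relationship to
  recover;
- **reverse source**: a shared latent AR(1) that drives the seed with the
  group-dependent reverse coefficient (default 0.0 / 0.25).

Stationarity (`|a| + |b| < 1`) is validated for every planted pair, and the
target voxels' lag-1 autocorrelation matches the VAR(1) value from the
discrete Lyapunov equation (tested). The default group layout deliberately
gives the *patient* group the weaker influence, so the patient-minus-control
contrast in the target region is negative, and the synthetic
insomnia-severity score `ISI = 19.5 - 30 a + N(0, 1)` is higher in patients
and negatively coupled to the planted coefficient — the qualitative
signature the full pipeline must reproduce. PSQI, SAS and SDS are noisy
increasing transforms of ISI.

Noise model: spatially smooth background noise (white noise smoothed with a
3 mm FWHM kernel and rescaled to SD 0.35) added to *all* voxels — the
planted signals themselves are never smoothed, so ground-truth coefficients
stay exact. The mild 3 mm background correlation emulates
resampled-but-unsmoothed EPI noise; the analysis smoothing pass (6 mm) then
dominates the spatial covariance, keeping the EC-map noise close to a
single-FWHM Gaussian autocorrelation family, which is the regime the
cluster-extent Monte Carlo models. Slow (< 0.01 Hz) cosine drifts are added
globally and, with larger amplitude, inside shipped WM-like and CSF-like
mask blocks; six motion-like zero-mean random walks (steps 0.01 mm /
0.0002 rad) are written to the motion tables and leaked into the data
through small random spatial weight maps. Default walks stay well below the
1.5 mm / 1.5 deg exclusion bound, so exclusion logic is exercised without
firing.

What the generator does **not** emulate: scanner artifacts, slice-timing
offsets, physiological cardiac/respiratory cycles, realistic motion
interpolation effects, non-Gaussian BOLD noise, or anatomically shaped
masks. Passing tests therefore demonstrate correctness of the estimators and
calibration of the inference under a well-specified generative model, not
robustness to every property of real fMRI data — in particular, real data's
heavier-tailed spatial autocorrelation is known to make single-FWHM
cluster-extent corrections anticonservative.

## Pipeline and reproducibility

One global seed deterministically derives the per-stage seeds (simulation,
cluster-extent Monte Carlo, permutation test) through a seed sequence, so a
config plus one integer reproduces a run bit-for-bit. The pipeline refuses
to write into a non-empty output directory unless forced. Validation
failures (missing files, bad bands, too few subjects per group) abort with
itemized messages before any computation. Cluster peaks in the report are
round-trip consistent with the stat maps written to disk (tested).

Problem sizes used by the test suite and the acceptance script (16^3 grids,
12 + 12 subjects, 200 calibration replicates, 200 permutations, 500-1000
Monte-Carlo iterations, 10-20 end-to-end replicates) are the package's
desk-scale defaults for validating the machinery; all are configurable
upward.

## Known limitations

- Bivariate GCA only: no conditional/multivariate variant, no higher lags,
  no spectral measures, no F-statistics.
- Filtering-induced coefficient attenuation (above) means absolute EC values
  from the standard pipeline are shrunken relative to generating
  coefficients; comparisons and correlations remain valid.
- The cluster-extent Monte Carlo assumes a single-FWHM Gaussian spatial
  autocorrelation; mixture or long-tailed autocorrelations (common in real
  data) violate it.
- Simple label permutation with covariates is exact only under the strong
  null; Freedman-Lane is left as an extension.
- Age/sex/education are generated without group differences; the demographic
  tests are exercised but never significant by construction.
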