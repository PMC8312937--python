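# Methods

## The model

`voxelbma` performs a mass-univariate Bayesian model averaging (BMA)
analysis of skeletonized fractional anisotropy (FA) volumes. At each
voxel v the response across the n subjects is an ordinary linear
regression

    y(v) = b0 + X beta(v) + eps,   eps ~ N(0, sigma^2(v) I),

where X is an n x k design matrix shared by all voxels. The default
design encodes four base covariates — sex (1 = male), years of cocaine
use (YCU, 0 for controls), and two binary SNP carrier indicators (GAD1a
= rs1978340, GAD1b = rs769390) — together with every two-way product
and the YCU|GAD1a|GAD1b three-way product, k = 11 columns in a fixed
order. Interactions are products of the raw, uncentered parent columns,
so a control subject (YCU = 0) is exactly zero in all five YCU-bearing
columns. No hierarchy constraint is imposed: the model space is all
2^k = 2048 covariate subsets, each with prior probability 1/2048.

## Priors and the closed-form marginal

Parameters common to all models get the standard non-informative prior
p(b0, sigma) ∝ 1/sigma; the included coefficients get the Zellner-type
prior beta_j ~ N(0, sigma^2 (g X_j'X_j)^{-1}) with g = 1/max{n, k^2}.
Note that g here multiplies X'X, so it is the reciprocal of the
conventional Zellner g: the default is the unit-information / BRIC
prior (conventional g_z = max{n, k^2} = 121 at n = 57, k = 11). The
marginal likelihood of model M_j is then closed-form; up to an additive
constant shared by every model at the voxel,

    log p(D|M_j) = (k_j/2) log(g/(g+1))
                   - ((n-1)/2) log( SSR_j/(g+1) + g TSS/(g+1) ),

with SSR_j the residual sum of squares of the centered response on the
centered included columns, TSS the total centered sum of squares, and
k_j the number of included covariates; the null model contributes
-((n-1)/2) log TSS. Both y and the included columns are demeaned before
the projection. The printed form of this marginal is ambiguous about
centering in the projection term; the fully centered form is used here
and is the one the test suite's independent 3-D quadrature oracle
(adaptive integration of likelihood x prior over (b0, beta, sigma) at
n = 6) confirms to well under 1% relative error.

All marginals are computed and normalized in log space (log-sum-exp),
since 2048 marginals at one voxel can span hundreds of log units.
Because X is voxel-invariant, the per-model QR factorizations of the
centered submatrices are computed once (`ModelSpace`) and each voxel
reduces to one matrix product; voxels are processed in vectorized
chunks of 512.

Models whose centered included submatrix is rank-deficient — which
happens for some interaction subsets with binary covariates at n = 57
— receive posterior probability 0 with a counted warning rather than
aborting the voxel. Within a model, the conditional posterior mean of
the included coefficients is the least-squares estimate on centered
data shrunk by 1/(1+g); the model-averaged (unconditional) coefficient
mean weights these by posterior model probabilities, with excluded
covariates contributing 0. Reported coefficient signs come from this
unconditional mean; the conditional-on-inclusion mean would differ only
in scale for any covariate, never in sign, but the unconditional choice
is documented because summaries depend on it.

## Posterior inclusion probabilities and MC3

The PIP of covariate c at a voxel is the total posterior mass of models
that include c. The default engine enumerates all 2048 models (cheap
with the precomputed factorizations); a Markov chain Monte Carlo model
composition (MC3) sampler is provided as an alternative for model
spaces beyond the enumeration guard (k > 20) and as a validation route.
The chain proposes uniformly from the neighborhood of the current
subset — all subsets at Hamming distance 1, plus the current subset
itself (self-inclusion is on by default and exposed as a flag; it does
not change the stationary distribution, only mixing) — and accepts with
probability min{1, marginal ratio}. Every visited model's marginal is
exact and cached, so two posterior estimates are available: raw visit
frequencies, and the exact marginals renormalized over the visited set.
The renormalized estimator has much lower variance (it equals the true
posterior restricted to the visited models) and is the pipeline
default. The chain starts at the null model for reproducibility (a
random start is available); per-voxel RNG streams are derived from
(master seed, voxel flat index), so results are independent of worker
count and scheduling. Default run length 20,000 iterations with 2,000
burn-in is this package's choice — at k = 11 it brings the per-voxel
PIP error of the renormalized estimator under 0.01 in the regimes the
tests cover.

## Masking and Bayesian FDR

A voxel enters the analysis iff no subject has FA exactly 0 there
("black voxel" rule; a flag switches to the weaker all-subjects-zero
reading) and the across-subject mean FA is at least 0.2, below which a
voxel carries little white matter. Constant-response voxels are
skipped and counted.

Voxel-level evidence is thresholded per covariate by the Bayesian false
discovery rate rule at level delta = 0.10: sort the PIPs descending
(Psi), take the largest k* such that the running mean of (1 - Psi) over
the top k* stays <= delta, and declare every voxel with PIP >= phi =
Psi[k*] (ties at the threshold all included). The quantity this rule
controls is the *realized Bayesian FDR* of the declared set — its mean
posterior non-inclusion probability — which is the standard notion of
realized FDR in the Bayesian FDR literature. The test suite verifies
this calibration on replicate pure-null images. The frequentist
false-discovery proportion under a point-null generator is *not*
controlled by this rule and is substantially larger on pure-noise data
(the calibration helper reports it alongside; on 20 null replicates of
~2,000 voxels most replicates contain a handful of chance-correlation
voxels with PIP above 0.9 that the rule admits). This is a property of
Bayesian FDR itself, not of the implementation. Thresholding is per
covariate; a pooled mode over all covariates exists for sensitivity
analysis. Raising delta never shrinks the declared set.

## Region aggregation

Significant voxels are mapped to atlas labels (0-based array indices;
spatial interpretation is entirely the affine's job, and no resampling
is performed — the atlas must share the FA grid). Off-atlas voxels
(label 0) get their own "unclassified" row so that region counts sum
exactly to each covariate's significant-voxel count. Sign-proportion
tables report, among a covariate's significant voxels in a region, the
fraction with positive (negative) model-averaged coefficient; exact
zeros count in neither, and cells with no significant voxels are
reported absent (NaN) rather than zero.

## Synthetic data

The generator reproduces the statistical structure the analysis
assumes, not DTI physics. Cohorts default to the study template: 39
cocaine-use-disorder subjects (29 male / 10 female; YCU uniform on
0.25-30 years) and 18 controls (11 male / 7 female; YCU = 0), with
GAD1a/GAD1b carrier frequencies 0.615/0.846 (CUD) and 0.421/0.789
(controls), drawn independently. FA volumes sit on a small grid (default
12^3) carved into axial-slab toy-atlas regions; the baseline is 0.45
with smooth low-frequency cosine jitter (amplitude 0.02), comfortably
above the 0.2 mask threshold, with an optional sub-threshold region
(baseline 0.15) and a zeroed border to exercise both masking rules.
Planted effects add effect_c * x_ic inside designated regions; noise is
iid Gaussian (sd 0.02) and values are clipped into (0.01, 0.99) with
the clip count reported (a construction check rejects effect sizes that
could leave the unit interval). A truth record lists every signal voxel
so recovery tests never re-derive ground truth. The response is
Gaussian with clipping rather than Beta-distributed — matching the
analysis model — and noise has no spatial autocorrelation, so passing
tests say nothing about spatially correlated noise, TBSS skeleton
geometry, or registration error in real data.

No FA-per-covariate effect scale is available to copy, so effect sizes
were chosen for test power by a pilot run performed before the test
suite was frozen: at the default strong effect (0.004 FA per YCU-year)
signal-voxel PIPs saturate near 1 and exceed null-voxel mean PIPs by
>0.5 (frozen margin); for end-to-end recovery the pilot selected 0.0016
FA per YCU-year, at which the planted covariate's FDR-significant set
concentrates >= 90% in the planted region across seeds (at much larger
effects the saturated signal PIPs let the running-mean rule admit more
off-region voxels, diluting concentration to ~84%).

## Problem sizes and numerical choices

Desk-scale defaults keep everything text-friendly and fast: test
images use 8^3-15^3 grids (a few hundred to ~2,500 masked voxels),
the null-calibration study uses 20 replicates of ~2,000 voxels, and
enumeration runs at roughly 1 ms/voxel on one core. A full-scale run
(hundreds of thousands of voxels) is supported by chunked processing
with periodic checkpoints (default every 50,000 voxels) keyed to a
config digest, so an interrupted run resumes without recomputation.
Ties in the best-model selection break to the smaller model-space
index; rank tolerance for the per-model QR is n * eps * max column
norm; posterior normalization is exact to 1e-10 by construction.

## Known limitations

- The linear-Gaussian response can in principle predict outside (0, 1);
  a Beta-response model would respect the FA range but is out of scope.
- Frequentist FDP is not controlled under point-null data (see above).
- No spatial modelling: voxels are analyzed independently, and the
  atlas must already be in register with the FA stack.
- Binary carrier coding for the SNPs; allele dosage is not supported.
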