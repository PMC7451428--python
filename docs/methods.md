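# Methods

`seedgc` implements a seed-based analysis of how directed (effective)
connectivity between a spherical seed region — by default the right
anterior insula (rAI), a 6-mm sphere at MNI (33, 21, −3) — and every brain
voxel changes when a person shifts from rest to an engaged working-memory
state, together with group inference, cluster-level correction and
clinical-association statistics, and a synthetic-cohort generator that
makes each stage testable by parameter recovery.

## The connectivity model

Directed influence is quantified by a bivariate lag-1 Granger regression.
For a source series x and target series y, both z-scored, the *path
coefficient* (PC) is the OLS coefficient b in

    y_t = c + a·y_{t−1} + b·x_{t−1} + e_t .

b is signed and standardised: on a stationary VAR(1) system it converges to
the standardised cross-coefficient (planted coefficient × sd_x / sd_y); on
independent series its null distribution is centred on zero with the usual
t calibration (verified empirically: 5% rejection within [0.03, 0.07] at
T = 235). Only the one-lag term is used; there is no instantaneous
regressor, so b is a purely directed quantity.

Maps are computed in both directions: seed→voxel (the seed's lag predicting
each voxel) and voxel→seed. These are two different regressions, not
transposes of one another.

- **Rest state.** The PC is estimated once over the full retained,
  preprocessed resting series (240 acquired volumes at TR 2.5 s, first 5
  discarded → 235).
- **Task state.** Only the highest-load (2-back) condition blocks are used.
  Within each 30-s block (12 volumes at TR 2.5 s) the series are linearly
  detrended, mean-centred and (by default) scaled to unit SD; the PC is
  estimated per block and averaged, unweighted, across the 14 blocks
  (7 per session × 2 sessions). Blocks shorter than 6 volumes are dropped
  with a warning. Volumes are assigned to blocks by acquisition midpoint;
  no haemodynamic shift is applied to block boundaries (a configurable
  offset exists, default 0 s).
- **CPC.** The change of path coefficient is the voxelwise task − rest
  difference — positive where the directed influence grows under task
  demand. A functional-connectivity analogue (`fc_change_map`, Pearson r
  instead of b) provides the undirected control analysis.

Per-block z-scoring is exposed as an option (`zscore_blocks`) because only
mean-centring is strictly required by the blockwise protocol; z-scoring is
the default for scale invariance across blocks.

Known finite-sample property: with only 12 samples per block, the
within-block demeaning/detrending couples the lagged regressors to the
error (a Hurwicz/Nickell-type bias), so a purely unidirectional planted
influence produces a small opposite-signed coefficient in the reverse
regression, roughly one third of the forward signal at 12 samples/block and
shrinking like 1/n_block. Forward/reverse asymmetry therefore remains clear
(the pipeline measures a forward:reverse magnitude ratio of ~3 at the
planted node, converged over 32 subjects) but does not reach arbitrarily
high ratios at this block length. This is a property of blockwise lag-1 GCM at short blocks, not of
this implementation.

## Preprocessing

Already-normalised 4D volumes are processed as: discard first 5 volumes
(rest only) → scrub → smooth (8 mm FWHM isotropic Gaussian) → band-pass
(rest only; ideal FFT filter retaining 0.01–0.08 Hz, DC removed) →
nuisance regression. Choices the protocol leaves open:

- **Framewise displacement** uses Power's scalar convention:
  fd_t = Σ|Δtrans| + 50 mm·Σ|Δrot|, fd_0 = 0.
- **Scrubbing** replaces volumes with fd > 0.5 mm (configurable) by linear
  temporal interpolation between the nearest clean neighbours
  (nearest-neighbour at the ends) — a stand-in for repair-style
  deweighting, exact on locally linear signals.
- **Nuisance regressors**: 6 motion parameters + global, white-matter and
  CSF means, computed state-specifically (rest and task each use their own
  session's signals). The task chain adds one HRF-convolved boxcar per
  condition (0/1/2-back, instruction, interval) to the nuisance matrix, so
  signal shared with the task design cannot masquerade as connectivity.
  Residuals are exactly orthogonal to every regressor.
- **Band-pass** is an ideal frequency-domain filter because its behaviour
  is exactly testable (pass/stop ratios verified against an FFT oracle).
- **Subject exclusion** follows the stated rules: translation > 3.0 mm or
  rotation > 3.0° (strict inequalities) or task hit rate < 30%.
- The canonical HRF is the double-gamma kernel (peak delay 6 s, undershoot
  16 s, unit dispersions, ratio 6), peak-normalised; for regressor
  construction it is rescaled to unit sum so a sustained boxcar plateaus at
  ~1 regardless of grid resolution.

Seed extraction averages voxels whose centres fall within the sphere
radius (≤, voxel-centre distance, 0-based indices, affine-defined mm).

## Group inference

Per-subject CPC maps are compared between groups voxelwise by OLS with
design columns [intercept, group ±1, age, gender, meanFD_rest,
meanFD_task]; the reported t is the group-contrast coefficient over its
standard error, df = n − 6 (54 at the full 29+31 sample). Two meanFD
columns are used — one per state — which is what makes the df arithmetic
come out at n − 6.

Cluster-level correction is a Monte-Carlo (AlphaSim-style) procedure run on
the analysis mask: per iteration, Gaussian noise is smoothed to the
residual smoothness (estimated per axis from within-mask first differences
of the regression residual maps, clamped to ≥ 1 voxel), re-standardised
within the mask, thresholded two-sided at the voxel p (default 0.01), and
the largest suprathreshold cluster recorded (26-connectivity by default;
positive and negative tails clustered separately, exactly as in the real
extraction, so opposite-signed clusters never merge). The extent threshold
is the smallest k whose null exceedance probability is ≤ α (default 0.05).
Self-consistency: applying the threshold to fresh matched null maps keeps
the familywise error ≤ α within binomial noise (measured ≤ 0.08 at
n_iter = 1000 / 500 fresh maps).

Cluster statistics: extent K, peak |t| voxel with MNI coordinates via the
affine, cluster p from the null max-extent distribution, per-subject
cluster-mean CPC, and Cohen's d = t·√(1/n1 + 1/n2). One-sample tests on
cluster means are reported per group in plain mode (df = n − 1) by default,
with a covariate-adjusted mode (intercept t after regressing on demeaned
covariates) available — both are provided because the protocol describes
covariate adjustment while its reported degrees of freedom correspond to
the plain test. The activation-confound control re-runs the group test
with per-subject 2-back GLM betas (seed and cluster) appended as
covariates.

## Clinical associations

Spearman correlations (Pearson on average ranks) are used for behaviour
and symptom scores, Pearson for the functioning/symptom-total scales;
partial variants correlate OLS residuals on the covariates (ranks first
for partial Spearman). p-values use the t approximation with
df = n − 2 − #covariates, which reproduces printed worked examples
(r = 0.478, n = 31 → p = 0.0065; r = 0.3765, n = 29 → p = 0.0441). Group
differences between correlations use the one-tailed Fisher r-to-Z test.
Demographic 2×2 tables use the Pearson chi-square without continuity
correction (the convention that reproduces the published table);
continuous demographics use the pooled-variance t from group summaries.
Hypothesised symptom tests are flagged at p < 0.025 two-tailed,
exploratory tests at p < 0.05.

## The synthetic cohort

Latent dynamics are a switching VAR(1): x_t = A_state·x_{t−1} + ε,
ε ~ N(0, 1), with A_rest everywhere except inside 2-back windows, where
the subject's group-specific task matrix applies (volume membership by
acquisition midpoint). Instruction/interval periods use A_rest. The
connectivity switch is instantaneous; haemodynamic lag applies only to the
additive task-activation signal (unit-plateau HRF-convolved 2-back boxcar,
amplitude 0.5 on seed and target by default), which exists precisely so the
activation-confound control has something to control for. Node series are
embedded as Gaussian spatial profiles (sd 4 mm) at configured positions on
a 3-mm grid (24×28×24 default; 16×18×16 in the desk-scale demo), plus
i.i.d. voxel noise (sd 0.3), a shared slow global signal recorded in the
confounds, and random-walk motion parameters (≈0.1 mm mean FD) that feed
the FD/scrubbing machinery.

The planted effect: the seed→target coefficient is 0 at rest for everyone;
during 2-back blocks it is σ_b-jittered around 0 for controls and around a
group shift Δ for patients. Δ is derived from the requested group CPC
effect size d via a theoretical SD of the observed CPC,

    sd_CPC ≈ √(σ_b² + SE_rest² + SE_task²),
    SE_rest = 1/√(T_eff − 3),  T_eff = T_rest·(f_hi − f_lo)/f_Nyq,
    SE_task = 1/√(n_block − 5)/√(B),

with σ_b = 0.25 between subjects, chosen so the total cluster-level CPC SD
lands near 0.29 — the magnitude typical of cluster CPC variability in this
kind of data. Behaviour coupling is constructed exactly in-sample: hit rate
is a linear mix of the standardised planted CPC and an orthogonalised noise
vector, so the cohort's planted correlation equals the configured r
(default 0.5) identically; one symptom score (psychomotor poverty) is
coupled the same way within the patient group, the rest are independent
draws truncated at zero.

What the generator does *not* emulate: anatomy, physiological noise
spectra, scanner drift and slice timing, spatial dependence of motion, or
any nonlinearity of the BOLD response. Passing recovery tests therefore
demonstrates correctness of the estimators and inference machinery under
the assumed generative structure, not robustness to real-data artefacts.

## Recovery behaviour and statistical ceilings

On desk-scale cohorts (12+12 subjects, 16×18×16 grid) the planted cluster
is recovered as a corrected seed→brain cluster touching the planted node in
roughly 60–75% of runs, not more, and this is a power ceiling rather than
an implementation property: a two-sample comparison at d = 1.2 with
n = 12+12 and 6 design columns has ≈55% per-voxel power at the two-sided
voxel threshold p < 0.01, and spatial smoothing cannot buy it back when
between-subject variance (which is spatially coherent) dominates the
estimation noise (which smoothing does average away). The behaviour
coupling (r = 0.5) reaches p < 0.05 in roughly 70–80% of the runs in which
the cluster is found (attenuation of the estimated cluster-mean CPC against
the planted truth is ~0.9). Larger cohorts or larger planted effects move
both rates toward 1; the desk-scale defaults are kept because they exercise
the full pipeline in seconds per cohort.

## Problem sizes and numerical choices

Validation studies run at: 100 replicates × T = 235 for estimator
consistency; 60 subjects × 5000 voxels for null calibration of the group
test; 1000 Monte-Carlo iterations + 500 fresh null maps for familywise
error; 25 repeated 12+12 cohorts for end-to-end recovery; 12 subjects for
direction specificity. Degenerate (zero-variance) voxels receive PC = 0
with a logged count so group maps stay complete. All randomness flows from
a single master seed split per stage (`numpy` SeedSequence spawning), and
identical (config, seed) reproduce outputs bit-identically. Ideal-filter,
smoothing and interpolation tolerances are verified against closed-form
oracles in the test suite.
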