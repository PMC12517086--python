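# Methods

`painconn` re-implements, as a tested and reusable pipeline, an analysis
framework for relating resting-state EEG brain-network connectivity to
chronic pain intensity across multiple recording sites.  This note
documents the models, the synthetic data that stand in for clinical
cohorts, the numerical choices, and the limits of what the test suite can
show.

## The analysis in one paragraph

Epoched, artifact-free sensor EEG is band-pass filtered into theta
(4–8 Hz), alpha (8–<13 Hz), and beta (13–30 Hz) bands.  Per band, an
array-gain LCMV beamformer (Tikhonov regularisation at 5 % of the average
sensor power) projects the sensors onto parcel centroids.  Parcel signals
are aggregated into seven large-scale (Yeo) networks by an
orthogonality-constrained representative-signal algorithm.  Connectivity
between networks is the amplitude envelope correlation (AEC) of the
representative signals after symmetric orthogonalisation; activity is the
log absolute variance a network's representative explains.  Features are
harmonised across sites with parametric empirical-Bayes ComBat (age
protected), the outcome is z-scored within site, and age is regressed from
both sides.  Univariate statistics are Pearson correlations with Bayes
factors (stretched-beta prior, kappa = 1/3) in a discovery →
one-sided-replication → mega-analysis sequence; multivariate statistics
are elastic-net models evaluated by leakage-free leave-one-participant-out
(LOO) and leave-one-site-out (LOSO) cross-validation, with a one-sided
Bayes factor on the prediction–observation correlation.

## Representative signals

For a brain structure with source-reconstructed signals `A` (k_A × n,
rows centered) the fraction of variance a unit-norm time series `r`
explains is

    nu(r, A) = r Aᵀ A rᵀ / tr(Aᵀ A).

Unconstrained maximisation of `nu` gives the first principal component.
Field spread, however, mixes other structures' activity into `A`, so the
package constrains the representative to be orthogonal to time series
representing the rest of the measured activity:

* **pairwise** – for structures A and B, maximise
  `nu(r1, A) + nu(r2, B)` over orthonormal pairs in the row space of
  `[A; B]`;
* **global** (default, Nc = 3) – for structure A versus the rest of the
  brain B, maximise `nu(r1, A) + Σᵢ nu(rᵢ, B)` over orthonormal
  (Nc+1)-frames and keep `r1`.

### Solver

Feasible points are reduced exactly: every representative lies in the row
space of the concatenated data, so an SVD basis change turns the problem
into maximising a sum of heterogeneous Rayleigh quotients
`Σᵢ zᵢᵀ Gᵢ zᵢ` over orthonormal frames `Z ∈ R^{d×p}` (a Stiefel
manifold).  The solver alternates two exactly-feasible, monotone steps:

1. **block eigenvector updates** – each column is set to the leading
   eigenvector of its quadratic form projected onto the orthogonal
   complement of the other columns;
2. **Jacobi rotations** – for each column pair the optimal 2×2 rotation
   has the closed form `θ* = ½·atan2(2c, a−b)` with
   `a = uᵀGᵢu + vᵀGⱼv`, `b = vᵀGᵢv + uᵀGⱼu`, `c = uᵀGᵢv − uᵀGⱼv`;
   these reach the joint rotations that block updates alone cannot.

A frame is accepted when the Riemannian gradient norm falls below `tol`
(default 1e-8) or the sweeps reach a machine-precision fixed point
(relative objective change < 1e-14 with gradient < 1e4·tol; the linear
convergence rate can stall a small factor above an aggressive tolerance).
Initialisation is deflation-based (leading eigenvector of G₁, then
deflated leading directions of the remaining forms) plus seeded random
orthonormal frames; `restarts = 5` by default for direct solver calls (the
cohort feature builder uses 2, and 1 in the shipped large runs — the
deflation start alone reaches the optimum on every oracle instance
tested).  On all combined-rank ≤ 4
instances tested, the solver matches a brute-force Nelder-Mead search over
QR-parameterised frames to < 1e-4 in objective (usually machine
precision).  The sign of each representative is fixed to correlate
non-negatively with its structure's mean row.

Weights can be re-estimated per 2 s epoch (the formalism's letter) or once
on the concatenated epochs; the package default for cohort feature
extraction is concatenated estimation, which is statistically equivalent
for stationary synthetic data and roughly two orders of magnitude cheaper.

## Connectivity and activity

AEC between two band-limited signals is the Pearson correlation of their
analytic-signal magnitudes.  Before envelope computation the structure
signals are symmetrically orthogonalised (the closest set of exactly
zero-lag-uncorrelated signals in the least-squares sense, found by
alternating polar decomposition and magnitude refitting; tol 1e-10, ≤ 200
iterations), which removes the spurious zero-lag correlations that field
spread produces.  Envelopes are smoothed with a 0.4 s moving average
before correlating and 10 % of each epoch edge is trimmed.  The smoothing
reflects the slow-co-fluctuation convention of amplitude connectivity; it
is also what makes large envelope correlations attainable at all — the
Rayleigh-distributed magnitude fluctuations of a narrowband stochastic
carrier otherwise cap the measurable envelope correlation near 0.45.
Per-epoch correlation matrices are Fisher-z averaged; a concatenated mode
is available and is the cohort default.

Activity of a structure is `log` of the absolute variance of its parcel
signals explained by its representative, averaged over epochs.

## Synthetic data

Two generator tiers emulate the eight-site clinical study (site sizes
119/63/60/57/77/68/47/123, total n = 614; ~2/3 chronic back pain; pain on
the 0–10 numerical rating scale; ages ~N(50, 12²) clipped to [20, 80]).

**Signal level.**  Network sources are band-limited white-noise carriers
multiplied by log-normal envelopes `exp(0.8·g)` driven by a Gaussian
copula; the latent correlation for each pair is found by monotone 1-D root
finding on an empirically calibrated curve (latent → measured envelope
correlation; 24 replicate pairs × 300 s per grid point, cached per
band/sampling rate with a fixed internal seed, so results are
deterministic).  Calibration accuracy is ±0.02 on the mean over 20 seeds
at 300 s; attainable targets are band-dependent (≈ 0.74 ceiling in theta,
≈ 0.8+ in alpha/beta) because narrower relative bandwidth leaves more
carrier-magnitude noise in the envelope.  Parcel signals are their
network's signal plus local band-limited noise (relative amplitude 0.5 by
default).  Sensors see `Lᵀ · parcels` plus spatially white 1/f-amplitude
noise at a configurable SNR, cut into 2 s epochs with 50 % overlap.  The
toy lead field places parcels and sensors on rings with overlapping
Gaussian gain profiles (full row rank enforced; 1 or 3 orientation columns
per parcel).  Planted pain effects shift the per-band envelope-correlation
targets linearly in a latent pain score: theta slopes of 0.12 on all
limbic-network pairs (plus 0.10 on salience–somatomotor), with weaker
(±0.03–0.04) distributed alpha/beta slopes — mirroring the reported
structure in which theta/limbic carries the strongest univariate signal
and the other bands add complementary multivariate information.

**Feature level.**  For cohort-scale statistics, features are latent
standard normals with planted feature–pain correlations (one-factor
construction, always positive semi-definite) or a planted multivariate
pattern (pain = noisy linear readout of k informative features with total
signal R²), distorted by per-feature age slopes and per-site
additive/multiplicative effects (defaults N(0, 0.4) shifts, log-normal
(0, 0.15) scales), with pain mapped to the NRS by affine clip-and-round.

What the generators do **not** model: eye/muscle artifacts and bad
channels (the upstream preprocessing that removes them is out of scope;
synthetic epochs arrive clean), realistic head geometry, non-stationarity,
and 1/f source spectra within bands.  Passing tests therefore demonstrate
the correctness and calibration of the analysis machinery under its own
assumptions, not clinical effect sizes.

## Harmonisation and statistics

ComBat is the parametric empirical-Bayes location–scale model: features
are standardised with a design that includes site indicators and protected
covariates (age), per-site per-feature effects are shrunk toward normal /
inverse-gamma priors by the classic iterative solver, and the transform is
stored so it can be applied, without refitting, to held-out rows.  The
implementation agrees with the Bioconductor `sva::ComBat` reference to
< 0.02 on a shared fixture.  Note one intrinsic property verified in the
tests: when the true site effect is *identical* across features the
empirical prior collapses and the EB step shrinks per-feature noise toward
the common site mean, so per-feature site means equalise only to the
sampling noise of a site mean; with feature-heterogeneous site effects
(the realistic case) they equalise within 0.05.

The correlation Bayes factor integrates the exact sampling density of the
sample correlation (Hotelling 1953, hypergeometric form, evaluated in log
space) against a stretched-beta prior `Beta(1/κ, 1/κ)` on (−1, 1) with
κ = 1/3; one-sided variants renormalise the truncated prior, so
`BF_two = (BF_pos + BF_neg)/2` holds identically.  Agreement with an
independent fine-grid quadrature and with an external closed-form
implementation is < 1 % (in practice ~1e-13).  Evidence labels use
thresholds 1, 3, 10 and their reciprocals; boundary values fall to the
weaker-evidence bin, so BF = 1 maps to "anecdotal against".  Spearman
correlations with Benjamini–Hochberg q-values (scoped per analysis table)
accompany every Bayesian table as an outlier-robust cross-check.

Discovery sets are tested two-sided (standard features use the
prespecified sides: theta/beta power positive, peak alpha frequency
negative, alpha power two-sided); pooled replication sets are tested
one-sided in the discovery direction; mega-analyses merge all sites.
Harmonisation is fitted separately within discovery and replication sets,
and across all sites in the mega-analysis.

## Predictive models

Elastic net in the convention
`(1/2n)‖y − Xb − b₀‖² + λ(α‖b‖₁ + (1−α)/2‖b‖₂²)` with an unpenalised
intercept and training-fold standardisation, so
`λ_max = maxⱼ |⟨xⱼ, y⟩| / (n·α)` is exactly the smallest all-zero λ.  The
hyperparameter grid crosses α ∈ {0.01, …, 0.64} with 20 log-spaced λ
values down to 0.001·λ_max (140 settings); nested selection maximises the
inner-CV prediction–outcome correlation (10-fold by default,
site-sorted folds, ties broken toward stronger regularisation).  Per CV
fold, ComBat, within-site outcome z-scoring, age slopes, and feature
standardisation are estimated on training rows only.  In LOSO-CV the
held-out site is unseen by ComBat, so each test participant receives one
prediction per training-site assumption and the mean is returned; test-set
normalisation and age removal are estimated on the test site itself.
Bootstrap weight stability resamples participants with replacement
(default 1000 samples, hyperparameters re-selected per sample with a
5-fold inner loop) and reports the median weight and the sign-flip
fraction as an empirical p-value.

## Problem sizes in the shipped tests and acceptance script

Simulations are scaled to run on one CPU in minutes: envelope-correlation
calibration checks use 2-signal, 300 s simulations over 20 seeds; solver
oracle checks use combined rank ≤ 4; planted-effect recovery uses one
eight-site n = 614 cohort (inner 5-fold selection); permutation null
calibration uses n = 60 cohorts over 50 seeds with a reduced 2×8 grid; the
explanatory model ordering uses signal-level cohorts of 56 participants,
36 s recordings, a square ill-conditioned 21-sensor/21-parcel lead field
at −6 dB SNR (heavy field spread), with a 3×10 grid.  The theta-ablation
ordering holds on every tested cohort; the advantage over the
PCA-representative variant is small on synthetic data (the shared
symmetric-orthogonalisation step already removes most leakage from both
variants) and is asserted on average over cohorts, consistent with its
formulation as an average-case property.

## Known limitations

* Per-epoch representative weights at cohort scale are expensive
  (thousands of eigendecompositions per participant); the concatenated
  mode is the practical default.
* The envelope-correlation ceiling is band-dependent; targets above ~0.7
  in theta are rejected as infeasible rather than silently clipped.
* The LOO prediction–observation correlation has the usual slight negative
  bias under the null; the permutation tests quantify it rather than
  correct it.
* Region- and parcel-level feature extraction reuses the toy ring
  geometry; it exercises the code paths, not a realistic atlas.
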