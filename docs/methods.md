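# Methods

`fibromap` re-implements, as a tested pipeline over synthetic data, a
multi-modal endogenous-contrast MRI analysis of tumour fibrosis: IVIM
diffusion, dual-regime ultrashort-echo (UTE) T2\* relaxometry and
magnetisation-transfer (MT) parameter mapping, histology stain
quantification, and the imaging–pathology correlation/PLSR statistics that
link them. No animal data are used anywhere: a phantom generator emulates
the acquisitions, a slide renderer emulates the stained sections, and a
cohort generator emulates the matched-section table.

## Signal models

**DWI / IVIM.** The voxel signal over b-values (s/mm²) is bi-exponential,

    S(b) = S0 [ f exp(-b D*) + (1 - f) exp(-b D) ],

with pseudodiffusion fraction `f`, pseudodiffusion coefficient `D*` and
tissue diffusivity `D` (mm²/s). The perfusion-insensitive ADC is the
mono-exponential rate fitted to b ≥ 200 s/mm² only (inclusive, where the
pseudo-diffusion pool has decayed by ≥ e⁻¹⁰ for physiological `D*`). The
compound parameter `fD* = f·D*` is formed from the final estimates, so the
identity holds exactly by construction. IVIM initial values use the
segmented approach: `D` and the extrapolated intercept from the high-b
mono-exponential and `f = (S_obs(0) − intercept)/S_obs(0)` clipped to
[0, 1]; the *measured* b=0 value is used in the denominator. Degeneracy
between the two exponentials is kept at bay by the default boxes
`f ∈ [0,1]`, `D ∈ [10⁻⁵, 4·10⁻³]`, `D* ∈ [10⁻³, 0.5]` mm²/s.

**UTE T2\*.** Echoes are split at 1 ms (an echo at exactly 1 ms counts as
conventional). The forward model is the smallest two-pool signal the
two-regime fit can distinguish: a short-lived pool of amplitude
`S0s − S0l` decaying at `T2*short` plus a long pool `S0l` decaying at
`T2*long` (ms). Fitting is sequential: the conventional echoes give
(`S0l`, `T2*long`) by a mono-exponential fit that never sees the
ultrashort echoes; the extrapolated long-pool baseline is then subtracted
from the ultrashort echoes before the short-pool mono-exponential fit.
Without the subtraction the long pool — essentially constant across
TE 0.07–0.56 ms — biases `T2*short` far beyond any useful tolerance, so
"separate mono-exponential models" is implemented as *sequential* rather
than fully independent fits; only the conventional→ultrashort direction of
independence is asserted. The short-pool share of the TE→0 signal,
`ratio = (S0s − S0l)/S0s` (clipped to [0,1]), is the analogue of the IVIM
`f`; this is an interpretation — the quantity is named but not defined as a
formula in the source analysis — and is flagged as such here.

**MT / VFA.** Four spoiled-GRE volumes (flip angles 4° and 24°, each
with/without the MT pulse, TR 15 ms) give

    MTR  = (S_ref − S_MT) / S_ref                       (4° pair)
    T1, T1s  from the two-point VFA closed form:  regress S/sin α on
              S/tan α;  slope m  ⇒  T1 = −TR / ln m
    ka   = MTR / T1s
    δ    = (R1app·TR + α_nom²/2) (S_ref − S_MT)/S_MT    (4° pair, α in rad)

with `R1app = 1/T1` from the without-MT pair. The 4° pair feeds MTR and δ
because the δ formula rests on the small-flip-angle approximation; the 24°
acquisition serves the VFA fits only. Negative MTR values from noise are
clipped to [−0.05, 1] with a logged count rather than discarded; VFA slopes
outside (0, 1) flag the voxel as NaN.

### The B1 multiplier

`simulate_mt(..., b1=β)` models a transmit-field error by scaling **both**
the achieved readout flips (`α → βα`) and the MT saturation power
(saturation per TR ∝ β², the quadratic dependence of saturated power on
pulse amplitude). Under this model the estimator's errors compose as
follows: the VFA `R1app` is biased by ≈ 1/β², the measured saturation by
β², and in δ the two cancel almost exactly, while MTR inherits the full
≈ β² drift. Numerically (three-region phantom, β = 0.9): median error
0.25% for δ versus 13.8% for MTR. Scaling the readout flips alone would
invert this ordering — the R1app bias would then be uncompensated — so the
saturation-power scaling is an essential part of the model, not an option.

## Ground-truth phantom

Seeded random ellipsoid/box regions (default 3) tile the grid; each region
draws its parameters uniformly from configurable ranges chosen as
tumour-plausible at 1.5 T: S0 800–1200 (a.u.), f 0.05–0.25,
D 0.6–1.4·10⁻³ mm²/s, D* 8–40·10⁻³ mm²/s, T2\*short 0.3–0.7 ms,
T2\*long 12–30 ms, short-pool ratio 0.10–0.35, T1 0.9–1.6 s,
T1s 0.45–0.80 s, MTR 0.10–0.40. Derived maps are computed from exact
identities (`ka = MTR/T1s`, `fD* = f·D*`, `S0l = S0s(1 − ratio)`,
ADC ≡ D). The ground-truth δ is derived from MTR through the small-angle
SPGR relation `δ = (R1·TR + α²/2)·MTR/(1 − MTR)` at the default protocol
constants (TR 15 ms, 4°), the same constants the simulator uses, so
noiseless round trips are exact. The ROI is a central ellipsoid; no
anatomical realism is claimed.

**Noise.** Magnitude noise is Rician: `sqrt((S+n₁)² + n₂²)` with i.i.d.
zero-mean Gaussians of scale σ (a Gaussian mode exists for unit tests).
SNR is defined on the **acquired images** of each modality:
σ = (mean in-ROI noiseless signal of that stack)/SNR. Defining it against
the proto-density S0 instead would leave the 4° MT volume — whose steady
state is only ≈ 5% of S0 — at an effective image SNR of ~3, which is not
what "an SNR-50 acquisition" means in practice and says nothing about the
estimators.

## Fitting engines

The least-squares reference is `scipy.optimize.least_squares`
(trust-region reflective, box bounds, tolerances 10⁻¹⁴) and is
deterministic. The MCMC estimator — used, as in the source analysis, as a
robust least-squares estimator rather than for posterior inference — is a
random-walk Metropolis sampler with a Gaussian likelihood whose unknown
noise scale is marginalised under a Jeffreys prior, giving
log-posterior ∝ −(M/2)·log RSS plus log-uniform priors for parameters with
strictly positive lower bounds (flat otherwise). Defaults: chain length
5000, burn-in 1000, per-parameter proposal scales started at 2% of the box
width and adapted every 50 steps during burn-in toward ≈ 25% acceptance,
frozen afterwards (preserving detailed balance for the retained samples).
The point estimate is the marginal posterior median; spread is the IQR.
The sampler is vectorised across voxels sharing a design, so volume fits
remain desk-scale. On noiseless data the marginalised likelihood
concentrates the chain onto the least-squares optimum, which is exactly
the intended "robust least-squares" behaviour; agreement with NLLS is
< 1% median over 100 problems per model family.

## Histology

The slide renderer draws an elliptical tissue section (eosin-pink) on a
white background and carves stain regions by thresholding a
Gaussian-smoothed noise field at the per-image quantile of the requested
fraction, making the ground-truth mask exact to one pixel while remaining
blob-like. Reference colours (picrosirius red, DAB brown, counterstain)
are fixed RGB values with per-pixel Gaussian jitter (σ = 5). Microvessels
are small disjoint disks.

Segmentation converts to CIELAB, removes background (chroma < 10 *and*
L\* > 80 — a chroma-based rule rather than a pure luminance cut, so that
±10% uniform brightness changes do not move tissue pixels in or out of the
denominator), k-means-partitions the tissue pixels in the (a\*, b\*) plane
into two classes (seeded, 5 restarts, fitted on ≤ 50k subsampled pixels)
and takes the class whose centroid is nearer the reference stain colour.
A guard zeroes the result when the two centroids are nearly equidistant
from the reference or both are far from it (blank slides). Percent
positivity is over tissue pixels, not canvas. Microvessel density counts
connected components whose centroid falls in one of six seeded,
non-overlapping square fields (default 0.25 mm² each, a configurable
stand-in for a ×200 field) and divides by the total sampled area.

## Cohort generator and statistics

Each synthetic cohort row is one matched section. Collagen (picrosirius
%) is drawn from a clipped normal (mean 25, SD 15, range 3–80); every MR
parameter is `mean + scale·(r·z + noise_sd·sqrt(1−r²)·ε)` with z the
standardised collagen, so the expected sample correlation is `r` at the
default `noise_sd = 1` and exactly ±1 at `noise_sd = 0`. The per-parameter
targets are the configurable MT effect size (default 0.85 for ka and δ)
scaled by a fixed relative pattern that reproduces the empirical sign and
magnitude ordering (strong positive ka, δ, fD\*; strong negative T1s, T1,
T2\*long; weak D\* and T2\*short; MTR deliberately the weakest MT
parameter). Pimonidazole, microvessel density and necrosis are independent
fillers.

The statistics layer computes ROI medians (outlier-damping), the
Sørenson–Dice overlap (defined 1 for two empty masks), the repeat-measures
CoV on log-transformed values (`σ_w² = mean(d²)/2`,
`CoV% = 100·sqrt(exp σ_w² − 1)`; the first-order `100·σ_w` available by
flag), Pearson correlations with exact t-based two-sided p-values
(pairwise-complete, per-cell n logged) and Bonferroni-adjusted
significance (family α = 0.05 over the 4 histology markers → p < 0.0125),
and PLSR (NIPALS via scikit-learn, fold-local z-scoring) evaluated by
leave-one-out cross-validation with NRMSE normalised by the observed
response range (mean-normalisation by option). With a single predictor the
procedure reduces to linear-regression LOOCV. The number of latent
variables, when not given, minimises the LOOCV NRMSE. Sections are treated
as independent observations; the repeated sections per tumour are not
modelled hierarchically — a known limitation inherited from the analysis
design.

## Problem sizes and determinism

Default desk-scale sizes: 1000-voxel phantoms for noiseless round trips;
100 noiseless problems per model family for the MCMC/NLLS comparison; 20
seeded SNR-50 replicates for bias estimation; 20 rendered slides for stain
accuracy; 50 cohort replicates (n = 18, r = 0.85) for the end-to-end
significance pattern. Every random draw flows from an explicit integer
seed (`numpy.random.default_rng`), and the pipeline rerun with the same
config is bit-identical.

## What passing tests do and do not show

The generators match the *assumptions* of the estimators (exact IVIM
bi-exponential, exact two-pool UTE decay, perfect spoiling, piecewise-
constant tissue, Rician noise, linear collagen–MR relations). Passing
round trips therefore validate the implementation, not the biology: they
say nothing about motion, partial volume, imperfect spoiling, B1/B0
inhomogeneity beyond the single multiplier studied, non-exponential
diffusion, or stain variability in real sections. Known limitations:
`f` and `D*` remain poorly conditioned at realistic SNR (their biases are
deliberately not part of the recovery bound); the ultrashort-regime
`T2*short` round trip is limited to ≈ 6·10⁻⁵ relative error by the
long-pool tail (see the fitting-order discussion above); the MCMC sampler
reports acceptance-rate style diagnostics only, not formal convergence
statistics.
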