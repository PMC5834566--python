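# fibromap

Multi-modal endogenous-contrast MRI parameter mapping and
imaging–pathology statistics for tumour fibrosis, driven end-to-end by
synthetic phantoms.

Fibrosis — excess collagen deposition — is a poor-prognosis feature of
mammary carcinoma, and detecting it without contrast agents is an open
problem in quantitative MRI. `fibromap` implements the full analysis
chain used to test three endogenous contrasts against histology in a
preclinical tumour model:

* **IVIM diffusion** — bi-exponential fits
  `S(b) = S0 [f e^(−b·D*) + (1−f) e^(−b·D)]` over a nine-b-value protocol
  (0–800 s/mm²) with segmented initialisation, plus the perfusion-
  insensitive ADC from b ≥ 200 s/mm² and the compound parameter `fD*`;
* **UTE T2\*** — dual-regime mono-exponential relaxometry from four
  ultrashort (0.07–0.56 ms) and four conventional (7.16–20.60 ms) echoes,
  plus the short-pool signal `ratio`;
* **Magnetisation transfer** — variable-flip-angle T1 and T1s, the ratio
  `MTR = (S_ref − S_MT)/S_ref`, the apparent MT rate `ka = MTR/T1s`, and
  the B1-robust saturation `δ = (R1app·TR + α²/2)(S_ref − S_MT)/S_MT`;
* **Histology** — Lab-colour-space stain segmentation (picrosirius red,
  DAB) with percent-positive area, field-based microvessel density, and
  the ellipsoid tumour-volume helper `(π/6)·L·W·D`;
* **Statistics** — ROI medians, Sørenson–Dice, log-transformed
  repeat-measures CoV, Pearson correlation tables with Bonferroni
  correction (p < 0.0125 for four histology markers), and PLSR with
  leave-one-out cross-validated NRMSE.

Voxel-wise fitting runs through either a bound-constrained least-squares
engine or a random-walk Metropolis MCMC estimator (marginalised noise
scale) used as a robust least-squares estimator; both are available behind
the same interface. Because no public dataset exists for the original
acquisitions, a first-class synthetic-data module generates seeded
phantoms, Rician-noise signal stacks, stain-rendered slides and matched
MR/histology cohorts with a tunable collagen–MT effect size, so every
stage is testable offline.

## Worked example

```python
import numpy as np
import fibromap as fm

gt = fm.make_phantom(fm.PhantomSpec(grid_shape=(12, 12, 4), n_regions=3, seed=0))
stack = fm.simulate_mt(gt)                       # 4 SPGR volumes: 4/24 deg, +/- MT
maps  = fm.mt_maps(stack, gt.roi)                # T1, T1s, MTR, ka, delta
print(round(fm.roi_median(maps["ka"], gt.roi), 4),
      round(fm.roi_median(gt.maps["ka"], gt.roi), 4))
```

prints `0.253 0.253` — on noiseless data the closed-form VFA/MT chain
recovers the ground-truth apparent MT rate (s⁻¹) exactly.

The numbered drivers under `analysis/` run the full study shape:

```
python analysis/01_simulate_phantom.py --seed 0    # stacks at image SNR 50
python analysis/02_fit_parameter_maps.py           # voxel-wise maps + ROI medians
python analysis/03_quantify_histology.py           # stain % and MVD
python analysis/04_cohort_statistics.py            # Table of r (p), PLSR NRMSE
python analysis/05_b1_robustness.py                # delta vs MTR under B1 error
```

`04_cohort_statistics.py` prints the MR-vs-histology correlation table for
a synthetic 18-section cohort; with the default effect size the MT
saturation parameters come out as the strongest collagen correlates, e.g.

```
significance threshold: p < 0.0125
ka      ... picrosirius:  0.783 (0.0001)*
delta   ... picrosirius:  0.781 (0.0001)*
T1s     ... picrosirius: -0.813 (0.0000)*
```

while no parameter correlates with the hypoxia marker, and
`05_b1_robustness.py` shows δ holding within ~0.5% while MTR drifts by
~13–28% under B1 multipliers 0.8–1.2.

A thin CLI mirrors the drivers:
`fibromap simulate|dwi|ute|mt|histo|stats|run` (see `fibromap --help`).

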