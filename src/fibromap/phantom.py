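"""Digital phantoms and forward simulation of the three MR modalities.

The phantom is a piecewise-constant tissue map: seeded random ellipsoidal /
box regions, each with parameter values drawn uniformly within configurable
ranges, plus a central ellipsoidal ROI standing in for the tumour.  Forward
models:

* DWI — bi-exponential IVIM signal over the nine-b-value protocol;
* UTE — two-pool signal, a short-lived pool of amplitude (S0s - S0l)
  decaying at T2*short on top of a long pool S0l decaying at T2*long (the
  smallest forward model the two-regime fitting procedure can distinguish);
* MT  — spoiled gradient echo at two flip angles, with and without the MT
  pulse.  The with-MT volumes use T1s and an amplitude chosen so that the
  fractional signal loss at the small flip angle equals the ground-truth MTR.

A B1 multiplier (default 1) scales both the achieved readout flip angles and
the MT saturation power (which goes as B1^2); this is what makes the MT
saturation parameter delta nearly B1-independent while MTR is not.

Noise is Rician on the magnitude data (a Gaussian mode exists for unit
tests); every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (AcquisitionSpec, ParameterMaps, SignalStack, B_VALUES,
                   UTE_ECHOES_MS, CONVENTIONAL_ECHOES_MS, MT_TR_S, MT_FLIPS_DEG)
from .engine import spgr_signal

__all__ = ["PhantomSpec", "GroundTruth", "make_phantom", "simulate_dwi",
           "simulate_ute", "simulate_mt", "add_noise", "DEFAULT_RANGES",
           "delta_from_mtr"]

# ground-truth sampling ranges: tumour-plausible values at 1.5 T
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "S0": (800.0, 1200.0),        # arbitrary signal units
    "f": (0.05, 0.25),            # pseudodiffusion fraction
    "D": (0.6e-3, 1.4e-3),        # mm^2/s
    "Dstar": (8e-3, 40e-3),       # mm^2/s
    "T2s_short": (0.3, 0.7),      # ms
    "T2s_long": (12.0, 30.0),     # ms
    "ratio": (0.10, 0.35),        # short-pool share of TE->0 signal
    "T1": (0.9, 1.6),             # s
    "T1s": (0.45, 0.80),          # s (with MT pulse)
    "MTR": (0.10, 0.40),          # dimensionless
}

_SAMPLED = tuple(DEFAULT_RANGES)  # order in which per-region values are drawn


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (16, 16, 4)
    n_regions: int = 3
    parameter_ranges: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three strictly positive sizes")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        ranges = dict(DEFAULT_RANGES)
        ranges.update(self.parameter_ranges)
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValueError(f"inverted range for {name}: ({lo}, {hi})")
        object.__setattr__(self, "parameter_ranges", ranges)


@dataclass
class GroundTruth:
    """Voxel-wise true parameter maps, tumour ROI and the region labels."""

    maps: ParameterMaps
    roi: np.ndarray
    region_labels: np.ndarray


def delta_from_mtr(mtr, t1, tr: float = MT_TR_S,
                   alpha_deg: float = MT_FLIPS_DEG[0]):
    """MT saturation per TR implied by an MTR under the small-angle SPGR model.

    delta = (R1 TR + a^2/2) * MTR / (1 - MTR), with a the nominal small flip
    in radians.  Inverse of MTR = delta / (R1 TR + a^2/2 + delta).
    """
    a = np.deg2rad(alpha_deg)
    return (tr / np.asarray(t1, dtype=float) + a * a / 2.0) * mtr / (1.0 - mtr)


def _ellipsoid_mask(shape, centre, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, centre, radii):
        acc = acc + ((g - c) / max(r, 1e-9)) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec) -> GroundTruth:
    """Piecewise-constant ground truth with internally consistent derived maps."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.grid_shape)

    labels = np.zeros(shape, dtype=int)
    for region in range(1, spec.n_regions):
        centre = [rng.uniform(0, s - 1) for s in shape]
        radii = [rng.uniform(0.15, 0.45) * s for s in shape]
        if rng.random() < 0.5:
            blob = _ellipsoid_mask(shape, centre, radii)
        else:  # axis-aligned box
            blob = np.ones(shape, dtype=bool)
            for ax, (c, r, s) in enumerate(zip(centre, radii, shape)):
                idx = np.arange(s)
                sel = (idx >= c - r) & (idx <= c + r)
                blob &= np.expand_dims(sel, tuple(a for a in range(3) if a != ax))
        labels[blob] = region

    # per-region uniform draws for every sampled parameter
    values = {name: rng.uniform(lo, hi, size=spec.n_regions)
              for name, (lo, hi) in ((n, spec.parameter_ranges[n]) for n in _SAMPLED)}
    maps = {name: vals[labels] for name, vals in values.items()}

    # derived maps: exact internal identities
    maps["ADC"] = maps["D"].copy()
    maps["fDstar"] = maps["f"] * maps["Dstar"]
    maps["S0s"] = maps["S0"].copy()                    # total TE->0 UTE amplitude
    maps["S0l"] = maps["S0s"] * (1.0 - maps["ratio"])  # long-pool amplitude
    maps["ka"] = maps["MTR"] / maps["T1s"]
    maps["delta"] = delta_from_mtr(maps["MTR"], maps["T1"])

    roi = _ellipsoid_mask(shape, [0.5 * (s - 1) for s in shape],
                          [0.42 * s for s in shape])
    return GroundTruth(ParameterMaps(maps), roi, labels)


# ---------------------------------------------------------------------------
# forward models


def simulate_dwi(gt: GroundTruth, bvalues=B_VALUES) -> SignalStack:
    """Noiseless IVIM signal S_b = S0 [f e^{-b D*} + (1-f) e^{-b D}]."""
    b = np.asarray(bvalues, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if b.size != np.unique(b).size:
        raise ValueError("duplicate b-values")
    if np.any(np.diff(b) <= 0):
        raise ValueError("b-values must be strictly increasing")
    m = gt.maps
    s0 = m["S0"][..., None]
    f = m["f"][..., None]
    data = s0 * (f * np.exp(-b * m["Dstar"][..., None])
                 + (1.0 - f) * np.exp(-b * m["D"][..., None]))
    return SignalStack(data, AcquisitionSpec("dwi", bvalues=tuple(b)))


def simulate_ute(gt: GroundTruth,
                 echo_times=UTE_ECHOES_MS + CONVENTIONAL_ECHOES_MS) -> SignalStack:
    """Two-pool UTE signal: (S0s - S0l) e^{-TE/T2*short} + S0l e^{-TE/T2*long}."""
    te = np.asarray(echo_times, dtype=float)
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")
    m = gt.maps
    short_amp = (m["S0s"] - m["S0l"])[..., None]
    data = (short_amp * np.exp(-te / m["T2s_short"][..., None])
            + m["S0l"][..., None] * np.exp(-te / m["T2s_long"][..., None]))
    return SignalStack(data, AcquisitionSpec("ute", te_ms=tuple(te)))


def simulate_mt(gt: GroundTruth, tr: float = MT_TR_S,
                flip_angles_deg=MT_FLIPS_DEG, b1: float = 1.0) -> SignalStack:
    """Four SPGR volumes: (flip1, flip2) without MT then (flip1, flip2) with MT.

    Without-MT signals follow the SPGR equation with T1.  With-MT signals
    follow it with T1s, amplitude-scaled so the fractional loss at the small
    achieved flip angle equals the effective MTR; the effective saturation is
    the ground-truth saturation scaled by b1**2 (MT pulse power), and the
    achieved flips are b1 times nominal.  At b1=1 the small-flip loss equals
    the ground-truth MTR exactly.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    flips = np.asarray(flip_angles_deg, dtype=float)
    if flips.size != 2:
        raise ValueError("exactly two flip angles required")
    if np.any(flips <= 0) or np.any(flips >= 90):
        raise ValueError("flip angles must be in (0, 90) degrees")
    a_low = np.deg2rad(flips.min())

    m = gt.maps
    t1, t1s, mtr, s0 = m["T1"], m["T1s"], m["MTR"], m["S0"]
    r1 = 1.0 / t1

    delta_true = delta_from_mtr(mtr, t1, tr=tr, alpha_deg=flips.min())
    delta_eff = b1 * b1 * delta_true
    a_low_eff = b1 * a_low
    mtr_eff = delta_eff / (r1 * tr + a_low_eff ** 2 / 2.0 + delta_eff)

    vols, flip_meta, mt_meta = [], [], []
    for a_nom_deg in flips:
        a = b1 * np.deg2rad(a_nom_deg)
        vols.append(spgr_signal(s0, a, t1, tr))
        flip_meta.append(float(a_nom_deg))
        mt_meta.append(False)
    # amplitude of the with-MT pool pinned at the small achieved flip
    sref_low = spgr_signal(s0, a_low_eff, t1, tr)
    amp_mt = (1.0 - mtr_eff) * sref_low / spgr_signal(1.0, a_low_eff, t1s, tr)
    for a_nom_deg in flips:
        a = b1 * np.deg2rad(a_nom_deg)
        vols.append(spgr_signal(amp_mt, a, t1s, tr))
        flip_meta.append(float(a_nom_deg))
        mt_meta.append(True)

    data = np.stack(vols, axis=-1)
    acq = AcquisitionSpec("mt", tr_s=float(tr), flip_deg=tuple(flip_meta),
                          mt_pulse=tuple(mt_meta))
    return SignalStack(data, acq)


def add_noise(stack: SignalStack, sigma: float, seed: int,
              mode: str = "rician") -> SignalStack:
    """Rician (default) or additive Gaussian noise; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return SignalStack(stack.data.copy(), stack.acq)
    rng = np.random.default_rng(seed)
    s = stack.data
    if mode == "rician":
        n1 = rng.normal(0.0, sigma, size=s.shape)
        n2 = rng.normal(0.0, sigma, size=s.shape)
        noisy = np.sqrt((s + n1) ** 2 + n2 ** 2)
    elif mode == "gaussian":
        noisy = s + rng.normal(0.0, sigma, size=s.shape)
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    return SignalStack(noisy, stack.acq)
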