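"""Magnetisation-transfer parameter estimation.

From four matched spoiled-GRE acquisitions (two flip angles, each with and
without the MT pulse) this module derives, voxel-wise:

* T1 and T1s — variable flip angle (VFA) longitudinal relaxation constants
  without / with the MT pulse, from the closed-form two-point solution;
* MTR = (Sref - SMT) / Sref, taken at the small flip angle;
* ka  = MTR / T1s, the apparent (empirical) MT rate constant;
* delta = (R1app TR + a_nom^2/2) (Sref - SMT) / SMT — the B1-independent MT
  saturation, using the small-flip pair (the small-flip-angle approximation
  underlies the formula) and R1app = 1/T1 from the without-MT VFA fit.

Negative MTR from noise is clipped (to [-0.05, 1]) with a logged count
rather than discarded; non-physical VFA slopes flag the voxel as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ParameterMaps, SignalStack

log = logging.getLogger(__name__)

__all__ = ["MtParams", "vfa_t1", "compute_mtr", "compute_ka", "compute_delta",
           "mt_maps"]

MTR_CLIP = (-0.05, 1.0)


@dataclass(frozen=True)
class MtParams:
    T1: float
    T1s: float
    MTR: float
    ka: float
    delta: float


def vfa_t1(s_low, s_high, flips_deg, tr):
    """Closed-form two-point VFA: regress S/sin(a) on S/tan(a).

    Slope m gives T1 = -TR / ln(m); intercept gives the amplitude
    S0 = b / (1 - m).  Non-physical slopes (m <= 0 or >= 1) return NaN.
    Vectorised over array signals.
    """
    a = np.deg2rad(np.asarray(flips_deg, dtype=float))
    if a.size != 2 or a[0] == a[1]:
        raise ValueError("two distinct flip angles required")
    s_low = np.asarray(s_low, dtype=float)
    s_high = np.asarray(s_high, dtype=float)
    y1, x1 = s_low / np.sin(a[0]), s_low / np.tan(a[0])
    y2, x2 = s_high / np.sin(a[1]), s_high / np.tan(a[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        m = (y2 - y1) / (x2 - x1)
        ok = (m > 0) & (m < 1)
        t1 = np.where(ok, -tr / np.log(np.where(ok, m, 0.5)), np.nan)
        s0 = np.where(ok, (y1 - m * x1) / (1.0 - m), np.nan)
    if np.ndim(t1) == 0:
        return float(t1), float(s0)
    return t1, s0


def compute_mtr(s_ref, s_mt):
    """MTR = (Sref - SMT) / Sref, clipped to [-0.05, 1] with clip logging."""
    s_ref = np.asarray(s_ref, dtype=float)
    if np.any(s_ref <= 0):
        raise ValueError("s_ref must be positive")
    mtr = (s_ref - np.asarray(s_mt, dtype=float)) / s_ref
    n_clip = int(np.sum((mtr < MTR_CLIP[0]) | (mtr > MTR_CLIP[1])))
    if n_clip:
        log.info("compute_mtr: clipped %d value(s) to %s", n_clip, MTR_CLIP)
    out = np.clip(mtr, *MTR_CLIP)
    return float(out) if np.ndim(out) == 0 else out


def compute_ka(mtr, t1s):
    """Apparent MT rate constant ka = MTR / T1s (1/s)."""
    t1s = np.asarray(t1s, dtype=float)
    if np.any(t1s[np.isfinite(t1s)] <= 0):
        raise ValueError("t1s must be positive")
    out = np.asarray(mtr, dtype=float) / t1s
    return float(out) if np.ndim(out) == 0 else out


def compute_delta(r1app, tr, alpha_nom_rad, s_ref, s_mt):
    """B1-independent MT saturation per TR (small-flip-angle approximation).

    delta = (R1app TR + a_nom^2 / 2) * (Sref - SMT) / SMT
    """
    s_mt = np.asarray(s_mt, dtype=float)
    if np.any(s_mt[np.isfinite(s_mt)] <= 0):
        raise ValueError("s_mt must be positive")
    s_ref = np.asarray(s_ref, dtype=float)
    out = (np.asarray(r1app, dtype=float) * tr + alpha_nom_rad ** 2 / 2.0) \
        * (s_ref - s_mt) / s_mt
    return float(out) if np.ndim(out) == 0 else out


def _mt_volumes(stack: SignalStack):
    """Locate the four volumes: returns (ref_low, ref_high, mt_low, mt_high, flips, tr)."""
    acq = stack.acq
    if acq.flip_deg is None or acq.mt_pulse is None or acq.tr_s is None:
        raise ValueError("stack lacks flip/MT/TR metadata")
    flips = np.asarray(acq.flip_deg, dtype=float)
    pulses = np.asarray(acq.mt_pulse, dtype=bool)
    uniq = np.unique(flips)
    if uniq.size != 2 or stack.n_volumes != 4:
        raise ValueError("need exactly four volumes at two flip angles")
    lo, hi = uniq.min(), uniq.max()
    idx = {}
    for key, (fl, mt) in (("ref_low", (lo, False)), ("ref_high", (hi, False)),
                          ("mt_low", (lo, True)), ("mt_high", (hi, True))):
        sel = np.flatnonzero((flips == fl) & (pulses == mt))
        if sel.size != 1:
            raise ValueError(f"missing or duplicated acquisition: flip={fl}, mt={mt}")
        idx[key] = sel[0]
    vols = {k: stack.data[..., i] for k, i in idx.items()}
    return vols, (lo, hi), float(acq.tr_s)


def mt_maps(stack: SignalStack, mask: np.ndarray) -> ParameterMaps:
    """T1, T1s, MTR, ka and delta maps within the mask (NaN outside)."""
    vols, (flip_lo, flip_hi), tr = _mt_volumes(stack)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack")
    if not mask.any():
        raise ValueError("empty mask")

    ref_lo, ref_hi = vols["ref_low"][mask], vols["ref_high"][mask]
    mt_lo, mt_hi = vols["mt_low"][mask], vols["mt_high"][mask]

    t1, _ = vfa_t1(ref_lo, ref_hi, (flip_lo, flip_hi), tr)
    t1s, _ = vfa_t1(mt_lo, mt_hi, (flip_lo, flip_hi), tr)
    n_warn = int(np.sum(t1s > t1))
    if n_warn:
        log.warning("mt_maps: %d voxel(s) with T1s > T1", n_warn)
    mtr = compute_mtr(ref_lo, mt_lo)
    ka = compute_ka(mtr, t1s)
    delta = compute_delta(1.0 / t1, tr, np.deg2rad(flip_lo), ref_lo, mt_lo)

    out = {}
    for name, vals in (("T1", t1), ("T1s", t1s), ("MTR", mtr),
                       ("ka", ka), ("delta", delta)):
        vol = np.full(mask.shape, np.nan)
        vol[mask] = vals
        out[name] = vol
    return ParameterMaps(out)
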