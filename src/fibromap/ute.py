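"""Dual-regime T2* estimation from ultrashort and conventional gradient echoes.

Echoes are partitioned at 1 ms.  The conventional (long-T2*) regime is
fitted first with a mono-exponential; its extrapolated long-pool signal is
then subtracted from the ultrashort echoes before the short-regime
mono-exponential fit, so that the near-constant long-pool baseline does not
bias T2*short.  The "ratio" parameter — the short-lived pool's share of the
total TE->0 signal, analogous to the IVIM f — is (S0s - S0l) / S0s with
S0s = short-pool amplitude + S0l.

The long-regime estimate never depends on the ultrashort echoes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterMaps, SignalStack, ULTRASHORT_THRESHOLD_MS
from .dwi import loglin_monoexp
from .engine import t2star_model, nlls_fit

__all__ = ["UteParams", "split_echoes", "fit_ute", "ute_maps"]


@dataclass(frozen=True)
class UteParams:
    T2s_short: float
    T2s_long: float
    S0s: float      # total TE->0 amplitude
    S0l: float      # long-pool amplitude
    ratio: float    # (S0s - S0l) / S0s, clipped to [0, 1]


def split_echoes(echo_times):
    """Partition echo times at 1 ms: (< 1 ms ultrashort, >= 1 ms conventional)."""
    te = np.asarray(echo_times, dtype=float)
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")
    ultra = te[te < ULTRASHORT_THRESHOLD_MS]
    conv = te[te >= ULTRASHORT_THRESHOLD_MS]
    if ultra.size == 0:
        raise ValueError("no ultrashort (< 1 ms) echoes")
    if conv.size == 0:
        raise ValueError("no conventional (>= 1 ms) echoes")
    return ultra, conv


def _nonlinear_monoexp(te, sig):
    """Fallback when log-linear fitting is undefined (non-positive residuals)."""
    model = t2star_model(s0_max=max(10.0 * float(np.max(np.abs(sig))), 10.0))
    amp0 = max(float(sig[0]), 1.0)
    t2_0 = float(np.clip(te[-1] - te[0], *model.bounds[1]))
    res = nlls_fit(model, te, sig, np.clip([amp0, t2_0], model.bounds[:, 0],
                                           model.bounds[:, 1]))
    return res["S0"], res["T2s"]


def fit_ute(signal, echo_times) -> UteParams:
    """Two-regime T2* fit of a single voxel's multi-echo signal."""
    te = np.asarray(echo_times, dtype=float)
    s = np.asarray(signal, dtype=float).ravel()
    if te.size != s.size:
        raise ValueError("echo_times and signal lengths differ")
    ultra, conv = split_echoes(te)
    if ultra.size < 2 or conv.size < 2:
        raise ValueError("need >= 2 echoes in each regime")
    s_ultra = s[te < ULTRASHORT_THRESHOLD_MS]
    s_conv = s[te >= ULTRASHORT_THRESHOLD_MS]

    def _fit_long(sig):
        if np.all(sig > 0):
            amp, rate = loglin_monoexp(conv, sig)
            if rate > 0 and np.isfinite(rate):
                return amp, 1.0 / rate
        return _nonlinear_monoexp(conv, np.maximum(sig, 1e-12))

    # conventional regime first (essentially pure long pool at these echoes);
    # this fit never sees the ultrashort echoes
    s0l, t2l = _fit_long(s_conv)

    # subtract the extrapolated long-pool baseline, then fit the short pool
    resid = s_ultra - s0l * np.exp(-ultra / t2l)
    if np.all(resid > 0):
        amp_s, rate_s = loglin_monoexp(ultra, resid)
        t2s = 1.0 / rate_s if rate_s > 0 else np.nan
        if not np.isfinite(t2s) or t2s <= 0:
            amp_s, t2s = _nonlinear_monoexp(ultra, np.maximum(resid, 1e-12))
    else:
        amp_s, t2s = 0.0, np.nan   # no resolvable short pool

    s0s = float(amp_s + s0l)
    ratio = float(np.clip(amp_s / s0s, 0.0, 1.0)) if s0s > 0 else 0.0
    return UteParams(float(t2s), float(t2l), s0s, float(s0l), ratio)


def ute_maps(stack: SignalStack, mask: np.ndarray) -> ParameterMaps:
    """T2*short, T2*long, S0s, S0l and ratio maps within the mask."""
    if stack.acq.te_ms is None:
        raise ValueError("stack carries no echo-time metadata")
    te = np.asarray(stack.acq.te_ms, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack")
    if not mask.any():
        raise ValueError("empty mask")
    signals = stack.data[mask]
    fields = ("T2s_short", "T2s_long", "S0s", "S0l", "ratio")
    est = np.empty((signals.shape[0], len(fields)))
    for i, s in enumerate(signals):
        p = fit_ute(s, te)
        est[i] = (p.T2s_short, p.T2s_long, p.S0s, p.S0l, p.ratio)
    out = {}
    for j, name in enumerate(fields):
        vol = np.full(mask.shape, np.nan)
        vol[mask] = est[:, j]
        out[name] = vol
    return ParameterMaps(out)
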