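"""Diffusion parameter estimation: ADC, IVIM with segmented initialisation, fD*.

The perfusion-insensitive ADC uses only b >= 200 s/mm^2 (inclusive), where
the pseudo-diffusion pool has effectively decayed away.  The full IVIM fit
uses all b-values; its initial values come from the segmented approach: D
and the extrapolated intercept from the high-b mono-exponential, and
f = (S_obs(0) - intercept) / S_obs(0) clipped to [0, 1].

Mono-exponential fits are done in log-signal closed form (signal-weighted
linear regression), which is deterministic and exact on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterMaps, SignalStack
from .engine import ModelSpec, ivim_model, nlls_fit, mcmc_fit

__all__ = ["DwiParams", "fit_adc", "fit_ivim", "ivim_maps", "ADC_B_THRESHOLD"]

ADC_B_THRESHOLD = 200.0  # s/mm^2, inclusive


@dataclass(frozen=True)
class DwiParams:
    S0: float
    ADC: float
    f: float
    D: float
    Dstar: float

    @property
    def fDstar(self) -> float:
        return self.f * self.Dstar


def loglin_monoexp(x: np.ndarray, signal: np.ndarray):
    """Weighted linear regression of log(signal) on x.

    Weights are signal^2, the standard Gaussian-equivalent weighting for a
    log-transformed exponential fit.  Returns (amplitude, rate) for
    signal = amplitude * exp(-rate * x); vectorised over leading axes of
    ``signal`` with shape (..., len(x)).
    """
    x = np.asarray(x, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if np.any(signal <= 0):
        raise ValueError("log-linear fit requires strictly positive signals")
    w = signal ** 2
    y = np.log(signal)
    sw = w.sum(axis=-1)
    xbar = (w * x).sum(axis=-1) / sw
    ybar = (w * y).sum(axis=-1) / sw
    dx = x - xbar[..., None]
    slope = (w * dx * (y - ybar[..., None])).sum(axis=-1) / (w * dx * dx).sum(axis=-1)
    amp = np.exp(ybar - slope * xbar)
    return amp, -slope


def fit_adc(signal, bvalues):
    """Mono-exponential ADC from b >= 200 only; returns (intercept, ADC)."""
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signal, dtype=float)
    sel = b >= ADC_B_THRESHOLD
    if sel.sum() < 2:
        raise ValueError("need at least two b-values >= 200 s/mm^2")
    amp, adc = loglin_monoexp(b[sel], s[..., sel])
    return amp, adc


def segmented_init(signal, bvalues):
    """Segmented IVIM initialisation: (S0, f, D, Dstar) start values."""
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signal, dtype=float)
    intercept, d_init = fit_adc(s, b)
    s_meas0 = s[..., np.argmin(b)]
    f_init = np.clip((s_meas0 - intercept) / s_meas0, 0.0, 1.0)
    return s_meas0, f_init, d_init


def fit_ivim(signal, bvalues, engine: str = "nlls", chain_length: int = 5000,
             seed: int = 0) -> DwiParams:
    """Four-parameter IVIM fit of a single voxel's signal over all b-values."""
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signal, dtype=float).ravel()
    if b.size < 9 or b.min() != 0 or b.max() < ADC_B_THRESHOLD:
        raise ValueError("IVIM requires >= 9 b-values spanning 0 and >= 200")
    s0_obs = s[np.argmin(b)]
    if s0_obs <= 0:
        raise ValueError("S(0) must be positive")
    if s[np.argmax(b)] > s0_obs:
        raise ValueError("catastrophically non-monotone signal (S(b_max) > S(0))")

    model = ivim_model(s0_max=max(10.0 * s0_obs, 10.0))
    s0_i, f_i, d_i = segmented_init(s, b)
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    init = np.clip([s0_i, f_i, d_i, max(10.0 * d_i, 5e-3)], lo, hi)

    if engine == "nlls":
        res = nlls_fit(model, b, s, init)
    elif engine == "mcmc":
        res = mcmc_fit(model, b, s, init, chain_length=chain_length, seed=seed)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    p = res.as_dict()
    return DwiParams(p["S0"], fit_adc(s, b)[1], p["f"], p["D"], p["Dstar"])


def ivim_maps(stack: SignalStack, mask: np.ndarray, engine: str = "nlls",
              chain_length: int = 5000, seed: int = 0) -> ParameterMaps:
    """ADC, f, D, D* and fD* maps within the mask (NaN outside)."""
    if stack.acq.bvalues is None:
        raise ValueError("stack carries no b-value metadata")
    b = np.asarray(stack.acq.bvalues, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack")
    if not mask.any():
        raise ValueError("empty mask")

    signals = stack.data[mask]
    n = signals.shape[0]
    out = {k: np.full(mask.shape, np.nan) for k in ("ADC", "f", "D", "Dstar", "fDstar", "S0")}
    est = np.empty((n, 5))  # S0, f, D, Dstar, ADC
    if engine == "mcmc":
        from .engine import mcmc_fit_batch
        model = ivim_model(s0_max=max(10.0 * float(signals.max()), 10.0))
        s0_i, f_i, d_i = segmented_init(signals, b)
        init = np.stack([s0_i, f_i, d_i, np.maximum(10.0 * d_i, 5e-3)], axis=-1)
        init = np.clip(init, model.bounds[:, 0], model.bounds[:, 1])
        med, _, _ = mcmc_fit_batch(model, b, signals, init,
                                   chain_length=chain_length, seed=seed)
        est[:, :4] = med
        est[:, 4] = fit_adc(signals, b)[1]
    else:
        for i, s in enumerate(signals):
            p = fit_ivim(s, b, engine=engine, seed=seed)
            est[i] = (p.S0, p.f, p.D, p.Dstar, p.ADC)

    for j, name in enumerate(("S0", "f", "D", "Dstar")):
        out[name][mask] = est[:, j]
    out["ADC"][mask] = est[:, 4]
    out["fDstar"][mask] = est[:, 1] * est[:, 3]
    return ParameterMaps(out)
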