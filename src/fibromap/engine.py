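"""Voxel-wise curve fitting: bound-constrained NLLS and an MCMC estimator.

The MCMC estimator is a random-walk Metropolis sampler used as a robust
least-squares estimator: Gaussian likelihood with the unknown noise scale
marginalised under a Jeffreys prior, which reduces the log-posterior to
``-(M/2) * log(RSS)`` plus the parameter priors (log-uniform for parameters
with strictly positive lower bounds, uniform otherwise).  The point estimate
is the marginal posterior median after burn-in; the reported spread is the
per-parameter interquartile range.

All samplers are vectorised over a batch of voxels that share a design, so
whole-volume MCMC fits remain cheap on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ModelSpec", "FitResult", "nlls_fit", "mcmc_fit", "fit_volume",
    "monoexp_model", "ivim_model", "t2star_model", "spgr_model", "spgr_signal",
]

# physiologically-motivated default bounds (b-value units s/mm^2, TE in ms, T1 in s)
DEFAULT_BOUNDS = {
    "f": (0.0, 1.0),
    "D": (1e-5, 4e-3),
    "Dstar": (1e-3, 0.5),
}


@dataclass(frozen=True)
class ModelSpec:
    """A parametric signal model: names, box bounds and a forward map.

    ``forward(params, design)`` must accept ``params`` of shape ``(..., P)``
    and return predicted signal of shape ``(..., M)`` for ``M`` design points.
    """

    name: str
    parameter_names: tuple[str, ...]
    bounds: np.ndarray  # (P, 2)
    forward: Callable[[np.ndarray, np.ndarray], np.ndarray]

    def __post_init__(self):
        b = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if b.shape != (len(self.parameter_names), 2):
            raise ValueError("bounds must be (n_params, 2)")
        if not np.all(np.isfinite(b)):
            raise ValueError("bounds must be finite")
        if not np.all(b[:, 0] < b[:, 1]):
            raise ValueError("each bound must satisfy low < high")
        object.__setattr__(self, "bounds", b)

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


@dataclass
class FitResult:
    """Per-voxel point estimate with optional posterior spread."""

    parameter_names: tuple[str, ...]
    point_estimate: np.ndarray
    posterior_spread: np.ndarray | None
    rss: float
    n_iter: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.parameter_names, np.asarray(self.point_estimate)))

    def __getitem__(self, name: str) -> float:
        return float(self.point_estimate[self.parameter_names.index(name)])


# ---------------------------------------------------------------------------
# model factories


def _monoexp_forward(params: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0, adc = params[..., :1], params[..., 1:2]
    return s0 * np.exp(-b * adc)


def monoexp_model(s0_max: float = 1e5) -> ModelSpec:
    """S(b) = S0 * exp(-b * ADC)."""
    return ModelSpec(
        "monoexp_adc", ("S0", "ADC"),
        np.array([[1e-6, s0_max], DEFAULT_BOUNDS["D"]]),
        _monoexp_forward,
    )


def _ivim_forward(params: np.ndarray, b: np.ndarray) -> np.ndarray:
    s0 = params[..., 0:1]
    f = params[..., 1:2]
    d = params[..., 2:3]
    dstar = params[..., 3:4]
    return s0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * d))


def ivim_model(s0_max: float = 1e5) -> ModelSpec:
    """Bi-exponential IVIM: S0 * [f exp(-b D*) + (1-f) exp(-b D)]."""
    return ModelSpec(
        "ivim", ("S0", "f", "D", "Dstar"),
        np.array([[1e-6, s0_max], DEFAULT_BOUNDS["f"],
                  DEFAULT_BOUNDS["D"], DEFAULT_BOUNDS["Dstar"]]),
        _ivim_forward,
    )


def _t2star_forward(params: np.ndarray, te: np.ndarray) -> np.ndarray:
    s0, t2 = params[..., :1], params[..., 1:2]
    return s0 * np.exp(-te / t2)


def t2star_model(s0_max: float = 1e5, t2_bounds: tuple[float, float] = (1e-3, 200.0)) -> ModelSpec:
    """Mono-exponential T2* decay, TE and T2* in ms."""
    return ModelSpec(
        "t2star", ("S0", "T2s"),
        np.array([[1e-6, s0_max], t2_bounds]),
        _t2star_forward,
    )


def spgr_signal(s0, flip_rad, t1, tr):
    """Spoiled gradient-echo steady state: S0 sin(a) (1-E1)/(1-E1 cos(a))."""
    e1 = np.exp(-tr / np.asarray(t1, dtype=float))
    return s0 * np.sin(flip_rad) * (1.0 - e1) / (1.0 - e1 * np.cos(flip_rad))


def spgr_model(tr: float, s0_max: float = 1e5,
               t1_bounds: tuple[float, float] = (0.05, 10.0)) -> ModelSpec:
    """SPGR signal vs flip angle (radians) at fixed TR; parameters (S0, T1) in s."""

    def forward(params: np.ndarray, flips: np.ndarray) -> np.ndarray:
        s0, t1 = params[..., :1], params[..., 1:2]
        return spgr_signal(s0, flips, t1, tr)

    return ModelSpec("spgr", ("S0", "T1"),
                     np.array([[1e-6, s0_max], t1_bounds]), forward)


# ---------------------------------------------------------------------------
# fitting


def _validate(model: ModelSpec, design, signal, init):
    design = np.asarray(design, dtype=float).ravel()
    signal = np.asarray(signal, dtype=float).ravel()
    init = np.asarray(init, dtype=float).ravel()
    if design.size != signal.size:
        raise ValueError("design and signal lengths differ")
    if signal.size < model.n_params:
        raise ValueError("fewer observations than parameters")
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite signal values")
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    if init.size != model.n_params or np.any(init < lo) or np.any(init > hi):
        raise ValueError("init must lie within bounds")
    return design, signal, init


def nlls_fit(model: ModelSpec, design: Sequence[float], signal: Sequence[float],
             init: Sequence[float]) -> FitResult:
    """Bound-constrained least squares (trust-region reflective); deterministic."""
    design, signal, init = _validate(model, design, signal, init)
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    # strict interior start for trf
    width = hi - lo
    x0 = np.clip(init, lo + 1e-12 * width, hi - 1e-12 * width)

    def resid(p):
        return model.forward(p, design) - signal

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
    rss = float(np.sum(sol.fun ** 2))
    return FitResult(model.parameter_names, sol.x, None, rss,
                     int(sol.nfev), bool(sol.success))


def _log_prior_terms(theta: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Sum of per-parameter prior log-densities (up to constants).

    Log-uniform (1/theta) for parameters with strictly positive lower bound,
    flat otherwise; support is the box, enforced by the proposal filter.
    """
    positive = bounds[:, 0] > 0
    if not np.any(positive):
        return np.zeros(theta.shape[:-1])
    return -np.sum(np.log(theta[..., positive]), axis=-1)


def _metropolis_batch(model: ModelSpec, design: np.ndarray, signals: np.ndarray,
                      init: np.ndarray, chain_length: int, burn_in: int,
                      rng: np.random.Generator):
    """Random-walk Metropolis over a batch of voxels sharing one design.

    signals: (N, M); init: (N, P).  Returns (medians, iqr, rss, accept_rate),
    each leading dimension N.
    """
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    width = hi - lo
    n_vox, n_par = init.shape
    m_obs = signals.shape[1]

    theta = np.clip(init, lo + 1e-12 * width, hi - 1e-12 * width).copy()

    def log_post(th):
        pred = model.forward(th, design)          # (N, M)
        rss = np.sum((pred - signals) ** 2, axis=-1)
        rss = np.maximum(rss, 1e-300)
        return -0.5 * m_obs * np.log(rss) + _log_prior_terms(th, model.bounds), rss

    lp, rss = log_post(theta)
    # per-voxel, per-parameter proposal scales; adapted during burn-in only
    step = np.broadcast_to(0.02 * width, (n_vox, n_par)).copy()
    n_keep = chain_length - burn_in
    samples = np.empty((n_keep, n_vox, n_par))
    acc_win = np.zeros(n_vox)
    n_accept_total = 0

    for it in range(chain_length):
        prop = theta + step * rng.standard_normal((n_vox, n_par))
        in_box = np.all((prop >= lo) & (prop <= hi), axis=-1)
        lp_prop = np.full(n_vox, -np.inf)
        rss_prop = np.empty(n_vox)
        if np.any(in_box):
            lp_in, rss_in = log_post(prop[in_box])
            lp_prop[in_box] = lp_in
            rss_prop[in_box] = rss_in
        accept = np.log(rng.random(n_vox)) < (lp_prop - lp)
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        rss[accept] = rss_prop[accept]
        acc_win += accept
        n_accept_total += int(accept.sum())
        if it < burn_in and (it + 1) % 50 == 0:
            rate = acc_win / 50.0
            # nudge each voxel's scale toward ~25% acceptance
            step *= np.exp((rate - 0.25))[:, None]
            step = np.clip(step, 1e-12 * width, width)
            acc_win[:] = 0.0
        if it >= burn_in:
            samples[it - burn_in] = theta

    med = np.median(samples, axis=0)
    q75, q25 = np.percentile(samples, [75, 25], axis=0)
    # report RSS at the point estimate
    pred = model.forward(med, design)
    rss_pt = np.sum((pred - signals) ** 2, axis=-1)
    return med, q75 - q25, rss_pt, n_accept_total / (chain_length * n_vox)


def mcmc_fit(model: ModelSpec, design: Sequence[float], signal: Sequence[float],
             init: Sequence[float], chain_length: int = 5000, seed: int = 0,
             burn_in: int | None = None) -> FitResult:
    """Single-voxel MCMC fit; posterior median point estimate, IQR spread."""
    if chain_length < 1000:
        raise ValueError("chain_length must be >= 1000")
    design, signal, init = _validate(model, design, signal, init)
    if not np.any(signal != 0):
        raise ValueError("all-zero signal")
    if burn_in is None:
        burn_in = max(chain_length // 5, 200)
    rng = np.random.default_rng(seed)
    med, iqr, rss, acc = _metropolis_batch(
        model, design, signal[None, :], init[None, :], chain_length, burn_in, rng)
    return FitResult(model.parameter_names, med[0], iqr[0], float(rss[0]),
                     chain_length, True)


def mcmc_fit_batch(model: ModelSpec, design, signals: np.ndarray, init: np.ndarray,
                   chain_length: int = 5000, seed: int = 0,
                   burn_in: int | None = None):
    """Vectorised MCMC over many voxels; returns (medians, iqr, rss)."""
    if chain_length < 1000:
        raise ValueError("chain_length must be >= 1000")
    design = np.asarray(design, dtype=float).ravel()
    signals = np.asarray(signals, dtype=float)
    init = np.asarray(init, dtype=float)
    if burn_in is None:
        burn_in = max(chain_length // 5, 200)
    rng = np.random.default_rng(seed)
    med, iqr, rss, _ = _metropolis_batch(model, design, signals, init,
                                         chain_length, burn_in, rng)
    return med, iqr, rss


def fit_volume(model: ModelSpec, stack, mask: np.ndarray, engine: str = "nlls",
               init_fn: Callable[[np.ndarray], np.ndarray] | None = None,
               chain_length: int = 5000, seed: int = 0):
    """Fit every in-mask voxel of a 4D stack; out-of-mask voxels are NaN.

    ``init_fn(signal) -> init vector``; defaults to mid-bounds with S0 set
    from the first volume.  Voxel processing order does not affect results.
    """
    from .core import ParameterMaps

    data = stack.data
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match stack spatial shape")
    if not mask.any():
        raise ValueError("empty mask")
    design = _stack_design(stack)
    signals = data[mask]  # (N, M)

    lo, hi = model.bounds[:, 0], model.bounds[:, 1]

    def default_init(sig):
        init = 0.5 * (lo + hi)
        if model.parameter_names[0] == "S0":
            init = init.copy()
            init[0] = np.clip(max(sig[0], 1.0), lo[0], hi[0])
        return init

    init_fn = init_fn or default_init
    inits = np.array([init_fn(s) for s in signals])
    inits = np.clip(inits, lo, hi)

    if engine == "mcmc":
        est, _, _ = mcmc_fit_batch(model, design, signals, inits,
                                   chain_length=chain_length, seed=seed)
    elif engine == "nlls":
        est = np.empty_like(inits)
        for i, (sig, ini) in enumerate(zip(signals, inits)):
            est[i] = nlls_fit(model, design, sig, ini).point_estimate
    else:
        raise ValueError(f"unknown engine {engine!r}")

    maps = {}
    for j, name in enumerate(model.parameter_names):
        vol = np.full(mask.shape, np.nan)
        vol[mask] = est[:, j]
        maps[name] = vol
    return ParameterMaps(maps)


def _stack_design(stack) -> np.ndarray:
    acq = stack.acq
    if acq.bvalues is not None:
        return np.asarray(acq.bvalues, dtype=float)
    if acq.te_ms is not None:
        return np.asarray(acq.te_ms, dtype=float)
    if acq.flip_deg is not None:
        return np.deg2rad(acq.flip_deg)
    raise ValueError("stack acquisition carries no design points")
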