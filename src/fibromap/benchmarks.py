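"""Reusable benchmark measurements over synthetic ground truth.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline and returns the measured quantities: round-trip accuracy,
estimator agreement, noisy-recovery bias, B1 robustness, stain recovery and
the end-to-end significance-pattern replication rate.  Problem sizes are
chosen for single-CPU desk-scale runs.
"""

from __future__ import annotations

import numpy as np

from .phantom import PhantomSpec, make_phantom, simulate_dwi, simulate_ute, \
    simulate_mt, add_noise
from .engine import (monoexp_model, ivim_model, t2star_model, spgr_model,
                     nlls_fit, mcmc_fit)
from .dwi import ivim_maps
from .ute import ute_maps
from .mt import mt_maps
from .slides import render_histology_slide
from .histology import segment_stain
from .cohort import CohortSpec, make_cohort, MR_PARAMS, HISTO_MARKERS
from .stats import roi_median, correlation_matrix

__all__ = ["roundtrip_errors", "mcmc_vs_nlls", "noisy_recovery",
           "b1_robustness", "stain_recovery", "end_to_end_significance"]

ROUNDTRIP_PARAMS = ("S0", "f", "D", "Dstar", "T2s_short", "T2s_long",
                    "T1", "T1s", "MTR", "ka", "delta")


def roundtrip_errors(seed: int = 0, grid_shape=(10, 10, 10),
                     n_regions: int = 3) -> dict[str, float]:
    """Max relative error of every noiseless simulate->fit round trip."""
    gt = make_phantom(PhantomSpec(grid_shape=grid_shape, n_regions=n_regions,
                                  seed=seed))
    mask = np.ones(grid_shape, dtype=bool)
    fitted = {}
    fitted.update(ivim_maps(simulate_dwi(gt), mask))
    fitted.update(ute_maps(simulate_ute(gt), mask))
    fitted.update(mt_maps(simulate_mt(gt), mask))
    out = {}
    for name in ROUNDTRIP_PARAMS:
        truth = gt.maps[name][mask]
        got = fitted[name][mask]
        out[name] = float(np.nanmax(np.abs(got - truth) / np.abs(truth)))
    return out


def _model_problems(seed: int, n: int):
    """Noiseless single-voxel problems per model family."""
    rng = np.random.default_rng(seed)
    b = np.array([0, 20, 40, 60, 80, 100, 200, 400, 800], dtype=float)
    te = np.array([7.16, 11.64, 16.12, 20.60])
    flips = np.deg2rad(np.array([4.0, 8.0, 14.0, 24.0]))
    problems = {}
    problems["monoexp_adc"] = (monoexp_model(1e4), b, np.stack(
        [rng.uniform(800, 1200, n), rng.uniform(0.6e-3, 1.4e-3, n)], axis=1))
    problems["ivim"] = (ivim_model(1e4), b, np.stack(
        [rng.uniform(800, 1200, n), rng.uniform(0.05, 0.25, n),
         rng.uniform(0.6e-3, 1.4e-3, n), rng.uniform(8e-3, 40e-3, n)], axis=1))
    problems["t2star"] = (t2star_model(1e4), te, np.stack(
        [rng.uniform(800, 1200, n), rng.uniform(12, 30, n)], axis=1))
    problems["spgr"] = (spgr_model(0.015, 1e4), flips, np.stack(
        [rng.uniform(800, 1200, n), rng.uniform(0.9, 1.6, n)], axis=1))
    return problems


def mcmc_vs_nlls(seed: int = 0, n_problems: int = 100,
                 chain_length: int = 5000) -> dict[str, float]:
    """Median relative |MCMC - NLLS| disagreement on noiseless problems."""
    out = {}
    for name, (model, design, truths) in _model_problems(seed, n_problems).items():
        diffs = []
        for i, truth in enumerate(truths):
            sig = model.forward(truth, design)
            init = truth * 0.9 + 0.1 * model.bounds.mean(axis=1)
            ref = nlls_fit(model, design, sig, init).point_estimate
            est = mcmc_fit(model, design, sig, init, chain_length=chain_length,
                           seed=seed * 100003 + i).point_estimate
            diffs.append(np.abs(est - ref) / np.abs(ref))
        out[name] = float(np.median(np.max(np.asarray(diffs), axis=1)))
    return out


def noisy_recovery(seed: int = 0, n_seeds: int = 20, snr: float = 50.0,
                   grid_shape=(8, 8, 3)) -> dict[str, float]:
    """Median-over-replicates ROI-median relative bias at the given Rician SNR."""
    biases: dict[str, list[float]] = {k: [] for k in ("D", "ADC", "T2s_long", "T1")}
    for rep in range(n_seeds):
        s = seed * 1009 + rep
        gt = make_phantom(PhantomSpec(grid_shape=grid_shape, n_regions=2, seed=s))
        roi = gt.roi

        def noisy(stack, sub):
            # SNR defined on the acquired images: mean in-ROI signal / sigma
            sigma = float(np.mean(stack.data[roi])) / snr
            return add_noise(stack, sigma, seed=s + sub)

        dmaps = ivim_maps(noisy(simulate_dwi(gt), 1), roi)
        umaps = ute_maps(noisy(simulate_ute(gt), 2), roi)
        mmaps = mt_maps(noisy(simulate_mt(gt), 3), roi)
        fitted = {"D": dmaps["D"], "ADC": dmaps["ADC"],
                  "T2s_long": umaps["T2s_long"], "T1": mmaps["T1"]}
        for name, fmap in fitted.items():
            truth = roi_median(gt.maps[name], roi)
            biases[name].append(roi_median(fmap, roi) / truth - 1.0)
    return {k: float(np.median(v)) for k, v in biases.items()}


def b1_robustness(seed: int = 0, b1: float = 0.9,
                  grid_shape=(10, 10, 4)) -> dict[str, float]:
    """Median relative error of delta and MTR under a B1 multiplier."""
    gt = make_phantom(PhantomSpec(grid_shape=grid_shape, n_regions=3, seed=seed))
    maps = mt_maps(simulate_mt(gt, b1=b1), gt.roi)
    out = {"n_voxels": int(gt.roi.sum())}
    for name in ("MTR", "delta"):
        truth = gt.maps[name][gt.roi]
        got = maps[name][gt.roi]
        out[name] = float(np.nanmedian(np.abs(got - truth) / truth))
    return out


def stain_recovery(seed: int = 0, n_slides: int = 20,
                   size=(192, 192)) -> dict[str, float]:
    """Percent-positive recovery error and repeat-segmentation correlation."""
    fracs = np.linspace(0.05, 0.80, n_slides)
    errs, rep_a, rep_b = [], [], []
    for i, frac in enumerate(fracs):
        slide = render_histology_slide(collagen_fraction=float(frac),
                                       size=size, seed=seed * 977 + i)
        truth = 100.0 * slide.collagen_mask.sum() / slide.tissue_mask.sum()
        a = segment_stain(slide.image, "picrosirius_red", seed=1).percent_positive
        b = segment_stain(slide.image, "picrosirius_red", seed=2).percent_positive
        errs.append(a - truth)
        rep_a.append(a)
        rep_b.append(b)
    return {"max_abs_err_pp": float(np.max(np.abs(errs))),
            "repeat_corr": float(np.corrcoef(rep_a, rep_b)[0, 1])}


def end_to_end_significance(seed: int = 0, n_replicates: int = 50,
                            collagen_mt_r: float = 0.85,
                            n_sections: int = 18) -> float:
    """Fraction of replicates where ka and delta are significant vs collagen
    and non-significant vs pimonidazole at the Bonferroni-adjusted threshold."""
    n_pass = 0
    for rep in range(n_replicates):
        df = make_cohort(CohortSpec(n_sections=n_sections,
                                    collagen_mt_r=collagen_mt_r,
                                    seed=seed * 7919 + rep))
        res = correlation_matrix(df, MR_PARAMS, HISTO_MARKERS,
                                 n_comparisons=4, family_alpha=0.05)
        ok = all(res.significant.loc[p, "picrosirius_pct"] for p in ("ka", "delta"))
        ok &= not any(res.significant.loc[p, "pimonidazole_pct"]
                      for p in ("ka", "delta"))
        n_pass += bool(ok)
    return n_pass / n_replicates
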