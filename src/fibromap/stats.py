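"""Cohort statistics: ROI summaries, Dice, log-CoV, correlations, PLSR.

ROI parameter summaries use the median to damp partial-volume outliers.
Repeat-measures coefficients of variation for positive-constrained
parameters use the within-subject log-SD form:

    d_i = ln x_i1 - ln x_i2,  sigma_w^2 = mean(d_i^2) / 2,
    CoV% = 100 * sqrt(exp(sigma_w^2) - 1)

Pearson correlations carry exact t-distribution two-sided p-values with a
Bonferroni-adjusted significance threshold (family alpha over the number of
histological markers).  PLSR (NIPALS, z-scored predictors) is evaluated by
leave-one-out cross-validation, refitting from scratch for each left-out
section; NRMSE is normalised by the observed response range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression

log = logging.getLogger(__name__)

__all__ = ["roi_median", "dice", "cov_log", "correlation_matrix",
           "CorrelationResult", "plsr_loocv", "PlsrResult"]


def roi_median(param_map: np.ndarray, roi: np.ndarray) -> float:
    """Median of finite in-ROI voxels; flagged (NaN) voxels excluded, logged."""
    roi = np.asarray(roi, dtype=bool)
    vals = np.asarray(param_map, dtype=float)[roi]
    if vals.size == 0:
        raise ValueError("empty ROI")
    finite = np.isfinite(vals)
    n_flagged = int(vals.size - finite.sum())
    if n_flagged:
        log.info("roi_median: excluded %d flagged voxel(s)", n_flagged)
    if not finite.any():
        raise ValueError("all ROI voxels are flagged")
    return float(np.median(vals[finite]))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Sorenson-Dice overlap 2|A^B| / (|A|+|B|); 1 if both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask dimensions differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def cov_log(pairs, simple: bool = False) -> float:
    """Repeat-measures CoV (%) for positive-valued parameters, log scale.

    ``pairs`` is a sequence of (x1, x2) repeat observations.  With
    ``simple=True`` the first-order approximation 100*sigma_w is returned.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 pairs of repeat observations")
    if np.any(arr <= 0):
        raise ValueError("all values must be positive")
    d = np.log(arr[:, 0]) - np.log(arr[:, 1])
    sw2 = np.mean(d ** 2) / 2.0
    if simple:
        return float(100.0 * np.sqrt(sw2))
    return float(100.0 * np.sqrt(np.exp(sw2) - 1.0))


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    n: pd.DataFrame
    adjusted_alpha: float

    def to_table(self) -> pd.DataFrame:
        """Printed layout: r with p in parentheses, significance starred."""
        out = self.r.copy().astype(object)
        for i in self.r.index:
            for j in self.r.columns:
                star = "*" if self.significant.loc[i, j] else ""
                out.loc[i, j] = f"{self.r.loc[i, j]:.3f} ({self.p.loc[i, j]:.4f}){star}"
        return out


def correlation_matrix(cohort: pd.DataFrame, mr_params, histo_markers,
                       n_comparisons: int = 4,
                       family_alpha: float = 0.05) -> CorrelationResult:
    """Pearson r and two-sided t-test p for every MR x histology pair.

    Significance at the Bonferroni-adjusted threshold
    family_alpha / n_comparisons.  Pairwise-complete observations are used,
    with the per-cell n reported.
    """
    if len(cohort) < 4:
        raise ValueError("need >= 4 records")
    adj = family_alpha / n_comparisons
    r = pd.DataFrame(index=list(mr_params), columns=list(histo_markers), dtype=float)
    p = r.copy()
    n_df = r.copy()
    for mp in mr_params:
        for hm in histo_markers:
            sub = cohort[[mp, hm]].dropna()
            if len(sub) < len(cohort):
                log.info("correlation_matrix: %s vs %s uses %d of %d records",
                         mp, hm, len(sub), len(cohort))
            x, y = sub[mp].to_numpy(), sub[hm].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError(f"zero-variance column in pair ({mp}, {hm})")
            res = sps.pearsonr(x, y)
            r.loc[mp, hm] = res.statistic
            p.loc[mp, hm] = res.pvalue
            n_df.loc[mp, hm] = len(sub)
    return CorrelationResult(r, p, p < adj, n_df.astype(int), adj)


@dataclass
class PlsrResult:
    predictors: tuple[str, ...]
    response: str
    n_lv: int
    nrmse: float
    loadings: np.ndarray          # (n_predictors, n_lv); x-loadings of full fit
    predictions: np.ndarray       # LOOCV predictions, record order


def _loocv_predictions(X: np.ndarray, y: np.ndarray, n_lv: int) -> np.ndarray:
    """Leave-one-out predictions, refitting (with fold-local z-scoring) each time."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr = (X[tr] - mu) / sd
        Xte = (X[i:i + 1] - mu) / sd
        if X.shape[1] == 1:
            model = LinearRegression().fit(Xtr, y[tr])
        else:
            model = PLSRegression(n_components=n_lv, scale=False).fit(Xtr, y[tr])
        preds[i] = float(np.ravel(model.predict(Xte))[0])
    return preds


def plsr_loocv(cohort: pd.DataFrame, predictors, response: str,
               n_lv: int | None = None,
               normaliser: str = "range") -> PlsrResult:
    """LOOCV-evaluated PLSR (or single-predictor linear regression).

    With one predictor this is the per-parameter linear-regression procedure;
    with several, NIPALS PLSR on z-scored predictors.  ``n_lv=None`` selects
    the number of latent variables minimising the LOOCV NRMSE.  NRMSE is
    RMSE(pred, obs) divided by the observed range (or the observed mean with
    ``normaliser="mean"``).
    """
    predictors = tuple(predictors)
    X = cohort[list(predictors)].to_numpy(dtype=float)
    y = cohort[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    n, p = X.shape
    if n <= p:
        log.warning("plsr_loocv: %d records <= %d predictors; "
                    "cross-validated error remains meaningful but the full "
                    "model is not uniquely determined", n, p)

    def nrmse_of(preds):
        rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
        denom = float(np.ptp(y)) if normaliser == "range" else float(np.mean(y))
        return rmse / denom

    if p == 1:
        best_lv, preds = 1, _loocv_predictions(X, y, 1)
    elif n_lv is not None:
        best_lv, preds = int(n_lv), _loocv_predictions(X, y, int(n_lv))
    else:
        candidates = range(1, min(p, n - 2) + 1)
        scored = [(lv, _loocv_predictions(X, y, lv)) for lv in candidates]
        best_lv, preds = min(scored, key=lambda t: nrmse_of(t[1]))

    # full-data loadings for reporting
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Xz = (X - mu) / sd
    if p == 1:
        full = LinearRegression().fit(Xz, y)
        loadings = np.asarray(full.coef_).reshape(1, 1)
    else:
        full = PLSRegression(n_components=best_lv, scale=False).fit(Xz, y)
        loadings = np.asarray(full.x_loadings_)

    return PlsrResult(predictors, response, best_lv, nrmse_of(preds),
                      loadings, preds)
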