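"""Predictive assessment: WAIC model comparison and calibration tables.

WAIC is computed from the pointwise log-likelihood evaluated at the retained
posterior draws: lppd sums the log of the per-observation mean likelihood
(stabilised by a max shift) and the effective-parameter penalty p_waic sums
the per-observation sample variance of the log-likelihood; WAIC is
-2 (lppd - p_waic), so lower is better.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DesignMatrix, Posterior, _expit

log = logging.getLogger(__name__)

__all__ = ["WAICResult", "pointwise_loglik", "waic", "compare_waic",
           "observed_vs_fitted"]

_CLAMP = 1e-12


def pointwise_loglik(posterior: Posterior, design: DesignMatrix,
                     max_draws: int | None = 400) -> np.ndarray:
    """(draws x observations) Bernoulli log-likelihood table.

    Entry (s, i) = y_i log p_i^(s) + (1 - y_i) log(1 - p_i^(s)).  Predicted
    probabilities of exactly 0 or 1 that contradict the outcome are clamped at
    1e-12 with a logged count.
    """
    eta = posterior.linear_predictor(design, max_draws=max_draws)
    p = _expit(eta)
    y = design.y
    n_clamped = int(((p <= 0.0) & (y == 1)).sum() + ((p >= 1.0) & (y == 0)).sum())
    if n_clamped:
        log.warning("clamped %d degenerate predicted probabilities", n_clamped)
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    return y * np.log(p) + (1.0 - y) * np.log1p(-p)


@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    lppd_pointwise: np.ndarray = field(repr=False)
    p_waic_pointwise: np.ndarray = field(repr=False)
    n_draws: int = 0

    def to_dict(self) -> dict:
        return {"lppd": self.lppd, "p_waic": self.p_waic, "waic": self.waic,
                "n_draws": self.n_draws}


def waic(loglik: np.ndarray, ddof: int = 1) -> WAICResult:
    """WAIC from a (draws x observations) log-likelihood table.

    lppd_i = log mean_s exp(ll_si) via a per-observation max shift;
    p_waic_i = sample variance over draws (zero, with a warning, for a single
    draw); waic = -2 (lppd - p_waic).

    ``ddof=1`` (default) is the unbiased variance convention; ``ddof=0`` is
    the population-consistent estimator, under which WAIC is exactly
    invariant to duplicating every draw.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("loglik table must be draws x observations")
    S = ll.shape[0]
    shift = ll.max(axis=0)
    lppd_i = shift + np.log(np.exp(ll - shift).mean(axis=0))
    if S < 2:
        log.warning("single posterior draw: p_waic is zero")
        p_i = np.zeros(ll.shape[1])
    else:
        p_i = ll.var(axis=0, ddof=ddof)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WAICResult(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic),
                      lppd_pointwise=lppd_i, p_waic_pointwise=p_i, n_draws=S)


def compare_waic(result_a: WAICResult, result_b: WAICResult) -> dict:
    """Delta report between two fitted variants (positive delta favours B)."""
    return {
        "waic_a": result_a.waic,
        "waic_b": result_b.waic,
        "delta": result_a.waic - result_b.waic,
        "preferred": "B" if result_b.waic < result_a.waic else "A",
    }


def observed_vs_fitted(posterior: Posterior, design: DesignMatrix,
                       grouping: str = "cluster",
                       max_draws: int | None = 400) -> pd.DataFrame:
    """Observed vs posterior-mean fitted prevalence per group.

    The result carries the global linear fit of observed on fitted prevalence
    (slope, intercept) and the squared correlation in ``attrs``; a calibrated
    model has slope near 1 (posterior-mean fitted values are shrunken, so
    this regression direction is the calibrated one).  With constant fitted
    values the correlation is undefined and reported as NaN.
    """
    codes = {"cluster": design.cluster_codes, "district": design.district_codes,
             "round": design.round_codes}.get(grouping)
    if codes is None:
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = {"cluster": design.cluster_ids, "district": design.district_ids,
              "round": design.round_dates}[grouping]
    phat = posterior.fitted_probabilities(design, max_draws=max_draws)
    n_groups = len(labels)
    counts = np.bincount(codes, minlength=n_groups)
    obs = np.bincount(codes, weights=design.y, minlength=n_groups)
    fit = np.bincount(codes, weights=phat, minlength=n_groups)
    present = counts > 0
    table = pd.DataFrame({
        grouping: [labels[i] for i in np.flatnonzero(present)],
        "n": counts[present],
        "observed": obs[present] / counts[present],
        "fitted": fit[present] / counts[present],
    })
    if table["fitted"].nunique() > 1 and table["observed"].nunique() > 1:
        slope, intercept = np.polyfit(table["fitted"], table["observed"], 1)
        r = float(np.corrcoef(table["observed"], table["fitted"])[0, 1])
        table.attrs.update(slope=float(slope), intercept=float(intercept),
                           r_squared=r * r)
    else:
        table.attrs.update(slope=np.nan, intercept=np.nan, r_squared=np.nan)
    return table
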