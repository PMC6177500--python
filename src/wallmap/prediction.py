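"""Linear wall-thickness models and prediction of individual WT maps.

The wall model relates the three per-vertex maps through an interaction
regression::

    WT = b0 + b1*WSS + b2*D + b3*WSS*D + eps

fitted per subject on the subject's own vertices (individual model), or
per bootstrap replicate on cohort-averaged maps, whose B coefficient
vectors are averaged and applied to individual WSS/diameter maps to
predict individual WT maps.  Reduced models keep only WSS, only D, or
only the interaction term.

Agreement between predicted and measured maps is quantified by
Spearman's rho, Bland-Altman mean difference and limits of agreement
(1.96 x SD of the paired differences), and the "maximum WT" (mean of
the top 5% of vertex values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .atlas import CohortMapSet
from .stats import bootstrap_multisets, spearman_rho

__all__ = [
    "RegressionFit",
    "BetaEnsemble",
    "PredictionEval",
    "FULL_MODEL",
    "fit_wt_regression",
    "fit_bootstrap_regressions",
    "predict_wt_map",
    "evaluate_prediction",
    "max_wall_thickness",
]

#: canonical term order; beta vectors are always length 4 in this order
#: (intercept, WSS, D, WSS*D), with zeros for terms not in the model
FULL_MODEL: Tuple[str, ...] = ("WSS", "D", "WSS*D")
_TERM_SLOT = {"WSS": 1, "D": 2, "WSS*D": 3}


def _design_matrix(wss: np.ndarray, d: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones_like(wss)]
    for t in terms:
        if t == "WSS":
            cols.append(wss)
        elif t == "D":
            cols.append(d)
        elif t == "WSS*D":
            cols.append(wss * d)
        else:
            raise ValueError(f"unknown model term {t!r}")
    return np.column_stack(cols)


@dataclass
class RegressionFit:
    """OLS fit of the wall model on one set of aligned maps."""

    beta: np.ndarray  # length 4: (b0, b1, b2, b3); zeros for absent terms
    residual_map: np.ndarray  # aligned with the input vectors, NaN where missing
    r_squared: float
    model_terms: Tuple[str, ...]
    n_used: int


def fit_wt_regression(
    wt: np.ndarray,
    wss: np.ndarray,
    d: np.ndarray,
    terms: Sequence[str] = FULL_MODEL,
) -> RegressionFit:
    """Ordinary least squares of WT on the requested terms, with intercept.

    Input vectors must be vertex-aligned; rows with any missing value
    are dropped from the fit and carry NaN residuals.  Raises on a
    rank-deficient design, naming the offending term.
    """
    wt = np.asarray(wt, dtype=float)
    wss = np.asarray(wss, dtype=float)
    d = np.asarray(d, dtype=float)
    if not (len(wt) == len(wss) == len(d)):
        raise ValueError("maps must be vertex-aligned (equal length)")
    terms = tuple(terms)
    ok = np.isfinite(wt) & np.isfinite(wss) & np.isfinite(d)
    n_used = int(ok.sum())
    if n_used < len(terms) + 2:
        raise ValueError(f"need at least {len(terms) + 2} complete vertices")

    x = _design_matrix(wss[ok], d[ok], terms)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        for j, t in enumerate(terms):
            col = x[:, j + 1]
            others = np.delete(x, j + 1, axis=1)
            proj, *_ = np.linalg.lstsq(others, col, rcond=None)
            if np.allclose(others @ proj, col, atol=1e-10 * max(1.0, np.abs(col).max())):
                raise ValueError(f"rank-deficient design: term {t!r} is collinear")
        raise ValueError("rank-deficient design matrix")

    coef, *_ = np.linalg.lstsq(x, wt[ok], rcond=None)
    beta = np.zeros(4)
    beta[0] = coef[0]
    for t, c in zip(terms, coef[1:]):
        beta[_TERM_SLOT[t]] = c

    resid = np.full(len(wt), np.nan)
    fitted = x @ coef
    resid[ok] = wt[ok] - fitted
    ss_res = float(np.sum(resid[ok] ** 2))
    ss_tot = float(np.sum((wt[ok] - wt[ok].mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return RegressionFit(
        beta=beta, residual_map=resid, r_squared=r2, model_terms=terms, n_used=n_used
    )


@dataclass
class BetaEnsemble:
    """Per-bootstrap coefficient vectors with ensemble mean and 95% CIs."""

    betas: np.ndarray  # (B, 4)
    mean_beta: np.ndarray  # (4,)
    ci95: np.ndarray  # (4, 2) percentile bounds
    model_terms: Tuple[str, ...]
    seed: int

    @property
    def B(self) -> int:
        return len(self.betas)


def fit_bootstrap_regressions(
    mapset: CohortMapSet,
    B: int = 1000,
    seed: int = 0,
    terms: Sequence[str] = FULL_MODEL,
) -> BetaEnsemble:
    """Wall-model OLS on each of B bootstrapped cohort-averaged map sets.

    Uses the same subject multisets as :func:`bootstrap_correlations`
    run with the same seed, so joint analyses share their resampling.
    """
    terms = tuple(terms)
    complete = mapset.complete_vertices(("WT", "WSS", "D"))
    if not complete.any():
        raise ValueError("no atlas vertex is covered by all subjects")
    wt_m = mapset.matrices["WT"][:, complete]
    wss_m = mapset.matrices["WSS"][:, complete]
    d_m = mapset.matrices["D"][:, complete]
    multisets = bootstrap_multisets(mapset.n_subjects, B, seed)
    betas = np.empty((B, 4))
    for i, idx in enumerate(multisets):
        fit = fit_wt_regression(
            wt_m[idx].mean(axis=0), wss_m[idx].mean(axis=0), d_m[idx].mean(axis=0), terms
        )
        betas[i] = fit.beta
    ci = np.stack(
        [np.percentile(betas, [2.5, 97.5], axis=0).T[k] for k in range(4)]
    )
    return BetaEnsemble(
        betas=betas, mean_beta=betas.mean(axis=0), ci95=ci, model_terms=terms, seed=seed
    )


def predict_wt_map(
    wss: np.ndarray,
    d: np.ndarray,
    beta: np.ndarray,
    terms: Sequence[str] = FULL_MODEL,
) -> Tuple[np.ndarray, int]:
    """Predicted WT map from WSS/diameter maps and model coefficients.

    Negative predictions are retained (and counted), matching the raw
    linear model; clip only for display.  Returns ``(values, n_negative)``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (4,) or not np.all(np.isfinite(beta)):
        raise ValueError("beta must be 4 finite coefficients (b0, b1, b2, b3)")
    wss = np.asarray(wss, dtype=float)
    d = np.asarray(d, dtype=float)
    pred = np.full(len(wss), beta[0], dtype=float)
    for t in terms:
        slot = _TERM_SLOT[t]
        col = {"WSS": wss, "D": d, "WSS*D": wss * d}[t]
        pred = pred + beta[slot] * col
    n_negative = int(np.sum(pred[np.isfinite(pred)] < 0))
    return pred, n_negative


def max_wall_thickness(values: np.ndarray) -> float:
    """Mean of the top 5% of values (ties by value then index order)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    k = max(1, math.ceil(0.05 * len(v)))
    top = np.sort(v)[-k:]
    return float(top.mean())


@dataclass
class PredictionEval:
    """Agreement between a predicted and a measured WT map."""

    spearman_rho: float
    mean_difference: float  # mm, mean(predicted - original)
    loa: float  # mm, 1.96 x SD of the paired differences
    max_wt_original: float
    max_wt_predicted: float


def evaluate_prediction(
    original: np.ndarray, predicted: np.ndarray
) -> PredictionEval:
    """Spearman rho, Bland-Altman statistics and top-5% maximum WT."""
    original = np.asarray(original, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if len(original) != len(predicted):
        raise ValueError("maps must be aligned")
    ok = np.isfinite(original) & np.isfinite(predicted)
    diff = predicted[ok] - original[ok]
    mean_diff = float(diff.mean())
    loa = 0.0 if len(diff) < 2 else float(1.96 * diff.std(ddof=1))
    rho = spearman_rho(original, predicted) if ok.sum() >= 3 else float("nan")
    return PredictionEval(
        spearman_rho=rho,
        mean_difference=mean_diff,
        loa=loa,
        max_wt_original=max_wall_thickness(original[ok]),
        max_wt_predicted=max_wall_thickness(predicted[ok]),
    )
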