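"""Individual and bootstrap cohort-level correlation inference.

Spatial autocorrelation makes vertex-wise parametric tests on
cohort-averaged maps invalid; the subject-level bootstrap is the
inference tool: subjects are resampled with replacement, each replicate
is averaged vertex-wise on the shared geometry, Spearman's rho is
computed between the averaged maps, and the 2.5th-97.5th percentile
interval of the B replicate rho values forms the 95% CI.  A correlation
is significant when that interval excludes 0.

Individual-level inference Fisher-z-transforms the per-subject rho
values and applies a one-sample two-sided Student's t-test against 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .atlas import CohortMapSet, average_maps

__all__ = [
    "spearman_rho",
    "fisher_z_test",
    "individual_correlations",
    "bootstrap_multisets",
    "bootstrap_correlations",
    "linearity_check",
    "CorrelationResult",
    "BootstrapResult",
    "LinearityCheck",
]

DEFAULT_PAIRS = (("WT", "WSS"), ("WT", "D"), ("WSS", "D"))


def spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman's rank correlation with mid-rank tie handling.

    Pairwise-missing entries are removed first; returns NaN (with a
    warning) when either ranked vector has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs for Spearman's rho")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant input: Spearman's rho undefined", stacklevel=2)
        return float("nan")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def _spearman_matrix_prepared(ranked_ok: np.ndarray, b: np.ndarray) -> float:
    """Fast path used by the bootstrap: both inputs already complete."""
    ra = sps.rankdata(ranked_ok)
    rb = sps.rankdata(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        return float("nan")
    return float((ra @ rb) / denom)


@dataclass
class CorrelationResult:
    """Per-subject Spearman correlations for one map pair."""

    pair: Tuple[str, str]
    per_subject_rho: np.ndarray
    mean_rho: float
    sd_rho: float
    p_value: float


def fisher_z_test(rhos: Sequence[float]) -> Tuple[float, float, float]:
    """Mean, SD and Fisher-z t-test p-value of per-subject rho values.

    The test transforms rho to z = atanh(rho) and applies a one-sample
    two-sided t-test of the z values against 0; the reported mean and SD
    are of the raw rho values.  |rho| = 1 is clipped just inside the
    open interval with a warning.
    """
    rhos = np.asarray(rhos, dtype=float)
    rhos = rhos[np.isfinite(rhos)]
    if len(rhos) < 2:
        raise ValueError("need at least 2 finite correlations")
    if np.any(np.abs(rhos) >= 1):
        warnings.warn("|rho| = 1 clipped for the Fisher z-transform", stacklevel=2)
        rhos = np.clip(rhos, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(rhos)
    if np.allclose(z, 0):
        p = 1.0
    else:
        p = float(sps.ttest_1samp(z, 0.0).pvalue)
    return float(np.mean(rhos)), float(np.std(rhos, ddof=1)), p


def individual_correlations(
    per_subject_maps: Sequence[Dict[str, np.ndarray]],
    pairs: Sequence[Tuple[str, str]] = DEFAULT_PAIRS,
) -> List[CorrelationResult]:
    """Subject-level Spearman correlations using all vertices per subject."""
    results = []
    for pair in pairs:
        rhos = np.array(
            [spearman_rho(maps[pair[0]], maps[pair[1]]) for maps in per_subject_maps]
        )
        mean, sd, p = fisher_z_test(rhos)
        results.append(
            CorrelationResult(
                pair=tuple(pair), per_subject_rho=rhos, mean_rho=mean, sd_rho=sd, p_value=p
            )
        )
    return results


def bootstrap_multisets(n_subjects: int, B: int, seed: int) -> np.ndarray:
    """The (B, n) subject multisets used by every bootstrap quantity.

    Drawn once from ``default_rng(seed)``; correlation and regression
    bootstraps run with the same seed therefore share their multisets.
    """
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_subjects, size=(B, n_subjects))


@dataclass
class BootstrapResult:
    """Bootstrap distribution of cohort-averaged Spearman's rho."""

    pair: Tuple[str, str]
    B: int
    rho_per_bootstrap: np.ndarray
    mean_rho: float
    ci95: Tuple[float, float]
    significant: bool
    seed: int


def bootstrap_correlations(
    mapset: CohortMapSet,
    pairs: Sequence[Tuple[str, str]] = DEFAULT_PAIRS,
    B: int = 1000,
    seed: int = 0,
) -> List[BootstrapResult]:
    """Subject-level bootstrap of correlations between cohort-averaged maps.

    Per replicate: draw n subjects with replacement, average each
    quantity vertex-wise over the multiset, correlate the averaged maps
    over complete vertices.  The 95% CI is the 2.5th-97.5th percentile
    of the B rho values; significance means 0 lies outside it.
    """
    if mapset.n_subjects < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    if B < 1:
        raise ValueError("B must be >= 1")
    quantities = sorted({q for pair in pairs for q in pair})
    complete = mapset.complete_vertices(quantities)
    if not complete.any():
        raise ValueError("no atlas vertex is covered by all subjects")
    sub = {q: mapset.matrices[q][:, complete] for q in quantities}
    multisets = bootstrap_multisets(mapset.n_subjects, B, seed)

    results = []
    for pair in pairs:
        rhos = np.empty(B)
        for b_i, idx in enumerate(multisets):
            ma = sub[pair[0]][idx].mean(axis=0)
            mb = sub[pair[1]][idx].mean(axis=0)
            rhos[b_i] = _spearman_matrix_prepared(ma, mb)
        lo, hi = np.percentile(rhos, [2.5, 97.5])
        results.append(
            BootstrapResult(
                pair=tuple(pair),
                B=B,
                rho_per_bootstrap=rhos,
                mean_rho=float(np.mean(rhos)),
                ci95=(float(lo), float(hi)),
                significant=bool(lo > 0 or hi < 0),
                seed=seed,
            )
        )
    return results


@dataclass
class LinearityCheck:
    adequate: bool
    f_statistic: float
    p_value: float
    n_bins: int
    reason: str = ""


def linearity_check(
    x: np.ndarray, y: np.ndarray, n_bins: int = 10, alpha: float = 0.05
) -> LinearityCheck:
    """Lack-of-fit test of a simple linear model via decile-binned means.

    ``x`` is cut at its deciles; within-bin means provide the "pure
    error" model.  The F statistic compares the linear model's excess
    sum of squares over the binned-means model to the within-bin
    variability; p < alpha flags the linear model as inadequate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 4:
        return LinearityCheck(
            adequate=False, f_statistic=float("nan"), p_value=float("nan"),
            n_bins=len(edges) - 1, reason="too few distinct x deciles",
        )
    bins = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sse_lin = float(resid @ resid)
    if sse_lin <= 1e-12 * max(1.0, float(y @ y)):
        # the line fits (numerically) perfectly; nothing left to explain
        return LinearityCheck(adequate=True, f_statistic=0.0, p_value=1.0,
                              n_bins=len(edges) - 1)

    sse_pe = 0.0
    c = 0
    n = len(x)
    for b in range(len(edges) - 1):
        yy = y[bins == b]
        if len(yy):
            sse_pe += float(np.sum((yy - yy.mean()) ** 2))
            c += 1
    df_lof, df_pe = c - 2, n - c
    if df_lof <= 0 or df_pe <= 0:
        return LinearityCheck(
            adequate=False, f_statistic=float("nan"), p_value=float("nan"),
            n_bins=c, reason="insufficient degrees of freedom",
        )
    sse_lof = max(sse_lin - sse_pe, 0.0)
    if sse_pe == 0:
        adequate = sse_lof <= 1e-12
        return LinearityCheck(adequate, float("inf") if not adequate else 0.0,
                              0.0 if not adequate else 1.0, c,
                              reason="zero within-bin variance")
    f = (sse_lof / df_lof) / (sse_pe / df_pe)
    p = float(sps.f.sf(f, df_lof, df_pe))
    return LinearityCheck(adequate=p >= alpha, f_statistic=float(f), p_value=p, n_bins=c)
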