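"""Univariable two-sample MR estimators and diagnostics.

Given J harmonized instruments with exposure effects bx_j (SE sx_j) and
outcome effects by_j (SE sy_j), the per-SNP Wald ratio by_j/bx_j estimates the
causal effect under the IV assumptions. This module implements:

* :func:`wald_ratio` — the per-SNP building block (first-order delta SE);
* :func:`ivw` — the inverse-variance-weighted average, fixed-effect or with a
  multiplicative random-effects SE inflation sqrt(max(1, Q/df)), plus
  Cochran's Q heterogeneity test;
* :func:`egger` — MR-Egger weighted regression with a free intercept; the
  intercept is the directional-pleiotropy test, the slope the pleiotropy-robust
  causal estimate, and the weighted residual sum of squares Rücker's Q;
* :func:`weighted_median` — the estimate at the 50% point of the weight
  distribution, consistent when up to half the weight comes from invalid
  instruments, with a seeded parametric-bootstrap SE.

IVW p-values use the standard normal; Egger slope/intercept p-values use a
t distribution on J−2 df, matching the reference implementations' conventions.
All estimates are reported on the log-odds scale alongside OR = exp(beta) and
a 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    DegenerateInstrumentError,
    EmptyInputError,
    InsufficientInstrumentsError,
)
from .gwas_io import HarmonizedSet

_Z95 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with OR-scale CI and Egger diagnostics."""

    method: str  # IVW_fixed | IVW_random | Egger | WeightedMedian | WaldRatio
    beta: float
    se: float
    pval: float
    n_snp: int
    or_value: float
    ci_low: float
    ci_high: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    @property
    def significant(self) -> bool:
        """Causal association at the conventional p < 0.05 level."""
        return self.pval < 0.05


@dataclass(frozen=True)
class QTestResult:
    """Heterogeneity test: Cochran's Q (IVW) or Rücker's Q (Egger)."""

    q: float
    df: int
    pval: float
    flavor: str  # "Cochran" | "Rucker"


def _finish(method: str, beta: float, se: float, pval: float, n_snp: int,
            **kw) -> MREstimate:
    return MREstimate(
        method=method, beta=float(beta), se=float(se), pval=float(pval),
        n_snp=int(n_snp),
        or_value=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        **kw,
    )


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, sx: float, by: float, sy: float,
               second_order: bool = False) -> tuple[float, float]:
    """Per-SNP causal estimate by/bx with its delta-method standard error.

    The default first-order SE, sy/|bx|, ignores exposure uncertainty; it is
    the dominant convention in two-sample MR and makes IVW coincide with the
    no-intercept weighted regression of by on bx. ``second_order`` adds the
    bx-uncertainty term sqrt(sy²/bx² + by²·sx²/bx⁴).
    """
    if bx == 0:
        raise DegenerateInstrumentError("exposure beta is zero")
    ratio = by / bx
    if second_order:
        se = float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))
    else:
        se = sy / abs(bx)
    return ratio, se


def _ratios(h: HarmonizedSet, second_order: bool = False):
    if np.any(h.bx == 0):
        raise DegenerateInstrumentError("exposure beta is zero for some SNP")
    r = h.by / h.bx
    if second_order:
        s = np.sqrt(h.sy**2 / h.bx**2 + h.by**2 * h.sx**2 / h.bx**4)
    else:
        s = h.sy / np.abs(h.bx)
    return r, s


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(
    h: HarmonizedSet,
    effects_model: str = "random_multiplicative",
    second_order: bool = False,
) -> tuple[MREstimate, QTestResult | None]:
    """Inverse-variance-weighted causal estimate with Cochran's Q.

    With weights w_j = 1/ratio_se_j², beta = Σ w_j·ratio_j / Σ w_j and the
    fixed-effect SE is (Σ w_j)^(−1/2). Under ``"random_multiplicative"`` the
    SE is inflated by sqrt(max(1, Q/(J−1))), which widens the CI exactly when
    the instruments are over-dispersed relative to their sampling error.
    A single instrument degenerates to the Wald ratio (no Q test).
    """
    if effects_model not in ("fixed", "random_multiplicative"):
        raise ConfigurationError(f"unknown effects model: {effects_model!r}")
    j = len(h)
    if j == 0:
        raise EmptyInputError("empty harmonized set")
    r, s = _ratios(h, second_order)
    if j == 1:
        beta, se = float(r[0]), float(s[0])
        pval = 2 * sps.norm.sf(abs(beta / se))
        return _finish("WaldRatio", beta, se, pval, 1), None
    w = 1.0 / s**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (r - beta) ** 2))
    df = j - 1
    qtest = QTestResult(q=q, df=df, pval=float(sps.chi2.sf(q, df)),
                        flavor="Cochran")
    if effects_model == "fixed":
        se, method = se_fixed, "IVW_fixed"
    else:
        se = se_fixed * float(np.sqrt(max(1.0, q / df)))
        method = "IVW_random"
    pval = 2 * sps.norm.sf(abs(beta / se))
    return _finish(method, beta, se, pval, j), qtest


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger(h: HarmonizedSet) -> tuple[MREstimate, QTestResult]:
    """MR-Egger regression: slope = causal estimate, intercept = pleiotropy.

    Each SNP is oriented so its exposure effect is non-negative (negating both
    bx and by otherwise), then by is regressed on bx with a free intercept and
    weights 1/sy². A nonzero intercept indicates directional horizontal
    pleiotropy; slope and intercept p-values use a t distribution on J−2 df.
    The weighted residual sum of squares is Rücker's Q.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs ≥ 3 instruments, got {j}")
    flip = np.where(h.bx < 0, -1.0, 1.0)
    bx = flip * h.bx
    by = flip * h.by
    w = 1.0 / h.sy**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    p_int, p_slope = fit.pvalues  # t distribution, J-2 df
    q = float(np.sum(w * fit.resid**2))
    df = j - 2
    qtest = QTestResult(q=q, df=df, pval=float(sps.chi2.sf(q, df)),
                        flavor="Rucker")
    est = _finish(
        "Egger", slope, se_slope, p_slope, j,
        intercept=float(intercept), intercept_se=float(se_int),
        intercept_pval=float(p_int),
    )
    return est, qtest


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the value at the 50% weight point.

    With sorted values and normalized weights w', the cumulative midpoints are
    p_j = Σ_{k≤j} w'_k − w'_j/2 and the estimate linearly interpolates the
    value at p = 0.5 (clamped at the extremes).
    """
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / np.sum(weights)
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, v))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 5000,
    seed: int = 0,
    second_order: bool = False,
) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Consistent when at least 50% of the total weight comes from valid
    instruments. The SE resamples (bx_j, by_j) from Normal(bx_j, sx_j) and
    Normal(by_j, sy_j) and takes the SD of the recomputed medians; the run is
    fully determined by ``seed``.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs ≥ 3 instruments, got {j}"
        )
    if n_boot < 100:
        raise ConfigurationError("n_boot must be at least 100")
    r, s = _ratios(h, second_order)
    w = 1.0 / s**2
    beta = _weighted_median(r, w)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(h.bx, h.sx, size=(n_boot, j))
    by_star = rng.normal(h.by, h.sy, size=(n_boot, j))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    r_star = by_star / bx_star
    w_star = (bx_star / h.sy) ** 2  # 1/ratio_se² with first-order SE
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median(r_star[b], w_star[b])
    se = float(np.std(boots, ddof=1))
    pval = 2 * sps.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta else 1.0)
    return _finish("WeightedMedian", beta, se, pval, j)


# ---------------------------------------------------------------------------
# Convenience: all methods as a tidy table
# ---------------------------------------------------------------------------

def mr_all(
    h: HarmonizedSet,
    n_boot: int = 5000,
    seed: int = 0,
) -> "pd.DataFrame":
    """Run IVW (both effects models), MR-Egger and the weighted median.

    Returns a tidy table (one row per method) in the forest-plot layout:
    method, nsnp, beta, se, or, ci_low, ci_high, pval, q, q_df, q_pval,
    egger_intercept, egger_intercept_se, egger_intercept_pval. Methods whose
    instrument requirements are not met are simply omitted.
    """
    import pandas as pd

    rows = []

    def _row(est: MREstimate, qt: QTestResult | None) -> dict:
        return {
            "method": est.method, "nsnp": est.n_snp,
            "beta": est.beta, "se": est.se,
            "or": est.or_value, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval,
            "q": qt.q if qt else np.nan,
            "q_df": qt.df if qt else np.nan,
            "q_pval": qt.pval if qt else np.nan,
            "egger_intercept": est.intercept,
            "egger_intercept_se": est.intercept_se,
            "egger_intercept_pval": est.intercept_pval,
        }

    est, qt = ivw(h, effects_model="fixed")
    rows.append(_row(est, qt))
    if len(h) >= 2:
        est, qt = ivw(h, effects_model="random_multiplicative")
        rows.append(_row(est, qt))
    if len(h) >= 3:
        est, qt = egger(h)
        rows.append(_row(est, qt))
        rows.append(_row(weighted_median(h, n_boot=n_boot, seed=seed), None))
    return pd.DataFrame(rows)
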