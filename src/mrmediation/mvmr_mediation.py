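"""Multivariable MR and the mediation layer.

The mediation model decomposes the total effect of an exposure on the outcome
(β_C) into a direct effect (β_C′) and an indirect path through a mediator:
exposure → mediator (β_A) and mediator → outcome (β_B).

Two routes quantify the mediated component:

* **difference method** — fit a multivariable MR including instruments for
  both the exposure and the mediator; β_C′ is the exposure's coefficient after
  mutual adjustment, indirect = β_C − β_C′, proportion = indirect/β_C.
  Requires full summary data for the joint model.
* **product method** — indirect = β_A·β_B with the Sobel normal-theory test,
  proportion = β_A·β_B/β_C. Used when β_A is weak or the joint model cannot
  be fitted.

A mediator is declared to mediate only when β_A, β_B and β_C are all
significant (p < 0.05) and the mediation test itself passes (Sobel p < 0.05,
or for the difference method: β_C′ significant, attenuated in magnitude, and
an implied proportion > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    CollinearityError,
    ConfigurationError,
    EmptyHarmonizationError,
    InsufficientInstrumentsError,
    MRError,
    UndefinedProportionError,
)
from .estimators import ivw
from .gwas_io import (
    ClumpConfig,
    HarmonizedSet,
    PairwiseLD,
    SummaryStats,
    harmonize,
    select_instruments,
)

ALPHA = 0.05  # conventional significance threshold for all MR conclusions


# ---------------------------------------------------------------------------
# Multivariable IVW
# ---------------------------------------------------------------------------

@dataclass
class MVMRSet:
    """Jointly harmonized instruments: K exposure beta columns, one outcome."""

    snp_ids: list[str]
    bx: np.ndarray  # (J, K) exposure effects, aligned to a common effect allele
    sx: np.ndarray  # (J, K)
    by: np.ndarray  # (J,)
    sy: np.ndarray  # (J,)
    exposure_labels: list[str] = field(default_factory=list)
    outcome_label: str = ""

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        j = len(self.snp_ids)
        if self.bx.shape[0] != j or self.sx.shape != self.bx.shape:
            raise ValueError("bx/sx must be (J, K) with J = |snp_ids|")
        if self.by.shape != (j,) or self.sy.shape != (j,):
            raise ValueError("by/sy must have length J")
        if j and np.any(self.sy <= 0):
            raise ValueError("outcome SEs must be positive")

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]


@dataclass(frozen=True)
class MVMREstimate:
    """Direct effects of each exposure after mutual adjustment."""

    exposure_labels: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    n_snp: int

    def for_exposure(self, label: str) -> tuple[float, float, float]:
        k = self.exposure_labels.index(label)
        return float(self.betas[k]), float(self.ses[k]), float(self.pvals[k])


def mvmr_ivw(m: MVMRSet) -> MVMREstimate:
    """Multivariable IVW: weighted no-intercept regression of by on the
    exposure-beta matrix with weights 1/sy².

    Coefficient k is exposure k's direct effect. SEs come from the weighted
    least-squares covariance with the same multiplicative overdispersion
    inflation as univariable IVW, sqrt(max(1, Q/(J−K))); p-values are
    two-sided normal.

    An exposure whose beta column is identically zero contributes nothing to
    the fit; it is assigned a zero direct effect (infinite SE, p = 1) and the
    regression runs on the remaining columns, so the other exposures'
    estimates degenerate to their lower-dimensional model. Linearly dependent
    *nonzero* columns raise :class:`CollinearityError`.
    """
    j, k = m.bx.shape
    if j < k + 1:
        raise InsufficientInstrumentsError(
            f"multivariable IVW needs ≥ {k + 1} instruments for {k} exposures, got {j}"
        )
    w = 1.0 / m.sy**2
    nonzero = np.flatnonzero(np.any(m.bx != 0, axis=0))
    if nonzero.size == 0:
        raise CollinearityError("all exposure beta columns are zero")
    x = m.bx[:, nonzero]
    k_eff = x.shape[1]
    if np.linalg.matrix_rank(x * np.sqrt(w)[:, None]) < k_eff:
        raise CollinearityError("exposure beta matrix is rank deficient")
    fit = sm.WLS(m.by, x, weights=w).fit()
    resid = m.by - x @ fit.params
    q = float(np.sum(w * resid**2))
    df = j - k_eff
    scale = math.sqrt(max(1.0, q / df)) if df > 0 else 1.0
    xtwx_inv = np.linalg.inv(x.T @ (w[:, None] * x))
    betas = np.zeros(k)
    ses = np.full(k, np.inf)
    betas[nonzero] = np.asarray(fit.params, dtype=float)
    ses[nonzero] = np.sqrt(np.diag(xtwx_inv)) * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = np.where(
            np.isfinite(ses), 2 * sps.norm.sf(np.abs(betas) / ses), 1.0
        )
    labels = list(m.exposure_labels) or [f"exposure_{i+1}" for i in range(k)]
    return MVMREstimate(exposure_labels=labels, betas=betas, ses=ses,
                        pvals=pvals, n_snp=j)


def build_mvmr_set(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    clump: ClumpConfig | None = None,
    ld: PairwiseLD | None = None,
    blocklist: frozenset = frozenset(),
    drop_palindromes: bool = True,
) -> MVMRSet:
    """Pool instruments for exposure and mediator, align everything to the
    exposure's effect alleles, and harmonize to the outcome.

    The instrument set is the union of each trait's clumped instruments,
    re-clumped jointly (each SNP carries its smaller p across the two traits),
    restricted to SNPs present in all three datasets. Each exposure must
    contribute at least one significant instrument to the pooled set.
    """
    import warnings

    clump = clump or ClumpConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iv_exp = select_instruments(exposure, clump, ld, blocklist)
        iv_med = select_instruments(mediator, clump, ld, blocklist)

    # Union with per-SNP min-p, taking the record from the trait where the SNP
    # is stronger (alleles are re-aligned below, so the choice only fixes p).
    pool: dict[str, tuple[float, object]] = {}
    for rec in iv_exp.records + iv_med.records:
        cur = pool.get(rec.snp_id)
        if cur is None or rec.pval < cur[0]:
            pool[rec.snp_id] = (rec.pval, rec)
    pooled = SummaryStats(
        [rec for _, rec in pool.values()], trait_label="pooled_instruments"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = select_instruments(
            pooled, ClumpConfig(clump.r2_threshold, clump.window_kb, 1.0),
            ld, blocklist,
        )

    pooled_ids = set(pooled.snp_ids)
    exp_sub = SummaryStats(
        [r for r in exposure.records if r.snp_id in pooled_ids],
        trait_label=exposure.trait_label,
    )
    # Align mediator and outcome effects to the exposure's effect alleles.
    h_med = harmonize(exp_sub, mediator, drop_palindromes=drop_palindromes)
    h_out = harmonize(exp_sub, outcome, drop_palindromes=drop_palindromes)
    shared = [s for s in h_med.snp_ids if s in set(h_out.snp_ids)]
    if not shared:
        raise EmptyHarmonizationError("no pooled SNP present in all three datasets")
    im = {s: i for i, s in enumerate(h_med.snp_ids)}
    io = {s: i for i, s in enumerate(h_out.snp_ids)}
    med_idx = [im[s] for s in shared]
    out_idx = [io[s] for s in shared]

    bx = np.column_stack([h_med.bx[med_idx], h_med.by[med_idx]])
    sx = np.column_stack([h_med.sx[med_idx], h_med.sy[med_idx]])
    mv = MVMRSet(
        snp_ids=shared,
        bx=bx, sx=sx,
        by=h_out.by[out_idx], sy=h_out.sy[out_idx],
        exposure_labels=[exposure.trait_label or "exposure",
                         mediator.trait_label or "mediator"],
        outcome_label=outcome.trait_label,
    )
    for k, (label, iv) in enumerate(
        [(mv.exposure_labels[0], iv_exp), (mv.exposure_labels[1], iv_med)]
    ):
        if not (set(iv.snp_ids) & set(shared)):
            raise InsufficientInstrumentsError(
                f"{label}: no significant instrument survives in the pooled set"
            )
    return mv


# ---------------------------------------------------------------------------
# Sobel test and mediated proportion
# ---------------------------------------------------------------------------

class SobelResult(NamedTuple):
    indirect: float
    sobel_se: float
    z: float
    pval: float


def sobel_test(beta_a: float, se_a: float, beta_b: float, se_b: float) -> SobelResult:
    """Normal-theory test of the product-of-coefficients indirect effect.

    indirect = β_A·β_B, SE = sqrt(β_A²·S_B² + β_B²·S_A²), z = indirect/SE,
    two-sided standard-normal p. When both coefficients are exactly zero the
    statistic is undefined and p = 1 is reported.
    """
    if se_a <= 0 or se_b <= 0:
        raise ConfigurationError("Sobel test requires positive standard errors")
    indirect = beta_a * beta_b
    se = math.sqrt(beta_a**2 * se_b**2 + beta_b**2 * se_a**2)
    if se == 0:
        return SobelResult(indirect=indirect, sobel_se=0.0, z=0.0, pval=1.0)
    z = indirect / se
    pval = 2 * sps.norm.sf(abs(z))
    return SobelResult(indirect=indirect, sobel_se=se, z=float(z), pval=float(pval))


def proportion_mediated(
    beta_c: float,
    method: str,
    beta_a: float | None = None,
    beta_b: float | None = None,
    beta_c_prime: float | None = None,
) -> float:
    """Mediated proportion of the total effect, as a raw fraction.

    ``method="product"``: β_A·β_B/β_C. ``method="difference"``:
    (β_C − β_C′)/β_C. Sign-inconsistent mediation (outside [0, 1]) is
    returned as-is — callers flag it, never clip it.
    """
    if beta_c == 0:
        raise UndefinedProportionError("total effect beta_c is zero")
    if method == "product":
        if beta_a is None or beta_b is None:
            raise ConfigurationError("product method needs beta_a and beta_b")
        return beta_a * beta_b / beta_c
    if method == "difference":
        if beta_c_prime is None:
            raise ConfigurationError("difference method needs beta_c_prime")
        return (beta_c - beta_c_prime) / beta_c
    raise ConfigurationError(f"unknown method: {method!r}")


# ---------------------------------------------------------------------------
# Mediation result and the full exposure → mediator → outcome analysis
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """The β_A/β_B/β_C(′) bundle with indirect effect and verdict."""

    exposure_label: str
    mediator_label: str
    outcome_label: str
    beta_a: float
    se_a: float
    pval_a: float
    beta_b: float
    se_b: float
    pval_b: float
    beta_c: float
    se_c: float
    pval_c: float
    method: str  # "difference" | "product"
    indirect: float
    proportion: float  # raw fraction; see proportion_pct
    mediates: bool
    beta_c_prime: float | None = None
    se_c_prime: float | None = None
    pval_c_prime: float | None = None
    sobel_se: float | None = None
    sobel_z: float | None = None
    sobel_pval: float | None = None

    @property
    def proportion_pct(self) -> float:
        """Mediated proportion as a percentage, rounded to 2 decimals."""
        return round(100.0 * self.proportion, 2)

    @property
    def proportion_out_of_range(self) -> bool:
        """Sign-inconsistent mediation: proportion outside [0, 1]."""
        return not (0.0 <= self.proportion <= 1.0)


def mediation_from_coefficients(
    beta_a: float,
    se_a: float,
    beta_b: float,
    se_b: float,
    beta_c: float,
    se_c: float = float("nan"),
    pval_a: float | None = None,
    pval_b: float | None = None,
    pval_c: float | None = None,
    beta_c_prime: float | None = None,
    se_c_prime: float | None = None,
    pval_c_prime: float | None = None,
    alpha: float = ALPHA,
    labels: tuple[str, str, str] = ("exposure", "mediator", "outcome"),
) -> MediationResult:
    """Assemble a mediation verdict from pre-computed MR coefficients.

    Leg p-values default to the normal-theory two-sided p from beta/SE. When
    β_C′ is supplied the difference method is applied, otherwise the Sobel
    product method. This is the entry point for re-analysing published
    coefficient tables, where only the β's and SEs are available.
    """
    def _p(beta, se, given):
        if given is not None:
            return given
        if not (se > 0) or math.isnan(se):
            return float("nan")
        return float(2 * sps.norm.sf(abs(beta / se)))

    pval_a = _p(beta_a, se_a, pval_a)
    pval_b = _p(beta_b, se_b, pval_b)
    pval_c = _p(beta_c, se_c, pval_c)
    sob = sobel_test(beta_a, se_a, beta_b, se_b)
    legs_significant = all(
        p < alpha for p in (pval_a, pval_b, pval_c) if not math.isnan(p)
    ) and not math.isnan(pval_a) and not math.isnan(pval_b)

    if beta_c_prime is not None:
        method = "difference"
        indirect = beta_c - beta_c_prime
        proportion = proportion_mediated(beta_c, "difference",
                                         beta_c_prime=beta_c_prime)
        pcp = _p(beta_c_prime, se_c_prime if se_c_prime else float("nan"),
                 pval_c_prime)
        attenuated = (
            not math.isnan(pcp)
            and pcp < alpha
            and abs(beta_c_prime) < abs(beta_c)
            and proportion > 0
        )
        mediates = legs_significant and attenuated
    else:
        method = "product"
        indirect = sob.indirect
        proportion = proportion_mediated(beta_c, "product",
                                         beta_a=beta_a, beta_b=beta_b)
        mediates = legs_significant and sob.pval < alpha
        pcp = pval_c_prime

    return MediationResult(
        exposure_label=labels[0], mediator_label=labels[1],
        outcome_label=labels[2],
        beta_a=beta_a, se_a=se_a, pval_a=pval_a,
        beta_b=beta_b, se_b=se_b, pval_b=pval_b,
        beta_c=beta_c, se_c=se_c, pval_c=pval_c,
        method=method, indirect=float(indirect),
        proportion=float(proportion), mediates=bool(mediates),
        beta_c_prime=beta_c_prime, se_c_prime=se_c_prime, pval_c_prime=pcp,
        sobel_se=sob.sobel_se, sobel_z=sob.z, sobel_pval=sob.pval,
    )


@dataclass
class MediationSettings:
    """Knobs shared by the three univariable legs and the joint model."""

    clump: ClumpConfig = field(default_factory=ClumpConfig)
    ld: PairwiseLD | None = None
    blocklist: frozenset = frozenset()
    drop_palindromes: bool = True
    effects_model: str = "random_multiplicative"
    alpha: float = ALPHA


def _univariable_leg(
    exposure: SummaryStats,
    outcome: SummaryStats,
    s: MediationSettings,
) -> tuple[float, float, float, int]:
    """One instrument-selection → harmonization → IVW leg; returns
    (beta, se, pval, n_snp)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iv = select_instruments(exposure, s.clump, s.ld, s.blocklist)
    h = harmonize(iv, outcome, drop_palindromes=s.drop_palindromes)
    est, _ = ivw(h, effects_model=s.effects_model)
    return est.beta, est.se, est.pval, est.n_snp


def mediate(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    full_data_available: bool = True,
    settings: MediationSettings | None = None,
) -> MediationResult:
    """Full mediation analysis from three traits' summary statistics.

    Estimates β_A (exposure→mediator), β_B (mediator→outcome) and β_C
    (exposure→outcome) by univariable IVW. With ``full_data_available`` the
    joint multivariable model supplies β_C′ and the difference method decides;
    otherwise the Sobel test and product method are used. Errors from a
    failed leg propagate — callers orchestrating many pairs catch
    :class:`~mrmediation.errors.MRError` and mark the pair not estimable.
    """
    s = settings or MediationSettings()
    beta_a, se_a, pval_a, _ = _univariable_leg(exposure, mediator, s)
    beta_b, se_b, pval_b, _ = _univariable_leg(mediator, outcome, s)
    beta_c, se_c, pval_c, _ = _univariable_leg(exposure, outcome, s)

    labels = (exposure.trait_label or "exposure",
              mediator.trait_label or "mediator",
              outcome.trait_label or "outcome")
    if full_data_available:
        mv = build_mvmr_set(exposure, mediator, outcome, clump=s.clump,
                            ld=s.ld, blocklist=s.blocklist,
                            drop_palindromes=s.drop_palindromes)
        est = mvmr_ivw(mv)
        bcp, scp, pcp = est.betas[0], est.ses[0], est.pvals[0]
        return mediation_from_coefficients(
            beta_a, se_a, beta_b, se_b, beta_c, se_c,
            pval_a=pval_a, pval_b=pval_b, pval_c=pval_c,
            beta_c_prime=float(bcp), se_c_prime=float(scp),
            pval_c_prime=float(pcp),
            alpha=s.alpha, labels=labels,
        )
    return mediation_from_coefficients(
        beta_a, se_a, beta_b, se_b, beta_c, se_c,
        pval_a=pval_a, pval_b=pval_b, pval_c=pval_c,
        alpha=s.alpha, labels=labels,
    )
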