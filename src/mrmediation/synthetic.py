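"""Synthetic GWAS summary statistics with a known causal structure.

The generator works at the summary level: rather than simulating individual
genotypes, each SNP's estimated effect is drawn around its true value with the
sampling SD implied by the study size, se ≈ 1/sqrt(n·2f(1−f)) for an allele
frequency f. This exercises every estimator in the package at desk scale.

The causal structure is the mediation triangle: per-SNP effects γ_j on the
exposure; the mediator responds via the a-path; the outcome receives the
direct effect plus the mediated path plus (optionally) per-SNP horizontal
pleiotropy α_j, so its true per-SNP effect is θ_total·γ_j + α_j with
θ_total = θ_direct + a·b. Optional features:

* **balanced / directional pleiotropy** — α_j ~ N(0, sd) or N(mean, sd);
* **planted outliers** — selected SNPs get their outcome effect inflated to a
  multiple of the fitted value;
* **mediator-specific instruments** — extra SNPs with γ = 0 and their own
  mediator effects δ_j, so the mediator has instruments of its own (needed
  for the β_B leg and multivariable MR);
* **sample overlap** — exposure and outcome sampling errors are drawn with
  correlation equal to the overlap fraction (a summary-level shortcut for
  shared participants);
* **weak instruments** — scale the γ distribution down.

Everything is deterministic given the seed stored in the truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .gwas_io import SnpRecord, SummaryStats

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of one simulated dataset.

    The composition identity theta_total = theta_direct + a_path·b_path holds
    by construction and is validated here.
    """

    n_snp: int
    gamma: tuple  # true per-SNP exposure effects (length n_snp)
    theta_total: float
    theta_direct: float
    a_path: float
    b_path: float
    pleiotropy_mode: str  # "none" | "balanced" | "directional"
    alpha: tuple  # true per-SNP pleiotropic effects on the outcome
    outlier_idx: tuple
    n_exp: int
    n_out: int
    n_med: int
    overlap_frac: float
    seed: int
    delta: tuple = ()  # mediator-specific per-SNP effects (0 where absent)

    def __post_init__(self) -> None:
        if abs(self.theta_total - (self.theta_direct + self.a_path * self.b_path)) > 1e-12:
            raise ConfigurationError(
                "theta_total must equal theta_direct + a_path*b_path"
            )
        if not (0.0 <= self.overlap_frac <= 1.0):
            raise ConfigurationError("overlap_frac must be in [0, 1]")
        if min(self.n_exp, self.n_out, self.n_med) < 1:
            raise ConfigurationError("all sample sizes must be at least 1")
        if len(self.gamma) != self.n_snp or len(self.alpha) != self.n_snp:
            raise ConfigurationError("gamma and alpha must have length n_snp")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode: {self.pleiotropy_mode!r}")

    def to_dict(self) -> dict:
        d = {
            "n_snp": self.n_snp,
            "theta_total": self.theta_total,
            "theta_direct": self.theta_direct,
            "a_path": self.a_path,
            "b_path": self.b_path,
            "pleiotropy_mode": self.pleiotropy_mode,
            "outlier_idx": list(self.outlier_idx),
            "n_exp": self.n_exp, "n_out": self.n_out, "n_med": self.n_med,
            "overlap_frac": self.overlap_frac,
            "seed": self.seed,
            "gamma": list(self.gamma),
            "alpha": list(self.alpha),
            "delta": list(self.delta),
        }
        return d


@dataclass
class SyntheticDataset:
    """Three studies' summary statistics plus the truth that generated them."""

    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    truth: SyntheticTruth


def make_truth(
    n_snp: int = 50,
    theta_direct: float = 0.5,
    a_path: float = 0.0,
    b_path: float = 0.0,
    pleiotropy_mode: str = "none",
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    n_outliers: int = 0,
    outlier_multiplier: float = 10.0,
    n_snp_mediator: int = 0,
    instrument_strength: float = 1.0,
    n_exp: int = 200_000,
    n_out: int = 300_000,
    n_med: int = 150_000,
    overlap_frac: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a ground truth for one simulation scenario.

    True exposure effects |γ_j| are uniform on [0.03, 0.10] with random sign,
    scaled by ``instrument_strength`` (1.0 gives uniformly strong instruments
    at the default study sizes; ~0.3 makes a sizeable fraction weak). The
    first ``n_snp`` SNPs instrument the exposure; a further
    ``n_snp_mediator`` SNPs carry mediator-specific effects δ_j from the same
    distribution and no exposure effect. Outliers are chosen among the
    exposure instruments and receive pleiotropy that inflates their outcome
    effect to ``outlier_multiplier`` times the fitted value.
    """
    if n_outliers > n_snp:
        raise ConfigurationError("more outliers than exposure instruments")
    rng = np.random.default_rng(seed)
    j_total = n_snp + n_snp_mediator
    theta_total = theta_direct + a_path * b_path

    mag = rng.uniform(0.03, 0.10, size=j_total) * instrument_strength
    sign = rng.choice([-1.0, 1.0], size=j_total)
    gamma = mag * sign
    gamma[n_snp:] = 0.0
    delta = np.zeros(j_total)
    if n_snp_mediator:
        dmag = rng.uniform(0.03, 0.10, size=n_snp_mediator)
        dsign = rng.choice([-1.0, 1.0], size=n_snp_mediator)
        delta[n_snp:] = dmag * dsign

    if pleiotropy_mode == "none":
        alpha = np.zeros(j_total)
    elif pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, pleiotropy_sd, size=j_total)
    else:
        # Directional pleiotropy is defined relative to the exposure-increasing
        # allele (the orientation MR-Egger uses), so alpha follows gamma's sign.
        alpha = np.where(gamma >= 0, 1.0, -1.0) * rng.normal(
            pleiotropy_mean, pleiotropy_sd, size=j_total
        )

    if n_outliers:
        outlier_idx = tuple(
            int(i) for i in rng.choice(n_snp, size=n_outliers, replace=False)
        )
        for i in outlier_idx:
            # outcome effect becomes multiplier × the model-implied value
            alpha[i] += (outlier_multiplier - 1.0) * theta_total * gamma[i]
    else:
        outlier_idx = ()

    return SyntheticTruth(
        n_snp=j_total,
        gamma=tuple(gamma),
        theta_total=theta_total,
        theta_direct=theta_direct,
        a_path=a_path,
        b_path=b_path,
        pleiotropy_mode=pleiotropy_mode,
        alpha=tuple(alpha),
        outlier_idx=outlier_idx,
        n_exp=n_exp, n_out=n_out, n_med=n_med,
        overlap_frac=overlap_frac,
        seed=int(seed),
        delta=tuple(delta),
    )


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * sps.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_summary_stats(
    truth: SyntheticTruth,
    palindrome_rate: float = 0.0,
    noise_scale: float = 1.0,
) -> SyntheticDataset:
    """Emit exposure, mediator and outcome summary statistics for a truth.

    Allele frequencies are Uniform(0.05, 0.95); reported SEs follow the
    1/sqrt(n·2f(1−f)) formula for each study's sample size. ``noise_scale``
    multiplies the sampling noise actually added (0 gives estimates exactly at
    their true values while keeping the reported SEs positive, isolating the
    estimators' algebra from sampling error). ``palindrome_rate`` controls the
    fraction of A/T–C/G allele pairs, to exercise harmonization. SNPs are
    placed far apart on one chromosome so physical clump windows never
    overlap. Deterministic given ``truth.seed``.
    """
    if not (0.0 <= palindrome_rate <= 1.0):
        raise ConfigurationError("palindrome_rate must be in [0, 1]")
    if noise_scale < 0:
        raise ConfigurationError("noise_scale must be non-negative")
    j = truth.n_snp
    rng = np.random.default_rng(truth.seed)
    f = rng.uniform(0.05, 0.95, size=j)
    het = 2.0 * f * (1.0 - f)
    se_x = 1.0 / np.sqrt(truth.n_exp * het)
    se_m = 1.0 / np.sqrt(truth.n_med * het)
    se_y = 1.0 / np.sqrt(truth.n_out * het)

    gamma = np.asarray(truth.gamma)
    delta = np.asarray(truth.delta) if truth.delta else np.zeros(j)
    alpha = np.asarray(truth.alpha)
    mu_x = gamma
    mu_m = truth.a_path * gamma + delta
    mu_y = truth.theta_direct * gamma + truth.b_path * mu_m + alpha

    rho = truth.overlap_frac
    z1 = rng.standard_normal(j)
    z2 = rng.standard_normal(j)
    z3 = rng.standard_normal(j)
    e_x = se_x * z1
    e_y = se_y * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)  # shared participants
    e_m = se_m * z3

    bx = mu_x + noise_scale * e_x
    bm = mu_m + noise_scale * e_m
    by = mu_y + noise_scale * e_y

    is_pal = rng.random(j) < palindrome_rate
    pair_idx = rng.integers(0, 8, size=j)
    pal_idx = rng.integers(0, 4, size=j)
    alleles = [
        _PALINDROMIC_PAIRS[pal_idx[k]] if is_pal[k]
        else _NONPALINDROMIC_PAIRS[pair_idx[k]]
        for k in range(j)
    ]
    snp_ids = [f"rs{1_000_001 + k}" for k in range(j)]
    positions = [21_000_000 * (k + 1) for k in range(j)]  # > clump window apart

    def _stats(beta, se, n, label):
        p = _pvals(beta, se)
        recs = [
            SnpRecord(
                snp_id=snp_ids[k], chrom="1", pos=positions[k],
                effect_allele=alleles[k][0], other_allele=alleles[k][1],
                beta=float(beta[k]), se=float(se[k]), pval=float(p[k]),
                eaf=float(f[k]), n=n,
            )
            for k in range(j)
        ]
        return SummaryStats(recs, trait_label=label, n_total=n)

    return SyntheticDataset(
        exposure=_stats(bx, se_x, truth.n_exp, "exposure"),
        mediator=_stats(bm, se_m, truth.n_med, "mediator"),
        outcome=_stats(by, se_y, truth.n_out, "outcome"),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Sample-overlap bias / type-I error experiment
# ---------------------------------------------------------------------------

def overlap_bias_experiment(
    overlap_fracs,
    n_rep: int = 200,
    seed: int = 0,
    n_snp: int = 50,
    theta_alt: float = 0.3,
    instrument_strength: float = 1.0,
    n_exp: int = 200_000,
    n_out: int = 300_000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical bias and type-I error of IVW across sample-overlap fractions.

    For every overlap fraction (the grid must include 0, the no-overlap
    reference) and for θ_total ∈ {0, ``theta_alt``}, ``n_rep`` datasets are
    simulated on a shared seed ladder (paired across fractions), the IVW
    estimate computed on the instruments passing genome-wide significance,
    and the rejection of H0: θ = 0 recorded at the nominal level. Returns a
    tidy frame with columns overlap_frac, theta_total, bias, mean_estimate,
    rejection_rate, n_rep.
    """
    import warnings

    from .estimators import ivw as _ivw
    from .gwas_io import ClumpConfig, harmonize, select_instruments

    fracs = [float(x) for x in overlap_fracs]
    if 0.0 not in fracs:
        raise ConfigurationError("overlap grid must include 0 (the reference)")
    if n_rep < 100:
        raise ConfigurationError("n_rep must be at least 100")

    clump = ClumpConfig()
    rows = []
    for frac in fracs:
        for theta in (0.0, theta_alt):
            estimates, rejected = [], 0
            used = 0
            for r in range(n_rep):
                truth = make_truth(
                    n_snp=n_snp, theta_direct=theta,
                    instrument_strength=instrument_strength,
                    n_exp=n_exp, n_out=n_out,
                    overlap_frac=frac, seed=seed + r,  # paired ladder
                )
                ds = simulate_summary_stats(truth)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        iv = select_instruments(ds.exposure, clump)
                    h = harmonize(iv, ds.outcome)
                    est, _ = _ivw(h)
                except Exception:
                    continue
                used += 1
                estimates.append(est.beta)
                if est.pval < alpha:
                    rejected += 1
            est_arr = np.asarray(estimates)
            rows.append(
                {
                    "overlap_frac": frac,
                    "theta_total": theta,
                    "bias": float(np.mean(est_arr) - theta) if used else np.nan,
                    "mean_estimate": float(np.mean(est_arr)) if used else np.nan,
                    "rejection_rate": rejected / used if used else np.nan,
                    "n_rep": used,
                }
            )
    return pd.DataFrame(rows)
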