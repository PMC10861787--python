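"""MR-PRESSO: global heterogeneity test, per-SNP outlier test, distortion test.

The global test asks whether the observed residual sum of squares (RSS) around
the IVW fit is larger than expected under a pleiotropy-free null. For each SNP
j the leave-one-out IVW slope β_(−j) gives a fitted outcome effect
β_(−j)·bx_j, and RSS_j = w_j·(by_j − β_(−j)·bx_j)² with w_j = 1/sy_j². The
null distribution is built by parametric simulation: by_j* ~ N(β_(−j)·bx_j,
sy_j) and bx_j* ~ N(bx_j, sx_j), with the whole RSS computation (including
leave-one-out slopes) recomputed on each simulated dataset.

Per-SNP outliers are SNPs whose observed RSS_j falls in the extreme tail of
its own simulated distribution (empirical p, Bonferroni-adjusted by the number
of instruments). The distortion test compares the raw-vs-corrected slope shift
against removals of random subsets of the same size.

Empirical p-values use add-one smoothing, (1 + #{sim ≥ obs})/(n_sim + 1), so
they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import MREstimate, ivw
from .gwas_io import HarmonizedSet


@dataclass(frozen=True)
class PressoResult:
    """Outcome of the MR-PRESSO procedure on one harmonized set."""

    global_rss: float
    global_pval: float
    outlier_snps: list  # [(snp_id, bonferroni-adjusted outlier p), ...]
    distortion_pval: float | None
    estimate_raw: MREstimate
    estimate_corrected: MREstimate
    rss_per_snp: dict = field(default_factory=dict)
    outlier_pvals: dict = field(default_factory=dict)  # adjusted p for every SNP
    n_sim: int = 0
    seed: int = 0

    @property
    def has_outliers(self) -> bool:
        return len(self.outlier_snps) > 0


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes, vectorized over trailing SNP axis.

    The IVW slope is Σ w·bx·by / Σ w·bx²; removing SNP j subtracts its
    contribution from both sums. Works on 1-D observed data or on an
    (n_sim, J) matrix of simulated datasets.
    """
    num = w * bx * by
    den = w * bx**2
    s1 = num.sum(axis=-1, keepdims=True)
    s2 = den.sum(axis=-1, keepdims=True)
    return (s1 - num) / (s2 - den)


def _rss_components(bx, by, w):
    beta_loo = _loo_slopes(bx, by, w)
    return w * (by - beta_loo * bx) ** 2


def presso_test(
    h: HarmonizedSet,
    n_sim: int = 10_000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
    effects_model: str = "random_multiplicative",
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Requires at least 4 instruments (with fewer, the leave-one-out residual
    has no information to spare; callers should report "not applicable" and
    pass the data through). ``n_sim`` ≥ 1000 keeps the empirical p resolution
    meaningful after the Bonferroni adjustment. The result is bit-reproducible
    for a fixed ``seed``.

    ``estimate_corrected`` is the IVW estimate on the input minus the flagged
    outliers (identical to ``estimate_raw`` when none are flagged).
    """
    j = len(h)
    if j < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs ≥ 4 instruments, got {j}"
        )
    if n_sim < 1000:
        raise ConfigurationError("n_sim must be at least 1000")

    bx, by, sy, sx = h.bx, h.by, h.sy, h.sx
    w = 1.0 / sy**2
    rss_j = _rss_components(bx, by, w)
    rss_obs = float(rss_j.sum())

    # Parametric null: outcome effects centered on the leave-one-out fit.
    rng = np.random.default_rng(seed)
    beta_loo = _loo_slopes(bx, by, w).ravel()
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(beta_loo * bx, sy, size=(n_sim, j))
    rss_star = _rss_components(bx_star, by_star, w)  # (n_sim, J)
    global_star = rss_star.sum(axis=1)

    global_pval = float((1 + np.sum(global_star >= rss_obs)) / (n_sim + 1))

    # Per-SNP outlier test against each SNP's own simulated RSS distribution.
    tail = (1 + np.sum(rss_star >= rss_j, axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, tail * j)  # Bonferroni by number of instruments
    flagged = adj < outlier_alpha
    outliers = [(h.snp_ids[k], float(adj[k])) for k in np.flatnonzero(flagged)]

    est_raw, _ = ivw(h, effects_model=effects_model)
    if flagged.any():
        keep = ~flagged
        if keep.sum() < 2:
            raise InsufficientInstrumentsError(
                "outlier removal would leave fewer than 2 instruments; "
                "the heterogeneity is global, not attributable to single SNPs"
            )
        est_corr, _ = ivw(h.subset(keep), effects_model=effects_model)
        distortion_pval = _distortion_test(
            bx, by, w, int(flagged.sum()), flagged, rng, n_sim
        )
    else:
        est_corr = est_raw
        distortion_pval = None

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_snps=outliers,
        distortion_pval=distortion_pval,
        estimate_raw=est_raw,
        estimate_corrected=est_corr,
        rss_per_snp=dict(zip(h.snp_ids, rss_j.tolist())),
        outlier_pvals=dict(zip(h.snp_ids, adj.tolist())),
        n_sim=n_sim,
        seed=seed,
    )


def _distortion_test(bx, by, w, m, flagged, rng, n_draw):
    """Compare the outlier-driven slope shift against random same-size removals.

    The observed shift is slope(all) − slope(without flagged outliers); the
    null removes m random SNPs each draw. Two-sided empirical p with add-one
    smoothing.
    """
    j = len(bx)
    num = w * bx * by
    den = w * bx**2
    s1, s2 = num.sum(), den.sum()
    slope_all = s1 / s2
    slope_corr = (s1 - num[flagged].sum()) / (s2 - den[flagged].sum())
    d_obs = slope_all - slope_corr

    # Random subsets of the same size (vectorized via argsort of uniforms).
    u = rng.random((n_draw, j))
    idx = np.argpartition(u, m - 1, axis=1)[:, :m]
    s1_sub = s1 - np.take(num, idx).sum(axis=1)
    s2_sub = s2 - np.take(den, idx).sum(axis=1)
    d_null = slope_all - s1_sub / s2_sub
    return float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_draw + 1))


def presso_report_frame(result: PressoResult, h: HarmonizedSet):
    """Per-SNP outlier report: snp, rss, outlier flag (tidy TSV layout)."""
    import pandas as pd

    flagged_ids = {s for s, _ in result.outlier_snps}
    return pd.DataFrame(
        {
            "snp": h.snp_ids,
            "rss": [result.rss_per_snp[s] for s in h.snp_ids],
            "outlier_pval": [result.outlier_pvals.get(s, np.nan) for s in h.snp_ids],
            "flagged": [s in flagged_ids for s in h.snp_ids],
        }
    )
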