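"""Four-step MR mediation pipeline with reproducible reports.

Step 1: each exposure → outcome (instrument selection, harmonization,
MR-PRESSO outlier removal, IVW / MR-Egger / weighted-median estimates with
heterogeneity and pleiotropy diagnostics).
Step 2: each candidate mediator → outcome (β_B screening).
Step 3: each exposure → each surviving mediator (β_A screening).
Step 4: mediation analysis for every triple whose β_A, β_B and β_C are all
significant, via the multivariable-MR difference method when full data are
available and the Sobel product method otherwise.

A failed leg degrades to a "not estimable" row rather than aborting the run.
Reports are plain TSV plus a JSON summary embedding the config hash and all
seeds, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MRError
from .estimators import egger, ivw, weighted_median
from .gwas_io import (
    ClumpConfig,
    PairwiseLD,
    SummaryStats,
    harmonize,
    read_blocklist,
    read_summary_stats,
    select_instruments,
)
from .mvmr_mediation import MediationResult, MediationSettings, mediate
from .presso import presso_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    ``exposures`` and ``mediators`` map trait labels to summary-statistics
    file paths; all estimator seeds live here so every report can embed them.
    """

    exposures: dict[str, str] = field(default_factory=dict)
    mediators: dict[str, str] = field(default_factory=dict)
    outcome: str = ""
    outcome_label: str = "outcome"
    blocklist: str | None = None
    ld: str | None = None
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    clump_p: float = 5e-8
    effects_model: str = "random_multiplicative"
    alpha: float = 0.05
    n_boot: int = 5000
    wm_seed: int = 0
    presso_n_sim: int = 10_000
    presso_seed: int = 0
    full_data_available: bool = True
    drop_palindromes: bool = True
    out_dir: str = "mr_out"

    @property
    def clump(self) -> ClumpConfig:
        return ClumpConfig(self.clump_r2, self.clump_window_kb, self.clump_p)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in every report."""
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file.

    Exposure and mediator entries use ``exposure.<label> = <path>`` and
    ``mediator.<label> = <path>``. Blank lines and ``#`` comments are
    ignored. Referenced paths must exist.
    """
    cfg = PipelineConfig()
    base = Path(path).parent
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected key = value")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("exposure."):
            cfg.exposures[key.split(".", 1)[1]] = str(base / value)
        elif key.startswith("mediator."):
            cfg.mediators[key.split(".", 1)[1]] = str(base / value)
        elif key in ("outcome", "blocklist", "ld"):
            setattr(cfg, key, str(base / value))
        elif key in ("clump_r2", "clump_window_kb", "clump_p", "alpha"):
            setattr(cfg, key, float(value))
        elif key in ("n_boot", "wm_seed", "presso_n_sim", "presso_seed"):
            setattr(cfg, key, int(value))
        elif key in ("full_data_available", "drop_palindromes"):
            setattr(cfg, key, _BOOL[value.lower()])
        elif key in ("effects_model", "out_dir", "outcome_label"):
            setattr(cfg, key, value)
        else:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
    for p in [*cfg.exposures.values(), *cfg.mediators.values(), cfg.outcome,
              cfg.blocklist, cfg.ld]:
        if p and not Path(p).exists():
            raise ConfigurationError(f"referenced path does not exist: {p}")
    return cfg


def _load_inputs(cfg: PipelineConfig):
    exposures = {
        label: read_summary_stats(path, trait_label=label)[0]
        for label, path in cfg.exposures.items()
    }
    mediators = {
        label: read_summary_stats(path, trait_label=label)[0]
        for label, path in cfg.mediators.items()
    }
    outcome = read_summary_stats(cfg.outcome, trait_label=cfg.outcome_label)[0]
    blocklist = read_blocklist(cfg.blocklist) if cfg.blocklist else frozenset()
    ld = PairwiseLD.read(cfg.ld) if cfg.ld else None
    return exposures, mediators, outcome, blocklist, ld


# ---------------------------------------------------------------------------
# Step 1
# ---------------------------------------------------------------------------

def step1_for_exposure(
    exposure: SummaryStats,
    outcome: SummaryStats,
    cfg: PipelineConfig,
    blocklist: frozenset = frozenset(),
    ld: PairwiseLD | None = None,
) -> tuple[list[dict], dict]:
    """One exposure's full Step-1 analysis; returns (method rows, run notes)."""
    label = exposure.trait_label
    notes: dict = {"exposure": label, "presso": "not run"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iv = select_instruments(exposure, cfg.clump, ld, blocklist)
    notes["instruments"] = iv.snp_ids
    h = harmonize(iv, outcome, drop_palindromes=cfg.drop_palindromes)
    notes["dropped"] = h.dropped

    if len(h) >= 4 and cfg.presso_n_sim >= 1000:
        pres = presso_test(h, n_sim=cfg.presso_n_sim, seed=cfg.presso_seed,
                           effects_model=cfg.effects_model)
        notes["presso"] = {
            "global_pval": pres.global_pval,
            "outliers": [s for s, _ in pres.outlier_snps],
            "distortion_pval": pres.distortion_pval,
        }
        if pres.has_outliers:
            flagged = {s for s, _ in pres.outlier_snps}
            h = h.subset(np.array([s not in flagged for s in h.snp_ids]))
            logger.info("%s: removed %d MR-PRESSO outlier(s)", label, len(flagged))
    else:
        notes["presso"] = "not applicable (< 4 instruments)"

    rows: list[dict] = []

    def _row(est, qt):
        rows.append({
            "exposure": label, "outcome": outcome.trait_label,
            "method": est.method, "nsnp": est.n_snp,
            "beta": est.beta, "se": est.se,
            "or": est.or_value, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pval": est.pval,
            "q": qt.q if qt else np.nan, "q_df": qt.df if qt else np.nan,
            "q_pval": qt.pval if qt else np.nan,
            "egger_intercept": est.intercept,
            "egger_intercept_pval": est.intercept_pval,
            "note": "",
        })

    est, qt = ivw(h, effects_model="fixed")
    _row(est, qt)
    if len(h) >= 2:
        est, qt = ivw(h, effects_model="random_multiplicative")
        _row(est, qt)
    if len(h) >= 3:
        est, qt = egger(h)
        _row(est, qt)
        _row(weighted_median(h, n_boot=cfg.n_boot, seed=cfg.wm_seed), None)
    return rows, notes


def run_step1(cfg: PipelineConfig, inputs=None) -> tuple[pd.DataFrame, dict]:
    """Step 1 for every exposure; failed exposures degrade to a stub row."""
    if inputs is None:
        exposures, _, outcome, blocklist, ld = _load_inputs(cfg)
    else:
        exposures, outcome, blocklist, ld = inputs
    all_rows: list[dict] = []
    run_notes: dict = {}
    for label, stats in exposures.items():
        logger.info("Step 1: %s -> %s", label, outcome.trait_label)
        try:
            rows, notes = step1_for_exposure(stats, outcome, cfg, blocklist, ld)
            all_rows.extend(rows)
            run_notes[label] = notes
        except MRError as exc:
            logger.warning("%s: not estimable (%s)", label, exc)
            all_rows.append({
                "exposure": label, "outcome": outcome.trait_label,
                "method": "not_estimable", "nsnp": 0,
                "note": f"not estimable: {exc}",
            })
            run_notes[label] = {"error": str(exc)}
    return pd.DataFrame(all_rows), run_notes


# ---------------------------------------------------------------------------
# Steps 2-4
# ---------------------------------------------------------------------------

def run_steps2_to_4(cfg: PipelineConfig, inputs=None) -> tuple[pd.DataFrame, dict]:
    """Mediator screening and mediation analysis.

    Returns the mediation table (one row per exposure/mediator pair reaching
    Step 4) and run notes recording the screening decisions.
    """
    if inputs is None:
        exposures, mediators, outcome, blocklist, ld = _load_inputs(cfg)
    else:
        exposures, mediators, outcome, blocklist, ld = inputs
    settings = MediationSettings(
        clump=cfg.clump, ld=ld, blocklist=blocklist,
        drop_palindromes=cfg.drop_palindromes,
        effects_model=cfg.effects_model, alpha=cfg.alpha,
    )
    notes: dict = {"step2": {}, "step3": {}, "step4": {}}

    def _leg(exp, out):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iv = select_instruments(exp, cfg.clump, ld, blocklist)
        h = harmonize(iv, out, drop_palindromes=cfg.drop_palindromes)
        est, _ = ivw(h, effects_model=cfg.effects_model)
        return est

    # Step 2: mediator -> outcome (beta_B)
    surviving: dict[str, object] = {}
    for label, stats in mediators.items():
        try:
            est = _leg(stats, outcome)
            notes["step2"][label] = {"beta_b": est.beta, "pval": est.pval}
            if est.pval < cfg.alpha:
                surviving[label] = stats
        except MRError as exc:
            notes["step2"][label] = {"error": str(exc)}
    logger.info("Step 2: %d/%d mediators associated with the outcome",
                len(surviving), len(mediators))

    # Step 3: exposure -> surviving mediators (beta_A); Step 4: mediation.
    rows: list[dict] = []
    for elabel, estats in exposures.items():
        try:
            est_c = _leg(estats, outcome)
        except MRError as exc:
            notes["step3"][elabel] = {"error": str(exc)}
            continue
        for mlabel, mstats in surviving.items():
            key = f"{elabel}->{mlabel}"
            try:
                est_a = _leg(estats, mstats)
            except MRError as exc:
                notes["step3"][key] = {"error": str(exc)}
                continue
            notes["step3"][key] = {"beta_a": est_a.beta, "pval": est_a.pval}
            if est_a.pval >= cfg.alpha or est_c.pval >= cfg.alpha:
                continue  # Step-4 entry requires significant beta_A and beta_C
            logger.info("Step 4: mediation %s -> %s -> %s",
                        elabel, mlabel, outcome.trait_label)
            try:
                res = mediate(
                    estats, mstats, outcome,
                    full_data_available=cfg.full_data_available,
                    settings=settings,
                )
                rows.append(_mediation_row(res))
                notes["step4"][key] = "ok"
            except MRError as exc:
                notes["step4"][key] = f"not estimable: {exc}"
                rows.append({
                    "exposure": elabel, "mediator": mlabel,
                    "method": "NA", "mediates": False,
                    "note": f"not estimable: {exc}",
                })
    if not rows:
        logger.info("Step 4: no exposure/mediator triple qualified for mediation")
    return pd.DataFrame(rows), notes


def _mediation_row(res: MediationResult) -> dict:
    return {
        "exposure": res.exposure_label,
        "mediator": res.mediator_label,
        "beta_a": res.beta_a, "s_a": res.se_a,
        "beta_b": res.beta_b, "s_b": res.se_b,
        "beta_c": res.beta_c,
        "beta_c_prime": res.beta_c_prime,
        "sobel_pval": res.sobel_pval,
        "proportion_pct": res.proportion_pct,
        "method": res.method,
        "mediates": res.mediates,
        "note": "proportion outside [0,1]" if res.proportion_out_of_range else "",
    }


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run Steps 1-4, writing TSV reports and a JSON summary to ``out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exposures, mediators, outcome, blocklist, ld = _load_inputs(cfg)

    step1_df, step1_notes = run_step1(cfg, (exposures, outcome, blocklist, ld))
    step1_df.to_csv(out / "step1_mr.tsv", sep="\t", index=False)

    mediation_df, screen_notes = run_steps2_to_4(
        cfg, (exposures, mediators, outcome, blocklist, ld)
    )
    mediation_df.to_csv(out / "mediation.tsv", sep="\t", index=False)

    summary = {
        "config_hash": cfg.digest(),
        "seeds": {"weighted_median": cfg.wm_seed, "presso": cfg.presso_seed},
        "alpha": cfg.alpha,
        "clump": {"r2": cfg.clump_r2, "window_kb": cfg.clump_window_kb,
                  "p": cfg.clump_p},
        "step1": step1_notes,
        "screening": screen_notes,
        "n_mediation_rows": int(len(mediation_df)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True, default=str))
    return summary
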