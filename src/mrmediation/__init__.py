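"""Two-sample Mendelian randomization with mediation analysis.

Estimators (IVW, MR-Egger, weighted median), diagnostics (Cochran's/Rücker's
Q, the Egger pleiotropy intercept, MR-PRESSO), multivariable MR, and the
exposure → mediator → outcome mediation layer (difference and Sobel product
methods), operating on GWAS summary statistics in delimited text.
"""

from importlib import resources

import pandas as pd

from .errors import (
    CollinearityError,
    ConfigurationError,
    DegenerateInstrumentError,
    EmptyHarmonizationError,
    EmptyInputError,
    EmptyInstrumentError,
    FormatError,
    InsufficientInstrumentsError,
    MRError,
    UndefinedProportionError,
)
from .estimators import (
    MREstimate,
    QTestResult,
    egger,
    ivw,
    mr_all,
    wald_ratio,
    weighted_median,
)
from .gwas_io import (
    ClumpConfig,
    HarmonizedSet,
    PairwiseLD,
    ParseReport,
    SnpRecord,
    SummaryStats,
    harmonize,
    read_blocklist,
    read_summary_stats,
    select_instruments,
    write_summary_stats,
)
from .mvmr_mediation import (
    MediationResult,
    MediationSettings,
    MVMREstimate,
    MVMRSet,
    build_mvmr_set,
    mediate,
    mediation_from_coefficients,
    mvmr_ivw,
    proportion_mediated,
    sobel_test,
)
from .pipeline import (
    PipelineConfig,
    load_config,
    run_pipeline,
    run_step1,
    run_steps2_to_4,
)
from .presso import PressoResult, presso_test
from .synthetic import (
    SyntheticDataset,
    SyntheticTruth,
    make_truth,
    overlap_bias_experiment,
    simulate_summary_stats,
)

__version__ = "0.1.0"


def load_published_coefficients() -> pd.DataFrame:
    """The packaged table of published mediation coefficients.

    One row per exposure/mediator pair: β_A, S_A, β_B, S_B, β_C (and, where
    printed, the Sobel p-value and mediated proportion), for regression
    tests of the coefficient-level mediation path.
    """
    ref = resources.files(__package__) / "data" / "table2_coefficients.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])
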