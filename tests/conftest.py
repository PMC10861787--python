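import warnings

import numpy as np
import pytest

from mrmediation import SnpRecord, SummaryStats, HarmonizedSet


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                beta=0.1, se=0.01, pval=1e-9, eaf=None, n=None):
    return SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                     other_allele=oa, beta=beta, se=se, pval=pval, eaf=eaf, n=n)


def make_stats(rows, label="trait"):
    """Build SummaryStats from dicts of make_record keyword overrides."""
    return SummaryStats([make_record(**r) for r in rows], trait_label=label)


@pytest.fixture
def simple_harmonized():
    """Five strong instruments on an exact causal line with slope 0.5."""
    bx = np.array([0.05, 0.08, 0.10, 0.06, 0.12])
    sy = np.array([0.01, 0.012, 0.008, 0.015, 0.011])
    return HarmonizedSet(
        snp_ids=[f"rs{i}" for i in range(5)],
        bx=bx, sx=np.full(5, 0.005),
        by=0.5 * bx, sy=sy,
    )


@pytest.fixture(autouse=True)
def _silence_ld_warning():
    """select_instruments warns when no LD table is given; tests opt in."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
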