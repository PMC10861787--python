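"""Reading, instrument selection, clumping and harmonization."""

import itertools
import warnings

import numpy as np
import pytest

from mrmediation import (
    ClumpConfig,
    EmptyHarmonizationError,
    EmptyInputError,
    EmptyInstrumentError,
    FormatError,
    PairwiseLD,
    SummaryStats,
    harmonize,
    read_summary_stats,
    select_instruments,
)
from mrmediation.errors import ConfigurationError

from conftest import make_record, make_stats

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, rows, header=HEADER, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(header + "".join(rows))
    return path


def _row(snp="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
         beta=0.1, se=0.01, p=1e-9, n=10000):
    return f"{snp}\t{chrom}\t{pos}\t{ea}\t{oa}\t{eaf}\t{beta}\t{se}\t{p}\t{n}\n"


class TestReader:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        path = _write(tmp_path, [_row(snp=f"rs{i}", pos=1000 * i) for i in (1, 2, 3)])
        stats, report = read_summary_stats(path)
        assert len(stats) == 3
        assert report.n_read == 3 and report.n_kept == 3 and not report.rejections
        rec = stats.get("rs2")
        assert rec.beta == 0.1 and rec.se == 0.01 and rec.eaf == 0.3

    def test_zero_se_row_dropped_and_reported(self, tmp_path):
        path = _write(tmp_path, [_row(snp="rs1"), _row(snp="rs2", se=0.0)])
        stats, report = read_summary_stats(path)
        assert stats.snp_ids == ["rs1"]
        assert report.rejections == [("rs2", "nonpositive_se")]

    def test_duplicate_rsid_keeps_first(self, tmp_path):
        path = _write(tmp_path, [_row(snp="rs1", beta=0.1), _row(snp="rs1", beta=0.9)])
        stats, report = read_summary_stats(path)
        assert stats.get("rs1").beta == 0.1
        assert report.rejections == [("rs1", "duplicate")]

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tBETA\nrs1\t0.1\n")
        with pytest.raises(FormatError):
            read_summary_stats(path)

    def test_empty_file_is_empty_input_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(EmptyInputError):
            read_summary_stats(path)
        path.write_text(HEADER)  # header only
        with pytest.raises(EmptyInputError):
            read_summary_stats(path)

    def test_comma_delimited_and_column_map(self, tmp_path):
        path = tmp_path / "stats.csv"
        path.write_text(
            "rsid,chrom,bp,a1,a2,freq,b,stderr,pv\n"
            "rs1,2,500,T,C,0.4,0.2,0.05,1e-10\n"
        )
        stats, _ = read_summary_stats(path, column_map={
            "snp_id": "rsid", "chrom": "chrom", "pos": "bp",
            "effect_allele": "a1", "other_allele": "a2", "eaf": "freq",
            "beta": "b", "se": "stderr", "pval": "pv",
        })
        assert stats.get("rs1").effect_allele == "T"

    def test_invalid_allele_and_pval_rows_dropped(self, tmp_path):
        path = _write(tmp_path, [
            _row(snp="rs1"),
            _row(snp="rs2", ea="N"),
            _row(snp="rs3", p=0.0),
            _row(snp="rs4", ea="A", oa="A"),
        ])
        stats, report = read_summary_stats(path)
        assert stats.snp_ids == ["rs1"]
        assert dict(report.rejections) == {
            "rs2": "invalid_allele", "rs3": "pval_out_of_range",
            "rs4": "identical_alleles",
        }


class TestSummaryStatsInvariants:
    def test_duplicate_ids_rejected_on_construction(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_stats([{"snp_id": "rs1"}, {"snp_id": "rs1", "pos": 2}])

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError, match="nonpositive_se"):
            make_stats([{"se": 0.0}])


class TestClumpConfig:
    @pytest.mark.parametrize("kwargs", [
        {"r2_threshold": 0.0}, {"r2_threshold": 1.0},
        {"window_kb": 0}, {"p_threshold": 0.0}, {"p_threshold": 1.5},
    ])
    def test_out_of_range_settings_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            ClumpConfig(**kwargs)


def _greedy_oracle(records, ld, r2_threshold, window_kb):
    """Independent re-implementation of the greedy clumping rule."""
    kept = []
    for rec in sorted(records, key=lambda r: (r.pval, r.snp_id)):
        if all(
            k.chrom != rec.chrom
            or abs(k.pos - rec.pos) > window_kb * 1000
            or ld.r2(k.snp_id, rec.snp_id) < r2_threshold
            for k in kept
        ):
            kept.append(rec)
    return [r.snp_id for r in kept]


class TestSelectInstruments:
    def test_single_significant_snp_retained(self):
        stats = make_stats([{"snp_id": "rs1", "pval": 1e-9}])
        assert select_instruments(stats).snp_ids == ["rs1"]

    def test_linked_pair_drops_weaker_member(self):
        # p-values 1e-10 < 1e-9 < 1e-8, r2(1,2)=0.5, others independent:
        # SNP2 is linked to the stronger SNP1 and is clumped away.
        stats = make_stats([
            {"snp_id": "rs1", "pos": 1_000_000, "pval": 1e-10},
            {"snp_id": "rs2", "pos": 2_000_000, "pval": 1e-9},
            {"snp_id": "rs3", "pos": 3_000_000, "pval": 1e-8},
        ])
        ld = PairwiseLD({frozenset(("rs1", "rs2")): 0.5})
        cfg = ClumpConfig(r2_threshold=0.001, window_kb=10_000, p_threshold=5e-8)
        got = select_instruments(stats, cfg, ld).snp_ids
        assert got == ["rs1", "rs3"]
        assert got == _greedy_oracle(stats.records, ld, 0.001, 10_000)

    def test_matches_greedy_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = 8
            records = [
                make_record(
                    snp_id=f"rs{i}", chrom=str(rng.integers(1, 3)),
                    pos=int(rng.integers(1, 2_000_0000)),
                    pval=float(rng.uniform(1e-12, 4e-8)),
                )
                for i in range(n)
            ]
            pairs = {
                frozenset((f"rs{i}", f"rs{j}")): float(rng.uniform(0, 1))
                for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.4
            }
            ld = PairwiseLD(pairs)
            cfg = ClumpConfig(r2_threshold=0.1, window_kb=10_000)
            stats = SummaryStats(records)
            got = select_instruments(stats, cfg, ld).snp_ids
            assert got == _greedy_oracle(records, ld, 0.1, 10_000)

    def test_output_invariant_to_input_row_order(self):
        records = [
            make_record(snp_id=s, pos=p, pval=pv)
            for s, p, pv in [("rsa", 1_000_000, 1e-9), ("rsb", 1_500_000, 1e-9),
                             ("rsc", 9_000_000, 1e-10)]
        ]
        ld = PairwiseLD({frozenset(("rsa", "rsb")): 0.9,
                         frozenset(("rsb", "rsc")): 0.9})
        expected = None
        for perm in itertools.permutations(records):
            got = select_instruments(SummaryStats(list(perm)),
                                     ClumpConfig(), ld).snp_ids
            expected = expected or got
            assert got == expected

    def test_blocklisted_snp_excluded_regardless_of_pvalue(self):
        stats = make_stats([
            {"snp_id": "rs1", "pval": 1e-20},
            {"snp_id": "rs2", "pos": 99_000_000, "pval": 1e-9},
        ])
        got = select_instruments(stats, blocklist=frozenset({"rs1"}))
        assert got.snp_ids == ["rs2"]

    def test_no_significant_snp_raises(self):
        stats = make_stats([{"pval": 1e-3}])
        with pytest.raises(EmptyInstrumentError):
            select_instruments(stats)

    def test_missing_ld_emits_independence_warning(self):
        stats = make_stats([{"snp_id": "rs1", "pval": 1e-9}])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            select_instruments(stats)
        assert any("independen" in str(w.message) for w in caught)


class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, out_beta=0.05, exp_eaf=None,
              out_eaf=None):
        exp = make_stats(
            [{"snp_id": "rs1", "ea": exp_alleles[0], "oa": exp_alleles[1],
              "beta": 0.1, "eaf": exp_eaf}], label="exp")
        out = make_stats(
            [{"snp_id": "rs1", "ea": out_alleles[0], "oa": out_alleles[1],
              "beta": out_beta, "eaf": out_eaf}], label="out")
        return exp, out

    def test_identical_orientation_kept_as_is(self):
        h = harmonize(*self._pair(("A", "G"), ("A", "G")))
        assert h.snp_ids == ["rs1"] and h.by[0] == 0.05

    def test_swapped_alleles_negate_outcome_beta(self):
        h = harmonize(*self._pair(("A", "G"), ("G", "A")))
        assert h.by[0] == -0.05

    def test_strand_flip_resolves_to_same_orientation(self):
        h = harmonize(*self._pair(("A", "G"), ("T", "C")))
        assert h.by[0] == 0.05
        h = harmonize(*self._pair(("A", "G"), ("C", "T")))
        assert h.by[0] == -0.05

    def test_palindromic_snp_dropped_by_default(self):
        with pytest.raises(EmptyHarmonizationError):
            harmonize(*self._pair(("A", "T"), ("A", "T")))
        # with a second clean SNP the palindrome appears in the drop log
        exp = make_stats([
            {"snp_id": "rs1", "ea": "A", "oa": "T"},
            {"snp_id": "rs2", "pos": 2000, "ea": "A", "oa": "G"},
        ])
        out = make_stats([
            {"snp_id": "rs1", "ea": "A", "oa": "T", "beta": 0.05},
            {"snp_id": "rs2", "pos": 2000, "ea": "A", "oa": "G", "beta": 0.05},
        ])
        h = harmonize(exp, out)
        assert h.snp_ids == ["rs2"]
        assert ("rs1", "palindrome") in h.dropped

    def test_irreconcilable_alleles_dropped_as_mismatch(self):
        exp = make_stats([
            {"snp_id": "rs1", "ea": "A", "oa": "G"},
            {"snp_id": "rs2", "pos": 2000, "ea": "A", "oa": "G"},
        ])
        out = make_stats([
            {"snp_id": "rs1", "ea": "A", "oa": "C", "beta": 0.05},
            {"snp_id": "rs2", "pos": 2000, "ea": "A", "oa": "G", "beta": 0.05},
        ])
        h = harmonize(exp, out)
        assert ("rs1", "mismatch") in h.dropped

    def test_kept_plus_dropped_partition_shared_snps(self):
        exp = make_stats([
            {"snp_id": "rs1", "ea": "A", "oa": "T"},
            {"snp_id": "rs2", "pos": 2000, "ea": "A", "oa": "G"},
            {"snp_id": "rs3", "pos": 3000, "ea": "C", "oa": "T"},
            {"snp_id": "rs_only_exp", "pos": 4000},
        ])
        out = make_stats([
            {"snp_id": "rs1", "ea": "A", "oa": "T", "beta": 0.05},
            {"snp_id": "rs2", "pos": 2000, "ea": "G", "oa": "A", "beta": 0.05},
            {"snp_id": "rs3", "pos": 3000, "ea": "A", "oa": "G", "beta": 0.05},
        ])
        h = harmonize(exp, out)
        n_shared = 3
        assert len(h) + len(h.dropped) == n_shared
        assert not (set(h.snp_ids) & {s for s, _ in h.dropped})

    def test_idempotent_on_aligned_pair(self):
        exp = make_stats([{"snp_id": "rs1", "ea": "A", "oa": "G", "beta": 0.1}])
        out = make_stats([{"snp_id": "rs1", "ea": "A", "oa": "G", "beta": 0.05}])
        h1 = harmonize(exp, out)
        # feeding the harmonized orientation back changes nothing
        out2 = make_stats([{"snp_id": "rs1", "ea": "A", "oa": "G",
                            "beta": float(h1.by[0])}])
        h2 = harmonize(exp, out2)
        assert np.array_equal(h1.by, h2.by) and h1.snp_ids == h2.snp_ids

    def test_strand_flip_consistency_non_palindromic(self):
        # negating the outcome's allele orientation and beta together leaves
        # the harmonized set unchanged
        exp = make_stats([{"snp_id": "rs1", "ea": "A", "oa": "G", "beta": 0.1}])
        out_fwd = make_stats([{"snp_id": "rs1", "ea": "A", "oa": "G", "beta": 0.05}])
        out_rev = make_stats([{"snp_id": "rs1", "ea": "G", "oa": "A", "beta": -0.05}])
        h1, h2 = harmonize(exp, out_fwd), harmonize(exp, out_rev)
        assert np.array_equal(h1.by, h2.by)

    def test_eaf_inference_rescues_clear_palindromes(self):
        # frequencies on the same side of 0.5 -> aligned
        h = harmonize(*self._pair(("A", "T"), ("A", "T"),
                                  exp_eaf=0.1, out_eaf=0.12),
                      infer_strand_from_eaf=True)
        assert h.by[0] == 0.05
        # opposite sides -> the outcome is on the other strand: flip
        h = harmonize(*self._pair(("A", "T"), ("A", "T"),
                                  exp_eaf=0.1, out_eaf=0.88),
                      infer_strand_from_eaf=True)
        assert h.by[0] == -0.05

    def test_eaf_inference_still_drops_ambiguous(self):
        with pytest.raises(EmptyHarmonizationError):
            harmonize(*self._pair(("A", "T"), ("A", "T"),
                                  exp_eaf=0.5, out_eaf=0.5),
                      infer_strand_from_eaf=True)

    def test_no_shared_snps_raises(self):
        exp = make_stats([{"snp_id": "rs1"}])
        out = make_stats([{"snp_id": "rs2"}])
        with pytest.raises(EmptyHarmonizationError):
            harmonize(exp, out)

    def test_tsv_round_trip(self, tmp_path, simple_harmonized):
        from mrmediation import HarmonizedSet

        path = tmp_path / "h.tsv"
        simple_harmonized.write_tsv(path)
        back = HarmonizedSet.read_tsv(path)
        assert back.snp_ids == simple_harmonized.snp_ids
        np.testing.assert_allclose(back.by, simple_harmonized.by)
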