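import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twosample_mr.harmonize import (
    DROP_ABSENT,
    DROP_ALLELE_MISMATCH,
    DROP_PALINDROMIC,
    DROP_WEAK,
    HarmonizationError,
    SelectionConfig,
    compute_f,
    compute_r2,
    harmonize,
    instruments_from_dataframe,
    instruments_to_dataframe,
    select_instruments,
)
from twosample_mr.summary_io import SummaryDataset, SummaryRecord

from conftest import make_instrument


def rec(rsid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3, beta=0.01,
        se=0.002, pval=1e-9, n=100_000):
    return SummaryRecord(rsid, chrom, pos, ea, oa, eaf, beta, se, pval, n)


class TestStrengthMetrics:
    # Published per-variant values for the bundled exposure block,
    # (beta, se, eaf) with N = 361,194 -> (R2 to 3 s.f., F to 3 s.f.)
    @pytest.mark.parametrize(
        "beta,se,eaf,r2_3sf,f_3sf",
        [
            (0.004, 1.615e-4, 0.320, 1.70e-3, 613.0),
            (0.005, 2.742e-4, 0.095, 9.20e-4, 333.0),
            (0.002, 2.037e-4, 0.193, 2.67e-4, 96.4),
            (0.002, 2.475e-4, 0.102, 1.81e-4, 65.3),
        ],
    )
    def test_r2_and_f_match_published_columns(self, beta, se, eaf, r2_3sf, f_3sf):
        def sig3(x):
            return float(f"{x:.3g}")

        r2 = compute_r2(beta, se, eaf, 361_194)
        assert sig3(r2) == pytest.approx(r2_3sf)
        assert sig3(compute_f(r2, 361_194)) == pytest.approx(f_3sf)

    def test_zero_effect_explains_zero_variance(self):
        assert compute_r2(0.0, 0.1, 0.3, 1000) == 0.0
        assert compute_f(0.0, 1000) == 0.0

    def test_r2_requires_n_at_least_two(self):
        with pytest.raises(ValueError):
            compute_r2(0.01, 0.002, 0.3, 1)

    def test_f_rejects_r2_of_one(self):
        with pytest.raises(ValueError):
            compute_f(1.0, 1000)

    @given(
        r2=st.floats(1e-8, 0.5),
        n=st.integers(100, 10**6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f_increasing_in_r2_and_n(self, r2, n):
        f = compute_f(r2, n)
        assert f >= 0
        assert compute_f(r2 * 1.1, n) > f
        assert compute_f(r2, n + 1000) > f

    def test_r2_in_unit_interval(self):
        assert 0 <= compute_r2(0.5, 0.01, 0.1, 10_000) < 1


class TestSelectInstruments:
    def test_significance_filter(self):
        ds = SummaryDataset("x", [
            rec("rs1", pval=1.72e-106),
            rec("rs2", pos=50_000_000, pval=0.33),
        ])
        kept = select_instruments(ds, SelectionConfig())
        assert kept.rsids == ["rs1"]

    def test_threshold_one_keeps_all(self):
        ds = SummaryDataset("x", [rec("rs1"), rec("rs2", pos=50_000_000, pval=0.9)])
        kept = select_instruments(ds, SelectionConfig(p_threshold=1.0))
        assert len(kept) == 2

    def test_ld_pruning_keeps_smaller_p(self):
        ds = SummaryDataset("x", [
            rec("rs1", pos=1000, pval=1e-10),
            rec("rs2", pos=6000, pval=1e-9),
        ])
        ld = {frozenset(("rs1", "rs2")): 0.5}
        kept = select_instruments(ds, SelectionConfig(), ld=ld)
        assert kept.rsids == ["rs1"]

    def test_ld_below_threshold_keeps_both(self):
        ds = SummaryDataset("x", [
            rec("rs1", pos=1000, pval=1e-10),
            rec("rs2", pos=6000, pval=1e-9),
        ])
        ld = {frozenset(("rs1", "rs2")): 0.001}
        kept = select_instruments(ds, SelectionConfig(), ld=ld)
        assert sorted(kept.rsids) == ["rs1", "rs2"]

    def test_distance_fallback_prunes_within_window(self, caplog):
        ds = SummaryDataset("x", [
            rec("rs1", pos=1000, pval=1e-10),
            rec("rs2", pos=6000, pval=1e-9),
        ])
        with caplog.at_level("WARNING"):
            kept = select_instruments(ds, SelectionConfig())
        assert kept.rsids == ["rs1"]
        assert any("LD" in m for m in caplog.messages)

    def test_result_ordered_by_chrom_pos(self):
        ds = SummaryDataset("x", [
            rec("rs2", chrom="2", pos=100),
            rec("rs1", chrom="1", pos=200),
            rec("rs3", chrom="10", pos=50),
        ])
        kept = select_instruments(ds, SelectionConfig())
        assert kept.rsids == ["rs1", "rs2", "rs3"]

    def test_empty_result_is_error(self):
        ds = SummaryDataset("x", [rec("rs1", pval=0.5)])
        with pytest.raises(HarmonizationError, match="no instruments"):
            select_instruments(ds, SelectionConfig())


class TestHarmonize:
    def test_bundled_pair_keeps_all_four_strong_instruments(self, example_instruments):
        assert len(example_instruments) == 4
        assert all(i.f_stat > 10 for i in example_instruments)

    def test_sum_r2_matches_published_total(self, example_instruments):
        assert sum(i.r2_exp for i in example_instruments) == pytest.approx(3.06e-3, rel=0.01)

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = SummaryDataset("e", [rec("rs1", ea="A", oa="G", eaf=0.3)])
        out = SummaryDataset("o", [rec("rs1", ea="G", oa="A", eaf=0.7, beta=0.1)])
        inst = harmonize(exp, out, SelectionConfig(f_min=0.0))[0]
        assert inst.beta_out == pytest.approx(-0.1)
        assert inst.eaf_out == pytest.approx(0.3)

    def test_complemented_strand_aligned(self):
        # outcome coded on the opposite strand: A/G reads as T/C
        exp = SummaryDataset("e", [rec("rs1", ea="A", oa="G", eaf=0.3)])
        out = SummaryDataset("o", [rec("rs1", ea="T", oa="C", eaf=0.3, beta=0.1)])
        inst = harmonize(exp, out, SelectionConfig(f_min=0.0))[0]
        assert inst.beta_out == pytest.approx(0.1)

    def test_complemented_and_swapped_flips(self):
        exp = SummaryDataset("e", [rec("rs1", ea="A", oa="G", eaf=0.3)])
        out = SummaryDataset("o", [rec("rs1", ea="C", oa="T", eaf=0.7, beta=0.1)])
        inst = harmonize(exp, out, SelectionConfig(f_min=0.0))[0]
        assert inst.beta_out == pytest.approx(-0.1)

    def test_self_harmonization_is_identity(self, example_exposure):
        insts = harmonize(example_exposure, example_exposure, SelectionConfig(f_min=0.0))
        for inst in insts:
            assert inst.beta_out == pytest.approx(inst.beta_exp)
            assert inst.eaf_out == pytest.approx(inst.eaf_exp)

    def test_drop_reason_codes_are_exclusive_and_complete(self):
        exp = SummaryDataset("e", [
            rec("rs_absent", pos=1000),
            rec("rs_mismatch", pos=50_000_000),
            rec("rs_palin", pos=90_000_000, ea="A", oa="T", eaf=0.5),
            rec("rs_weak", pos=130_000_000, beta=1e-5),
            rec("rs_keep", pos=170_000_000),
        ])
        out = SummaryDataset("o", [
            rec("rs_mismatch", pos=50_000_000, ea="A", oa="C"),
            rec("rs_palin", pos=90_000_000, ea="A", oa="T", eaf=0.5),
            rec("rs_weak", pos=130_000_000),
            rec("rs_keep", pos=170_000_000),
        ])
        drops: dict = {}
        kept = harmonize(exp, out, SelectionConfig(), drop_log=drops)
        assert [i.rsid for i in kept] == ["rs_keep"]
        assert drops == {
            "rs_absent": DROP_ABSENT,
            "rs_mismatch": DROP_ALLELE_MISMATCH,
            "rs_palin": DROP_PALINDROMIC,
            "rs_weak": DROP_WEAK,
        }

    def test_palindromic_kept_with_concordant_extreme_frequencies(self):
        exp = SummaryDataset("e", [rec("rs1", ea="A", oa="T", eaf=0.1)])
        out = SummaryDataset("o", [rec("rs1", ea="A", oa="T", eaf=0.12, beta=0.1)])
        inst = harmonize(exp, out, SelectionConfig(f_min=0.0))[0]
        assert inst.beta_out == pytest.approx(0.1)

    def test_palindromic_discordant_frequencies_flip(self):
        exp = SummaryDataset("e", [rec("rs1", ea="A", oa="T", eaf=0.1)])
        out = SummaryDataset("o", [rec("rs1", ea="A", oa="T", eaf=0.88, beta=0.1)])
        inst = harmonize(exp, out, SelectionConfig(f_min=0.0))[0]
        assert inst.beta_out == pytest.approx(-0.1)
        assert inst.eaf_out == pytest.approx(0.12)

    def test_output_never_exceeds_intersection(self, example_exposure, example_outcome):
        insts = harmonize(example_exposure, example_outcome, SelectionConfig())
        shared = set(example_exposure.rsids) & set(example_outcome.rsids)
        assert len(insts) <= len(shared)

    def test_empty_harmonized_set_is_error(self):
        exp = SummaryDataset("e", [rec("rs1")])
        out = SummaryDataset("o", [rec("rs2", pos=2000)])
        with pytest.raises(HarmonizationError):
            harmonize(exp, out, SelectionConfig())


@given(
    beta=st.floats(-1.0, 1.0, allow_nan=False),
    eaf=st.floats(0.01, 0.99),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_allele_flip_involution_property(beta, eaf):
    r = rec("rs1", beta=beta, eaf=eaf)
    back = r.flipped().flipped()
    assert (back.effect_allele, back.other_allele) == (r.effect_allele, r.other_allele)
    assert back.beta == r.beta
    assert back.eaf == pytest.approx(r.eaf, abs=1e-15)


def test_instrument_table_round_trip(example_instruments):
    df = instruments_to_dataframe(example_instruments)
    back = instruments_from_dataframe(df)
    assert back == list(example_instruments)


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(palindrome_eaf_band=0.6)
    with pytest.raises(ValueError):
        SelectionConfig(p_threshold=-1.0)


def test_instrument_invariants_enforced():
    with pytest.raises(ValueError):
        make_instrument(se_out=0.0)
    with pytest.raises(ValueError):
        make_instrument(r2_exp=1.5)
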