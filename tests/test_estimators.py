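"""Estimator tests against independent closed-form oracles.

The oracles recompute each estimate directly from the weighted-sum /
sorting definitions with plain numpy, independently of the implementation
path (which goes through RatioSet/statsmodels).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twosample_mr.estimators import (
    RatioSet,
    ivw,
    mr_egger,
    to_or,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_instrument


def ivw_oracle(bx, sy, by):
    """Ratio-of-weighted-sums IVW slope and fixed-effect SE."""
    w = 1.0 / sy**2
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sum(w * bx**2) ** -0.5
    return beta, se


def instrument_strategy():
    return st.builds(
        make_instrument,
        beta_exp=st.floats(0.01, 0.2),
        se_exp=st.floats(1e-3, 1e-2),
        beta_out=st.floats(-0.05, 0.05),
        se_out=st.floats(1e-3, 1e-2),
    )


def instrument_sets(min_size=3, max_size=8):
    return st.lists(instrument_strategy(), min_size=min_size, max_size=max_size).map(
        lambda insts: [
            make_instrument(
                rsid=f"rs{i}",
                beta_exp=x.beta_exp, se_exp=x.se_exp,
                beta_out=x.beta_out, se_out=x.se_out,
            )
            for i, x in enumerate(insts)
        ]
    )


class TestWaldRatio:
    def test_quotients_from_bundled_first_row(self):
        inst = make_instrument(beta_exp=0.004, beta_out=1.759e-4, se_out=1.814e-4)
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.043975, rel=1e-6)
        assert est.se == pytest.approx(0.04535, rel=1e-3)

    def test_zero_outcome_effect_gives_null(self):
        est = wald_ratio(make_instrument(beta_out=0.0))
        assert est.beta == 0.0 and est.pval == 1.0

    def test_scale_equivariance(self):
        a = wald_ratio(make_instrument(beta_out=0.01, se_out=0.004))
        b = wald_ratio(make_instrument(beta_out=0.02, se_out=0.008))
        assert b.beta == pytest.approx(2 * a.beta)
        assert b.se == pytest.approx(2 * a.se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(make_instrument(beta_exp=0.0))


class TestIVW:
    def test_bundled_fixture_against_weighted_sum_oracle(self, example_instruments, example_arrays):
        bx, _, by, sy = example_arrays
        beta_o, se_o = ivw_oracle(bx, sy, by)
        est = ivw(example_instruments)
        assert est.beta == pytest.approx(beta_o, rel=1e-12)
        assert est.se == pytest.approx(se_o, rel=1e-12)
        # frozen from the oracle evaluated on the bundled table
        assert est.beta == pytest.approx(0.08209, abs=5e-5)
        assert est.se == pytest.approx(0.03374, abs=5e-5)
        assert est.pval == pytest.approx(0.01497, abs=2e-4)

    def test_duplicated_instrument_equals_wald_ratio(self):
        inst = make_instrument(beta_out=0.012)
        est = ivw([inst, inst])
        assert est.beta == pytest.approx(wald_ratio(inst).beta)

    def test_all_null_outcomes_give_zero(self):
        insts = [make_instrument(rsid=f"rs{i}", beta_out=0.0) for i in range(3)]
        assert ivw(insts).beta == 0.0

    def test_single_instrument_redirects_to_wald(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw([make_instrument()])

    def test_random_effects_never_shrinks_se(self, example_instruments):
        fixed = ivw(example_instruments, model="fixed")
        mre = ivw(example_instruments, model="multiplicative_random")
        assert mre.se >= fixed.se
        assert mre.beta == fixed.beta
        # bundled instruments are homogeneous (Q/df < 1): models coincide
        assert mre.se == pytest.approx(fixed.se)

    @given(insts=instrument_sets())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_order_invariance(self, insts):
        est1 = ivw(insts)
        est2 = ivw(insts[::-1])
        assert est2.beta == pytest.approx(est1.beta, rel=1e-9)
        assert est2.se == pytest.approx(est1.se, rel=1e-9)

    def test_uniform_se_scaling(self, example_instruments):
        base = ivw(example_instruments)
        scaled = [
            make_instrument(
                rsid=i.rsid, beta_exp=i.beta_exp, se_exp=i.se_exp,
                beta_out=i.beta_out, se_out=3.0 * i.se_out,
            )
            for i in example_instruments
        ]
        est = ivw(scaled)
        assert est.beta == pytest.approx(base.beta, rel=1e-12)
        assert est.se == pytest.approx(3.0 * base.se, rel=1e-12)


class TestEgger:
    def test_bundled_fixture_against_wls_oracle(self, example_instruments, example_arrays):
        bx, _, by, sy = example_arrays
        # normal-equation oracle for weighted regression with intercept
        w = 1.0 / sy**2
        X = np.column_stack([np.ones_like(bx), bx])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        slope, intercept = mr_egger(example_instruments)
        assert intercept.intercept == pytest.approx(coef[0], rel=1e-9)
        assert slope.beta == pytest.approx(coef[1], rel=1e-9)
        # frozen oracle values from the bundled table
        assert slope.beta == pytest.approx(0.01521, abs=5e-5)
        assert intercept.intercept == pytest.approx(2.444e-4, abs=5e-7)

    def test_exact_line_recovered_with_zero_residual(self):
        a, b = 0.002, 0.3
        insts = [
            make_instrument(rsid=f"rs{i}", beta_exp=bx, beta_out=a + b * bx)
            for i, bx in enumerate([0.02, 0.05, 0.08, 0.12])
        ]
        slope, intercept = mr_egger(insts)
        assert slope.beta == pytest.approx(b, rel=1e-9)
        assert intercept.intercept == pytest.approx(a, rel=1e-9)
        assert slope.extra["q_egger"] == pytest.approx(0.0, abs=1e-15)

    def test_sign_orientation_makes_result_coding_invariant(self):
        insts = [
            make_instrument(rsid=f"rs{i}", beta_exp=bx, beta_out=0.001 + 0.1 * bx)
            for i, bx in enumerate([0.02, 0.05, 0.08, 0.12])
        ]
        # recode one variant on the other allele: both betas change sign
        flipped = list(insts)
        flipped[1] = make_instrument(
            rsid="rs1", beta_exp=-insts[1].beta_exp, beta_out=-insts[1].beta_out,
        )
        a, b = mr_egger(insts)
        a2, b2 = mr_egger(flipped)
        assert a2.beta == pytest.approx(a.beta, rel=1e-9)
        assert b2.intercept == pytest.approx(b.intercept, rel=1e-9)

    def test_minimum_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger([make_instrument("rs1"), make_instrument("rs2")])

    def test_intercept_zero_constraint_reproduces_ivw(self, example_instruments, example_arrays):
        # with the intercept column removed, the weighted fit IS the IVW slope
        bx, _, by, sy = example_arrays
        w = 1.0 / sy**2
        slope_no_intercept = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert ivw(example_instruments).beta == pytest.approx(slope_no_intercept, rel=1e-12)

    def test_t2_reference_distribution(self, example_instruments):
        slope, _ = mr_egger(example_instruments)
        t = slope.beta / slope.se
        assert slope.pval == pytest.approx(2 * stats.t.sf(abs(t), df=2), rel=1e-9)


class TestWeightedMedian:
    def test_bundled_fixture_against_interpolation_oracle(self, example_instruments, example_arrays):
        bx, _, by, sy = example_arrays
        r = by / bx
        w = bx**2 / sy**2
        order = np.argsort(r)
        r, w = r[order], w[order]
        p = (np.cumsum(w) - w / 2) / w.sum()
        expected = np.interp(0.5, p, r)
        est = weighted_median(example_instruments, n_boot=200, seed=3)
        assert est.beta == pytest.approx(expected, rel=1e-12)
        assert est.beta == pytest.approx(0.0750, abs=2e-4)  # frozen oracle value

    def test_constant_ratios_recovered(self):
        insts = [
            make_instrument(rsid=f"rs{i}", beta_exp=bx, beta_out=0.05 * bx)
            for i, bx in enumerate([0.02, 0.05, 0.08])
        ]
        assert weighted_median(insts, n_boot=100, seed=1).beta == pytest.approx(0.05)

    def test_equal_weights_symmetric_median(self):
        insts = [
            make_instrument(rsid=f"rs{i}", beta_exp=0.1, beta_out=0.1 * c, se_out=0.01)
            for i, c in enumerate([1.0, 2.0, 3.0])
        ]
        assert weighted_median(insts, n_boot=100, seed=1).beta == pytest.approx(2.0)

    def test_bootstrap_se_reproducible(self, example_instruments):
        a = weighted_median(example_instruments, n_boot=200, seed=11)
        b = weighted_median(example_instruments, n_boot=200, seed=11)
        assert a.se == b.se

    def test_small_bootstrap_rejected(self, example_instruments):
        with pytest.raises(ValueError):
            weighted_median(example_instruments, n_boot=50, seed=1)

    @given(insts=instrument_sets())
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_estimate_within_ratio_range(self, insts):
        rs = RatioSet.from_instruments(insts)
        est = weighted_median(insts, n_boot=100, seed=5)
        assert rs.ratios.min() - 1e-12 <= est.beta <= rs.ratios.max() + 1e-12


class TestWeightedMode:
    def test_constant_ratios_recovered(self):
        insts = [
            make_instrument(rsid=f"rs{i}", beta_exp=bx, beta_out=0.07 * bx)
            for i, bx in enumerate([0.02, 0.05, 0.08])
        ]
        est = weighted_mode(insts, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.07)

    def test_mode_attracted_to_cluster_not_outlier(self):
        # ratios {0, 0.01, 0.011, 0.012, 5} with equal weights
        ratios = [0.0, 0.01, 0.011, 0.012, 5.0]
        insts = [
            make_instrument(rsid=f"rs{i}", beta_exp=0.1, beta_out=0.1 * c, se_out=0.01)
            for i, c in enumerate(ratios)
        ]
        est = weighted_mode(insts, phi=1.0, n_boot=100, seed=1)
        assert 0.0 < est.beta < 0.02

    def test_bundled_fixture_same_direction_as_ivw(self, example_instruments):
        est = weighted_mode(example_instruments, n_boot=200, seed=3)
        assert est.beta > 0

    def test_reproducible_and_order_invariant(self, example_instruments):
        a = weighted_mode(example_instruments, n_boot=150, seed=9)
        b = weighted_mode(list(example_instruments)[::-1], n_boot=150, seed=9)
        assert a.beta == pytest.approx(b.beta, rel=1e-9)

    @given(insts=instrument_sets())
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_estimate_within_ratio_range(self, insts):
        rs = RatioSet.from_instruments(insts)
        est = weighted_mode(insts, n_boot=100, seed=5)
        assert rs.ratios.min() - 1e-9 <= est.beta <= rs.ratios.max() + 1e-9

    def test_invalid_phi_rejected(self, example_instruments):
        with pytest.raises(ValueError):
            weighted_mode(example_instruments, phi=0.0, n_boot=100, seed=1)


class TestOddsRatioConversion:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [
            (0.092, 0.038, (1.096, 1.018, 1.180)),
            (0.015, 0.122, (1.015, 0.800, 1.288)),
        ],
    )
    def test_published_or_ci_reproduced(self, beta, se, expected):
        or_, lo, hi = to_or(beta, se)
        assert (round(or_, 3), round(lo, 3), round(hi, 3)) == pytest.approx(expected, abs=1.5e-3)

    def test_null_effect_symmetric_on_log_scale(self):
        or_, lo, hi = to_or(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            to_or(0.1, -0.1)
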