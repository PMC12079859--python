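import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partmr.datatypes import DataError, PreconditionError
from partmr.twosample import (
    heterogeneity,
    ivw,
    mr_egger,
    mvmr_pp4_weighted,
    steiger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from .conftest import make_pair, pairs_from_arrays


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(make_pair(beta_exp=0.1, beta_out=0.05, se_out=0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome(self):
        est = wald_ratio(make_pair(beta_exp=0.1, beta_out=0.0))
        assert est.beta == 0.0

    def test_zero_exposure_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(make_pair(beta_exp=0.0))

    def test_delta_se_vs_parametric_bootstrap(self):
        # 1e6-draw parametric bootstrap of the ratio distribution
        pair = make_pair(beta_exp=0.2, se_exp=0.002, beta_out=0.05, se_out=0.01)
        est = wald_ratio(pair)
        rng = np.random.default_rng(0)
        by = pair.beta_out + pair.se_out * rng.standard_normal(1_000_000)
        bx = pair.beta_exp + pair.se_exp * rng.standard_normal(1_000_000)
        boot_sd = np.std(by / bx)
        assert est.se == pytest.approx(boot_sd, rel=0.05)


class TestIVW:
    def test_single_pair_fixed_equals_wald(self):
        pair = make_pair(beta_exp=0.1, beta_out=0.03, se_out=0.02)
        est = ivw([pair], model="fixed")
        wald = wald_ratio(pair)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_symmetric_mean(self):
        pairs = pairs_from_arrays([1, 1], [0.4, 0.6], [1, 1])
        assert ivw(pairs).beta == pytest.approx(0.5)

    def test_insufficient_instruments(self):
        with pytest.raises(PreconditionError):
            ivw([make_pair()], model="random")

    def test_wls_oracle_20_pairs(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0.1, 0.05, 20)
        by = 0.3 * bx + rng.normal(0, 0.01, 20)
        sy = rng.uniform(0.005, 0.02, 20)
        pairs = pairs_from_arrays(bx, by, sy)
        est = ivw(pairs, model="fixed")
        w = 1 / sy**2
        beta_o = np.sum(w * bx * by) / np.sum(w * bx**2)
        se_o = np.sqrt(1 / np.sum(w * bx**2))
        assert est.beta == pytest.approx(beta_o, rel=1e-12)
        assert est.se == pytest.approx(se_o, rel=1e-12)

    def test_random_effects_inflates_se_only(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0.1, 0.05, 30)
        by = 0.3 * bx + rng.normal(0, 0.05, 30)  # overdispersed
        pairs = pairs_from_arrays(bx, by, np.full(30, 0.01))
        fixed = ivw(pairs, model="fixed")
        random = ivw(pairs, model="random")
        assert random.beta == pytest.approx(fixed.beta)
        assert random.se > fixed.se


class TestEgger:
    def test_exact_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = pairs_from_arrays(bx, 0.3 * bx, np.full(4, 0.01))
        slope, intercept = mr_egger(pairs)
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)

    def test_planted_intercept_recovery(self):
        rng = np.random.default_rng(6)
        bx = rng.uniform(0.05, 0.3, 50)
        sy = np.full(50, 0.01)
        by = 0.02 + 0.1 * bx + sy * rng.standard_normal(50)
        slope, intercept = mr_egger(pairs_from_arrays(bx, by, sy))
        assert abs(slope.beta - 0.1) < 2 * slope.se
        assert abs(intercept.beta - 0.02) < 2 * intercept.se

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.3, 10)
        sy = np.full(10, 0.01)
        by = 0.01 + 0.2 * bx + sy * rng.standard_normal(10)
        base_s, base_i = mr_egger(pairs_from_arrays(bx, by, sy))
        bx2, by2 = bx.copy(), by.copy()
        bx2[3], by2[3] = -bx2[3], -by2[3]
        flip_s, flip_i = mr_egger(pairs_from_arrays(bx2, by2, sy))
        assert flip_s.beta == pytest.approx(base_s.beta, rel=1e-12)
        assert flip_i.beta == pytest.approx(base_i.beta, rel=1e-12)

    def test_needs_three(self):
        with pytest.raises(PreconditionError):
            mr_egger(pairs_from_arrays([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


class TestWeightedMedian:
    def test_odd_equal_weights_middle_ratio(self):
        pairs = pairs_from_arrays([1, 1, 1], [0.1, 0.5, 0.9], [1, 1, 1])
        est = weighted_median(pairs, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_hand_computed_interpolation(self):
        # ratios (0.1, 0.2, 0.9), weights (1, 1, 8):
        # cumulative (w - w/2)/W = (0.05, 0.15, 0.6); 0.5 crossing between
        # the 2nd and 3rd ratio: 0.2 + 0.7*(0.5-0.15)/(0.6-0.15) = 0.74444...
        pairs = pairs_from_arrays(
            [1, 1, 1], [0.1, 0.2, 0.9], [1.0, 1.0, 1 / np.sqrt(8)])
        est = weighted_median(pairs, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2 + 0.7 * (0.35 / 0.45), rel=1e-9)

    def test_identical_ratios(self):
        pairs = pairs_from_arrays([1, 1, 1], [0.3, 0.3, 0.3],
                                  [0.01, 0.01, 0.01])
        est = weighted_median(pairs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 0.05


class TestWeightedMode:
    def test_cluster_beats_outliers(self):
        ratios = np.array([0.48, 0.49, 0.5, 0.5, 0.51, 0.52, 0.5, 3.0, 3.1])
        pairs = pairs_from_arrays(np.ones(9), ratios, np.full(9, 0.05))
        est = weighted_mode(pairs, n_boot=50, seed=0)
        assert abs(est.beta - 0.5) < 0.1

    def test_identical_ratios(self):
        pairs = pairs_from_arrays([1, 1, 1], [0.7, 0.7, 0.7], [0.01] * 3)
        est = weighted_mode(pairs, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.7)

    def test_uniform_se_rescaling_leaves_mode(self):
        rng = np.random.default_rng(8)
        bx = np.ones(9)
        by = np.concatenate([0.5 + 0.02 * rng.standard_normal(7), [2.0, 2.2]])
        a = weighted_mode(pairs_from_arrays(bx, by, np.full(9, 0.02)),
                          n_boot=10, seed=0)
        b = weighted_mode(pairs_from_arrays(bx, by, np.full(9, 0.04)),
                          n_boot=10, seed=0)
        assert a.beta == pytest.approx(b.beta)


class TestHeterogeneity:
    def test_identical_ratios_q_zero(self):
        pairs = pairs_from_arrays([1, 1, 1], [0.3, 0.3, 0.3], [0.01] * 3)
        het = heterogeneity(pairs, ivw(pairs))
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.I2 == 0.0

    def test_printed_formula_q10_k6(self):
        # construct 6 equal-weight ratios with Q = 10 about their mean
        a = np.sqrt(5 / 3)
        by = np.array([a, -a, a, -a, a, -a])
        pairs = pairs_from_arrays(np.ones(6), by, np.ones(6))
        est = ivw(pairs, model="fixed")
        het = heterogeneity(pairs, est)
        assert het.Q == pytest.approx(10.0)
        assert het.I2 == pytest.approx(0.5)          # (10 - 5) / 10
        assert het.Q_het == pytest.approx(2.5)       # 10 / (6 - 1 - 1)

    def test_f_statistic(self):
        pairs = pairs_from_arrays([0.1, 0.1], [0.0, 0.0], [1, 1],
                                  sx=[0.01, 0.01])
        het = heterogeneity(pairs, ivw(pairs))
        assert het.mean_F == pytest.approx(100.0)

    def test_total_r2_from_eaf(self):
        pairs = pairs_from_arrays([0.2, 0.1], [0.0, 0.0], [1, 1], eaf=0.5)
        het = heterogeneity(pairs, ivw(pairs))
        assert het.total_R2 == pytest.approx(2 * 0.25 * (0.04 + 0.01))

    def test_qdf_one_undefined_qhet(self):
        pairs = pairs_from_arrays([1, 1], [0.1, 0.2], [1, 1])
        het = heterogeneity(pairs, ivw(pairs))
        assert het.Q_het is None

    def test_fixed_ivw_minimizes_q(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.3, 15)
        by = 0.2 * bx + rng.normal(0, 0.02, 15)
        sy = rng.uniform(0.005, 0.02, 15)
        pairs = pairs_from_arrays(bx, by, sy)
        est = ivw(pairs, model="fixed")
        w = (bx / sy) ** 2
        ratios = by / bx

        def q_at(beta):
            return np.sum(w * (ratios - beta) ** 2)

        q0 = q_at(est.beta)
        for delta in (-0.01, -0.001, 0.001, 0.01):
            assert q_at(est.beta + delta) > q0


class TestSteiger:
    def test_clear_direction(self):
        pairs = pairs_from_arrays([0.5], [0.001], [0.5], sx=[0.05])
        res = steiger(pairs, n_exp=10_000, n_out=10_000)
        assert res.direction_correct
        assert res.r2_exposure > res.r2_outcome
        assert res.steiger_p < 1e-6

    def test_symmetric_tie(self):
        pairs = pairs_from_arrays([0.5], [0.5], [0.05], sx=[0.05])
        res = steiger(pairs, n_exp=10_000, n_out=10_000)
        assert res.tie and res.direction_correct
        assert res.steiger_p == pytest.approx(1.0)

    def test_missing_n_raises(self):
        pairs = pairs_from_arrays([0.5], [0.001], [0.5])
        with pytest.raises(PreconditionError):
            steiger(pairs, None, 1000)

    def test_simulated_chain_direction(self):
        # X -> Y chain with 50 instruments: direction recovered in >= 99/100
        correct = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_exp = n_out = 50_000
            bx = rng.normal(0, 0.05, 50)
            sx = np.full(50, 0.005)
            bx_obs = bx + sx * rng.standard_normal(50)
            theta = 0.3
            sy = np.full(50, 0.005)
            by_obs = theta * bx + sy * rng.standard_normal(50)
            pairs = pairs_from_arrays(bx_obs, by_obs, sy, sx=sx)
            if steiger(pairs, n_exp, n_out).direction_correct:
                correct += 1
        assert correct >= 99


class TestMVMRPP4:
    def test_reduction_when_other_tissue_zero(self):
        rng = np.random.default_rng(10)
        bx = rng.uniform(0.05, 0.3, 10)
        sy = np.full(10, 0.01)
        by = 0.2 * bx + sy * rng.standard_normal(10)
        pairs = pairs_from_arrays(bx, by, sy)
        pp4 = {p.variant_id: (1.0, 0.0) for p in pairs}
        est_a, est_b = mvmr_pp4_weighted(pairs, pp4, exclude_below=None)
        # with pp4_B = 0 the fit is univariable IVW on the pp4-scaled bx_A
        w = 1 / sy**2
        beta_o = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert est_a.beta == pytest.approx(beta_o, rel=1e-9)

    def test_proportional_pp4_collinear(self):
        pairs = pairs_from_arrays([0.1, 0.2, 0.3], [0.02, 0.04, 0.06],
                                  [0.01] * 3)
        pp4 = {p.variant_id: (0.95, 0.95) for p in pairs}
        with pytest.raises(DataError):
            mvmr_pp4_weighted(pairs, pp4, exclude_below=None)

    def test_recovery_two_tissue(self):
        # direct effects (0.1, 0.0) with informative pp4: recovered within 2 SE
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            m = 30
            tissue = rng.integers(0, 2, size=m)
            bx = rng.normal(0, 0.1, m)
            sx = np.full(m, 0.01)
            sy = np.full(m, 0.01)
            bx_obs = bx + sx * rng.standard_normal(m)
            by = np.where(tissue == 0, 0.1 * bx, 0.0) + sy * rng.standard_normal(m)
            pairs = pairs_from_arrays(bx_obs, by, sy, sx=sx)
            pp4 = {
                p.variant_id: ((0.97, 0.02) if tissue[i] == 0 else (0.02, 0.97))
                for i, p in enumerate(pairs)
            }
            est_a, est_b = mvmr_pp4_weighted(pairs, pp4)
            if abs(est_a.beta - 0.1) <= 2 * est_a.se \
                    and abs(est_b.beta) <= 2 * est_b.se:
                hits += 1
        assert hits >= int(0.85 * reps)

    def test_missing_pp4_raises(self):
        pairs = pairs_from_arrays([0.1, 0.2], [0.02, 0.04], [0.01, 0.01])
        with pytest.raises(PreconditionError):
            mvmr_pp4_weighted(pairs, {"rs0": (0.9, 0.1)})


class TestEstimatorConsistency:
    def test_agreement_under_no_pleiotropy(self):
        rng = np.random.default_rng(11)
        m = 60
        bx = rng.normal(0, 0.12, m)
        sx = np.full(m, 0.005)
        sy = np.full(m, 0.005)
        theta = 0.25
        pairs = pairs_from_arrays(
            bx + sx * rng.standard_normal(m),
            theta * bx + sy * rng.standard_normal(m), sy, sx=sx)
        ests = {
            "ivw": ivw(pairs).beta,
            "egger": mr_egger(pairs)[0].beta,
            "median": weighted_median(pairs, n_boot=100, seed=0).beta,
            "mode": weighted_mode(pairs, n_boot=100, seed=0).beta,
        }
        for name, val in ests.items():
            assert abs(val - theta) < 0.05, name

    def test_order_and_signflip_invariance(self):
        rng = np.random.default_rng(12)
        m = 12
        bx = rng.uniform(0.05, 0.3, m)
        sy = rng.uniform(0.005, 0.02, m)
        by = 0.2 * bx + sy * rng.standard_normal(m)
        pairs = pairs_from_arrays(bx, by, sy)
        perm = list(rng.permutation(m))
        flipped = pairs_from_arrays(
            np.where(np.arange(m) == 5, -bx, bx),
            np.where(np.arange(m) == 5, -by, by), sy)
        for fn in (lambda p: ivw(p).beta,
                   lambda p: mr_egger(p)[0].beta,
                   lambda p: weighted_median(p, n_boot=10, seed=0).beta,
                   lambda p: weighted_mode(p, n_boot=10, seed=0).beta):
            assert fn([pairs[i] for i in perm]) == pytest.approx(fn(pairs))
            assert fn(flipped) == pytest.approx(fn(pairs))


@given(st.lists(st.tuples(
    st.floats(0.05, 0.5), st.floats(-0.2, 0.2), st.floats(0.005, 0.05)),
    min_size=3, max_size=12))
@settings(max_examples=30, deadline=None)
def test_weighted_median_within_ratio_range(data):
    bx = [d[0] for d in data]
    by = [d[1] for d in data]
    sy = [d[2] for d in data]
    pairs = pairs_from_arrays(bx, by, sy)
    ratios = np.array(by) / np.array(bx)
    est = weighted_median(pairs, n_boot=5, seed=0)
    assert ratios.min() - 1e-9 <= est.beta <= ratios.max() + 1e-9
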