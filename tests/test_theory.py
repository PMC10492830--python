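import numpy as np
import pytest

from kerneltransfer.synthetic import gen_weights_with_epsilon
from kerneltransfer.theory import (
    LinearTransferTask,
    c_direction_predicate,
    corollary_asymptotic_risk,
    epsilon_similarity,
    mc_risk,
    risk_baseline,
    risk_projected,
    risk_translated,
    s_monotone_predicate,
    small_tc_expansion,
    translated_crossover_angle,
)


class TestEpsilonSimilarity:
    def test_full_row_rank_source_gives_zero(self, rng):
        omega_s = rng.standard_normal((4, 4))  # full rank d=4
        omega_t = rng.standard_normal((3, 4))
        assert epsilon_similarity(omega_t, omega_s) == pytest.approx(0.0, abs=1e-12)

    def test_factorizable_target_gives_zero(self, rng):
        omega_s = rng.standard_normal((3, 8))
        omega_p = rng.standard_normal((2, 3))
        assert epsilon_similarity(omega_p @ omega_s, omega_s) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_rows(self):
        e1 = np.array([[1.0, 0.0]])
        e2 = np.array([[0.0, 1.0]])
        assert epsilon_similarity(e2, e1) == pytest.approx(1.0)


class TestClosedForms:
    def test_baseline_full_recovery(self):
        assert risk_baseline(10, 10, 3.0) == 0.0

    def test_baseline_half_sampled(self):
        assert risk_baseline(10, 5, 1.0) == pytest.approx(0.5)

    def test_baseline_out_of_regime(self):
        with pytest.raises(ValueError, match="regime"):
            risk_baseline(10, 11, 1.0)

    def test_projected_hand_evaluated_constants(self):
        rb = risk_projected(4, 4, 2, 2, 1.0, 0.0)
        assert rb.C1 == pytest.approx(0.0)
        assert rb.C2 == pytest.approx(1.0)
        assert rb.K1 == pytest.approx(7 / 9)
        assert rb.risk == pytest.approx(7 / 18)

    def test_projected_perfect_transfer_limit(self):
        assert risk_projected(8, 8, 8, 8, 1.0, 0.0).risk == pytest.approx(0.0, abs=1e-12)

    def test_projected_regime_guard(self):
        with pytest.raises(ValueError):
            risk_projected(2, 1, 1, 1, 1.0, 0.0)
        with pytest.raises(ValueError, match="regime"):
            risk_projected(8, 9, 2, 2, 1.0, 0.0)

    def test_translated_identical_tasks_fully_sampled(self):
        assert risk_translated(16, 16, 4, 0.0, 1.0) == pytest.approx(0.0)

    def test_translated_no_source_equals_baseline(self):
        assert risk_translated(16, 0, 4, 0.5, 1.0) == pytest.approx(risk_baseline(16, 4, 1.0))

    def test_translated_is_weighted_average(self, rng):
        # exact interpolation between baseline and A*baseline with weight n_s/d
        d, n_t = 12, 5
        A = 0.7
        base = risk_baseline(d, n_t, 2.0)
        for n_s in range(0, d + 1):
            expected = (n_s / d) * (A * base) + (1 - n_s / d) * base
            assert risk_translated(d, n_s, n_t, A * 2.0, 2.0) == pytest.approx(expected)


class TestAsymptotics:
    def test_s1_c0_eps0_reduces_to_squared_baseline(self):
        for T in (0.1, 0.4, 0.9):
            assert corollary_asymptotic_risk(1.0, T, 0.0, 0.0, 1.0) == pytest.approx((1 - T) ** 2)

    def test_no_target_data_limit(self):
        assert corollary_asymptotic_risk(1.0, 0.0, 0.3, 0.0, 1.0) == pytest.approx(1.0)

    def test_finite_d_converges_to_limit(self):
        d = 2000
        for T, C, eps in [(0.25, 0.1, 0.0), (0.5, 0.25, 0.3), (0.75, 0.5, 0.1)]:
            finite = risk_projected(d, d, int(T * d), int(C * d), 1.0, eps).risk
            limit = (1 - T + T * C) * (1 - T) + eps * T * (2 - T)
            assert finite == pytest.approx(limit, rel=0.01)

    def test_c_direction_matches_derivative_sign(self):
        for S, T in [(0.9, 0.1), (0.4, 0.5), (0.6, 0.9)]:
            sign = c_direction_predicate(S, T)
            r = [corollary_asymptotic_risk(S, T, C, 0.0, 1.0) for C in (0.2, 0.4, 0.6)]
            if sign > 0:
                assert r[0] < r[1] < r[2]
            else:
                assert r[0] >= r[1] >= r[2]

    def test_s_monotone_predicate_forms(self):
        assert s_monotone_predicate(0.1, 0.5, 1.0)
        assert not s_monotone_predicate(0.9, 0.5, 1.0)
        assert s_monotone_predicate(0.1, 0.5, 0.8, squared=True) == (0.1 < 0.5 * 0.64)

    def test_small_tc_expansion_value(self):
        assert small_tc_expansion(0.05, 0.2, 1.0) == pytest.approx(0.9 + 0.1 * 0.2)

    def test_crossover_angle_is_pi_over_three(self):
        # equal-norm maps: translated beats baseline iff ||ws - wt|| < ||wt||
        for n_s in (4, 10, 16):
            angle = translated_crossover_angle(16, n_s, 4)
            assert angle == pytest.approx(np.pi / 3, abs=1e-8)


class TestMonteCarlo:
    def make_task(self, d, n_s, n_t, c_s, c_t, eps, seed=7):
        ws, wt = gen_weights_with_epsilon(d, c_s, c_t, eps, 1.0, seed=seed)
        return LinearTransferTask(d=d, n_s=n_s, n_t=n_t, omega_s=ws, omega_t=wt)

    def test_baseline_interpolation_regime_is_exact(self):
        task = self.make_task(8, 2, 8, 2, 2, 0.0)
        mean, se = mc_risk(task, "baseline", 200, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-16)

    def test_translated_identical_tasks_zero_risk(self, rng):
        wt = rng.standard_normal((3, 8))
        task = LinearTransferTask(d=8, n_s=8, n_t=3, omega_s=wt, omega_t=wt)
        mean, _ = mc_risk(task, "translated", 200, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-20)

    def test_reproducible_given_seed(self):
        task = self.make_task(8, 4, 3, 2, 2, 0.1)
        assert mc_risk(task, "projected", 500, seed=3) == mc_risk(task, "projected", 500, seed=3)

    def test_baseline_matches_closed_form(self):
        task = self.make_task(12, 1, 7, 2, 2, 0.25)
        mean, se = mc_risk(task, "baseline", 20000, seed=5)
        closed = risk_baseline(12, 7, 1.0)
        assert abs(mean - closed) <= 3 * se

    def test_translated_matches_closed_form(self):
        task = self.make_task(16, 12, 6, 3, 3, 0.25)
        mean, se = mc_risk(task, "translated", 20000, seed=5)
        closed = risk_translated(
            16, 12, 6, float(np.sum((task.omega_s - task.omega_t) ** 2)), 1.0
        )
        assert abs(mean - closed) <= 3 * se

    def test_rowspace_projected_matches_closed_form_at_full_source_sampling(self):
        # with n_s = d the source row space is recovered exactly and the
        # closed-form projected risk describes the row-space-projected
        # baseline estimator
        task = self.make_task(16, 16, 4, 4, 3, 0.25)
        mean, se = mc_risk(task, "projected_rowspace", 20000, seed=5)
        closed = risk_projected(16, 16, 4, 4, 1.0, 0.25).risk
        assert abs(mean - closed) <= 3 * se

    def test_composed_projection_recovers_factorizable_target_exactly(self):
        # n_s = d, eps = 0, n_t >= c_s: the composed estimator y_t(w_s X_t)^+ w_s
        # interpolates the projection head exactly and achieves zero risk
        # (whereas the closed form reports 7/18 at d=4 — see docs/methods.md)
        task = self.make_task(4, 4, 2, 2, 3, 0.0)
        mean, _ = mc_risk(task, "projected", 500, seed=2)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_source_estimator_risk_reflects_task_distance(self, rng):
        wt = rng.standard_normal((2, 8))
        task = LinearTransferTask(d=8, n_s=8, n_t=2, omega_s=wt, omega_t=wt)
        mean, _ = mc_risk(task, "source", 100, seed=0)
        assert mean == pytest.approx(0.0, abs=1e-20)

    def test_label_dimension_guard(self):
        task = self.make_task(8, 4, 3, 2, 3, 0.1)
        with pytest.raises(ValueError, match="c_s == c_t"):
            mc_risk(task, "translated", 10, seed=0)

    def test_unknown_estimator_rejected(self):
        task = self.make_task(8, 4, 3, 2, 2, 0.1)
        with pytest.raises(ValueError, match="estimator"):
            mc_risk(task, "oracle", 10, seed=0)
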