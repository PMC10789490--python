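import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from costbayes import (BistableModeError, ModelSpec, asymptotic_mode,
                       implied_entropy, predictive_path, stationary_distribution)
from costbayes.observers import (PrecisionBelief, QGridPosterior, binary_entropy,
                                 grid_axis)

A, B = 1, 0


def run_updates(obs, seq):
    for x in seq:
        obs.update(x)
    return obs


class TestPrecisionBelief:
    def test_costfree_counts_are_raw_counts(self):
        obs = run_updates(PrecisionBelief(0, 0.0), [A, A, B, A])
        assert obs.counts.tolist() == [1.0, 3.0]  # (n_B, n_A)

    def test_repeated_stimulus_geometric_series(self):
        lam, t = 1.5, 12
        gamma = 1 / (1 + lam)
        obs = run_updates(PrecisionBelief(0, lam), [A] * t)
        assert obs.counts[0] == 0.0
        assert obs.counts[1] == pytest.approx((1 - gamma ** t) / (1 - gamma), abs=1e-12)

    def test_order1_hand_computed_counts(self):
        # gamma = 0.5; sequence A B A: first stimulus builds context only,
        # then pattern AB is counted and decays once, then BA is counted
        obs = run_updates(PrecisionBelief(1, 1.0), [A, B, A])
        counts = {"BB": obs.counts[0], "BA": obs.counts[1],
                  "AB": obs.counts[2], "AA": obs.counts[3]}
        assert counts == {"BB": 0.0, "BA": 1.0, "AB": 0.5, "AA": 0.0}

    def test_predictive_fresh_belief_is_half(self):
        assert PrecisionBelief(0, 2.0).predictive() == 0.5

    def test_predictive_laplace_ratio(self):
        obs = run_updates(PrecisionBelief(0, 0.0), [A, A, A, B])
        assert obs.predictive() == pytest.approx(4 / 6)

    def test_predictive_unseen_context_is_half(self):
        # all-A history: context B has zero counts
        obs = run_updates(PrecisionBelief(1, 0.0), [A, A, A, A, B])
        assert obs.context == (B,)
        assert obs.predictive() == 0.5

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40),
           st.sampled_from([0, 1, 2]))
    @settings(max_examples=40, deadline=None)
    def test_costfree_reduces_to_bayesian_counts(self, seq, m):
        obs = run_updates(PrecisionBelief(m, 0.0), seq)
        expected = np.zeros(2 ** (m + 1))
        for t in range(m, len(seq)):
            idx = 0
            for s in seq[t - m: t + 1]:
                idx = (idx << 1) | s
            expected[idx] += 1
        assert np.array_equal(obs.counts, expected)

    def test_json_roundtrip(self):
        obs = run_updates(PrecisionBelief(1, 0.7), [A, B, B, A])
        clone = PrecisionBelief.from_json(obs.to_json())
        assert np.array_equal(clone.counts, obs.counts)
        assert clone.context == obs.context
        assert clone.predictive() == obs.predictive()


class TestQGridPosterior:
    def test_costfree_equals_discretised_bayes(self):
        seq = [A, A, B, A, B, A, A]
        obs = run_updates(QGridPosterior(0, 0.0, 0.0), seq)
        q = grid_axis(0)
        w = q ** 5 * (1 - q) ** 2
        np.testing.assert_allclose(obs.posterior(), w / w.sum(), atol=1e-12)

    def test_hybrid_with_zero_weights_equals_bayes(self):
        seq = [A, B, A, A]
        pure = run_updates(QGridPosterior(1, 0.0, 0.0), seq)
        # lambda_p = 0 makes filtered counts equal exact counts
        np.testing.assert_array_equal(pure.filtered_counts, pure.exact_counts)
        q = grid_axis(1)
        # sequence A B A A: counts AA=1, AB=1, BA=1, BB=0; the posterior
        # factorises over contexts (axis 0 = q_B, axis 1 = q_A)
        np.testing.assert_array_equal(pure.exact_counts, [0, 1, 1, 1])
        w = np.outer(q, q * (1 - q))
        np.testing.assert_allclose(pure.posterior(), w / w.sum(), atol=1e-12)

    def test_fresh_predictive_is_half(self):
        assert QGridPosterior(0, 0.8).predictive() == pytest.approx(0.5)

    def test_concentrated_posterior_predictive(self):
        obs = QGridPosterior(0, 0.0, 0.0)
        obs.exact_counts = np.array([2000.0, 8000.0])
        obs.t = 10_000
        assert obs.predictive() == pytest.approx(0.8, abs=1e-3)

    def test_biased_mode_under_unpredictability_cost(self, rng):
        obs = QGridPosterior(0, 1.0, 0.0)
        for x in (rng.random(3000) < 0.7).astype(int):
            obs.update(x)
        assert obs.map_estimate()[0] > 0.75  # pushed beyond the true 0.7

    def test_unbiased_at_half_with_weak_cost(self, rng):
        obs = QGridPosterior(0, 0.5, 0.0)
        for x in (rng.random(4000) < 0.5).astype(int):
            obs.update(x)
        assert abs(obs.map_estimate()[0] - 0.5) < 0.05

    def test_discounted_time_recursion(self):
        lam = 0.8
        gamma = 1 / (1 + lam)
        obs = run_updates(QGridPosterior(0, 0.3, lam), [A, B, A, A, B])
        assert obs.S == pytest.approx(gamma * (1 - gamma ** 5) / (1 - gamma))

    def test_json_roundtrip(self):
        obs = run_updates(QGridPosterior(1, 0.6, 0.4), [A, B, B, A, A])
        clone = QGridPosterior.from_json(obs.to_json())
        assert clone.predictive() == obs.predictive()
        assert clone.t == obs.t and clone.S == obs.S


class TestEngineMatchesStatefulObservers:
    """The vectorised path used by fitting/simulation must reproduce the
    trial-by-trial reference to floating-point accuracy."""

    @pytest.mark.parametrize("spec", [
        ModelSpec.precision(0, 0.0), ModelSpec.precision(0, 0.7),
        ModelSpec.precision(1, 1.3), ModelSpec.precision(2, 0.4),
        ModelSpec.precision(3, 0.9),
        ModelSpec.unpredictability(0, 0.8), ModelSpec.unpredictability(1, 1.5),
        ModelSpec.unpredictability(2, 0.6),
        ModelSpec.hybrid(0, 0.5, 0.5), ModelSpec.hybrid(1, 0.9, 0.3),
    ])
    def test_paths_agree(self, spec, rng):
        from costbayes.observers import make_observer
        stim = (rng.random(70) < 0.65).astype(np.int8)
        n_skip = 15
        obs = make_observer(spec)
        ref = []
        for t, x in enumerate(stim):
            if t >= n_skip:
                ref.append(obs.predictive())
            obs.update(int(x))
        eng = predictive_path(spec, stim, n_skip)
        np.testing.assert_allclose(eng, ref, atol=1e-10)


def _power_iteration_stationary(q, m, n_iter=20_000):
    """Independent oracle: iterate the context chain to its fixed point."""
    n = 2 ** m
    M = np.zeros((n, n))
    for c in range(n):
        M[c, ((c << 1) | 1) & (n - 1)] += q[c]
        M[c, (c << 1) & (n - 1)] += 1 - q[c]
    pi = np.full(n, 1.0 / n)
    for _ in range(n_iter):
        new = pi @ M
        if np.max(np.abs(new - pi)) < 1e-15:
            return new
        pi = new
    return pi


class TestStationaryDistribution:
    def test_iid_chain_recovers_q(self):
        pi = stationary_distribution(np.array([0.3, 0.3]), 1)
        np.testing.assert_allclose(pi, [0.7, 0.3], atol=1e-12)

    def test_order1_closed_form(self):
        # q = (q_B, q_A) = (0.3, 0.9): p_A = q_B / (1 + q_B - q_A) = 0.75
        pi = stationary_distribution(np.array([0.3, 0.9]), 1)
        np.testing.assert_allclose(pi, [0.25, 0.75], atol=1e-12)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_matches_power_iteration_oracle(self, m, rng):
        for _ in range(50):
            q = rng.random(2 ** m)
            pi = stationary_distribution(q, m)
            oracle = _power_iteration_stationary(np.clip(q, 1e-9, 1 - 1e-9), m)
            assert pi.min() >= 0 and pi.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(pi, oracle, atol=1e-10)

    def test_reducible_corner_handled_without_nan(self):
        pi = stationary_distribution(np.array([0.0, 1.0]), 1)
        assert np.all(np.isfinite(pi))
        np.testing.assert_allclose(pi.sum(), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([1.2, 0.5]), 1)


class TestImpliedEntropy:
    def test_bernoulli_limits(self):
        assert implied_entropy(np.array(0.5), 0) == pytest.approx(np.log(2))
        assert implied_entropy(np.array(0.0), 0) == 0.0
        assert implied_entropy(np.array(1.0), 0) == 0.0

    def test_order1_weighted_conditional_entropies(self):
        got = implied_entropy(np.array([0.3, 0.9]), 1)
        expected = 0.75 * binary_entropy(0.9) + 0.25 * binary_entropy(0.3)
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m", [1, 2])
    def test_invariant_under_outcome_relabeling(self, m, rng):
        # swapping A and B maps context c to its bitwise complement and
        # q_c to 1 - q_c; the entropy of the chain is unchanged
        n = 2 ** m
        for _ in range(25):
            q = rng.random(n)
            q_rel = np.empty(n)
            for c in range(n):
                q_rel[(n - 1) ^ c] = 1 - q[c]
            assert implied_entropy(q, m) == pytest.approx(
                implied_entropy(q_rel, m), abs=1e-12)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_range(self, qa, qb):
        h = implied_entropy(np.array([qb, qa]), 1)
        assert -1e-12 <= h <= np.log(2) + 1e-12


class TestAsymptoticMode:
    def test_costfree_mode_is_truth(self):
        assert asymptotic_mode(0.7, 0.0) == pytest.approx(0.7, abs=1e-9)

    def test_equiprobable_weak_cost_unbiased(self):
        assert asymptotic_mode(0.5, 0.5) == pytest.approx(0.5, abs=1e-9)

    def test_matches_fine_grid_oracle(self):
        p, lam = 0.7, 1.0
        qs = np.arange(1e-5, 1.0, 1e-5)
        obj = p * np.log(qs) + (1 - p) * np.log1p(-qs) - lam * binary_entropy(qs)
        oracle = qs[np.argmax(obj)]
        assert asymptotic_mode(p, lam) == pytest.approx(oracle, abs=1e-5)

    def test_bistable_regime_flagged(self):
        with pytest.raises(BistableModeError) as exc:
            asymptotic_mode(0.5, 1.5)
        lo, hi = sorted(exc.value.modes)
        assert lo < 0.5 < hi and lo + hi == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(0.05, 0.95), st.floats(0.0, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_mode_at_least_as_extreme_as_truth(self, p, lam):
        try:
            q = asymptotic_mode(p, lam)
        except BistableModeError:
            return
        assert abs(q - 0.5) >= abs(p - 0.5) - 1e-6
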