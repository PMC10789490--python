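import numpy as np
import pandas as pd
import pytest

from costbayes import (CostlyInferenceModel, ModelSpec, fit_mle,
                       information_criteria, simulate_subject, trial_log_likelihood)
from costbayes.io import filter_blocks
from costbayes.observers import make_observer
from costbayes.response import choice_probability, choice_probability_with_propensity

from conftest import make_block_table


class TestTrialLogLikelihood:
    def test_coin_flip_model(self, precision_subject):
        spec = ModelSpec.precision(0, 1.0, kappa=0.0)
        res = trial_log_likelihood(spec, precision_subject)
        assert res.total == pytest.approx(res.n_obs * np.log(0.5), abs=1e-9)

    def test_hand_computed_laplace_fixture(self):
        # passive AABAA, then three active trials with stimuli B, A and
        # responses A, B, A under the cost-free m=0 matching observer:
        # contributions 5/7 (counts 4A,1B), 1 - 5/8 (4A,2B), 6/9 (5A,2B)
        stimuli = [1, 1, 0, 1, 1, 0, 1, 1]
        responses = [1, 0, 1]
        tab = make_block_table(stimuli, responses, n_passive=5)
        res = trial_log_likelihood(ModelSpec.precision(0, 0.0, 1.0), tab)
        expected = np.log(5 / 7) + np.log(3 / 8) + np.log(6 / 9)
        assert res.total == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(
            res.per_trial, [np.log(5 / 7), np.log(3 / 8), np.log(6 / 9)], atol=1e-12)

    def test_missed_trials_update_state_but_score_nothing(self):
        stimuli = [1, 1, 0, 1, 1, 0, 1, 1]
        full = make_block_table(stimuli, [1, 0, 1], n_passive=5)
        holed = make_block_table(stimuli, [1, None, 1], n_passive=5)
        spec = ModelSpec.precision(0, 0.0, 1.0)
        r_full = trial_log_likelihood(spec, full)
        r_holed = trial_log_likelihood(spec, holed)
        assert r_holed.n_obs == r_full.n_obs - 1
        # remaining contributions identical: the missed stimulus still counted
        np.testing.assert_allclose(r_holed.per_trial, r_full.per_trial[[0, 2]],
                                   atol=1e-12)

    @pytest.mark.parametrize("spec", [
        ModelSpec.precision(1, 0.8, 2.2),
        ModelSpec.unpredictability(1, 1.1, 1.7),
        ModelSpec.hybrid(0, 0.5, 0.7, 2.0),
    ])
    def test_relabeling_invariance(self, spec, small_design):
        tab = simulate_subject(spec, small_design, seed=4)
        flipped = tab.copy()
        flipped["stimulus"] = 1 - flipped["stimulus"]
        flipped["response"] = 1.0 - flipped["response"]
        flipped["p"] = 1.0 - flipped["p"]
        a = trial_log_likelihood(spec, tab).total
        b = trial_log_likelihood(spec, flipped).total
        assert a == pytest.approx(b, abs=1e-9)

    def test_contributions_nonpositive_and_finite(self, precision_subject):
        res = trial_log_likelihood(ModelSpec.unpredictability(1, 0.9, 2.0),
                                   precision_subject)
        assert np.all(res.per_trial <= 0) and np.all(np.isfinite(res.per_trial))

    @pytest.mark.parametrize("spec", [
        ModelSpec.precision(1, 0.6, 2.5, eta=0.2),
        ModelSpec.unpredictability(0, 1.2, 1.5),
        ModelSpec.unpredictability(1, 0.7, 2.8),
        ModelSpec.hybrid(1, 0.4, 0.8, 2.0),
    ])
    def test_cached_engine_matches_naive_recomputation(self, spec, small_design):
        """Grid caching/vectorisation must not change the likelihood (1e-10)."""
        tab = simulate_subject(spec, small_design, seed=11, missed_rate=0.05)
        fast = trial_log_likelihood(spec, tab).total
        # naive: stateful observer loop, trial by trial
        total = 0.0
        for _, blk in tab.groupby("block_index"):
            blk = blk.sort_values("trial_index")
            obs = make_observer(spec)
            prev = None
            for _, row in blk.iterrows():
                if row["phase"] == "active":
                    cp = choice_probability(obs.predictive(), spec.kappa)
                    if spec.eta != 0:
                        cp = choice_probability_with_propensity(cp, prev, spec.eta)
                    if np.isfinite(row["response"]):
                        total += np.log(cp if row["response"] == 1.0 else 1 - cp)
                        prev = row["response"]
                obs.update(int(row["stimulus"]))
        assert fast == pytest.approx(total, abs=1e-10)


class TestInformationCriteria:
    def test_unit_sample_size_gives_zero_penalty(self):
        assert information_criteria(0.0, 2, 1) == (0.0, 0.0)

    def test_forced_arithmetic(self):
        bic, lev = information_criteria(-100.0, 2, int(round(np.exp(2))))
        n = int(round(np.exp(2)))
        assert bic == pytest.approx(200 + 2 * np.log(n))
        assert lev == pytest.approx(-100 - np.log(n))
        assert bic == pytest.approx(-2 * lev)

    def test_extra_parameter_penalised(self):
        bic2, _ = information_criteria(-50.0, 2, 100)
        bic3, _ = information_criteria(-50.0, 3, 100)
        assert bic3 > bic2


class TestFitMle:
    def test_true_model_beats_coin_flip(self, precision_subject):
        res = fit_mle(ModelSpec.precision(0), precision_subject)
        null = trial_log_likelihood(
            ModelSpec.precision(0, 1.0, kappa=0.0), precision_subject)
        assert res.log_likelihood > null.total

    def test_coin_flip_subject_flags_unidentifiable_lambda(self):
        tab = simulate_subject(ModelSpec.precision(0, 1.0, kappa=0.0), seed=5)
        res = fit_mle(ModelSpec.precision(0), tab)
        assert res.spec.kappa < 0.1
        assert not res.lambda_identifiable

    def test_informative_subject_has_identifiable_lambda(self, precision_subject):
        assert fit_mle(ModelSpec.precision(0), precision_subject).lambda_identifiable

    def test_fit_is_deterministic(self, small_design):
        tab = simulate_subject(ModelSpec.precision(0, 1.0, 2.0), small_design, seed=6)
        r1 = fit_mle(ModelSpec.precision(0), tab)
        r2 = fit_mle(ModelSpec.precision(0), tab)
        assert r1.spec == r2.spec and r1.log_likelihood == r2.log_likelihood

    def test_bic_consistency(self, precision_subject):
        res = fit_mle(ModelSpec.precision(0), precision_subject)
        assert res.bic == pytest.approx(-2 * res.log_evidence)
        assert res.n_obs == 2000

    def test_cost_factor_correlates_across_probability_ranges(self):
        # subjects with diverse decay rates: their fitted ln(1+lambda) on
        # medium-probability blocks should track the fit on extreme blocks
        rng = np.random.default_rng(42)
        lams_med, lams_ext = [], []
        for i in range(12):
            lam = float(np.exp(rng.uniform(np.log(0.1), np.log(3.0))))
            tab = simulate_subject(ModelSpec.precision(0, lam, 2.0), rng=rng,
                                   subject_id=f"s{i}")
            for which, store in (("medium", lams_med), ("extreme", lams_ext)):
                sub = filter_blocks(tab, which)
                res = fit_mle(ModelSpec.precision(0), sub)
                store.append(np.log1p(res.spec.lambda_p))
        r = np.corrcoef(lams_med, lams_ext)[0, 1]
        assert r > 0.5


class TestEstimator:
    def test_sklearn_params_roundtrip(self):
        est = CostlyInferenceModel(cost="unpredictability", m=1)
        params = est.get_params()
        assert params["cost"] == "unpredictability" and params["m"] == 1
        est.set_params(m=0)
        assert est.m == 0

    def test_fit_sets_attributes_and_predicts(self, small_design):
        tab = simulate_subject(ModelSpec.precision(0, 1.0, 2.0), small_design, seed=8)
        est = CostlyInferenceModel(cost="precision", m=0).fit(tab)
        assert est.lambda_p_ > 0 and est.kappa_ > 0
        assert est.log_likelihood_ <= 0
        proba = est.predict_proba(tab)
        n_active = (tab["phase"] == "active").sum()
        assert proba.shape == (n_active, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert est.score(tab) == pytest.approx(est.log_likelihood_ / est.n_obs_)

    def test_unfitted_estimator_raises(self, precision_subject):
        with pytest.raises(AttributeError):
            CostlyInferenceModel().predict_proba(precision_subject)
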