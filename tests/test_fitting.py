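"""Model fitting: cross-entropy, BIC, PSO behaviour and recovery."""

import dataclasses

import numpy as np
import pytest

import volatok as v
from volatok.fitting import PARAM_BOUNDS, _batch_objective


class TestCrossEntropy:
    def test_chance_predictions(self):
        n = 64
        choices = np.where(np.arange(n) % 2 == 0, 1, -1)
        assert v.cross_entropy(choices, np.full(n, 0.5)) == pytest.approx(
            n * np.log(2)
        )

    def test_perfect_prediction_approaches_zero(self):
        choices = np.array([1, -1, 1])
        p = np.array([1 - 1e-12, 1e-12, 1 - 1e-12])
        assert v.cross_entropy(choices, p) < 1e-6

    def test_hand_computed_example(self):
        e = v.cross_entropy(np.array([1, -1]), np.array([0.8, 0.4]))
        assert e == pytest.approx(-(np.log(0.8) + np.log(0.6)), abs=1e-12)
        assert e == pytest.approx(0.7340, abs=1e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            v.cross_entropy(np.array([1, -1]), np.array([0.5]))


class TestBIC:
    def test_arithmetic(self):
        assert v.bic(50.0, 2, 100) == pytest.approx(100 + 2 * np.log(100))
        assert v.bic(50.0, 2, 100) == pytest.approx(109.2103, abs=1e-4)

    def test_zero_parameters(self):
        assert v.bic(7.0, 0, 10) == 14.0

    def test_monotone_in_k(self):
        assert v.bic(5.0, 3, 50) > v.bic(5.0, 2, 50)

    def test_identity_holds_in_fit_results(self, small_trialset):
        rng = np.random.default_rng(0)
        traces = v.run_observer_set(small_trialset, v.ObserverParams())
        choices = v.simulate_choices(traces.L_final, 1.0, rng)
        fit = v.fit_model(small_trialset, choices, "perfect",
                          v.FitConfig(n_particles=20, max_iters=30, seed=1))
        assert fit.bic == pytest.approx(
            2 * fit.cross_entropy + fit.k_free * np.log(fit.n_trials_fit)
        )


class TestBatchObjective:
    """The swarm objective must agree with the scalar observer pathway."""

    @pytest.mark.parametrize("kind", ["normative", "perfect", "bounded", "leaky"])
    def test_matches_single_observer_route(self, small_trialset, kind):
        rng = np.random.default_rng(5)
        gen = v.run_observer_set(small_trialset, v.ObserverParams())
        choices = v.simulate_choices(gen.L_final, 1.0, rng)
        names = list(PARAM_BOUNDS[kind])
        thetas = []
        expected = []
        for i in range(4):
            lo = np.array([b[0] for b in PARAM_BOUNDS[kind].values()])
            hi = np.array([b[1] for b in PARAM_BOUNDS[kind].values()])
            theta = lo + (hi - lo) * rng.random(len(lo)) * 0.4
            params = v.ObserverParams(model_kind=kind, **dict(zip(names, theta)))
            traces = v.run_observer_set(small_trialset, params)
            p = v.choice_probability(traces.L_final, params.noise)
            expected.append(v.cross_entropy(choices, p))
            thetas.append(theta)
        got = _batch_objective(
            np.array(thetas), kind, small_trialset.llr, small_trialset.mask,
            small_trialset.n_samples, choices,
        )
        np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestFitModel:
    def test_deterministic_for_fixed_seed(self, small_trialset):
        rng = np.random.default_rng(2)
        traces = v.run_observer_set(small_trialset, v.ObserverParams())
        choices = v.simulate_choices(traces.L_final, 1.0, rng)
        cfg = v.FitConfig(n_particles=15, max_iters=25, seed=42)
        a = v.fit_model(small_trialset, choices, "normative", cfg)
        b = v.fit_model(small_trialset, choices, "normative", cfg)
        assert a.cross_entropy == b.cross_entropy
        assert a.best_params == b.best_params
        np.testing.assert_array_equal(a.convergence, b.convergence)

    def test_random_choices_yield_chance_entropy_and_large_noise(self):
        ts = v.generate_trials(v.TaskConfig(n_trials=600, seed=31))
        rng = np.random.default_rng(32)
        choices = rng.choice([-1, 1], size=len(ts))
        fit = v.fit_model(ts, choices, "normative",
                          v.FitConfig(n_particles=40, max_iters=120, seed=33))
        assert fit.cross_entropy == pytest.approx(len(ts) * np.log(2), rel=0.02)
        assert fit.best_params.noise > 3.0

    def test_fit_beats_generating_parameters_on_convergence(self, small_trialset):
        true = v.ObserverParams(h_subj=0.1, gain=1.0, noise=1.0)
        traces = v.run_observer_set(small_trialset, true)
        rng = np.random.default_rng(7)
        choices = v.simulate_choices(traces.L_final, true.noise, rng)
        fit = v.fit_model(small_trialset, choices, "normative",
                          v.FitConfig(n_particles=60, max_iters=250, seed=8))
        e_true = v.cross_entropy(
            choices, v.choice_probability(traces.L_final, true.noise)
        )
        assert fit.cross_entropy <= e_true + 1e-6 * len(small_trialset)

    def test_unknown_model_rejected(self, small_trialset):
        with pytest.raises(ValueError):
            v.fit_model(small_trialset, np.ones(len(small_trialset)), "nope")

    def test_choices_length_checked(self, small_trialset):
        with pytest.raises(ValueError):
            v.fit_model(small_trialset, np.ones(5), "perfect")


class TestRecovery:
    def test_hazard_recovery_small_cohort(self):
        """Group-mean subjective hazard lands near the generative value."""
        rep = v.recover_parameters(
            v.ObserverParams(h_subj=0.1, gain=1.0, noise=1.0),
            v.TaskConfig(n_trials=720),
            n_agents=4,
            fit_config=v.FitConfig(n_particles=40, max_iters=120),
            seed=55,
        )
        assert abs(rep.attrs["summary"]["h_subj"]["mean_fit"] - 0.1) < 0.05

    def test_zero_noise_agents_fit_with_matching_accuracy(self):
        ts = v.generate_trials(v.TaskConfig(n_trials=800, seed=61))
        traces = v.run_observer_set(ts, v.ObserverParams())
        choices = np.where(traces.L_final >= 0, 1, -1)  # noise -> 0 limit
        fit = v.fit_model(ts, choices, "normative",
                          v.FitConfig(n_particles=50, max_iters=200, seed=62))
        pred = v.run_observer_set(ts, fit.best_params)
        pred_choice = np.where(pred.L_final >= 0, 1, -1)
        agent_acc = np.mean(choices == np.sign(ts.final_state))
        model_acc = np.mean(pred_choice == np.sign(ts.final_state))
        # gain and noise trade off; effective determinism is noise per unit
        # of accumulated (gain-scaled) evidence
        assert fit.best_params.noise / fit.best_params.gain < 0.5
        assert model_acc >= agent_acc - 0.01


class TestCompareModels:
    def test_single_model_ranking(self, small_trialset):
        rng = np.random.default_rng(9)
        traces = v.run_observer_set(small_trialset, v.ObserverParams())
        choices = v.simulate_choices(traces.L_final, 1.0, rng)
        fit = v.fit_model(small_trialset, choices, "perfect",
                          v.FitConfig(n_particles=15, max_iters=20, seed=10))
        tab = v.compare_models({"perfect": fit})
        assert len(tab) == 1 and tab["delta_bic"].iloc[0] == 0.0

    def test_normative_data_prefers_normative_model(self):
        """Model recovery: data from the normative agent picks it by BIC."""
        wins = 0
        n_agents = 3
        for seed in range(n_agents):
            ts = v.generate_trials(v.TaskConfig(n_trials=1440, seed=700 + seed))
            traces = v.run_observer_set(ts, v.ObserverParams())
            rng = np.random.default_rng(800 + seed)
            choices = v.simulate_choices(traces.L_final, 1.0, rng)
            cfg = v.FitConfig(n_particles=40, max_iters=150, seed=900 + seed)
            fits = {
                kind: v.fit_model(ts, choices, kind, cfg)
                for kind in ("normative", "perfect", "leaky")
            }
            tab = v.compare_models(fits)
            wins += tab["model_kind"].iloc[0] == "normative"
        assert wins >= 2

    def test_mismatched_trial_counts_rejected(self, small_trialset):
        rng = np.random.default_rng(3)
        traces = v.run_observer_set(small_trialset, v.ObserverParams())
        choices = v.simulate_choices(traces.L_final, 1.0, rng)
        cfg = v.FitConfig(n_particles=10, max_iters=10, seed=1)
        f1 = v.fit_model(small_trialset, choices, "perfect", cfg)
        other = v.generate_trials(v.TaskConfig(n_trials=300, seed=77))
        ch2 = np.ones(300)
        f2 = v.fit_model(other, ch2, "perfect", cfg)
        with pytest.raises(ValueError):
            v.compare_models({"a": f1, "b": f2})
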