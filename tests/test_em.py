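"""Unit and property tests for the constrained mixture EM engine."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from tetradose.datamodel import (PANEL_HW, MarkerSignals, Population,
                                 PopulationStructure)
from tetradose.em import (EMConfig, EMError, IDEAL_MU, MU_CONSTRAINTS,
                          MeanParameterization, MixtureModel, P_F1, P_FIXED,
                          P_FREE, P_HW, PosteriorMatrix, count_parameters,
                          default_start, e_step, fit_mean_parameterization,
                          m_step_mu_sigma, m_step_pi, mixture_density,
                          modal_dosage, observed_loglik, run_em,
                          spiked_proportions)
from tetradose.simulate import simulate_marker

from _oracle import oracle_posteriors
from conftest import panel_sim_spec


def _panel_marker(y, pi=None):
    """Wrap raw transformed values as a one-panel marker."""
    n = len(y)
    samples = [f"s{i}" for i in range(n)]
    ms = MarkerSignals("m", samples, np.ones(n), np.ones(n),
                       np.full(n, 0.5), np.asarray(y, dtype=float))
    structure = PopulationStructure(
        populations={"PANEL": Population("PANEL", PANEL_HW)},
        assignments={s: "PANEL" for s in samples})
    model = MixtureModel(
        mu=np.array([0.15, 0.5, 0.8, 1.1, 1.4]), sigma2=0.002,
        pi={"PANEL": pi if pi is not None
            else np.full(5, 0.2)})
    return ms, structure, model


class TestMixtureDensity:
    def test_single_component_peak(self):
        _, _, model = _panel_marker([0.5])
        model.pi["PANEL"] = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        val = mixture_density(model.mu[2], model, "PANEL")
        assert val == pytest.approx(1 / np.sqrt(2 * np.pi * model.sigma2))

    def test_matches_hand_computed_sum(self):
        _, _, model = _panel_marker([0.5])
        y = 0.73
        expected = sum(0.2 * norm.pdf(y, model.mu[j],
                                      np.sqrt(model.sigma2))
                       for j in range(5))
        assert mixture_density(y, model, "PANEL") == pytest.approx(expected)

    def test_integrates_to_one(self):
        _, _, model = _panel_marker([0.5])
        total, _ = quad(lambda y: mixture_density(y, model, "PANEL"),
                        -2.0, 4.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_unknown_population(self):
        _, _, model = _panel_marker([0.5])
        with pytest.raises(Exception):
            mixture_density(0.5, model, "NOPE")


class TestEStep:
    def test_dominant_component(self):
        ms, structure, model = _panel_marker([0.8])
        post = e_step(ms, structure, model)
        assert post.values[0, 2] > 0.999  # index 2 <-> dosage 2

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        ms, structure, model = _panel_marker(rng.uniform(0, np.pi / 2, 50))
        post = e_step(ms, structure, model)
        np.testing.assert_allclose(post.values.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0, np.pi / 2, 30)
        ms, structure, model = _panel_marker(y)
        post = e_step(ms, structure, model)
        expected = oracle_posteriors(y, model.mu, model.sigma2,
                                     model.pi["PANEL"])
        np.testing.assert_allclose(post.values, expected, atol=1e-10)

    def test_missing_rows_flagged(self):
        ms, structure, model = _panel_marker([0.5, np.nan, 0.8])
        post = e_step(ms, structure, model)
        assert not post.observed[1]
        assert np.isnan(post.values[1]).all()

    def test_all_missing_errors(self):
        ms, structure, model = _panel_marker([np.nan, np.nan])
        with pytest.raises(EMError, match="no observations"):
            e_step(ms, structure, model)


class TestMStepPi:
    def test_free_all_first_component(self):
        ms, structure, _ = _panel_marker([0.1] * 4)
        post = PosteriorMatrix(
            values=np.tile([1.0, 0, 0, 0, 0], (4, 1)),
            observed=np.ones(4, dtype=bool))
        pi = m_step_pi(post, ms, structure, {"PANEL": P_FREE},
                       {"PANEL": np.full(5, 0.2)})
        np.testing.assert_allclose(pi["PANEL"], [1, 0, 0, 0, 0])

    def test_hw_mean_dosage_two(self):
        ms, structure, _ = _panel_marker([0.5] * 4)
        post = PosteriorMatrix(
            values=np.tile([0, 0, 1.0, 0, 0], (4, 1)),
            observed=np.ones(4, dtype=bool))
        pi = m_step_pi(post, ms, structure, {"PANEL": P_HW},
                       {"PANEL": np.full(5, 0.2)})
        np.testing.assert_allclose(pi["PANEL"],
                                   np.array([1, 4, 6, 4, 1]) / 16)

    def test_f1_from_parental_modes(self, family_structure):
        samples = list(family_structure.assignments)
        n = len(samples)
        y = np.full(n, 0.5)
        ms = MarkerSignals("m", samples, np.ones(n), np.ones(n),
                           np.full(n, 0.5), y)
        values = np.zeros((n, 5))
        for i, s in enumerate(samples):
            pop = family_structure.population_of(s)
            if pop == "P1":
                values[i, 2] = 1.0  # duplex parent
            elif pop == "P2":
                values[i, 4] = 1.0  # quadruplex parent
            else:
                values[i] = 0.2
        post = PosteriorMatrix(values=values, observed=np.ones(n, dtype=bool))
        constraints = {"P1": P_FREE, "P2": P_FREE, "F1": P_F1,
                       "PANEL": P_FREE}
        current = {p: np.full(5, 0.2) for p in constraints}
        pi = m_step_pi(post, ms, family_structure, constraints, current)
        # duplex x quadruplex segregates 0:0:1:4:1
        np.testing.assert_allclose(pi["F1"], np.array([0, 0, 1, 4, 1]) / 6)

    def test_fixed_unchanged(self, family_structure):
        samples = list(family_structure.assignments)
        n = len(samples)
        ms = MarkerSignals("m", samples, np.ones(n), np.ones(n),
                           np.full(n, 0.5), np.full(n, 0.5))
        post = PosteriorMatrix(values=np.full((n, 5), 0.2),
                               observed=np.ones(n, dtype=bool))
        spiked = spiked_proportions(3)
        constraints = {"P1": P_FIXED, "P2": P_FREE, "F1": P_FREE,
                       "PANEL": P_FREE}
        current = {p: np.full(5, 0.2) for p in constraints}
        current["P1"] = spiked
        pi = m_step_pi(post, ms, family_structure, constraints, current)
        np.testing.assert_array_equal(pi["P1"], spiked)

    def test_vectors_sum_to_one(self, family_structure):
        rng = np.random.default_rng(3)
        samples = list(family_structure.assignments)
        n = len(samples)
        ms = MarkerSignals("m", samples, np.ones(n), np.ones(n),
                           np.full(n, 0.5), rng.uniform(0, 1.5, n))
        raw = rng.random((n, 5))
        post = PosteriorMatrix(values=raw / raw.sum(1, keepdims=True),
                               observed=np.ones(n, dtype=bool))
        constraints = {"P1": P_FREE, "P2": P_FREE, "F1": P_F1,
                       "PANEL": P_HW}
        current = {p: np.full(5, 0.2) for p in constraints}
        pi = m_step_pi(post, ms, family_structure, constraints, current)
        for v in pi.values():
            assert v.sum() == pytest.approx(1.0, abs=1e-9)


class TestModalDosage:
    def test_plain_argmax(self):
        assert modal_dosage(np.array([0.1, 0.5, 0.2, 0.1, 0.1])) == 1

    def test_tie_breaks_toward_mean(self):
        # tie between 0 and 4; mean dosage pulled right by mass at 3
        w = np.array([0.35, 0.0, 0.0, 0.3, 0.35])
        assert modal_dosage(w) == 4

    def test_tie_breaks_low_when_symmetric(self):
        w = np.array([0.4, 0.1, 0.0, 0.1, 0.4])
        assert modal_dosage(w) == 0


class TestMStepMuSigma:
    def test_free_recovers_group_means(self):
        y = np.array([0.2, 0.5, 0.8, 1.1, 1.4])
        ms, _, _ = _panel_marker(y)
        values = np.eye(5)
        post = PosteriorMatrix(values=values, observed=np.ones(5, dtype=bool))
        mu, sigma2, _ = m_step_mu_sigma(ms, post, "free", None, IDEAL_MU)
        np.testing.assert_allclose(mu, y)

    def test_zero_background_linear_is_ideal(self):
        mp = MeanParameterization(0.0, 0.0, 0.0)
        np.testing.assert_allclose(mp.mu(), IDEAL_MU)

    @pytest.mark.parametrize("truth", [
        MeanParameterization(0.3, 0.1, 0.0),
        MeanParameterization(0.2, 0.2, 0.15),
        MeanParameterization(0.05, 0.4, 0.3),
    ])
    def test_parameter_recovery(self, truth):
        # hard posteriors at the implied means recover (c_a, c_b, k)
        constraint = ("background_unequal_quadratic" if truth.k > 0
                      else "background_unequal_linear")
        weights = np.array([50.0, 80, 120, 80, 50])
        fitted = fit_mean_parameterization(weights, truth.mu(), constraint)
        np.testing.assert_allclose(fitted.mu(), truth.mu(), atol=1e-6)
        assert fitted.c_a == pytest.approx(truth.c_a, abs=1e-4)
        assert fitted.c_b == pytest.approx(truth.c_b, abs=1e-4)

    def test_constrained_means_always_increasing(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mp = MeanParameterization(*rng.uniform(0, 2, 2), rng.uniform(0, 1))
            assert np.all(np.diff(mp.mu()) > 0)


class TestRunEM:
    def test_recovers_well_separated_components(self):
        signals, structure, truth = simulate_marker(
            panel_sim_spec(seed=10, n=500, sigma=0.03), 0)
        model, post = run_em(signals, structure, "free",
                             {"PANEL": P_FREE})
        assert model.converged
        np.testing.assert_allclose(model.mu, IDEAL_MU, atol=0.02)
        calls = np.argmax(post.values, axis=1)
        assert (calls == truth).mean() >= 0.99

    def test_loglik_monotone_all_constraints(self):
        signals, structure, _ = simulate_marker(
            panel_sim_spec(seed=11, n=200), 0)
        for muc in MU_CONSTRAINTS:
            for pic in (P_FREE, P_HW):
                model, _ = run_em(signals, structure, muc, {"PANEL": pic})
                diffs = np.diff(model.loglik_trace)
                assert diffs.min() > -1e-8, (muc, pic)

    def test_one_component_degenerate(self):
        rng = np.random.default_rng(12)
        ms, structure, _ = _panel_marker(rng.normal(0.78, 0.02, 100))
        model, _ = run_em(ms, structure, "free", {"PANEL": P_FREE})
        assert model.converged
        assert model.pi["PANEL"].max() > 0.95

    def test_too_few_observations(self):
        ms, structure, _ = _panel_marker([0.5, 0.7, np.nan])
        with pytest.raises(EMError, match="min_samples"):
            run_em(ms, structure, "free", {"PANEL": P_FREE},
                   config=EMConfig(min_samples=10))

    def test_bic_identity(self):
        signals, structure, _ = simulate_marker(
            panel_sim_spec(seed=13, n=150), 0)
        model, _ = run_em(signals, structure, "free", {"PANEL": P_FREE})
        n_obs = signals.n_observed
        assert model.bic == pytest.approx(
            -2 * model.loglik + model.n_params * np.log(n_obs))
        assert model.n_params == 1 + 5 + 4


class TestParameterCounts:
    @pytest.mark.parametrize("muc,expected", [
        ("free", 5), ("background_equal_linear", 2),
        ("background_unequal_linear", 3),
        ("background_equal_quadratic", 3),
        ("background_unequal_quadratic", 4)])
    def test_mu_counts(self, muc, expected):
        assert count_parameters(muc, {}) == 1 + expected

    def test_pi_counts(self):
        constraints = {"A": P_FREE, "B": P_HW, "C": P_FIXED, "D": P_F1}
        assert count_parameters("free", constraints) == 1 + 5 + 4 + 1 + 0 + 0

    def test_masked_counts(self):
        mask = np.array([False, True, True, True, True])
        assert count_parameters("free", {"A": P_FREE}, mask) == 1 + 4 + 3
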