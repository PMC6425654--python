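"""Model grid, selection, re-evaluation and dosage-calling logic."""

import numpy as np
import pytest

from tetradose.calling import (GridEntry, MarkerResult, STATUS_CALLED,
                               STATUS_NO_MODEL, STATUS_SINGLE_CATEGORY,
                               STATUS_TOO_MANY_NA, build_model_grid,
                               call_dosages, fit_marker, select_model,
                               starting_mu_from_priors)
from tetradose.config import RunConfig
from tetradose.datamodel import MarkerSignals
from tetradose.em import (MixtureModel, P_F1, P_FIXED, P_FREE, P_HW,
                          PosteriorMatrix)
from tetradose.simulate import make_test_layout, simulate_marker


FAST = RunConfig(min_samples=10, em_max_iter=300)


class TestBuildModelGrid:
    def test_panel_only_ten_combos(self, panel_structure):
        grid = build_model_grid(panel_structure, priors_present=False)
        assert len(grid) == 10
        pi_sets = {entry.pi_constraints for entry in grid}
        assert (("PANEL", P_HW),) in pi_sets
        assert (("PANEL", P_FREE),) in pi_sets

    def test_family_with_priors_has_fixed_and_free_parents(
            self, family_structure):
        grid = build_model_grid(family_structure, priors_present=True)
        parent_regimes = {dict(e.pi_constraints)["P1"] for e in grid}
        assert parent_regimes == {P_FIXED, P_FREE}
        assert any(e.uses_priors for e in grid)
        assert any(not e.uses_priors for e in grid)
        assert len(grid) == 5 * 2 * 2 * 2

    def test_grid_is_deterministic(self, family_structure):
        g1 = build_model_grid(family_structure, True)
        g2 = build_model_grid(family_structure, True)
        assert g1 == g2


class TestStartingMeansFromPriors:
    def test_line_through_zero_and_four(self):
        mu = starting_mu_from_priors(0, 4, 0.1, 1.45)
        np.testing.assert_allclose(mu, [0.1, 0.4375, 0.775, 1.1125, 1.45])

    def test_two_four_extrapolates(self):
        mu = starting_mu_from_priors(2, 4, 0.8, 1.4)
        assert mu[2] == pytest.approx(0.8)
        assert mu[4] == pytest.approx(1.4)
        assert mu[0] == pytest.approx(max(0.8 - 2 * 0.3, 1e-3))
        assert np.all(np.diff(mu) > 0)

    def test_equal_priors_degenerate(self):
        assert starting_mu_from_priors(2, 2, 0.7, 0.75) is None

    def test_decreasing_line_rejected(self):
        assert starting_mu_from_priors(0, 4, 1.2, 0.3) is None


def _fit(bic, n_params, converged=True):
    m = MixtureModel(mu=np.linspace(0.1, 1.4, 5), sigma2=0.01,
                     pi={"PANEL": np.full(5, 0.2)})
    m.bic, m.n_params, m.converged = bic, n_params, converged
    return m


class TestSelectModel:
    def _entry(self):
        return GridEntry("free", (("PANEL", P_FREE),))

    def test_lower_bic_wins(self):
        fits = [(self._entry(), _fit(100.0, 10), None),
                (self._entry(), _fit(90.0, 7), None)]
        assert select_model(fits)[1].bic == 90.0

    def test_tie_broken_by_fewer_params(self):
        fits = [(self._entry(), _fit(100.0, 10), None),
                (self._entry(), _fit(100.0, 7), None)]
        assert select_model(fits)[1].n_params == 7

    def test_unconverged_excluded(self):
        fits = [(self._entry(), _fit(50.0, 7, converged=False), None),
                (self._entry(), _fit(90.0, 7), None)]
        assert select_model(fits)[1].bic == 90.0

    def test_no_converged_fit(self):
        fits = [(self._entry(), _fit(50.0, 7, converged=False), None)]
        assert select_model(fits) is None

    def test_single_fit_returned(self):
        fits = [(self._entry(), _fit(75.0, 7), None)]
        assert select_model(fits)[1].bic == 75.0


class TestCallDosages:
    def _result(self, posterior_rows, config=None):
        n = len(posterior_rows)
        samples = [f"s{i}" for i in range(n)]
        values = np.asarray(posterior_rows, dtype=float)
        obs = ~np.isnan(values).all(axis=1)
        y = np.where(obs, 0.5, np.nan)
        ms = MarkerSignals("m", samples, np.ones(n), np.ones(n),
                           np.full(n, 0.5), y)
        post = PosteriorMatrix(values=values, observed=obs)
        model = MixtureModel(mu=np.linspace(0.1, 1.4, 5), sigma2=0.01,
                             pi={"PANEL": np.full(5, 0.2)})
        entry = GridEntry("free", (("PANEL", P_FREE),))
        return call_dosages(ms, entry, model, post, config or RunConfig())

    def test_confident_posterior_called(self):
        rows = [[0.01, 0.02, 0.95, 0.01, 0.01]] * 6 \
            + [[0.9, 0.1, 0, 0, 0]] * 4
        res = self._result(rows)
        assert res.status == STATUS_CALLED
        assert res.calls[0] == 2
        assert res.calls[-1] == 0

    def test_below_threshold_missing(self):
        rows = [[0.6, 0.4, 0, 0, 0]] + [[0.0, 0.9, 0.1, 0, 0]] * 9
        res = self._result(rows)
        assert np.isnan(res.calls[0])
        assert res.calls[1] == 1

    def test_single_category_rejection(self):
        rows = [[1.0, 0, 0, 0, 0]] * 95 + [[0, 1.0, 0, 0, 0]] * 5
        res = self._result(rows)
        assert res.status == STATUS_SINGLE_CATEGORY

    def test_too_many_na(self):
        rows = [[0.95, 0.05, 0, 0, 0]] * 6 + [[np.nan] * 5] * 4
        res = self._result(rows)
        assert res.status == STATUS_TOO_MANY_NA

    def test_na_filter_precedes_peak_filter(self):
        rows = [[1.0, 0, 0, 0, 0]] * 7 + [[np.nan] * 5] * 3
        res = self._result(rows)
        assert res.status == STATUS_TOO_MANY_NA


class TestReevaluateExtremes:
    def test_trigger_logic(self):
        from tetradose.calling import overall_component_weights
        post = PosteriorMatrix(
            values=np.tile([0.01, 0.20, 0.40, 0.30, 0.09], (100, 1)),
            observed=np.ones(100, dtype=bool))
        w = overall_component_weights(post)
        config = RunConfig()
        assert w[0] < config.extreme_trigger
        assert w[1] > config.adjacent_trigger

    def test_no_trigger_balanced(self):
        config = RunConfig()
        w = np.array([0.10, 0.20, 0.40, 0.20, 0.10])
        assert not (w[0] < config.extreme_trigger)

    def test_no_trigger_adjacent_small(self):
        config = RunConfig()
        w = np.array([0.01, 0.05, 0.44, 0.30, 0.20])
        assert w[0] < config.extreme_trigger
        assert not (w[1] > config.adjacent_trigger)

    def test_refit_drops_spurious_extreme(self):
        # data truly has no nulliplex class: 1:4:1 segregation shifted up
        spec = make_test_layout(n_f1=150, n_panel=0, n_parent1=6,
                                n_parent2=6, n_markers=1, seed=21,
                                sigma=0.05, parent_dosages=(2, 4))
        signals, structure, truth = simulate_marker(spec, 0)
        res = fit_marker(signals, structure, config=FAST)
        assert res.status == STATUS_CALLED
        pi_f1 = res.selected_model.pi["F1"]
        assert pi_f1[0] < 0.05  # no spurious nulliplex mass


class TestFitMarker:
    def test_too_few_samples_no_model(self, panel_structure):
        samples = list(panel_structure.assignments)[:3]
        ms = MarkerSignals("m", samples, np.ones(3), np.ones(3),
                           np.full(3, 0.5), np.full(3, 0.6))
        res = fit_marker(ms, panel_structure, config=RunConfig(min_samples=10))
        assert res.status == STATUS_NO_MODEL

    def test_statuses_partition(self):
        spec = make_test_layout(n_f1=60, n_panel=20, n_parent1=4,
                                n_parent2=4, n_markers=3, seed=30,
                                sigma=0.04)
        results = []
        for m in range(3):
            signals, structure, _ = simulate_marker(spec, m)
            results.append(fit_marker(signals, structure, config=FAST))
        from tetradose.calling import STATUSES
        assert all(r.status in STATUSES for r in results)

    def test_deterministic(self):
        spec = make_test_layout(n_f1=80, n_panel=0, n_parent1=5,
                                n_parent2=5, n_markers=1, seed=31,
                                sigma=0.04, parent_dosages=(1, 2))
        signals, structure, _ = simulate_marker(spec, 0)
        r1 = fit_marker(signals, structure, config=FAST)
        r2 = fit_marker(signals, structure, config=FAST)
        assert r1.status == r2.status
        np.testing.assert_array_equal(r1.calls, r2.calls)
        np.testing.assert_array_equal(r1.selected_model.mu,
                                      r2.selected_model.mu)
        assert r1.models_tried == r2.models_tried

    def test_prior_using_entry_can_win(self):
        spec = make_test_layout(n_f1=100, n_panel=0, n_parent1=8,
                                n_parent2=8, n_markers=1, seed=32,
                                sigma=0.04, parent_dosages=(2, 4))
        signals, structure, truth = simulate_marker(spec, 0)
        res = fit_marker(signals, structure,
                         prior_dosages={"P1": 2, "P2": 4}, config=FAST)
        assert res.status == STATUS_CALLED
        labels = [lbl for lbl, _, _ in res.models_tried]
        assert any("p_fixed" in lbl for lbl in labels)
        assert any("p_fixed" not in lbl for lbl in labels)
        obs = np.isfinite(res.calls)
        assert (res.calls[obs] == truth[obs]).mean() > 0.97

    def test_f1_constraint_beats_free_on_true_f1(self):
        # power check, small version of the acceptance criterion
        wins = 0
        for rep in range(5):
            spec = make_test_layout(n_f1=150, n_panel=0, n_parent1=6,
                                    n_parent2=6, n_markers=1, seed=100 + rep,
                                    sigma=0.04, parent_dosages=(2, 2))
            signals, structure, _ = simulate_marker(spec, 0)
            from tetradose.em import run_em
            pic_f1 = {"P1": P_FREE, "P2": P_FREE, "F1": P_F1}
            pic_free = {"P1": P_FREE, "P2": P_FREE, "F1": P_FREE}
            m1, _ = run_em(signals, structure, "free", pic_f1)
            m2, _ = run_em(signals, structure, "free", pic_free)
            if m1.bic < m2.bic:
                wins += 1
        assert wins >= 4
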