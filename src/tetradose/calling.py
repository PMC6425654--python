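"""Per-marker model grid, BIC selection, re-evaluation and dosage calling.

For each marker every mean parameterisation is crossed with a small set
of mixing-proportion configurations; every combination is fitted by EM
and the converged fit with the lowest BIC wins.  When parental dosage
priors are available the grid contains both prior-using (``p_fixed``
parents, regression-seeded means) and prior-free variants, so wrong
priors can be outvoted by the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .datamodel import (F1, MAX_DOSAGE, N_DOSAGES, PANEL_FREE, PANEL_HW,
                        PARENT, MarkerSignals, PopulationStructure)
from .em import (EMError, MU_CONSTRAINTS, MU_FREE, P_F1, P_FIXED, P_FREE,
                 P_HW, MixtureModel, PosteriorMatrix, count_parameters,
                 default_start, e_step, run_em)

logger = logging.getLogger(__name__)

STATUS_CALLED = "called"
STATUS_SINGLE_CATEGORY = "rejected_single_category"
STATUS_TOO_MANY_NA = "rejected_too_many_na"
STATUS_NO_MODEL = "no_model"
STATUSES = (STATUS_CALLED, STATUS_SINGLE_CATEGORY, STATUS_TOO_MANY_NA,
            STATUS_NO_MODEL)


@dataclass(frozen=True)
class GridEntry:
    """One fit attempt: a mean constraint plus per-population pi regimes."""

    mu_constraint: str
    pi_constraints: tuple[tuple[str, str], ...]  # (population_id, regime)
    uses_priors: bool = False

    @property
    def label(self) -> str:
        pis = ",".join(f"{p}={c}" for p, c in self.pi_constraints)
        tag = "+priors" if self.uses_priors else ""
        return f"{self.mu_constraint}|{pis}{tag}"

    def pi_dict(self) -> dict[str, str]:
        return dict(self.pi_constraints)


@dataclass
class MarkerResult:
    """Outcome of fitting and calling one marker."""

    marker_id: str
    status: str
    sample_ids: list[str]
    selected_model: MixtureModel | None = None
    posteriors: PosteriorMatrix | None = None
    calls: np.ndarray | None = None          # float; NaN = not called
    max_posterior: np.ndarray | None = None
    models_tried: list[tuple[str, float, bool]] = field(default_factory=list)
    used_parental_prior: bool = False

    @property
    def called_mask(self) -> np.ndarray:
        if self.calls is None:
            return np.zeros(len(self.sample_ids), dtype=bool)
        return np.isfinite(self.calls)


def build_model_grid(structure: PopulationStructure,
                     priors_present: bool) -> list[GridEntry]:
    """Deterministic grid of constraint combinations for one marker.

    HW panels toggle between ``p_HW`` and ``p_free``; F1 families
    between ``p_F1`` and ``p_free``; parent populations between
    ``p_fixed`` (only when priors exist) and ``p_free``.  Free panels
    are always ``p_free``.
    """
    hw_panels = structure.populations_of_type(PANEL_HW)
    free_panels = structure.populations_of_type(PANEL_FREE)
    f1_pops = structure.populations_of_type(F1)
    parent_pops = structure.populations_of_type(PARENT)

    panel_opts = [P_HW, P_FREE] if hw_panels else [None]
    f1_opts = [P_F1, P_FREE] if f1_pops else [None]
    parent_opts = ([P_FIXED, P_FREE] if priors_present else [P_FREE]) \
        if parent_pops else [None]

    grid: list[GridEntry] = []
    for mu_constraint in MU_CONSTRAINTS:
        for parent_opt in parent_opts:
            for f1_opt in f1_opts:
                for panel_opt in panel_opts:
                    combo: list[tuple[str, str]] = []
                    for pid in structure.populations:
                        ptype = structure.populations[pid].ptype
                        if ptype == PANEL_HW:
                            combo.append((pid, panel_opt))
                        elif ptype == PANEL_FREE:
                            combo.append((pid, P_FREE))
                        elif ptype == F1:
                            combo.append((pid, f1_opt))
                        else:
                            combo.append((pid, parent_opt))
                    grid.append(GridEntry(
                        mu_constraint=mu_constraint,
                        pi_constraints=tuple(combo),
                        uses_priors=(parent_opt == P_FIXED)))
    return grid


def starting_mu_from_priors(prior1: int, prior2: int,
                            mean1: float, mean2: float) -> np.ndarray | None:
    """Seed all five means from two known parental dosages.

    The two parental (dosage, mean-y) points define a line; the three
    remaining means are read off it, clipped into (0, pi/2).  Returns
    None for degenerate geometry (equal dosages or non-increasing line).
    """
    if prior1 == prior2:
        return None
    slope = (mean2 - mean1) / (prior2 - prior1)
    if slope <= 0:
        return None
    j = np.arange(N_DOSAGES, dtype=float)
    mu = mean1 + slope * (j - prior1)
    eps = 1e-3
    mu = np.clip(mu, eps, np.pi / 2 - eps)
    mu = np.maximum.accumulate(mu)
    if np.any(np.diff(mu) <= 0):
        mu += np.arange(N_DOSAGES) * 1e-6
    return np.sort(mu)


def starting_model_from_priors(signals: MarkerSignals,
                               structure: PopulationStructure,
                               entry: GridEntry,
                               prior_dosages: dict[str, int]) -> MixtureModel:
    """Prior-guided starting model (falls back to naive seeding).

    Requires an F1 family whose two parents both carry priors and have
    observed replicates; with two distinct parental dosages the means
    are seeded by the two-point regression, with equal dosages naive
    seeding is used with the shared parental mean pinned.
    """
    start_mu = None
    for f1_id in structure.populations_of_type(F1):
        par1, par2 = structure.parents_of(f1_id)
        if par1 not in prior_dosages or par2 not in prior_dosages:
            continue
        means = []
        for pid in (par1, par2):
            members = set(structure.members(pid))
            idx = [i for i, s in enumerate(signals.sample_ids)
                   if s in members and np.isfinite(signals.y[i])]
            means.append(float(np.mean(signals.y[idx])) if idx else None)
        if means[0] is None or means[1] is None:
            continue
        d1, d2 = prior_dosages[par1], prior_dosages[par2]
        if d1 == d2:
            # one shared dosage: naive seeding with that mean pinned
            start_mu = np.arcsin(np.sqrt(np.arange(N_DOSAGES) / MAX_DOSAGE))
            start_mu[d1] = (means[0] + means[1]) / 2.0
            start_mu = np.sort(np.clip(start_mu, 1e-3, np.pi / 2 - 1e-3))
        else:
            start_mu = starting_mu_from_priors(d1, d2, means[0], means[1])
        if start_mu is not None:
            break
    return default_start(signals, structure, entry.mu_constraint,
                         entry.pi_dict(), prior_dosages=prior_dosages,
                         start_mu=start_mu)


def _degrade_unresolvable_f1(entry: GridEntry, signals: MarkerSignals,
                             structure: PopulationStructure,
                             prior_dosages: dict[str, int]) -> GridEntry:
    """p_F1 needs parental modes; without samples or priors it degrades."""
    observed_samples = {s for i, s in enumerate(signals.sample_ids)
                        if np.isfinite(signals.y[i])}
    new_combo = []
    changed = False
    for pid, constraint in entry.pi_constraints:
        if constraint == P_F1:
            resolvable = all(
                par in prior_dosages or
                any(s in observed_samples for s in structure.members(par))
                for par in structure.parents_of(pid))
            if not resolvable:
                logger.warning(
                    "marker %s: F1 population %s has parents without samples "
                    "or priors; p_F1 degraded to p_free",
                    signals.marker_id, pid)
                new_combo.append((pid, P_FREE))
                changed = True
                continue
        new_combo.append((pid, constraint))
    if not changed:
        return entry
    return GridEntry(entry.mu_constraint, tuple(new_combo), entry.uses_priors)


def _parent_mode_overrides(entry: GridEntry, signals: MarkerSignals,
                           structure: PopulationStructure,
                           prior_dosages: dict[str, int]) -> dict[str, int]:
    """Fix p_F1 parental modes at the prior for sample-less parents."""
    observed_samples = {s for i, s in enumerate(signals.sample_ids)
                        if np.isfinite(signals.y[i])}
    overrides: dict[str, int] = {}
    for pid, constraint in entry.pi_constraints:
        if constraint != P_F1:
            continue
        for par in structure.parents_of(pid):
            has_samples = any(s in observed_samples
                              for s in structure.members(par))
            if not has_samples and par in prior_dosages:
                overrides[par] = prior_dosages[par]
    return overrides


def select_model(fits: list[tuple[GridEntry, MixtureModel, PosteriorMatrix]]
                 ) -> tuple[GridEntry, MixtureModel, PosteriorMatrix] | None:
    """Lowest BIC among converged fits; ties to fewer parameters, then
    earlier grid position."""
    best = None
    best_key = None
    for rank, (entry, model, post) in enumerate(fits):
        if not model.converged:
            continue
        key = (model.bic, model.n_params, rank)
        if best_key is None or key < best_key:
            best, best_key = (entry, model, post), key
    return best


def overall_component_weights(posteriors: PosteriorMatrix) -> np.ndarray:
    """Mean posterior mass per component over all observed samples."""
    return posteriors.values[posteriors.observed].mean(axis=0)


def reevaluate_extremes(signals: MarkerSignals,
                        structure: PopulationStructure,
                        entry: GridEntry, model: MixtureModel,
                        posteriors: PosteriorMatrix,
                        config: RunConfig,
                        parent_mode_overrides: dict[str, int] | None = None
                        ) -> tuple[MixtureModel, PosteriorMatrix]:
    """Refit without a thinly supported extreme component.

    Triggered when an extreme component carries less than
    ``extreme_trigger`` of all samples while its neighbour carries more
    than ``adjacent_trigger``; the 4-component refit replaces the model
    only if it improves the BIC.
    """
    weights = overall_component_weights(posteriors)
    triggers = []
    if (weights[0] < config.extreme_trigger
            and weights[1] > config.adjacent_trigger):
        triggers.append(0)
    if (weights[MAX_DOSAGE] < config.extreme_trigger
            and weights[MAX_DOSAGE - 1] > config.adjacent_trigger):
        triggers.append(MAX_DOSAGE)

    best_model, best_post = model, posteriors
    for dropped in triggers:
        mask = np.ones(N_DOSAGES, dtype=bool)
        mask[dropped] = False
        try:
            refit, refit_post = run_em(
                signals, structure, entry.mu_constraint, entry.pi_dict(),
                start=model, config=config.em_config(),
                component_mask=mask,
                parent_mode_overrides=parent_mode_overrides)
        except EMError as exc:
            logger.warning("marker %s: re-evaluation refit failed (%s)",
                           signals.marker_id, exc)
            continue
        if refit.converged and refit.bic < best_model.bic:
            logger.info("marker %s: dropped extreme component %d "
                        "(BIC %.2f -> %.2f)", signals.marker_id, dropped,
                        best_model.bic, refit.bic)
            best_model, best_post = refit, refit_post
    return best_model, best_post


def call_dosages(signals: MarkerSignals, entry: GridEntry,
                 model: MixtureModel, posteriors: PosteriorMatrix,
                 config: RunConfig,
                 models_tried: list[tuple[str, float, bool]] | None = None
                 ) -> MarkerResult:
    """Assign dosages by thresholded posteriors, then apply marker filters."""
    values = np.nan_to_num(posteriors.values, nan=-1.0)
    max_post = np.where(posteriors.observed, values.max(axis=1), np.nan)
    best = np.where(posteriors.observed, values.argmax(axis=1), -1)
    calls = np.where(
        posteriors.observed & (max_post >= config.call_threshold),
        best.astype(float), np.nan)

    n_samples = len(signals.sample_ids)
    n_called = int(np.isfinite(calls).sum())
    na_fraction = 1.0 - n_called / n_samples

    status = STATUS_CALLED
    if na_fraction > config.na_fraction_max:
        status = STATUS_TOO_MANY_NA
    elif n_called > 0:
        counts = np.bincount(calls[np.isfinite(calls)].astype(int),
                             minlength=N_DOSAGES)
        if counts.max() / n_called > config.peak_threshold:
            status = STATUS_SINGLE_CATEGORY

    return MarkerResult(
        marker_id=signals.marker_id, status=status,
        sample_ids=list(signals.sample_ids),
        selected_model=model, posteriors=posteriors, calls=calls,
        max_posterior=max_post,
        models_tried=models_tried or [],
        used_parental_prior=entry.uses_priors)


def no_model_result(signals: MarkerSignals,
                    models_tried: list[tuple[str, float, bool]] | None = None
                    ) -> MarkerResult:
    return MarkerResult(marker_id=signals.marker_id, status=STATUS_NO_MODEL,
                        sample_ids=list(signals.sample_ids),
                        calls=np.full(len(signals.sample_ids), np.nan),
                        max_posterior=np.full(len(signals.sample_ids), np.nan),
                        models_tried=models_tried or [])


def fit_marker(signals: MarkerSignals, structure: PopulationStructure,
               prior_dosages: dict[str, int] | None = None,
               config: RunConfig | None = None) -> MarkerResult:
    """Fit the whole model grid for one marker and call dosages."""
    config = config or RunConfig()
    prior_dosages = prior_dosages or {}
    if signals.n_observed < config.min_samples:
        return no_model_result(signals)

    grid = build_model_grid(structure, priors_present=bool(prior_dosages))
    fits: list[tuple[GridEntry, MixtureModel, PosteriorMatrix]] = []
    models_tried: list[tuple[str, float, bool]] = []
    for raw_entry in grid:
        entry = _degrade_unresolvable_f1(raw_entry, signals, structure,
                                         prior_dosages)
        overrides = _parent_mode_overrides(entry, signals, structure,
                                           prior_dosages)
        try:
            if entry.uses_priors:
                start = starting_model_from_priors(signals, structure, entry,
                                                   prior_dosages)
            else:
                start = default_start(signals, structure, entry.mu_constraint,
                                      entry.pi_dict(),
                                      prior_dosages=prior_dosages
                                      if entry.uses_priors else None)
            model, post = run_em(signals, structure, entry.mu_constraint,
                                 entry.pi_dict(), start=start,
                                 config=config.em_config(),
                                 parent_mode_overrides=overrides or None)
        except (EMError, FloatingPointError) as exc:
            logger.debug("marker %s: fit %s failed (%s)",
                         signals.marker_id, raw_entry.label, exc)
            models_tried.append((raw_entry.label, float("nan"), False))
            continue
        models_tried.append((raw_entry.label, model.bic, model.converged))
        fits.append((entry, model, post))

    chosen = select_model(fits)
    if chosen is None:
        return no_model_result(signals, models_tried)
    entry, model, post = chosen
    overrides = _parent_mode_overrides(entry, signals, structure,
                                       prior_dosages)
    model, post = reevaluate_extremes(signals, structure, entry, model, post,
                                      config,
                                      parent_mode_overrides=overrides or None)
    return call_dosages(signals, entry, model, post, config,
                        models_tried=models_tried)
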