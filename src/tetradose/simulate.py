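"""Synthetic marker datasets with the statistical structure the caller assumes.

Dosages are drawn per population (Hardy-Weinberg for panels, tetrasomic
segregation for F1 families, fixed across replicates for parents);
transformed values get Gaussian noise at the model's constant-variance
scale and are mapped back to a unit-total two-channel signal pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (F1, MAX_DOSAGE, N_DOSAGES, PANEL_FREE, PANEL_HW,
                        PARENT, MarkerSignals, ParentalPrior, Population,
                        PopulationStructure, ValidationError)
from .em import IDEAL_MU, MeanParameterization
from .segregation import f1_segregation, hw_proportions


@dataclass(frozen=True)
class PopSpec:
    """One simulated subpopulation."""

    population_id: str
    ptype: str
    n_samples: int
    allele_freq: float | None = None      # HW panels; None = draw per marker
    dosage: int | None = None             # parents; None = draw per marker
    parents: tuple[str, str] | None = None  # F1 links

    def __post_init__(self):
        if self.n_samples < 0:
            raise ValidationError("n_samples must be nonnegative")
        if self.allele_freq is not None and not 0 <= self.allele_freq <= 1:
            raise ValidationError("allele_freq outside [0, 1]")
        if self.dosage is not None and self.dosage not in range(N_DOSAGES):
            raise ValidationError("parent dosage outside 0..4")


@dataclass(frozen=True)
class SimSpec:
    """Recipe for a synthetic dataset."""

    n_markers: int
    populations: tuple[PopSpec, ...]
    sigma: float = 0.04
    na_rate: float = 0.0
    seed: int = 1
    mu: tuple[float, ...] | None = None
    mean_param: MeanParameterization | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not 0 <= self.na_rate < 1:
            raise ValidationError("na_rate outside [0, 1)")
        if self.n_markers < 0:
            raise ValidationError("n_markers must be nonnegative")

    def truth_mu(self) -> np.ndarray:
        if self.mu is not None:
            return np.asarray(self.mu, dtype=float)
        if self.mean_param is not None:
            return self.mean_param.mu()
        return IDEAL_MU.copy()


def build_structure(spec: SimSpec) -> tuple[PopulationStructure, list[str]]:
    """Population structure and the ordered global sample list."""
    populations: dict[str, Population] = {}
    assignments: dict[str, str] = {}
    sample_ids: list[str] = []
    for pop in spec.populations:
        populations[pop.population_id] = Population(
            population_id=pop.population_id, ptype=pop.ptype,
            parents=pop.parents,
            family=None)
    # back-fill parent -> family links for reporting convenience
    for pop in list(populations.values()):
        if pop.ptype == F1 and pop.parents:
            for par in pop.parents:
                old = populations.get(par)
                if old is not None and old.ptype == PARENT:
                    populations[par] = Population(
                        population_id=par, ptype=PARENT,
                        family=pop.population_id)
    for pop in spec.populations:
        for i in range(pop.n_samples):
            sid = f"{pop.population_id}_{i + 1:04d}"
            sample_ids.append(sid)
            assignments[sid] = pop.population_id
    return PopulationStructure(populations=populations,
                               assignments=assignments), sample_ids


def _marker_rng(seed: int, marker_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(marker_index,)))


def _draw_dosages(spec: SimSpec, rng: np.random.Generator
                  ) -> dict[str, np.ndarray | int]:
    """Per-population dosage draws for one marker.

    Returns per-population arrays; parents draw one dosage shared by all
    replicates.  F1 offspring segregate from their parents' dosages.
    """
    parent_dosage: dict[str, int] = {}
    for pop in spec.populations:
        if pop.ptype == PARENT:
            d = pop.dosage if pop.dosage is not None \
                else int(rng.integers(0, N_DOSAGES))
            parent_dosage[pop.population_id] = d

    out: dict[str, np.ndarray] = {}
    for pop in spec.populations:
        n = pop.n_samples
        if pop.ptype == PARENT:
            out[pop.population_id] = np.full(
                n, parent_dosage[pop.population_id], dtype=int)
        elif pop.ptype == F1:
            d1 = parent_dosage.get(pop.parents[0]) if pop.parents else None
            d2 = parent_dosage.get(pop.parents[1]) if pop.parents else None
            if d1 is None or d2 is None:
                raise ValidationError(
                    f"F1 population {pop.population_id} lacks simulated "
                    "parents")
            props = np.asarray(f1_segregation(d1, d2).proportions)
            out[pop.population_id] = rng.choice(N_DOSAGES, size=n, p=props)
        else:  # panels
            p = pop.allele_freq if pop.allele_freq is not None \
                else float(rng.uniform(0.05, 0.95))
            out[pop.population_id] = rng.choice(N_DOSAGES, size=n,
                                                p=hw_proportions(p))
    return out


def simulate_marker(spec: SimSpec, marker_index: int = 0,
                    marker_id: str | None = None
                    ) -> tuple[MarkerSignals, PopulationStructure, np.ndarray]:
    """One synthetic marker: signals, structure, true per-sample dosages."""
    structure, sample_ids = build_structure(spec)
    rng = _marker_rng(spec.seed, marker_index)
    marker_id = marker_id or f"marker_{marker_index + 1:05d}"
    mu = spec.truth_mu()

    dosage_by_pop = _draw_dosages(spec, rng)
    truth = np.concatenate([np.asarray(dosage_by_pop[p.population_id])
                            for p in spec.populations]) \
        if spec.populations else np.array([], dtype=int)

    y = mu[truth] + rng.normal(0.0, spec.sigma, size=truth.size)
    y = np.clip(y, 0.0, np.pi / 2)
    ratio = np.sin(y) ** 2
    signal_a = 1.0 - ratio
    signal_b = ratio.copy()
    if spec.na_rate > 0:
        na = rng.random(truth.size) < spec.na_rate
        signal_a[na] = np.nan
        signal_b[na] = np.nan
    signals = MarkerSignals.from_signals(marker_id, sample_ids,
                                         signal_a, signal_b)
    return signals, structure, truth


def simulate_dataset(spec: SimSpec) -> tuple[list[MarkerSignals],
                                             PopulationStructure,
                                             dict[str, np.ndarray],
                                             list[ParentalPrior]]:
    """All markers of a spec plus true-dosage parental priors."""
    structure, _ = build_structure(spec)
    markers: list[MarkerSignals] = []
    truths: dict[str, np.ndarray] = {}
    priors: list[ParentalPrior] = []
    parent_pops = [p for p in spec.populations if p.ptype == PARENT]
    for m in range(spec.n_markers):
        signals, _, truth = simulate_marker(spec, m)
        markers.append(signals)
        truths[signals.marker_id] = truth
        offset = 0
        for pop in spec.populations:
            if pop.ptype == PARENT and pop.n_samples > 0:
                priors.append(ParentalPrior(
                    marker_id=signals.marker_id,
                    parent_population_id=pop.population_id,
                    dosage=int(truth[offset])))
            offset += pop.n_samples
    return markers, structure, truths, priors


def make_test_layout(n_f1: int = 200, n_parent1: int = 12,
                     n_parent2: int = 13, n_panel: int = 60,
                     sigma: float = 0.04, na_rate: float = 0.0,
                     n_markers: int = 10, seed: int = 1,
                     full_scale: bool = False,
                     parent_dosages: tuple[int, int] | None = None,
                     panel_allele_freq: float | None = None) -> SimSpec:
    """Spec mirroring the benchmark layout: one tetraploid full-sib
    family with replicated parents plus an unstructured panel.

    ``full_scale`` switches to the published sample sizes (975 offspring,
    parents in 12 and 13 replicates, 222 panel samples).
    """
    if full_scale:
        n_f1, n_parent1, n_parent2, n_panel = 975, 12, 13, 222
    pops = [
        PopSpec("P1", PARENT, n_parent1,
                dosage=None if parent_dosages is None else parent_dosages[0]),
        PopSpec("P2", PARENT, n_parent2,
                dosage=None if parent_dosages is None else parent_dosages[1]),
        PopSpec("F1", F1, n_f1, parents=("P1", "P2")),
    ]
    if n_panel > 0:
        pops.append(PopSpec("PANEL", PANEL_HW, n_panel,
                            allele_freq=panel_allele_freq))
    return SimSpec(n_markers=n_markers, populations=tuple(pops),
                   sigma=sigma, na_rate=na_rate, seed=seed)
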