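"""Core data types: per-marker signals, population structure, parental priors.

The calling model works on the arcsine-square-root transformed B-allele
signal fraction ``y = arcsin(sqrt(s_b / (s_a + s_b)))``, which maps the
ratio range [0, 1] onto [0, pi/2] and approximately stabilises the
variance of the five dosage-class distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Number of allele copies distinguishable in an autotetraploid.
MAX_DOSAGE = 4
#: Number of mixture components / dosage classes (0..4).
N_DOSAGES = 5

DOSAGES = np.arange(N_DOSAGES)

PANEL_FREE = "panel_free"
PANEL_HW = "panel_HW"
F1 = "F1"
PARENT = "parent"

POPULATION_TYPES = (PANEL_FREE, PANEL_HW, F1, PARENT)


class ValidationError(ValueError):
    """An input record or structure violates its contract."""


def transform_from_ratio(ratio):
    """arcsin(sqrt(r)) for r in [0, 1]; NaN propagates."""
    r = np.asarray(ratio, dtype=float)
    bad = (r < 0) | (r > 1)
    if np.any(bad & ~np.isnan(r)):
        raise ValidationError("signal ratio outside [0, 1]")
    out = np.arcsin(np.sqrt(r))
    return float(out) if np.isscalar(ratio) else out


def transform_ratio(signal_a, signal_b, *, marker_id=None, sample_ids=None):
    """Transformed B-fraction from two channel intensities.

    Returns ``arcsin(sqrt(s_b / (s_a + s_b)))``; NaN where either signal
    is missing or the total intensity is zero.  Negative signals raise
    :class:`ValidationError` naming the offending sample and marker when
    those identifiers are supplied.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    neg = (a < 0) | (b < 0)
    if np.any(neg):
        where = ""
        if sample_ids is not None:
            idx = int(np.flatnonzero(np.atleast_1d(neg))[0])
            where = f" (sample {np.atleast_1d(np.asarray(sample_ids))[idx]!s}"
            where += f", marker {marker_id})" if marker_id else ")"
        elif marker_id:
            where = f" (marker {marker_id})"
        raise ValidationError(f"negative signal intensity{where}")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, b / total, np.nan)
        y = np.arcsin(np.sqrt(ratio))
    if np.isscalar(signal_a) and np.isscalar(signal_b):
        return float(y)
    return y


@dataclass
class MarkerSignals:
    """Two-channel intensities and transformed ratio for one marker.

    ``signal_a``/``signal_b`` hold NaN for missing observations; ``y`` is
    NaN wherever either signal is missing or the total intensity is zero,
    and such samples are excluded from all likelihood terms.
    """

    marker_id: str
    sample_ids: list[str]
    signal_a: np.ndarray
    signal_b: np.ndarray
    ratio: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        n = len(self.sample_ids)
        for name in ("signal_a", "signal_b", "ratio", "y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValidationError(
                    f"{name} has length {arr.shape}, expected {n} "
                    f"(marker {self.marker_id})"
                )

    @classmethod
    def from_signals(cls, marker_id: str, sample_ids: Sequence[str],
                     signal_a, signal_b) -> "MarkerSignals":
        a = np.asarray(signal_a, dtype=float)
        b = np.asarray(signal_b, dtype=float)
        y = transform_ratio(a, b, marker_id=marker_id, sample_ids=sample_ids)
        total = a + b
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(total > 0, b / total, np.nan)
        return cls(marker_id, list(sample_ids), a, b, ratio, y)

    @classmethod
    def from_ratios(cls, marker_id: str, sample_ids: Sequence[str],
                    ratio) -> "MarkerSignals":
        """Build from precomputed ratios; synthesises unit-total signals."""
        r = np.asarray(ratio, dtype=float)
        y = transform_from_ratio(r)
        return cls(marker_id, list(sample_ids), 1.0 - r, r.copy(), r, y)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of samples with a usable transformed value."""
        return np.isfinite(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


@dataclass(frozen=True)
class Population:
    """One subpopulation: a panel, an F1 family, or a parent of a family."""

    population_id: str
    ptype: str
    parents: tuple[str, str] | None = None  # F1 only
    family: str | None = None               # parent only

    def __post_init__(self):
        if self.ptype not in POPULATION_TYPES:
            raise ValidationError(
                f"unknown population type {self.ptype!r} "
                f"for {self.population_id!r}"
            )


@dataclass
class PopulationStructure:
    """Sample-to-subpopulation map plus typed population definitions."""

    populations: dict[str, Population]
    assignments: dict[str, str]  # sample_id -> population_id

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        referenced_parents: dict[str, list[str]] = {}
        for pop in self.populations.values():
            if pop.ptype == F1:
                if pop.parents is None or len(set(pop.parents)) != 2:
                    raise ValidationError(
                        f"F1 population {pop.population_id!r} must reference "
                        "exactly two distinct parent populations"
                    )
                for par in pop.parents:
                    if par not in self.populations:
                        raise ValidationError(
                            f"F1 population {pop.population_id!r} references "
                            f"undefined parent population {par!r}"
                        )
                    if self.populations[par].ptype != PARENT:
                        raise ValidationError(
                            f"population {par!r} linked as a parent of "
                            f"{pop.population_id!r} but has type "
                            f"{self.populations[par].ptype!r}"
                        )
                    referenced_parents.setdefault(par, []).append(
                        pop.population_id)
        for pop in self.populations.values():
            if pop.ptype == PARENT and pop.population_id not in referenced_parents:
                raise ValidationError(
                    f"parent population {pop.population_id!r} is not linked "
                    "to any F1 family"
                )
        for sample, pop_id in self.assignments.items():
            if pop_id not in self.populations:
                raise ValidationError(
                    f"sample {sample!r} assigned to undefined population "
                    f"{pop_id!r}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def population_ids(self) -> list[str]:
        return list(self.populations)

    def population_of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} not in any population")

    def members(self, population_id: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population_id]

    def populations_of_type(self, ptype: str) -> list[str]:
        return [p.population_id for p in self.populations.values()
                if p.ptype == ptype]

    def parents_of(self, f1_id: str) -> tuple[str, str]:
        pop = self.populations[f1_id]
        if pop.ptype != F1:
            raise ValidationError(f"{f1_id!r} is not an F1 population")
        return pop.parents  # type: ignore[return-value]

    def membership_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Array of population ids aligned with ``sample_ids``."""
        return np.array([self.population_of(s) for s in sample_ids],
                        dtype=object)


@dataclass(frozen=True)
class ParentalPrior:
    """Externally supplied dosage for one parent population at one marker."""

    marker_id: str
    parent_population_id: str
    dosage: int

    def __post_init__(self):
        if self.dosage not in range(N_DOSAGES):
            raise ValidationError(
                f"parental dosage {self.dosage} outside 0..{MAX_DOSAGE} "
                f"(marker {self.marker_id}, population "
                f"{self.parent_population_id})"
            )


def priors_for_marker(priors: Iterable[ParentalPrior],
                      marker_id: str) -> dict[str, int]:
    """Map parent population id -> dosage for one marker."""
    out: dict[str, int] = {}
    for p in priors:
        if p.marker_id != marker_id:
            continue
        if p.parent_population_id in out:
            raise ValidationError(
                f"duplicate parental prior for marker {marker_id}, "
                f"population {p.parent_population_id}"
            )
        out[p.parent_population_id] = p.dosage
    return out
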