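"""Parent-offspring concordance QC and run-level summary.

For each called marker with an F1 family the called offspring dosage
counts are compared against the expected segregation of every one of
the 15 unordered parental dosage combinations by a Pearson chi-squared
goodness-of-fit statistic; a marker "matches" when the best-fitting
combination equals the parents' own called dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .calling import (MarkerResult, STATUS_CALLED, STATUS_NO_MODEL,
                      STATUS_SINGLE_CATEGORY, STATUS_TOO_MANY_NA)
from .datamodel import F1, N_DOSAGES, PopulationStructure, ValidationError
from .segregation import f1_segregation

logger = logging.getLogger(__name__)

VERDICT_MATCHING = "matching"
VERDICT_NOT_MATCHING = "not_matching"
VERDICT_NOT_ASSESSABLE = "not_assessable"

#: the 15 unordered parental dosage pairs, in fixed order
PARENT_COMBOS: list[tuple[int, int]] = list(
    combinations_with_replacement(range(N_DOSAGES), 2))

#: relative closeness of the two best chi-squared values below which
#: the match is flagged ambiguous (some patterns are near-identical)
AMBIGUITY_MARGIN = 0.10


@dataclass
class MatchReport:
    marker_id: str
    best_combo: tuple[int, int] | None
    chi2: float
    called_parents: tuple[int | None, int | None]
    verdict: str
    category_counts: np.ndarray
    ambiguous: bool = False


def best_matching_combo(offspring_counts) -> tuple[tuple[int, int], float]:
    """Minimum-chi-squared parental combination for offspring counts.

    Combinations expecting zero mass in a class with observed counts
    score infinity.  Ties resolve to the first combination in the fixed
    enumeration order.
    """
    counts = np.asarray(offspring_counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValidationError("offspring counts are all zero")
    best_combo, best_chi2, second_chi2 = None, np.inf, np.inf
    for combo in PARENT_COMBOS:
        expected = np.asarray(f1_segregation(*combo).proportions) * n
        if np.any((expected == 0) & (counts > 0)):
            chi2 = np.inf
        else:
            nz = expected > 0
            chi2 = float(((counts[nz] - expected[nz]) ** 2
                          / expected[nz]).sum())
        if chi2 < best_chi2:
            best_combo, best_chi2, second_chi2 = combo, chi2, best_chi2
        elif chi2 < second_chi2:
            second_chi2 = chi2
    if best_combo is None:
        raise ValidationError("no parental combination has finite chi-squared")
    return best_combo, best_chi2


def _second_best_close(counts: np.ndarray, best_chi2: float) -> bool:
    n = counts.sum()
    chi2s = []
    for combo in PARENT_COMBOS:
        expected = np.asarray(f1_segregation(*combo).proportions) * n
        if np.any((expected == 0) & (counts > 0)):
            continue
        nz = expected > 0
        chi2s.append(float(((counts[nz] - expected[nz]) ** 2
                            / expected[nz]).sum()))
    chi2s.sort()
    if len(chi2s) < 2:
        return False
    second = chi2s[1]
    if best_chi2 == 0:
        return second == 0
    return (second - best_chi2) / best_chi2 < AMBIGUITY_MARGIN


def _modal_called_dosage(result: MarkerResult, members: set[str]) -> int | None:
    idx = [i for i, s in enumerate(result.sample_ids) if s in members]
    calls = result.calls[idx] if result.calls is not None else np.array([])
    calls = calls[np.isfinite(calls)].astype(int) if calls.size else calls
    if calls.size == 0:
        return None
    counts = np.bincount(calls, minlength=N_DOSAGES)
    return int(counts.argmax())


def classify_marker(result: MarkerResult, structure: PopulationStructure,
                    f1_population: str | None = None) -> MatchReport:
    """Match verdict for one called marker against its F1 family."""
    f1_ids = structure.populations_of_type(F1)
    if not f1_ids:
        raise ValidationError("structure has no F1 population to assess")
    f1_id = f1_population or f1_ids[0]
    par1, par2 = structure.parents_of(f1_id)

    offspring = set(structure.members(f1_id))
    counts = np.zeros(N_DOSAGES)
    if result.calls is not None:
        idx = [i for i, s in enumerate(result.sample_ids) if s in offspring]
        called = result.calls[idx]
        called = called[np.isfinite(called)].astype(int)
        counts = np.bincount(called, minlength=N_DOSAGES).astype(float)

    p1 = _modal_called_dosage(result, set(structure.members(par1)))
    p2 = _modal_called_dosage(result, set(structure.members(par2)))

    if counts.sum() == 0 or p1 is None or p2 is None:
        return MatchReport(
            marker_id=result.marker_id, best_combo=None, chi2=np.nan,
            called_parents=(p1, p2), verdict=VERDICT_NOT_ASSESSABLE,
            category_counts=counts)

    best_combo, chi2 = best_matching_combo(counts)
    ambiguous = _second_best_close(counts, chi2)
    if ambiguous:
        logger.warning(
            "marker %s: two parental combinations fit almost equally well "
            "(chi2 margin < %.0f%%)", result.marker_id,
            AMBIGUITY_MARGIN * 100)
    called_pair = tuple(sorted((p1, p2)))
    verdict = (VERDICT_MATCHING if called_pair == best_combo
               else VERDICT_NOT_MATCHING)
    return MatchReport(
        marker_id=result.marker_id, best_combo=best_combo, chi2=chi2,
        called_parents=(p1, p2), verdict=verdict,
        category_counts=counts, ambiguous=ambiguous)


SUMMARY_ROWS = ("Called", "Matching", "Not matching", "Matching rate",
                "Not called", "> 90% in single category", "> 25% NAs",
                "No model")


def summarize_run(reports: dict[str, MatchReport],
                  results: list[MarkerResult]) -> pd.DataFrame:
    """Run summary as percentages over all markers.

    Matching / Not matching split the Called fraction (a called marker
    whose match could not be assessed counts as not matching); the
    Matching rate is Matching relative to Called.
    """
    n = len(results)
    if n == 0:
        raise ValidationError("no marker results to summarise")
    n_called = sum(r.status == STATUS_CALLED for r in results)
    n_single = sum(r.status == STATUS_SINGLE_CATEGORY for r in results)
    n_na = sum(r.status == STATUS_TOO_MANY_NA for r in results)
    n_nomodel = sum(r.status == STATUS_NO_MODEL for r in results)
    n_matching = sum(
        1 for r in results
        if r.status == STATUS_CALLED
        and r.marker_id in reports
        and reports[r.marker_id].verdict == VERDICT_MATCHING)

    pct = lambda x: 100.0 * x / n
    values = {
        "Called": pct(n_called),
        "Matching": pct(n_matching),
        "Not matching": pct(n_called - n_matching),
        "Matching rate": (100.0 * n_matching / n_called if n_called
                          else np.nan),
        "Not called": pct(n - n_called),
        "> 90% in single category": pct(n_single),
        "> 25% NAs": pct(n_na),
        "No model": pct(n_nomodel),
    }
    return pd.DataFrame({"metric": list(SUMMARY_ROWS),
                         "percent": [values[k] for k in SUMMARY_ROWS]})


def reports_to_frame(reports: dict[str, MatchReport]) -> pd.DataFrame:
    rows = []
    for marker_id, rep in reports.items():
        rows.append({
            "marker_id": marker_id,
            "verdict": rep.verdict,
            "best_combo": ("" if rep.best_combo is None
                           else f"{rep.best_combo[0]}x{rep.best_combo[1]}"),
            "chi2": rep.chi2,
            "parent1_call": ("" if rep.called_parents[0] is None
                             else rep.called_parents[0]),
            "parent2_call": ("" if rep.called_parents[1] is None
                             else rep.called_parents[1]),
            "offspring_counts": ":".join(
                str(int(c)) for c in rep.category_counts),
            "ambiguous": rep.ambiguous,
        })
    return pd.DataFrame(rows)
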