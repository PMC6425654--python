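"""Delimited-text readers and writers for signals, structure and priors.

All files are UTF-8, header-carrying TSV or CSV (the delimiter is
autodetected from the header line, or forced with ``delimiter=``).
Empty fields, ``NA`` and ``NaN`` are read as missing.

Signal tables come in two dialects:

* long — columns ``marker_id, sample_id, signal_a, signal_b`` (raw
  two-channel intensities) or ``marker_id, sample_id, ratio``
  (precomputed B-fractions);
* wide — one row per marker, first column ``marker_id``, one ratio
  column per sample.

Population structure files hold ``#population`` directive lines
(``#population <id> <type> [parent1,parent2]``) followed by a
two-column ``sample_id, population_id`` table; populations never
declared in a directive default to ``panel_HW``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np

from .datamodel import (F1, PANEL_HW, PARENT, MarkerSignals, ParentalPrior,
                        Population, PopulationStructure, ValidationError)

MISSING_CODES = {"", "NA", "NaN", "nan", "na"}

def _fmt_float(v) -> str:
    # full-precision repr so write -> read round-trips exactly
    return repr(float(v))


def _detect_delimiter(header: str, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "\t" if "\t" in header else ","


def _parse_float(token: str, path, line_no: int, column: str) -> float:
    token = token.strip()
    if token in MISSING_CODES:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ValidationError(
            f"{path}:{line_no}: unparseable numeric {token!r} "
            f"in column {column!r}")


# ---------------------------------------------------------------------------
# signal tables


def read_signal_table(path: str | Path,
                      delimiter: str | None = None) -> list[MarkerSignals]:
    """Parse a signal table (either dialect) into per-marker records."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    sep = _detect_delimiter(lines[0], delimiter)
    header = [h.strip() for h in lines[0].split(sep)]

    if header[:2] == ["marker_id", "sample_id"]:
        return _read_long(path, lines, sep, header)
    if header[0] == "marker_id":
        return _read_wide(path, lines, sep, header)
    raise ValidationError(
        f"{path}: unrecognised signal-table header {header[:3]}")


def _read_long(path: Path, lines: list[str], sep: str,
               header: list[str]) -> list[MarkerSignals]:
    has_ratio = "ratio" in header
    has_signals = "signal_a" in header and "signal_b" in header
    if not (has_ratio or has_signals):
        raise ValidationError(
            f"{path}: long format needs signal_a/signal_b or ratio columns")
    col = {name: i for i, name in enumerate(header)}

    sample_order: list[str] = []
    marker_order: list[str] = []
    records: dict[tuple[str, str], tuple[float, float]] = {}
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) != len(header):
            raise ValidationError(
                f"{path}:{line_no}: expected {len(header)} fields, "
                f"got {len(parts)}")
        marker = parts[col["marker_id"]].strip()
        sample = parts[col["sample_id"]].strip()
        if (marker, sample) in records:
            raise ValidationError(
                f"{path}:{line_no}: duplicate entry for marker {marker!r}, "
                f"sample {sample!r}")
        if has_signals:
            a = _parse_float(parts[col["signal_a"]], path, line_no, "signal_a")
            b = _parse_float(parts[col["signal_b"]], path, line_no, "signal_b")
        else:
            r = _parse_float(parts[col["ratio"]], path, line_no, "ratio")
            a, b = (1.0 - r, r) if np.isfinite(r) else (np.nan, np.nan)
        records[(marker, sample)] = (a, b)
        if marker not in marker_order:
            marker_order.append(marker)
        if sample not in sample_order:
            sample_order.append(sample)

    out = []
    for marker in marker_order:
        a = np.array([records.get((marker, s), (np.nan, np.nan))[0]
                      for s in sample_order])
        b = np.array([records.get((marker, s), (np.nan, np.nan))[1]
                      for s in sample_order])
        out.append(MarkerSignals.from_signals(marker, sample_order, a, b))
    return out


def _read_wide(path: Path, lines: list[str], sep: str,
               header: list[str]) -> list[MarkerSignals]:
    sample_ids = [h.strip() for h in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample columns")
    out = []
    seen = set()
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) != len(header):
            raise ValidationError(
                f"{path}:{line_no}: expected {len(header)} fields, "
                f"got {len(parts)}")
        marker = parts[0].strip()
        if marker in seen:
            raise ValidationError(
                f"{path}:{line_no}: duplicate marker {marker!r}")
        seen.add(marker)
        ratios = np.array([_parse_float(tok, path, line_no, s)
                           for tok, s in zip(parts[1:], sample_ids)])
        out.append(MarkerSignals.from_ratios(marker, sample_ids, ratios))
    return out


def write_signal_table(path: str | Path, markers: Iterable[MarkerSignals],
                       dialect: str = "long", ratios_only: bool = False,
                       delimiter: str = "\t") -> None:
    """Write markers back out; ``dialect`` is ``long`` or ``wide``."""
    path = Path(path)
    markers = list(markers)
    buf = _io.StringIO()
    if dialect == "wide":
        sample_ids = markers[0].sample_ids if markers else []
        buf.write(delimiter.join(["marker_id", *sample_ids]) + "\n")
        for m in markers:
            cells = ["NA" if not np.isfinite(r) else _fmt_float(r)
                     for r in m.ratio]
            buf.write(delimiter.join([m.marker_id, *cells]) + "\n")
    elif dialect == "long":
        cols = (["marker_id", "sample_id", "ratio"] if ratios_only
                else ["marker_id", "sample_id", "signal_a", "signal_b"])
        buf.write(delimiter.join(cols) + "\n")
        for m in markers:
            for i, s in enumerate(m.sample_ids):
                if ratios_only:
                    vals = [m.ratio[i]]
                else:
                    vals = [m.signal_a[i], m.signal_b[i]]
                cells = ["NA" if not np.isfinite(v) else _fmt_float(v)
                         for v in vals]
                buf.write(delimiter.join([m.marker_id, s, *cells]) + "\n")
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# population structure


def read_population_structure(path: str | Path,
                              delimiter: str | None = None
                              ) -> PopulationStructure:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    directives: list[tuple[int, list[str]]] = []
    body: list[tuple[int, str]] = []
    for line_no, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#population"):
            directives.append((line_no, line.replace(",", "\t").split()))
        elif line.startswith("#"):
            continue
        else:
            body.append((line_no, line))
    if not body:
        raise ValidationError(f"{path}: no sample assignments")
    sep = _detect_delimiter(body[0][1], delimiter)
    header = [h.strip() for h in body[0][1].split(sep)]
    if header[:2] != ["sample_id", "population_id"]:
        raise ValidationError(
            f"{path}:{body[0][0]}: expected header 'sample_id"
            f"{sep}population_id'")

    assignments: dict[str, str] = {}
    for line_no, line in body[1:]:
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2:
            raise ValidationError(f"{path}:{line_no}: expected 2 fields")
        sample, pop = parts[0], parts[1]
        if sample in assignments:
            raise ValidationError(
                f"{path}:{line_no}: sample {sample!r} listed twice")
        assignments[sample] = pop

    populations: dict[str, Population] = {}
    f1_parents: dict[str, tuple[str, str]] = {}
    for line_no, parts in directives:
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{line_no}: directive needs '#population <id> "
                "<type> [links]'")
        _, pop_id, ptype = parts[:3]
        links = parts[3:] if len(parts) > 3 else []
        if ptype == F1:
            if len(links) != 2:
                raise ValidationError(
                    f"{path}:{line_no}: F1 population {pop_id!r} must list "
                    f"exactly two parent populations, got {len(links)}")
            f1_parents[pop_id] = (links[0], links[1])
            populations[pop_id] = Population(pop_id, F1,
                                             parents=(links[0], links[1]))
        elif ptype == PARENT:
            populations[pop_id] = Population(
                pop_id, PARENT, family=links[0] if links else None)
        else:
            populations[pop_id] = Population(pop_id, ptype)
    # parent -> family links implied by the F1 directives
    for f1_id, (par1, par2) in f1_parents.items():
        for par in (par1, par2):
            existing = populations.get(par)
            if existing is not None and existing.family is None \
                    and existing.ptype == PARENT:
                populations[par] = Population(par, PARENT, family=f1_id)
    for pop_id in dict.fromkeys(assignments.values()):
        if pop_id not in populations:
            populations[pop_id] = Population(pop_id, PANEL_HW)
    return PopulationStructure(populations=populations,
                               assignments=assignments)


def write_population_structure(path: str | Path,
                               structure: PopulationStructure,
                               delimiter: str = "\t") -> None:
    path = Path(path)
    buf = _io.StringIO()
    for pop in structure.populations.values():
        parts = ["#population", pop.population_id, pop.ptype]
        if pop.ptype == F1 and pop.parents:
            parts.append(",".join(pop.parents))
        elif pop.ptype == PARENT and pop.family:
            parts.append(pop.family)
        buf.write(" ".join(parts) + "\n")
    buf.write(delimiter.join(["sample_id", "population_id"]) + "\n")
    for sample, pop in structure.assignments.items():
        buf.write(delimiter.join([sample, pop]) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# parental priors


def read_parental_priors(path: str | Path,
                         delimiter: str | None = None
                         ) -> list[ParentalPrior]:
    path = Path(path)
    lines = [l for l in path.read_text(encoding="utf-8").splitlines()
             if l.strip() and not l.startswith("#")]
    if not lines:
        return []
    sep = _detect_delimiter(lines[0], delimiter)
    header = [h.strip() for h in lines[0].split(sep)]
    required = ["marker_id", "population_id", "dosage"]
    if header[:3] != required:
        raise ValidationError(
            f"{path}: expected header {sep.join(required)!r}")
    priors: list[ParentalPrior] = []
    seen: set[tuple[str, str]] = set()
    for line_no, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 3:
            raise ValidationError(f"{path}:{line_no}: expected 3 fields")
        marker, pop, dosage_tok = parts[:3]
        if dosage_tok in MISSING_CODES:
            continue
        try:
            dosage = int(dosage_tok)
        except ValueError:
            raise ValidationError(
                f"{path}:{line_no}: unparseable dosage {dosage_tok!r}")
        key = (marker, pop)
        if key in seen:
            raise ValidationError(
                f"{path}:{line_no}: duplicate prior for marker {marker!r}, "
                f"population {pop!r}")
        seen.add(key)
        priors.append(ParentalPrior(marker, pop, dosage))
    return priors


def write_parental_priors(path: str | Path,
                          priors: Iterable[ParentalPrior],
                          delimiter: str = "\t") -> None:
    path = Path(path)
    buf = _io.StringIO()
    buf.write(delimiter.join(["marker_id", "population_id", "dosage"]) + "\n")
    for p in priors:
        buf.write(delimiter.join(
            [p.marker_id, p.parent_population_id, str(p.dosage)]) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
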