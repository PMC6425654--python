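"""Batch driver: fit and call every marker, write the output tables.

Outputs are TSV with a fixed column order and 6-decimal floats so that
reruns are byte-identical.  Per-marker work is independent; parallel and
serial execution produce the same files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import MarkerResult, STATUS_CALLED, fit_marker
from .config import RunConfig
from .datamodel import (F1, MarkerSignals, ParentalPrior,
                        PopulationStructure, ValidationError,
                        priors_for_marker)
from .io import (read_parental_priors, read_population_structure,
                 read_signal_table)
from .qc import MatchReport, classify_marker, reports_to_frame, summarize_run

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


def _fit_one(signals: MarkerSignals, structure: PopulationStructure,
             priors: list[ParentalPrior], config: RunConfig) -> MarkerResult:
    try:
        marker_priors = priors_for_marker(priors, signals.marker_id)
        return fit_marker(signals, structure, prior_dosages=marker_priors,
                          config=config)
    except Exception as exc:  # per-marker failures never abort the run
        logger.error("marker %s: unexpected failure (%s)",
                     signals.marker_id, exc)
        from .calling import no_model_result
        return no_model_result(signals)


def scores_frame(results: list[MarkerResult],
                 structure: PopulationStructure,
                 markers: list[MarkerSignals]) -> pd.DataFrame:
    rows = []
    by_id = {m.marker_id: m for m in markers}
    for res in results:
        signals = by_id[res.marker_id]
        for i, sample in enumerate(res.sample_ids):
            if not np.isfinite(signals.y[i]):
                continue
            post = (res.posteriors.values[i] if res.posteriors is not None
                    else np.full(5, np.nan))
            call = res.calls[i] if res.calls is not None else np.nan
            rows.append({
                "marker_id": res.marker_id,
                "sample_id": sample,
                "population_id": structure.population_of(sample),
                "y": signals.y[i],
                "p_0": post[0], "p_1": post[1], "p_2": post[2],
                "p_3": post[3], "p_4": post[4],
                "max_posterior": (res.max_posterior[i]
                                  if res.max_posterior is not None
                                  else np.nan),
                "dosage": "" if not np.isfinite(call) else int(call),
            })
    return pd.DataFrame(rows)


def models_frame(results: list[MarkerResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        model = res.selected_model
        row = {"marker_id": res.marker_id, "status": res.status}
        if model is not None:
            row.update({
                "mu_constraint": model.mu_constraint,
                "pi_constraints": ";".join(
                    f"{p}={c}" for p, c in model.pi_constraint.items()),
                **{f"mu_{j}": model.mu[j] for j in range(5)},
                "sigma2": model.sigma2,
                "pi": "|".join(
                    p + ":" + ",".join(f"{v:.6f}" for v in model.pi[p])
                    for p in model.pi),
                "loglik": model.loglik,
                "bic": model.bic,
                "n_iter": model.n_iter,
            })
        else:
            row.update({"mu_constraint": "", "pi_constraints": "",
                        **{f"mu_{j}": np.nan for j in range(5)},
                        "sigma2": np.nan, "pi": "", "loglik": np.nan,
                        "bic": np.nan, "n_iter": 0})
        row["used_parental_prior"] = res.used_parental_prior
        rows.append(row)
    return pd.DataFrame(rows)


def run_batch(signals_path: str | Path, structure_path: str | Path,
              priors_path: str | Path | None = None,
              out_dir: str | Path = ".",
              config: RunConfig | None = None
              ) -> tuple[list[MarkerResult], dict[str, MatchReport],
                         pd.DataFrame]:
    """Fit every marker in a signal table and write the result bundle.

    Writes ``scores.tsv`` (per observed sample), ``models.tsv`` (one row
    per marker), ``match_reports.tsv`` and ``qc_summary.tsv`` (only when
    the structure contains an F1 family) under ``out_dir``.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    markers = read_signal_table(signals_path)
    structure = read_population_structure(structure_path)
    priors = (read_parental_priors(priors_path) if priors_path else [])
    for m in markers:
        for s in m.sample_ids:
            structure.population_of(s)  # raises on unknown samples

    if config.threads > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=config.threads)(
            delayed(_fit_one)(m, structure, priors, config) for m in markers)
    else:
        results = [_fit_one(m, structure, priors, config) for m in markers]
    for res in results:
        logger.info("marker %s: status=%s bic=%s iterations=%s",
                    res.marker_id, res.status,
                    f"{res.selected_model.bic:.2f}" if res.selected_model
                    else "NA",
                    res.selected_model.n_iter if res.selected_model else 0)

    scores = scores_frame(results, structure, markers)
    scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    models_frame(results).to_csv(out_dir / "models.tsv", sep="\t",
                                 index=False, float_format=_FLOAT_FMT)

    reports: dict[str, MatchReport] = {}
    summary = pd.DataFrame()
    if structure.populations_of_type(F1):
        for res in results:
            if res.status == STATUS_CALLED:
                reports[res.marker_id] = classify_marker(res, structure)
        frame = reports_to_frame(reports)
        frame.to_csv(out_dir / "match_reports.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)
        summary = summarize_run(reports, results)
        summary.to_csv(out_dir / "qc_summary.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)

    if config.plot:
        from .plotting import plot_marker
        plot_dir = out_dir / "plots"
        plot_dir.mkdir(exist_ok=True)
        by_id = {m.marker_id: m for m in markers}
        for res in results:
            if res.selected_model is not None:
                plot_marker(by_id[res.marker_id], structure, res,
                            plot_dir / f"{res.marker_id}.png")

    if not results:
        raise ValidationError("no markers processed")
    return results, reports, summary
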