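"""Per-marker diagnostic plot: per-population histograms with the
fitted mixture density, parental replicates highlighted."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .calling import MarkerResult
from .datamodel import PARENT, MarkerSignals, PopulationStructure
from .em import mixture_density


def plot_marker(signals: MarkerSignals, structure: PopulationStructure,
                result: MarkerResult, path: str | Path) -> None:
    model = result.selected_model
    if model is None:
        return
    pops = [p for p in structure.populations
            if structure.populations[p].ptype != PARENT]
    fig, axes = plt.subplots(len(pops), 1, figsize=(7, 2.6 * len(pops)),
                             sharex=True, squeeze=False)
    grid = np.linspace(0, np.pi / 2, 400)
    pop_of = [structure.population_of(s) for s in signals.sample_ids]
    for ax, pid in zip(axes.ravel(), pops):
        idx = [i for i, p in enumerate(pop_of)
               if p == pid and np.isfinite(signals.y[i])]
        ax.hist(signals.y[idx], bins=40, range=(0, np.pi / 2),
                density=True, alpha=0.6, color="steelblue")
        ax.plot(grid, mixture_density(grid, model, pid), "k-", lw=1)
        ptype = structure.populations[pid].ptype
        if ptype == "F1":
            for par in structure.parents_of(pid):
                members = set(structure.members(par))
                pj = [i for i, s in enumerate(signals.sample_ids)
                      if s in members and np.isfinite(signals.y[i])]
                ax.plot(signals.y[pj], np.zeros(len(pj)), "rv", ms=6,
                        label=f"parent {par}")
            ax.legend(fontsize=7)
        ax.set_ylabel(pid, fontsize=8)
    axes.ravel()[-1].set_xlabel("transformed signal ratio")
    fig.suptitle(f"{signals.marker_id} ({result.status})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
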