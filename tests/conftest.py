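import numpy as np
import pytest

from tetradose.datamodel import (F1, PANEL_HW, PARENT, Population,
                                 PopulationStructure)
from tetradose.simulate import PopSpec, SimSpec, make_test_layout, simulate_marker


@pytest.fixture
def panel_structure():
    """Single HW panel of 8 samples."""
    samples = [f"s{i}" for i in range(8)]
    return PopulationStructure(
        populations={"PANEL": Population("PANEL", PANEL_HW)},
        assignments={s: "PANEL" for s in samples},
    )


@pytest.fixture
def family_structure():
    """F1 family with two linked parents and a panel."""
    populations = {
        "P1": Population("P1", PARENT, family="F1"),
        "P2": Population("P2", PARENT, family="F1"),
        "F1": Population("F1", F1, parents=("P1", "P2")),
        "PANEL": Population("PANEL", PANEL_HW),
    }
    assignments = {}
    for i in range(3):
        assignments[f"p1_{i}"] = "P1"
        assignments[f"p2_{i}"] = "P2"
    for i in range(20):
        assignments[f"f1_{i}"] = "F1"
    for i in range(10):
        assignments[f"pan_{i}"] = "PANEL"
    return PopulationStructure(populations=populations,
                               assignments=assignments)


@pytest.fixture
def small_sim():
    """One small simulated marker with known truth (2x4 cross)."""
    spec = make_test_layout(n_f1=120, n_panel=40, n_markers=1, seed=42,
                            sigma=0.03, parent_dosages=(2, 4),
                            panel_allele_freq=0.5)
    return simulate_marker(spec, 0)


def panel_sim_spec(seed, n=300, sigma=0.04, allele_freq=0.5):
    """Single-panel SimSpec used by EM tests."""
    return SimSpec(
        n_markers=1,
        populations=(PopSpec("PANEL", PANEL_HW, n, allele_freq=allele_freq),),
        sigma=sigma, seed=seed)
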