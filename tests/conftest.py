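import numpy as np
import pandas as pd
import pytest

from m6ascope.simulate import (NOISELESS, NoiseModel, Phenotype,
                               SimulationConfig, simulate_experiment)


def make_two_phenotypes(genes=None, mean_a=60, mean_b=40, frac_a=0.3, frac_b=0.15):
    genes = genes or {}
    return (
        Phenotype("K562", {"green": 250.0, "red": 30.0},
                  mean_molecules=mean_a, m6a_fraction=frac_a, expression=genes),
        Phenotype("YAC1", {"green": 30.0, "red": 250.0},
                  mean_molecules=mean_b, m6a_fraction=frac_b, expression=genes),
    )


DEFAULT_GATES = {
    "K562": {"green": (100.0, 1e9), "red": (0.0, 99.0)},
    "YAC1": {"green": (0.0, 99.0), "red": (100.0, 1e9)},
}


@pytest.fixture(scope="session")
def small_noisy_experiment():
    """A small two-phenotype experiment with realistic noise, shared by tests."""
    cfg = SimulationConfig(
        com_shape=(20, 30), rdm_shape=(6, 8), rdm_offset=(5, 9),
        fov_shape=(80, 80), phenotypes=make_two_phenotypes(),
    )
    return simulate_experiment(cfg, seed=3), cfg


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Sparse, noise-free experiment for exact round-trip checks."""
    cfg = SimulationConfig(
        com_shape=(14, 18), rdm_shape=(5, 6), rdm_offset=(4, 7),
        fov_shape=(80, 80), loading_rate=0.45,
        min_spot_separation=7.0, noise=NOISELESS,
        phenotypes=make_two_phenotypes(mean_a=25, mean_b=15),
    )
    return simulate_experiment(cfg, seed=5), cfg


def planted_cells_frame(singlets, doublets, gates_label="K562"):
    """Cell records for planted singlet/doublet wells, bypassing image detection."""
    rows = []
    for wr, wc in singlets:
        rows.append({"row": wr * 10.0, "col": wc * 10.0, "green": 250.0,
                     "red": 30.0, "well_row": wr, "well_col": wc,
                     "in_grid": True, "phenotype": gates_label})
    for wr, wc in doublets:
        for _ in range(2):
            rows.append({"row": wr * 10.0, "col": wc * 10.0, "green": 30.0,
                         "red": 250.0, "well_row": wr, "well_col": wc,
                         "in_grid": True, "phenotype": "YAC1"})
    return pd.DataFrame(rows)
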