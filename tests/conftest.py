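import numpy as np
import pandas as pd
import pytest

import smtkit as sk


@pytest.fixture(scope="session")
def two_state_dataset():
    """Mid-size two-state SMT dataset (30% bound at D=0.005, 70% free
    at D=2) with the acquisition defaults; shared across tests."""
    cfg = sk.SimulationConfig(states=((0.005, 0.3), (2.0, 0.7)),
                              n_days=2, cells_per_day=30,
                              mean_mols_per_cell=60, seed=101)
    locs, truth = sk.simulate_smt_dataset(cfg)
    return cfg, locs, truth


@pytest.fixture(scope="session")
def two_state_jumps(two_state_dataset):
    _, locs, _ = two_state_dataset
    return sk.compute_jumps(locs)


def make_locs(rows, **extra):
    """Small localization table from (frame, traj, x, y) tuples."""
    df = pd.DataFrame(rows, columns=["frame", "trajectory", "x", "y"])
    df["cell_id"] = extra.get("cell_id", 0)
    df["day_id"] = extra.get("day_id", 0)
    return df
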