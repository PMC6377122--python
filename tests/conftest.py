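import numpy as np
import pandas as pd
import pytest

from vmrnorm import SimConfig, simulate_experiment, simulate_light_map


def make_table(n_larvae=4, t_values=range(-2, 4), activity=0.05,
               strain="TL", stage_dpf=6, batch="R1", trial=1,
               stimulus="LightOn", wells=None):
    """Small hand-rollable activity table.

    ``activity`` may be a scalar, a callable ``f(larva_index, t)``, or an
    array of length n_larvae * len(t_values).
    """
    t_values = list(t_values)
    rows = []
    wells = wells or [f"{'ABCDEFGH'[i % 8]}{i % 12 + 1}"
                      for i in range(n_larvae)]
    for i in range(n_larvae):
        for t in t_values:
            rows.append({
                "larva_id": f"L{i + 1:03d}",
                "well": wells[i],
                "strain": strain,
                "stage_dpf": stage_dpf,
                "batch": batch,
                "trial": trial,
                "stimulus": stimulus,
                "t": t,
            })
    df = pd.DataFrame(rows)
    if callable(activity):
        df["activity"] = [activity(int(r.larva_id[1:]) - 1, r.t)
                          for r in df.itertuples()]
    else:
        df["activity"] = activity
    return df


@pytest.fixture(scope="session")
def light_map():
    return simulate_light_map(center=30.0, edge=20.0)


@pytest.fixture(scope="session")
def sim_default():
    """One standard simulated experiment: 3 stages, 2 batches, 48+48 larvae."""
    return simulate_experiment(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_flat():
    """Single flat-trace group (no stimulus response): the linear models are
    exactly the generator."""
    from vmrnorm import GroupSpec

    config = SimConfig(
        groups=(GroupSpec("TL", 6, baseline=0.01, peak=0.0, decay=1.0),),
        n_batches=2, n_larvae=48, t_range=(-29, 30), seed=11)
    return simulate_experiment(config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
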