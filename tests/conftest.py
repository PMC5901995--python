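"""Shared fixtures: small seeded landscapes and simulated telemetry.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

import seismove as sm


@pytest.fixture(scope="session")
def landscape():
    """A 4-km landscape at the study's default density and height mix."""
    return sm.make_landscape(2, extent_km=4.0)


@pytest.fixture(scope="session")
def truth():
    return sm.SimulationTruth(beta={"eDist": -1.0, "eDist:Veght": 0.5},
                              seed=3)


@pytest.fixture(scope="session")
def wolf_steps(landscape, truth):
    """Movement steps from five simulated wolves on the shared landscape."""
    tracks = [
        sm.simulate_ssf_track(landscape, truth, n_steps=300,
                              animal_id=f"w{i:02d}", species="wolf",
                              group=f"pack{i % 2}", seed=50 + i)
        for i in range(5)
    ]
    return pd.concat([sm.build_steps(t) for t in tracks], ignore_index=True)


@pytest.fixture(scope="session")
def wolf_strata(landscape, wolf_steps):
    return sm.build_strata(wolf_steps, landscape.seg_index, K=10, seed=11,
                           extent=landscape.extent)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_track(xy, start="2006-07-01T00:00:00", interval_h=1.0,
               animal_id="a1", species="bear", sex="F", group="g1"):
    """Helper: a Track from a coordinate list at a regular schedule."""
    xy = np.asarray(xy, dtype=float)
    t = pd.date_range(start, periods=len(xy),
                      freq=pd.Timedelta(hours=interval_h))
    fixes = pd.DataFrame({"animal_id": animal_id, "species": species,
                          "sex": sex, "group": group, "t": t,
                          "x": xy[:, 0], "y": xy[:, 1], "weight": 1.0})
    return sm.Track(animal_id, fixes, nominal_interval=interval_h)
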