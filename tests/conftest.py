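"""Shared fixtures: simulated tracks reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from tusktrack import preprocess as pp
from tusktrack import synthetic as syn
from tusktrack.geo import AzimuthalEquidistant
from tusktrack.preprocess import RegularTrack

SUMMER = (22.0, 78.2)
WINTER = (30.0, 80.3)


@pytest.fixture(scope="session")
def default_scenario():
    return syn.IndividualScenario(
        "A", SUMMER, WINTER, n_years=2, scouting=[(280, 10.0)])


@pytest.fixture(scope="session")
def sim_track(default_scenario):
    """(fixes, truth) for the default two-year scenario."""
    return syn.simulate_track(default_scenario, 7)


@pytest.fixture(scope="session")
def regular_track(sim_track):
    fixes, _ = sim_track
    screened, _ = pp.screen_fixes(fixes)
    return pp.regularize(screened)


@pytest.fixture(scope="session")
def clean_track():
    """Noise-light, gap-free one-year track where the regularized 3-h lattice
    coincides with the latent steps."""
    scn = syn.IndividualScenario("C", SUMMER, WINTER, n_years=1,
                                 fix_fail_prob=0.0, gps_noise_m=1.0)
    fixes, truth = syn.simulate_track(scn, 11)
    screened, _ = pp.screen_fixes(fixes)
    return pp.regularize(screened), truth, scn


def make_planar_track(x, y, step_hours=3.0, track_id="T"):
    """RegularTrack straight from planar coordinates (testing helper)."""
    t = pd.date_range("2015-01-01", periods=len(x), freq=f"{int(step_hours)}h")
    proj = AzimuthalEquidistant(0.0, 75.0)
    lon, lat = proj.inverse(np.asarray(x, float), np.asarray(y, float))
    df = pd.DataFrame({"id": track_id, "timestamp": t, "lon": lon, "lat": lat,
                       "x": x, "y": y, "segment": 0})
    return RegularTrack(df, proj, step_hours)
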