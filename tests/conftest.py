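"""Shared fixtures: a quick small scene for unit tests and the package's
reference study conditions (default scene, 835-row campaign table, 70/30
split) for the heavier recovery and comparison tests."""

from __future__ import annotations

import numpy as np
import pytest

from lurpm.ensemble import SplitSpec, split_table
from lurpm.synthetic import build_scene, default_scene
from lurpm.workflow import route_feature_table, station_feature_table

#: reduced-scale forest configuration used for the stochastic selection and
#: comparison experiments (20 trees, a third of the features per split)
RF_EXPERIMENT = dict(n_estimators=20, max_features=0.33)

#: forest configuration for impurity-importance ranking (plain RFE): feature
#: subsampling dilutes impurity importance across correlated buffer columns,
#: so ranking uses all features per split and a fuller forest
RF_RANKING = dict(n_estimators=100, max_features=1.0)

#: campaign row count used for the reference split
CAMPAIGN_ROWS = 835


@pytest.fixture(scope="session")
def small_scene():
    """An 800 m scene with 3 rounds: fast enough for unit tests."""
    return build_scene(
        seed=7,
        extent=800.0,
        resolution=10.0,
        route_lanes=5,
        n_rounds=3,
        n_stations=4,
        station_days=30,
    )


@pytest.fixture(scope="session")
def campaign():
    """Default study conditions: scene, 835-row feature table, 70/30 split."""
    scene = default_scene(seed=1)
    table = route_feature_table(scene, max_rows=CAMPAIGN_ROWS)
    assert len(table) == CAMPAIGN_ROWS
    train, test = split_table(table, SplitSpec(seed=1))
    return scene, table, train, test


@pytest.fixture(scope="session")
def campaign_station_table(campaign):
    scene = campaign[0]
    return station_feature_table(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
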