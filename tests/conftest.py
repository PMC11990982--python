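"""Shared fixtures: small seeded datasets built through the package's own
synthetic generator, plus a generic separable classification table."""

import datetime as dt
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
import pytest

from bloomcam import features
from bloomcam.features import FEATURES
from bloomcam.kknn import NEGATIVE, POSITIVE
from bloomcam.synthetic import (
    ScenarioConfig,
    generate_feature_table,
    generate_observation_schedule,
)

UTC = ZoneInfo("UTC")


def make_labeled_frame(
    n_pos: int,
    n_neg: int,
    n_features: int = 4,
    separation: float = 3.0,
    seed: int = 0,
    start: dt.datetime | None = None,
) -> pd.DataFrame:
    """A two-class Gaussian table with feature-table-like columns.

    Positive records sit ``separation`` standard units away from negatives
    in every feature.  Timestamps are hourly so diel grouping works.
    """
    rng = np.random.default_rng(seed)
    start = start or dt.datetime(2022, 5, 1, tzinfo=UTC)
    names = list(FEATURES[:n_features])
    X = np.vstack([
        rng.normal(0.0, 1.0, size=(n_neg, n_features)),
        rng.normal(separation, 1.0, size=(n_pos, n_features)),
    ])
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "roi_id", "Syn")
    df.insert(1, "timestamp", [start + dt.timedelta(hours=i) for i in range(len(df))])
    df["class"] = [NEGATIVE] * n_neg + [POSITIVE] * n_pos
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


@pytest.fixture(scope="session")
def season_table():
    """A filtered mid-season synthetic plant-year slice with ground truth."""
    cfg = ScenarioConfig(year=2022, start_doy=90, end_doy=200,
                         cadence_minutes=120, seed=11)
    table, truth = generate_feature_table(cfg)
    clean = features.preprocess(table, truth.site)
    return clean, truth


@pytest.fixture(scope="session")
def season_observations(season_table):
    _, truth = season_table
    return generate_observation_schedule(truth, seed=5)
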