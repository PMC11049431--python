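"""Shared fixtures: small simulated cohorts and hand-built record tables."""

import numpy as np
import pandas as pd
import pytest

from avoshelf.fruitdb import LabeledImageDatabase, annotate_days_left
from avoshelf.synthetic_orchard import (CohortConfig, RenderConfig, render_cohort,
                                        simulate_cohort)

#: 10-stage palette with widely separated colors per 5-stage class
#: (used for color-separability sanity checks; L* nonincreasing over 1..8).
SEPARABLE_PALETTE = np.array(
    [[90.0, -40.0, 60.0]] * 2 + [[70.0, 60.0, 50.0]] * 2 +
    [[50.0, -50.0, -20.0]] * 2 + [[30.0, 40.0, -50.0]] * 2 + [[15.0, 0.0, 0.0]] * 2)


def make_records(rows):
    """Build a valid records DataFrame from (sample_id, side, day, group, ri10) tuples."""
    recs = []
    for sample_id, side, day, group, ri10 in rows:
        recs.append({"sample_id": sample_id, "side": side, "group": group,
                     "day": day, "date_stamp": f"2022-03-{15 + day:02d}",
                     "ri5": (ri10 + 1) // 2, "ri10": ri10,
                     "days_left5": np.nan, "days_left9": np.nan, "censored": False})
    columns = ["sample_id", "side", "group", "day", "date_stamp",
               "ri5", "ri10", "days_left5", "days_left9", "censored"]
    return pd.DataFrame(recs, columns=columns)


@pytest.fixture(scope="session")
def small_cohort():
    """30-fruit fast-ripening cohort: trajectories + metadata (no images)."""
    cfg = CohortConfig(group_sizes={"T20": 20, "Tamb": 10})
    trajectories, records = simulate_cohort(cfg, rng_seed=101)
    return cfg, trajectories, records


@pytest.fixture(scope="session")
def small_db(small_cohort):
    """The 30-fruit cohort as an annotated database with rendered 48px images."""
    _, trajectories, records = small_cohort
    images = render_cohort(trajectories, records, RenderConfig(image_size=48), rng_seed=102)
    db = LabeledImageDatabase(records=records, images=images)
    return annotate_days_left(db)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
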