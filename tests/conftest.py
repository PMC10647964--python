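import numpy as np
import pandas as pd
import pytest

from artflag import CohortSpec, DoseGrid, StructureMask, generate_cohort
from artflag.protocol import ProtocolConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230713)


@pytest.fixture
def random_grid_and_mask(rng):
    """A small random dose grid with a non-trivial mask (<= 10^3 voxels)."""
    values = rng.uniform(0.0, 70.0, size=(8, 9, 10))
    mask = rng.random((8, 9, 10)) < 0.4
    mask[0, 0, 0] = True  # never empty
    return DoseGrid(values, spacing=(2.0, 2.0, 3.0)), StructureMask(mask, "PTV_T", "target")


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort (>= 2000 comparison units) shared by
    evaluation-level tests."""
    return generate_cohort(CohortSpec(n_patients=8, seed=42))


@pytest.fixture
def upgraded_config():
    return ProtocolConfig.upgraded()


@pytest.fixture
def initial_config():
    return ProtocolConfig.initial(level=1)


def make_metric_tables(planned: dict, estimated_by_fraction: dict, patient="P0"):
    """Build tidy planned/estimated tables from nested dicts.

    ``planned``: {(roi, metric): value}; ``estimated_by_fraction``:
    {fraction: {(roi, metric): value}}.
    """
    planned_df = pd.DataFrame(
        [
            {"patient_id": patient, "roi": roi, "metric": metric, "value_Gy": value}
            for (roi, metric), value in planned.items()
        ]
    )
    est_df = pd.DataFrame(
        [
            {"patient_id": patient, "fraction": fx, "roi": roi, "metric": metric,
             "value_Gy": value}
            for fx, metrics in estimated_by_fraction.items()
            for (roi, metric), value in metrics.items()
        ]
    )
    return planned_df, est_df
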