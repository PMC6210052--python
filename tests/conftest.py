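import numpy as np
import pandas as pd
import pytest

from ithfish.classify import Thresholds, classify_cells
from ithfish.cohort import CELL_COLUMNS
from ithfish.simulate import generate_cohort


def make_cells(rows: list[dict]) -> pd.DataFrame:
    """Cell table from compact dicts; unspecified fields get benign defaults."""
    defaults = {
        "patient_id": "P0",
        "timepoint": "pre",
        "image_id": "img0",
        "er_intensity": 10.0,
        "her2_intensity": 10.0,
        "her2_area_px": 30.0,
        "cent17_count": 2.0,
        "spatial_label": None,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=list(CELL_COLUMNS))


@pytest.fixture
def thresholds() -> Thresholds:
    return Thresholds()


@pytest.fixture(scope="session")
def archetype_cohort():
    """36-patient three-archetype cohort, classified; shared across tests."""
    cohort = generate_cohort(scenario="three_archetypes", seed=7, cells_per_sample=300)
    return cohort, classify_cells(cohort.cells)


@pytest.fixture(scope="session")
def kl_cohort():
    """40-patient shift-contrast cohort, classified; shared across tests."""
    cohort = generate_cohort(scenario="kl_contrast", seed=11, cells_per_sample=300)
    return cohort, classify_cells(cohort.cells)
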