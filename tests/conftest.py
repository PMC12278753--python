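import numpy as np
import pandas as pd
import pytest

from lipotrace.config import CohortConfig, PlateConfig
from lipotrace.cohort import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but fully structured synthetic study."""
    cfg = CohortConfig(n_control=12, n_statin=14, n_his=6)
    return generate_cohort(cfg, seed=11)


@pytest.fixture
def fast_plate_cfg():
    """Plate settings small enough for per-test simulation (monocyte-only wells)."""
    return PlateConfig(
        wells_per_condition=2, experiments=2, n_plate_batches=2,
        cells_per_well_mean=80, lymphocyte_fraction=0.0,
    )


@pytest.fixture
def deterministic_plate_cfg():
    """Zero-noise plate settings: every draw collapses to its expectation."""
    return PlateConfig(
        wells_per_condition=2, experiments=2, n_plate_batches=2,
        cells_per_well_mean=60, lymphocyte_fraction=0.0, noise_scale=0.0,
    )


def make_cells(well_id="W1", subject_id="S1", batch_id="B0E0", condition="R",
               assay="uptake", group="subject", **columns):
    """Hand-rolled single-cell records for pipeline unit tests."""
    n = max(len(np.atleast_1d(v)) for v in columns.values()) if columns else 1
    base = {
        "subject_id": subject_id, "group": group, "batch_id": batch_id,
        "well_id": well_id, "condition": condition, "assay": assay,
        "cell_area": 150.0, "ldl_intensity": np.nan, "ldl_organelles": np.nan,
        "ld_count": np.nan, "ld_area": np.nan, "ld_positive": np.nan,
    }
    data = {}
    for key, default in base.items():
        v = columns.get(key, default)
        data[key] = np.resize(np.atleast_1d(v), n) if np.ndim(v) else np.full(n, v, dtype=object if isinstance(v, str) else None)
    return pd.DataFrame(data)
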