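import warnings

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Short test chains legitimately trip the R-hat warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="split-Rhat")
        warnings.filterwarnings("ignore", message="single basin")
        yield


@pytest.fixture
def toy_survey_csv(tmp_path):
    """Three-row single-site count survey."""
    path = tmp_path / "survey.csv"
    pd.DataFrame(
        {
            "site_id": ["s1", "s1", "s1"],
            "basin_id": ["b1", "b1", "b1"],
            "date": ["2001-06-15", "2001-06-15", "2001-06-15"],
            "protocol": ["electrofishing"] * 3,
            "species_id": ["trout", "perch", "pike"],
            "abundance": [10, 5, 1],
            "unit": ["count"] * 3,
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def covariates_frame():
    rng = np.random.default_rng(7)
    n = 12
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "basin_id": ["b1"] * 6 + ["b2"] * 6,
            "hfi_1993": rng.uniform(1, 45, n),
            "hfi_2009": rng.uniform(1, 45, n),
            "altitude_m": rng.uniform(10, 900, n),
            "slope_deg": rng.uniform(0.1, 9, n),
            "discharge_m3s": rng.uniform(0.5, 80, n),
            "dist_source_km": rng.uniform(1, 300, n),
            "strahler": rng.integers(1, 8, n).astype(float),
            "limed": [False] * n,
            "realm": ["Palearctic"] * n,
        }
    )
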