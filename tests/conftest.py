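"""Shared fixtures: small panels, reduced-scale configs, cached estimands."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panelmediate.data_model import ANALYSIS_VARIABLES, PanelTable
from panelmediate.synthetic_data import default_config, estimand_paths, generate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_analysis_frame(n: int, seed: int) -> pd.DataFrame:
    """Random in-bounds analysis data (no structural model) for OLS oracles."""
    r = np.random.default_rng(seed)
    frame = pd.DataFrame({"subject_id": np.arange(1, n + 1)})
    bounds = {
        "x_t1": (1, 9),
        "m1_t2": (1, 5),
        "m2_t2": (1, 5),
        "m3_t2": (1, 4),
        "y_t2": (1, 4),
        "u1_t1": (1, 5),
        "u2_t1": (1, 5),
        "u3_t1": (1, 4),
        "u4_t1": (1, 4),
    }
    for col in ANALYSIS_VARIABLES:
        lo, hi = bounds[col]
        frame[col] = r.uniform(lo, hi, size=n)
    return frame


@pytest.fixture
def analysis_frame():
    return random_analysis_frame(60, seed=5)


@pytest.fixture(scope="session")
def complete_default_panel():
    """One moderate fully observed panel at the study conditions."""
    cfg = default_config(n=2000, seed=42, missing_rates={})
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def default_estimand():
    """Large-sample complete-data OLS benchmark under the default generator."""
    return estimand_paths(default_config(), n=150_000, seed=99)


def make_small_panel(values: dict[str, list], bounds=None) -> PanelTable:
    n = len(next(iter(values.values())))
    frame = pd.DataFrame({"subject_id": np.arange(1, n + 1), **values})
    return PanelTable(frame, bounds=bounds)
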