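import numpy as np
import pandas as pd
import pytest

import bpvar as bv


@pytest.fixture(scope="session")
def small_truth() -> bv.SimulationTruth:
    """Stable 3-variable VAR(1) truth for a 5-country, 12-year panel."""
    rng = np.random.default_rng(42)
    coefs = bv.random_stable_var(3, 1, max_spectral_radius=0.8, seed=rng)
    omega = bv.simulate.random_spd(3, rng, scale=0.5)
    return bv.SimulationTruth(
        n_countries=5, n_years=12, n_vars=3, lag_order=1,
        lag_coefficients=coefs, innovation_covariance=omega,
        fixed_effects=rng.normal(size=(5, 3)),
        trend_slopes=rng.normal(scale=0.01, size=(5, 3)),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_truth) -> bv.PanelDataset:
    return bv.simulate_panel(small_truth)


@pytest.fixture(scope="session")
def small_spec(small_panel) -> bv.VARSpec:
    return bv.VARSpec(tuple(small_panel.variable_order), lag_order=1)


@pytest.fixture(scope="session")
def small_design(small_panel, small_spec) -> bv.RegressorMatrices:
    return bv.build_design(small_panel, small_spec)


@pytest.fixture()
def toy_frame() -> pd.DataFrame:
    """Hand-written 3-country, 3-year, 2-variable long table."""
    rows = []
    for c, base in [("A", 1.0), ("B", 2.0), ("C", 3.0)]:
        for y in (2000, 2001, 2002):
            rows.append({"country": c, "year": y, "x": base + 0.1 * (y - 2000), "z": base * 2})
    return pd.DataFrame(rows)
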