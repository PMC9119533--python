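import numpy as np
import pandas as pd
import pytest

from holclink import (
    SyntheticConfig,
    generate_coverages,
    generate_outcomes,
    run_grid,
)


def coverage_frame(rows: dict[str, tuple[float, float, float, float, float]]
                   ) -> pd.DataFrame:
    """Build a coverage table from {tract_id: (A, B, C, D, U)}."""
    recs = [
        {"tract_id": tid, "pct_a": a, "pct_b": b, "pct_c": c,
         "pct_d": d, "pct_u": u}
        for tid, (a, b, c, d, u) in rows.items()
    ]
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def sim_config() -> SyntheticConfig:
    """Default study conditions: 1,500 tracts, all rank combinations enforced."""
    return SyntheticConfig(n_tracts=1500, seed=11)


@pytest.fixture(scope="session")
def sim_coverages(sim_config) -> pd.DataFrame:
    return generate_coverages(sim_config)


@pytest.fixture(scope="session")
def sim_outcomes(sim_config, sim_coverages) -> pd.DataFrame:
    return generate_outcomes(sim_coverages, sim_config)


@pytest.fixture(scope="session")
def sim_grid(sim_coverages, sim_outcomes) -> pd.DataFrame:
    """The full 54 x 6 x 7 cross-validation grid on the session universe."""
    return run_grid(sim_coverages, sim_outcomes, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
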