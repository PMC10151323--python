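import numpy as np
import pytest

from polarhit import TimeGrid, default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120 synthetic patients with a short 16-bin grid; shared read-only."""
    cfg = default_config(
        n_patients=120, seed=42, grid=TimeGrid(30, 450),
        followup_min_days=200, followup_max_days=420,
    )
    cohort, truth = generate_cohort(cfg)
    return cohort, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
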