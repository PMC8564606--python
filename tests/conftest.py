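import warnings

import numpy as np
import pandas as pd
import pytest

from impairfit.records import CANONICAL_COLUMNS, build_histories
from impairfit.simulate import (
    SimulationConfig,
    null_config,
    scenario_config,
    simulate_population,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical event frame from sparse row dicts."""
    defaults = dict(
        tag="A1", plot="GX", year=2015, week=20, day=1, x=30.0, y=30.0,
        sex="F", age="adult", mass_g=20.0, ticks=0, botflies=0,
        impair_codes="", tail_snip=False,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=CANONICAL_COLUMNS)


@pytest.fixture
def events_factory():
    return make_events


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated study with raised impairment hazards (shared
    across tests to keep the suite fast)."""
    cfg = scenario_config(n_individuals_per_plot_year=60)
    events, truth = simulate_population(cfg, seed=42)
    return cfg, events, truth


@pytest.fixture(scope="session")
def small_histories(small_sim):
    _, events, _ = small_sim
    return build_histories(events)


@pytest.fixture(scope="session")
def null_sim():
    cfg = null_config(
        n_individuals_per_plot_year=40,
        impairment_hazard={"tail": 6e-3, "limb": 1.5e-3, "eye": 1.5e-3},
    )
    events, truth = simulate_population(cfg, seed=7)
    return cfg, events, truth


from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
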