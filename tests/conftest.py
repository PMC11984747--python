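import numpy as np
import pandas as pd
import pytest

from venomclim.synth import (
    ScenarioConfig,
    bioclim_grids,
    extract_covariates,
    generate_scenario,
    preset_config,
    sample_sites,
    simulate_activities,
    simulate_monthly_climate,
)

SEED = 20260920


@pytest.fixture(scope="session")
def basic_scenario():
    """Default study: 115 samples, 34 locations, identity-scale truth."""
    return generate_scenario(preset_config("basic", SEED))


@pytest.fixture(scope="session")
def highsnr_pieces():
    """Shared climate/covariate machinery for replicate experiments."""
    cfg = preset_config("highsnr", SEED)
    monthly = simulate_monthly_climate(cfg)
    bgrids = bioclim_grids(monthly)
    return cfg, bgrids


@pytest.fixture(scope="session")
def lognormal_pieces():
    cfg = preset_config("lognormal", SEED)
    monthly = simulate_monthly_climate(cfg)
    bgrids = bioclim_grids(monthly)
    return cfg, bgrids


def redraw_dataset(cfg, bgrids, seed):
    """New noise (and new sites) under a fixed climate."""
    from dataclasses import replace

    cfg = replace(cfg, seed=seed)
    sites = sample_sites(cfg)
    X = extract_covariates(sites, bgrids)
    table, truth = simulate_activities(sites, X, cfg)
    return X, table, truth
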