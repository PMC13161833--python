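import numpy as np
import pandas as pd
import pytest

import kgflux as kg


@pytest.fixture(scope="session")
def small_site():
    """A 30-day synthetic site record (drivers, table with derived columns, truth)."""
    cfg = kg.SiteConfig(n_days=30, start_doy=150, seed=5)
    drivers = kg.generate_met(cfg)
    table, truth = kg.simulate_fluxes(drivers, cfg)
    table = kg.derive_base_reco(kg.derive_night_mask(table))
    return cfg, table, truth


@pytest.fixture(scope="session")
def tiny_model():
    """A small untrained network for fast structural tests."""
    cfg = kg.ModelConfig(encoder_width=16, head_width=8, seed=1)
    return kg.KGMLModel(cfg)


@pytest.fixture
def random_features(tiny_model):
    rng = np.random.default_rng(0)
    return rng.standard_normal((40, len(tiny_model.config.input_variables)))
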