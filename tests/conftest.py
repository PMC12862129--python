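import pytest

import statedep as sd


@pytest.fixture(scope="session")
def noise_free_panel():
    """Small switcher panel with life satisfaction exactly on the model."""
    cfg = sd.SyntheticConfig(n_individuals=2000, noise_sd=0.0, seed=11)
    return sd.filter_switchers(sd.simulate_panel(cfg))


@pytest.fixture(scope="session")
def small_noisy_panel():
    """Moderate switcher panel with realistic noise, for quick noisy fits."""
    cfg = sd.SyntheticConfig(n_individuals=2500, seed=7)
    return sd.filter_switchers(sd.simulate_panel(cfg))


@pytest.fixture(scope="session")
def default_panel():
    """Full-size switcher panel at the generator's calibrated defaults."""
    cfg = sd.SyntheticConfig(seed=1)
    return sd.filter_switchers(sd.simulate_panel(cfg))
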