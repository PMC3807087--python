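import pytest

from roseshoot import CropConfig, fit_crop, generate_crop, table4_defaults, table5_defaults


@pytest.fixture(scope="session")
def profiles():
    return table5_defaults()


@pytest.fixture(scope="session")
def coord():
    return table4_defaults()


@pytest.fixture(scope="session")
def default_crop():
    """The 30-plant virtual crop under default study conditions (seed 1)."""
    crop, truth = generate_crop(CropConfig(n_plants=30, seed=1))
    return crop, truth


@pytest.fixture(scope="session")
def default_crop_fits(default_crop):
    crop, _ = default_crop
    return fit_crop(crop)


@pytest.fixture(scope="session")
def small_noise_free_crop():
    """A small crop with every stochastic perturbation switched off."""
    config = CropConfig(n_plants=10, seed=2).zero_noise()
    crop, truth = generate_crop(config)
    return crop, truth
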