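import numpy as np
import pytest

from nanosers import synthetic as syn


@pytest.fixture(scope="session")
def band_table():
    return syn.make_band_table()


@pytest.fixture(scope="session")
def default_image():
    """One default synthetic micrograph with its ground truth."""
    spec = syn.ImageSpec(seed=7)
    image, truth = syn.generate_particle_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def axis():
    return syn.default_wavenumber_axis()


def make_map_spec(seed: int, **overrides) -> syn.MapSpec:
    import dataclasses

    return dataclasses.replace(syn.MapSpec(), seed=seed, **overrides)


@pytest.fixture
def map_spec_factory():
    return make_map_spec
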