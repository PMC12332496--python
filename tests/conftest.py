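import pytest

from geoschemes.builder import build_world
from geoschemes.synthworld import WorldSpec, generate_world, world_build_config


@pytest.fixture(scope="session")
def world():
    """Default toy planet: (spec, source layers, ground-truth manifest)."""
    spec = WorldSpec()
    layers, manifest = generate_world(spec)
    return spec, layers, manifest


@pytest.fixture(scope="session")
def built(world):
    """Full builder run over the default toy planet."""
    spec, layers, _ = world
    return build_world(layers, world_build_config(spec))


@pytest.fixture(scope="session")
def minimal_world():
    spec = WorldSpec.minimal()
    layers, manifest = generate_world(spec)
    return spec, layers, manifest
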