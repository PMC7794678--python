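import numpy as np
import pytest

from swardmap.scene import SceneSpec, compose_scene, make_sprite_bank


@pytest.fixture(scope="session")
def sprite_bank():
    return make_sprite_bank(12, rng_seed=7)


@pytest.fixture(scope="session")
def scene_factory(sprite_bank):
    """Factory for small labelled scenes; results cached per parameter set."""
    cache = {}

    def make(seed=0, size=128, coverage=0.7, mix=(0.4, 0.3, 0.2, 0.1)):
        key = (seed, size, coverage, mix)
        if key not in cache:
            spec = SceneSpec(width_px=size, height_px=size,
                             target_coverage=coverage, species_mix=mix,
                             rng_seed=seed)
            cache[key] = compose_scene(spec, sprite_bank)
        return cache[key]

    return make


@pytest.fixture(scope="session")
def scene(scene_factory):
    """One mixed scene containing every species."""
    return scene_factory(seed=3, size=160, coverage=0.75)


@pytest.fixture(scope="session")
def scene_set(scene_factory):
    """A small set of varied scenes (coverage and mixture sweep)."""
    mixes = [(0.4, 0.3, 0.2, 0.1), (0.7, 0.1, 0.1, 0.1),
             (0.2, 0.5, 0.2, 0.1), (0.25, 0.25, 0.25, 0.25)]
    return [scene_factory(seed=10 + i, size=128, coverage=cov, mix=mixes[i % 4])
            for i, cov in enumerate((0.3, 0.5, 0.7, 0.85, 0.6, 0.4, 0.75, 0.55))]
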