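import numpy as np
import pytest

from wsiseg import SlideSpec, generate_slide, tile_slide


@pytest.fixture(scope="session")
def default_spec() -> SlideSpec:
    return SlideSpec(seed=123)


@pytest.fixture(scope="session")
def slide_pair(default_spec):
    return generate_slide(default_spec)


@pytest.fixture(scope="session")
def slide_patches(slide_pair):
    """256x256 patch pairs from one default synthetic slide."""
    _, patches = tile_slide(slide_pair.image, slide_pair.mask,
                            slide_id=slide_pair.slide_id)
    return patches


@pytest.fixture(scope="session")
def small_patches():
    """64x64 patch pairs (cheap network inputs) from small slides."""
    spec = SlideSpec(width_px=256, height_px=256, blob_radius_px=(25, 60),
                     seed=99)
    patches = []
    for i in range(4):
        pair = generate_slide(spec, slide_id=f"small_{i}", seed=spec.seed + i)
        _, ps = tile_slide(pair.image, pair.mask, tile_size=64,
                           min_fg=0.1, slide_id=pair.slide_id)
        patches.extend(ps)
    return patches


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
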