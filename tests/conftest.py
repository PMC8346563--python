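import numpy as np
import pytest

from exudetect import Patch, SynthConfig, generate_fundus


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_patch(value=0, pixels=None, origin=(0, 0), source_id="test", provenance="original"):
    """A 224x224x3 patch filled with `value` unless explicit pixels are given."""
    if pixels is None:
        pixels = np.full((224, 224, 3), value, dtype=np.uint8)
    return Patch(pixels=pixels, origin=origin, source_id=source_id, provenance=provenance)


def lesion_patch(background=150, gain=80, center=(112, 112), axes=(8, 6), noise_seed=None):
    """A synthetic patch: uniform background plus one bright ellipse."""
    px = np.full((224, 224, 3), background, dtype=np.float64)
    yy, xx = np.mgrid[0:224, 0:224]
    foot = ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 <= 1.0
    px[foot] += gain
    if noise_seed is not None:
        px += np.random.default_rng(noise_seed).normal(0, 2, px.shape)
    return make_patch(pixels=np.clip(px, 0, 255).astype(np.uint8)), foot


@pytest.fixture(scope="session")
def small_fundus():
    """One deterministic 448x448 synthetic fundus with lesions."""
    return generate_fundus(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def fundus_config():
    return SynthConfig(seed=42)
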