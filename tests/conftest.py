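import numpy as np
import pytest

from slidequant import Layer, SyntheticSlideSpec, render_slide


@pytest.fixture(scope="session")
def rgb_layer():
    """Deterministic random RGB layer for tiling/masking geometry tests."""
    rng = np.random.default_rng(42)
    return Layer(rng.integers(0, 256, size=(700, 1000, 3), dtype=np.uint8), 20.0)


@pytest.fixture(scope="session")
def small_slide():
    """One rendered synthetic slide (separated nuclei, sensor noise)."""
    spec = SyntheticSlideSpec(
        seed=3, canvas=(1024, 1024), nucleus_count=50, clump_fraction=0.0,
        noise_sigma=2.0,
    )
    slide, truth = render_slide(spec)
    return slide, truth


@pytest.fixture(scope="session")
def clumped_slide():
    """Synthetic slide with 20% of nuclei in touching pairs."""
    spec = SyntheticSlideSpec(
        seed=2, canvas=(1024, 1024), nucleus_count=100, clump_fraction=0.2,
        noise_sigma=2.0,
    )
    slide, truth = render_slide(spec)
    return slide, truth
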