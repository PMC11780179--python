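import numpy as np
import pytest

from gatedlung import PhantomSpec, VolumeImage, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(64, 64, 64))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """Noise-free 64^3 phantom pair with truth (shared, read-only)."""
    return generate_phantom(small_spec)


def hu_image(values, spacing=0.075, phase="unknown", **kw):
    """Convenience constructor for small hand-built HU-scale grids."""
    return VolumeImage(
        values=np.asarray(values, float), spacing_mm=spacing,
        phase=phase, scale="HU", **kw,
    )
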