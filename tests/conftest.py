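import numpy as np
import pytest

from gfuse import BandImage, IlluminationRefs, Transform2D
from gfuse.synthetic import DEFAULT_SIZE, make_plant_capture


@pytest.fixture(scope="session")
def default_capture():
    """One default synthetic plant capture shared by read-only tests."""
    return make_plant_capture(seed=42)


@pytest.fixture(scope="session")
def clean_capture():
    """Noise-free capture on a single grid (identity thermal transform)."""
    return make_plant_capture(
        seed=5,
        noise_sd=0.0,
        gradient_amplitude=0.0,
        thermal_size=DEFAULT_SIZE,
        true_transform=Transform2D.identity(),
    )


@pytest.fixture()
def dark_refs():
    """Illumination references matching the generator's dark level (5 DN)."""
    h, w = 240, 320
    dark = BandImage(np.full((h, w), 5.0), "green", "unitless")
    return IlluminationRefs(dark=dark, corner_roi_px=4, ref_factor=0.80)
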