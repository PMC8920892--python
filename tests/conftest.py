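import numpy as np
import pytest
from scipy import ndimage

from replidyn.fiber_imaging import FiberImage
from replidyn.protocol import PulseProtocol


@pytest.fixture(scope="session")
def protocol() -> PulseProtocol:
    return PulseProtocol()


def synthetic_line_image(
    shape=(40, 120), row=20, col_span=(10, 110), amplitude=100.0, psf=1.5
) -> FiberImage:
    """Single straight horizontal line, PSF-blurred, no noise."""
    img = np.zeros(shape)
    img[row, col_span[0] : col_span[1]] = amplitude
    img = ndimage.gaussian_filter(img, psf)
    return FiberImage({"first": img, "second": np.zeros(shape)})


@pytest.fixture
def line_image() -> FiberImage:
    return synthetic_line_image()
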