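import numpy as np
import pytest

import hfus


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom shared by read-only tests."""
    spec = hfus.PhantomSpec(seed=7)
    image, truth = hfus.generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def segmented_phantom(default_phantom):
    """Default phantom plus its post-processed pipeline mask."""
    spec, image, truth = default_phantom
    mask = hfus.postprocess_mask(hfus.segment_entry_echo(image))
    return spec, image, truth, mask


@pytest.fixture()
def flat_band_image():
    """Noise-free frame: band of 220 on rows 100-140, dermis 100 below,
    background 20 above; default calibration, no ruler."""
    arr = np.full((400, 300), 20, dtype=np.uint8)
    arr[100:141, :] = 220
    arr[141:, :] = 100
    return hfus.BModeImage(arr, image_id="flat-band")


@pytest.fixture()
def flat_band_mask(flat_band_image):
    m = np.zeros(flat_band_image.intensities.shape, dtype=bool)
    m[100:141, :] = True
    return hfus.LayerMask(m, provenance="external")
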