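import numpy as np
import pytest

from nigraseg.imageio import ImageStack, Label, LabelMask
from nigraseg.phantom import PhantomParams, generate_subject


@pytest.fixture
def noiseless_params():
    return PhantomParams(sigma_noise=0.0, extent_sd=0.0)


@pytest.fixture
def subject_hc(noiseless_params):
    return generate_subject(noiseless_params, "HC", 7)


@pytest.fixture
def centered_params():
    """No geometric jitter: the midbrain sits exactly at the canvas centre."""
    return PhantomParams(
        sigma_noise=0.0, extent_sd=0.0, shift_px=0.0, rotation_deg=0.0, scale_range=(1.0, 1.0)
    )


def make_pair(image_slices, label_slices, spacing=(0.43, 0.43)):
    """Small hand-built (ImageStack, LabelMask) pair for example-based tests."""
    img = ImageStack(np.asarray(image_slices, dtype=float), pixel_spacing=spacing)
    msk = LabelMask(np.asarray(label_slices, dtype=np.uint8), pixel_spacing=spacing)
    return img, msk


@pytest.fixture
def tiny_pair():
    """Two 4x4 slices: a 2x2 midbrain with one SNpc pixel per slice."""
    lab = np.zeros((2, 4, 4), dtype=np.uint8)
    lab[:, 1:3, 1:3] = Label.BACKGROUND
    lab[0, 1, 1] = Label.SNPC
    lab[1, 2, 2] = Label.SNPC
    img = np.full((2, 4, 4), 50.0)
    img[lab == Label.BACKGROUND] = 100.0
    img[lab == Label.SNPC] = 140.0
    return make_pair(img, lab)
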