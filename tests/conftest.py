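import numpy as np
import pytest

from noduleomics import DiscretizationConfig, ImageVolume, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_cfg():
    """Bin width 1 so integer-valued toy volumes keep their levels."""
    return DiscretizationConfig(bin_width_hu=1.0)


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return ImageVolume(voxels=arr, spacing_mm=spacing)


def make_roi(volume: ImageVolume, mask=None, role="intra"):
    if mask is None:
        mask = np.ones(volume.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[:, :, None]
    return RoiMask(voxels=mask, role=role)


def ball_mask(shape, radius_vox, spacing=(1.0, 1.0, 1.0)):
    """Digitized ellipsoid: physical radius radius_vox * spacing[0]."""
    spacing = np.asarray(spacing, dtype=float)
    centre = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre, spacing))
    return d2 <= (radius_vox * spacing[0]) ** 2
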