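import numpy as np
import pytest

from capseg.model import (
    LABEL_INTIMA,
    LABEL_LUMEN,
    LABEL_MEDIA,
    CapSegParams,
    PolarimetricFrame,
    ScanGeometry,
    SegmentationMask,
)


@pytest.fixture
def geom():
    """Small frame geometry: 256 A-lines, 5 µm axial pitch, axis at depth 0."""
    return ScanGeometry(n_alines=256, axial_pitch=5.0)


@pytest.fixture
def params():
    return CapSegParams()


def make_layered_mask(geometry, lumen_radius_um, n_depth=320, wall_um=400.0):
    """Mask with a circular lumen of the given radius and a normal two-layer
    wall (intima then media) below the surface."""
    r = geometry.radius_of(np.arange(n_depth))
    rl = np.atleast_1d(np.asarray(lumen_radius_um, dtype=float))
    if rl.size == 1:
        rl = np.full(geometry.n_alines, rl[0])
    labels = np.zeros((geometry.n_alines, n_depth), dtype=np.uint8)
    depth = r[None, :] - rl[:, None]
    labels[depth < 0] = LABEL_LUMEN
    labels[(depth >= 0) & (depth < 0.4 * wall_um)] = LABEL_INTIMA
    labels[(depth >= 0.4 * wall_um) & (depth < wall_um)] = LABEL_MEDIA
    return SegmentationMask(labels, geometry)


def make_uniform_frame(geometry, n_depth=320, refl=40.0, biref=4.5e-4, depol=0.05):
    shape = (geometry.n_alines, n_depth)
    return PolarimetricFrame(
        np.full(shape, refl, dtype=np.float32),
        np.full(shape, biref, dtype=np.float32),
        np.full(shape, depol, dtype=np.float32),
        geometry,
    )
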