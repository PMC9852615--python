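import numpy as np
import pytest

from femcort.mapping import measure_femur
from femcort.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_1mm():
    """Default phantom at 1.0 mm voxels."""
    return generate_phantom(PhantomSpec(voxel_spacing=1.0))


@pytest.fixture(scope="session")
def phantom_05mm():
    """Default phantom at 0.5 mm voxels (the accuracy-bearing resolution)."""
    return generate_phantom(PhantomSpec(voxel_spacing=0.5))


@pytest.fixture(scope="session")
def measured_05(phantom_05mm):
    """Full 31-ROI measurement of the 0.5 mm phantom."""
    volume, truth = phantom_05mm
    return measure_femur(volume, truth.landmarks), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_annulus_volume(r_out=10.0, r_in=7.0, spacing=0.5, height=12.0,
                        cortical_hu=500.0, trabecular_hu=150.0,
                        background_hu=40.0, antialias=3):
    """A straight cortical tube along z: analytic oracle geometry.

    Returns a CTVolume whose cross-section is an annulus with exactly
    known radii, built with the same partial-volume averaging as the
    phantom generator.
    """
    from femcort.phantom import CTVolume

    half = r_out + 5.0
    xs = np.arange(-half, half + spacing, spacing)
    zs = np.arange(0.0, height + spacing, spacing)
    offs = (np.arange(antialias) + 0.5) / antialias - 0.5
    vals = np.zeros((xs.size, xs.size, zs.size))
    for ox in offs:
        for oy in offs:
            x = (xs + ox * spacing)[:, None]
            y = (xs + oy * spacing)[None, :]
            r = np.hypot(x, y)
            sect = np.full(r.shape, background_hu)
            sect[r <= r_out] = cortical_hu
            sect[r < r_in] = trabecular_hu
            vals += sect[:, :, None] / antialias ** 2
    return CTVolume(values=vals, voxel_spacing=np.repeat(spacing, 3),
                    origin=np.array([-half, -half, 0.0]))


def make_z_plane(z, label_pairs=(("medial", "lateral"), ("anterior", "posterior"))):
    """A section plane normal to z with grid-aligned direction pair."""
    from femcort.mapping import SectionPlane

    return SectionPlane(id="S6", origin=np.array([0.0, 0.0, z]),
                        normal=np.array([0.0, 0.0, 1.0]),
                        dir1=np.array([1.0, 0.0, 0.0]),
                        dir2=np.array([0.0, 1.0, 0.0]),
                        labels=label_pairs)
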