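"""Shared fixtures: small phantom volumes with analytic ground truth."""

import numpy as np
import pytest

from octavasc.phantom import PhantomConfig, VesselSpec, build_centerline, render_volume
from octavasc.volume import AcquisitionGeometry


def geometry_voxels(nx: int, ny: int, nz: int, pitch_um: float = 1.0) -> AcquisitionGeometry:
    """Geometry with the given dims and an isotropic pitch (µm)."""
    return AcquisitionGeometry(
        fov_mm=(nx * pitch_um / 1000, ny * pitch_um / 1000, nz * pitch_um / 1000),
        dims=(nx, ny, nz),
    )


def straight_tube_volume(diameter_um: float, *, lumen_level: float = 0.15, seed: int = 0,
                         speckle: float = 0.0, noise_sd: float = 0.0,
                         edge_smooth: float = 1.0):
    """A straight tube along x at the volume center, 1 µm voxels.

    Returns (volume, truth, geometry).  The centerline runs from
    (40, 24, 80) to (80, 24, 80) µm, so in the axial section at y index
    24 the tube crosses z = 80 µm (between voxel indices 79 and 80).
    """
    dims = (120, 48, 160)
    geom = geometry_voxels(*dims)
    centerline = build_centerline(
        "straight", length_um=40.0, n_points=5, origin=(40.0, 24.0, 80.0)
    )
    vessel = VesselSpec(
        centerline=centerline.points, radius_um=diameter_um / 2, lumen_level=lumen_level, id="tube"
    )
    config = PhantomConfig(
        geometry=geom,
        speckle_contrast=speckle,
        detector_noise_sd=noise_sd,
        edge_smooth_voxels=edge_smooth,
        seed=seed,
    )
    volume, truth = render_volume([vessel], config)
    return volume, truth, geom


@pytest.fixture(scope="session")
def tube20():
    """Noiseless 20 µm straight tube (session-scoped: rendering is pure)."""
    return straight_tube_volume(20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
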