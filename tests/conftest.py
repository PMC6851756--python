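"""Shared fixtures: small geometric volumes and a compact phantom."""

import numpy as np
import pytest

from seegaudit import PhantomSpec, VolumeGrid, generate_phantom


def make_grid(shape=(32, 32, 32), voxel=(1.0, 1.0, 1.0), center=True):
    """Axis-aligned affine with the world origin at the grid center."""
    vox = np.asarray(voxel, dtype=float)
    shape = np.asarray(shape)
    affine = np.diag([*vox, 1.0])
    if center:
        affine[:3, 3] = -(shape - 1) / 2.0 * vox
    return affine


def world_coords(shape, affine):
    """World coordinates of every voxel center, one array per axis."""
    idx = np.indices(shape).astype(float)
    x = affine[0, 0] * idx[0] + affine[0, 3]
    y = affine[1, 1] * idx[1] + affine[1, 3]
    z = affine[2, 2] * idx[2] + affine[2, 3]
    return x, y, z


def cylinder_volume(radius=1.0, voxel=0.25, shape=(48, 48, 48), axis=2,
                    intensity=100.0, background=0.0):
    """A bright cylinder along one axis through the grid center."""
    affine = make_grid(shape, (voxel,) * 3)
    x, y, z = world_coords(shape, affine)
    coords = [x, y, z]
    coords.pop(axis)
    r = np.sqrt(coords[0] ** 2 + coords[1] ** 2)
    values = np.where(r <= radius, intensity, background)
    return VolumeGrid(values, affine, "cylinder")


def sphere_mask(radius, voxel=1.0, shape=(32, 32, 32)):
    affine = make_grid(shape, (voxel,) * 3)
    x, y, z = world_coords(shape, affine)
    return VolumeGrid(x**2 + y**2 + z**2 <= radius**2, affine, "sphere")


@pytest.fixture(scope="session")
def small_phantom():
    """A compact multi-modal phantom shared by read-only tests."""
    spec = PhantomSpec(
        grid_shape=(96, 96, 96),
        voxel_size=(0.5, 0.5, 0.5),
        n_vessels=12,
        n_electrodes=4,
        seed=42,
    )
    return generate_phantom(spec)
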