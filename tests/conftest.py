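"""Shared fixtures and geometry helpers for the porespec test suite."""

from __future__ import annotations

import numpy as np
import pytest

from porespec import BinaryMask, VoxelVolume

VOXEL_UM = 7.5  # reference scan resolution


def ball_mask(shape, center, radius, voxel_size=VOXEL_UM, role="material"):
    """Solid ball by voxel-center inclusion."""
    grids = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return BinaryMask(d2 <= radius * radius, voxel_size, role)


def slab_mask(shape, axis, start, stop, voxel_size=VOXEL_UM, role="material"):
    """Axis-aligned slab occupying [start, stop) along ``axis``."""
    data = np.zeros(shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = slice(start, stop)
    data[tuple(sl)] = True
    return BinaryMask(data, voxel_size, role)


def brute_force_thickness(mask: np.ndarray, voxel_size: float) -> np.ndarray:
    """Exhaustive sphere-fitting local thickness (independent oracle).

    For every candidate center the available radius is the distance to the
    nearest background voxel center (found by brute-force search, integer
    squared distances throughout); its open sphere paints 2·r onto every
    voxel it strictly contains.
    """
    m = np.asarray(mask, dtype=bool)
    fg = np.argwhere(m).astype(np.int64)
    bg = np.argwhere(~m).astype(np.int64)
    d2 = np.empty(len(fg), dtype=np.int64)
    for i in range(0, len(fg), 256):
        blk = fg[i : i + 256]
        d2[i : i + 256] = ((blk[:, None, :] - bg[None, :, :]) ** 2).sum(-1).min(1)
    out_sq = np.zeros(m.shape, dtype=np.int64)
    for c, dc2 in zip(fg, d2):
        cover = ((fg - c) ** 2).sum(1) < dc2
        idx = tuple(fg[cover].T)
        out_sq[idx] = np.maximum(out_sq[idx], dc2)
    return 2.0 * np.sqrt(out_sq) * (voxel_size / 1000.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_volume():
    """A tiny deterministic grayscale volume for I/O round-trips."""
    data = (np.arange(4 * 5 * 6, dtype=np.uint16).reshape(4, 5, 6) * 7) % 1024
    return VoxelVolume(data=data, voxel_size=VOXEL_UM, name="tiny")
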