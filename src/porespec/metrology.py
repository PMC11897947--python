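"""Dimensional quality-assurance arithmetic for printed dosage forms.

Covers the three measurements used when qualifying an SLS print against its
digital design: signed percent deviation of a measured dimension from its
nominal value, the number of powder layers needed to build a given extent,
and a ray-cast tip-to-tip extent through a binary mask ("ray-tracing
thickness", e.g. the distance between the tip surfaces of two opposite
spikes of a spiked-ball specimen).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_volume import AXIS_INDEX, BinaryMask


@dataclass(frozen=True)
class DeviationRecord:
    """Signed deviation of a measured dimension from the design value."""

    measured: float  # mm
    nominal: float  # mm

    def __post_init__(self) -> None:
        if not self.nominal > 0:
            raise ValueError(f"nominal must be > 0 mm, got {self.nominal}")

    @property
    def deviation_pct(self) -> float:
        return 100.0 * (self.measured - self.nominal) / self.nominal

    @property
    def deviation_pct_display(self) -> float:
        """Deviation rounded to 2 decimals, as conventionally reported."""
        return round(self.deviation_pct, 2)


def percent_deviation(measured: float, nominal: float) -> float:
    """Signed percent deviation 100·(measured − nominal)/nominal.

    >>> round(percent_deviation(8.09, 8.24), 2)
    -1.82
    """
    return DeviationRecord(measured, nominal).deviation_pct


def layer_count(extent_mm: float, layer_height_mm: float) -> int:
    """Number of powder layers to cover ``extent_mm`` along the build axis.

    Any partial layer still has to be deposited, hence the ceiling: a
    4.00 mm tablet at 0.10 mm layers needs 40 layers, a 4.05 mm one 41.
    """
    if not extent_mm > 0 or not layer_height_mm > 0:
        raise ValueError("extent and layer height must both be > 0 mm")
    # guard against float fuzz making e.g. 4.00/0.10 = 40.000000000000006
    ratio = extent_mm / layer_height_mm
    nearest = round(ratio)
    if math.isclose(ratio, nearest, rel_tol=1e-9, abs_tol=1e-9):
        return int(nearest)
    return int(math.ceil(ratio))


def ray_extent(mask: BinaryMask, direction: str = "z", return_profile: bool = False):
    """Maximum first-to-last extent of a mask along an axis, in mm.

    Parallel rays are cast along ``direction`` ('z', 'y' or 'x'); each ray
    records the distance between its first and last intersection with the
    mask (measured between outer voxel faces, so a solid ball of radius 10
    voxels reports a diameter of 20 voxels).  The maximum over rays is the
    tip-to-tip distance surrogate; pass ``return_profile=True`` for the full
    per-ray distribution.  Only axis-aligned directions are supported; the
    specimen is assumed aligned beforehand.
    """
    if direction not in AXIS_INDEX:
        raise ValueError(
            f"direction must be axis-aligned, one of {tuple(AXIS_INDEX)}; "
            f"got {direction!r}"
        )
    axis = AXIS_INDEX[direction]
    data = np.moveaxis(mask.data, axis, 0)
    n = data.shape[0]
    hit = data.reshape(n, -1)
    any_hit = hit.any(axis=0)
    idx = np.arange(n)[:, None]
    first = np.where(any_hit, np.where(hit, idx, n).min(axis=0), 0)
    last = np.where(any_hit, np.where(hit, idx, -1).max(axis=0), -1)
    # outer-face to outer-face span in voxels; empty lanes contribute 0
    span_vox = np.where(any_hit, last - first + 1, 0)
    span_mm = span_vox * (mask.voxel_size / 1000.0)
    if not any_hit.any():
        raise ValueError("mask is empty; no ray intersects it")
    if return_profile:
        return float(span_mm.max()), span_mm[any_hit]
    return float(span_mm.max())
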