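"""Volume and mask containers plus on-disk formats.

All pipeline stages exchange :class:`VoxelVolume` and :class:`BinaryMask`
objects; this module is the only place that touches files.  Two formats are
supported, selected by extension:

* multi-page TIFF (``.tif``/``.tiff``) — grayscale, 8/16-bit integer or
  float32, one page per z-slice;
* raw binary (``.raw``/``.bin``) — C-order dump plus a JSON sidecar.

Either way a JSON sidecar carries the metadata (``shape``, ``dtype``,
``voxel_size_um``, ``axis_order``); a volume without a stated voxel size is
rejected rather than silently defaulted.  Axis order is fixed to (z, y, x)
with z the build/longitudinal axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

AXIS_ORDER = ("z", "y", "x")
AXIS_INDEX = {"z": 0, "y": 1, "x": 2}

#: dtypes write_volume will emit (grayscale μCT-style data)
SUPPORTED_DTYPES = ("uint8", "uint16", "float32")

MASK_ROLES = ("material", "closed_filled", "pore", "labeled-pore-source")

_TIFF_EXT = {".tif", ".tiff"}
_RAW_EXT = {".raw", ".bin"}


class VolumeFormatError(ValueError):
    """Raised for unreadable/ill-specified volume files."""


def _check_grid(data: np.ndarray, voxel_size: float) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {data.shape}")
    if not (voxel_size > 0):
        raise ValueError(f"voxel_size must be > 0 μm, got {voxel_size!r}")


@dataclass
class VoxelVolume:
    """A 3D grayscale attenuation grid with isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar attenuation values in arbitrary units.
    voxel_size : float
        Isotropic voxel edge length in μm (7.5 μm for the reference scans).
    name : str
        Free-text specimen label.
    """

    data: np.ndarray
    voxel_size: float
    name: str = ""
    axis_order: tuple[str, str, str] = field(default=AXIS_ORDER)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data, self.voxel_size)
        if tuple(self.axis_order) != AXIS_ORDER:
            raise ValueError(f"axis_order is fixed to {AXIS_ORDER}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(
            self.data
        ).all():
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size / 1000.0


@dataclass
class BinaryMask:
    """A 3D boolean grid tagged by its role in the mask algebra.

    Roles: ``material`` (thresholded solid), ``closed_filled`` (pore-free
    envelope of the solid), ``pore`` (envelope minus solid) and
    ``labeled-pore-source`` (a pore mask that has been fed to watershed
    separation).  The role is fixed at construction.
    """

    data: np.ndarray
    voxel_size: float
    role: str

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != bool:
            if np.issubdtype(data.dtype, np.integer) or data.dtype == np.uint8:
                data = data != 0
            else:
                raise ValueError(f"mask data must be boolean, got {data.dtype}")
        object.__setattr__(self, "data", data)
        _check_grid(data, self.voxel_size)
        if self.role not in MASK_ROLES:
            raise ValueError(f"role must be one of {MASK_ROLES}, got {self.role!r}")

    def __setattr__(self, key: str, value: Any) -> None:
        if key == "role" and "role" in self.__dict__:
            raise AttributeError("mask role is immutable after creation")
        object.__setattr__(self, key, value)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in mm³."""
        return (self.voxel_size / 1000.0) ** 3


# ---------------------------------------------------------------------------
# sidecar handling
# ---------------------------------------------------------------------------

def default_sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _load_sidecar(path: Path) -> dict:
    with open(path) as fh:
        meta = json.load(fh)
    if "voxel_size_um" not in meta and "voxel_size" not in meta:
        raise VolumeFormatError(
            f"sidecar {path} lacks required key 'voxel_size_um' (voxel size in μm)"
        )
    return meta


def _sidecar_dict(vol: VoxelVolume) -> dict:
    return {
        "shape": list(vol.shape),
        "dtype": str(vol.data.dtype),
        "voxel_size_um": float(vol.voxel_size),
        "axis_order": list(AXIS_ORDER),
        "name": vol.name,
    }


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, sidecar: str | Path | None = None) -> VoxelVolume:
    """Read a 3D volume from a TIFF stack or raw binary file.

    The voxel size always comes from the JSON sidecar (``<file>.json`` next
    to the volume unless ``sidecar`` is given); a missing sidecar or missing
    ``voxel_size_um`` key is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(sidecar) if sidecar is not None else default_sidecar_path(path)
    if not sidecar.exists():
        raise VolumeFormatError(
            f"no metadata sidecar found at {sidecar}; voxel size must be stated"
        )
    meta = _load_sidecar(sidecar)
    voxel_size = float(meta.get("voxel_size_um", meta.get("voxel_size")))

    ext = path.suffix.lower()
    if ext in _TIFF_EXT:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    elif ext in _RAW_EXT:
        try:
            shape = tuple(int(s) for s in meta["shape"])
            dtype = np.dtype(meta["dtype"])
        except KeyError as exc:
            raise VolumeFormatError(
                f"raw sidecar {sidecar} lacks required key {exc}"
            ) from None
        raw = np.fromfile(path, dtype=dtype)
        expected = int(np.prod(shape))
        if raw.size != expected:
            raise VolumeFormatError(
                f"{path}: file holds {raw.size} values but sidecar shape "
                f"{shape} implies {expected}"
            )
        data = raw.reshape(shape)
    else:
        raise VolumeFormatError(f"unsupported volume extension {ext!r}")

    if "shape" in meta and tuple(meta["shape"]) != data.shape:
        raise VolumeFormatError(
            f"{path}: data shape {data.shape} does not match sidecar "
            f"shape {tuple(meta['shape'])}"
        )
    return VoxelVolume(data=data, voxel_size=voxel_size, name=str(meta.get("name", "")))


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as TIFF stack or raw binary (by extension) + sidecar."""
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if str(vol.data.dtype) not in SUPPORTED_DTYPES:
        raise VolumeFormatError(
            f"dtype {vol.data.dtype} not supported; use one of {SUPPORTED_DTYPES}"
        )
    ext = path.suffix.lower()
    if ext in _TIFF_EXT:
        tifffile.imwrite(path, vol.data, photometric="minisblack")
    elif ext in _RAW_EXT:
        np.ascontiguousarray(vol.data).tofile(path)
    else:
        raise VolumeFormatError(f"unsupported volume extension {ext!r}")
    with open(default_sidecar_path(path), "w") as fh:
        json.dump(_sidecar_dict(vol), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit {0, 255} TIFF (universally readable)."""
    vol = VoxelVolume(
        data=np.where(mask.data, np.uint8(255), np.uint8(0)),
        voxel_size=mask.voxel_size,
        name=f"mask:{mask.role}",
    )
    write_volume(vol, path)


def read_mask(path: str | Path, role: str, sidecar: str | Path | None = None) -> BinaryMask:
    vol = read_volume(path, sidecar)
    return BinaryMask(data=vol.data != 0, voxel_size=vol.voxel_size, role=role)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _display(value: float, ndigits: int = 4) -> float:
    return float(f"{value:.{ndigits}g}")


def write_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Serialize named results: scalars/lists to JSON, tables to CSV.

    Scalar floats are written at full precision under their own key, with a
    parallel ``display`` object holding 4-significant-figure roundings.
    DataFrame values are written as ``<stem>_<key>.csv`` next to the JSON
    and referenced by relative path.  Key order is deterministic (sorted).
    """
    path = Path(path)
    body: dict[str, Any] = {}
    display: dict[str, float] = {}
    for key in sorted(results):
        value = results[key]
        if isinstance(value, pd.DataFrame):
            csv_path = path.with_name(f"{path.stem}_{key}.csv")
            value.to_csv(csv_path, index=False)
            body[key] = csv_path.name
        elif isinstance(value, (float, np.floating)):
            body[key] = float(value)
            display[key] = _display(float(value))
        elif isinstance(value, (int, np.integer, str, bool)) or value is None:
            body[key] = value if not isinstance(value, np.integer) else int(value)
        else:
            body[key] = json.loads(json.dumps(value, default=float))
    if display:
        body["display"] = display
    with open(path, "w") as fh:
        json.dump(body, fh, indent=1, sort_keys=True)
        fh.write("\n")
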