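"""Synthetic porous volumes and analytic flow fixtures.

Two kinds of test input are produced:

* :func:`generate_sintered_packing` — a statistical stand-in for a μCT scan
  of an SLS-sintered polymer matrix: overlapping spherical grains (diameters
  drawn from a truncated normal) are deposited at uniform random centers
  until the solid fraction reaches the target, a Gaussian blur creates
  sintering necks, and the grayscale mapping is centered on a threshold
  found by bisection so that the default segmentation recovers the target
  porosity to within a couple of percent.  Defaults emulate a matrix with
  ~44% interconnected porosity and ~50 ± 30 μm fused-element thickness at a
  7.5 μm voxel.

* :func:`generate_fixture` — pore masks with closed-form permeability and
  tortuosity (circular tube, plane slab, open rectangular duct, serpentine
  channel), the oracles for both flow solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_volume import BinaryMask, VoxelVolume
from .segmentation import SegmentationParams, porosity_percent, segment_volume

#: 1 darcy in m² (also used by the flow modules through stokes_flow)
_GRAIN_ATTEMPT_FACTOR = 50  # hard cap on grain placements vs. naive estimate


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic sintered packing.

    Units: lengths in μm except where noted; the grain diameter
    distribution (60 ± 20 μm by default) and 0.44 target porosity emulate
    the sintered PVA matrices the generator stands in for.
    ``anisotropy_stretch`` scales the grain (and hence pore) geometry along
    z; 1.0 is isotropic.
    """

    domain_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 7.5
    grain_diameter_mean: float = 60.0
    grain_diameter_sd: float = 20.0
    target_porosity: float = 0.44
    neck_blur_sigma: float = 1.0  # voxels
    anisotropy_stretch: float = 1.0
    skin_voxels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_porosity < 1.0):
            raise ValueError("target_porosity must be in (0, 1)")
        if not self.grain_diameter_mean > 2 * self.voxel_size:
            raise ValueError(
                "grain_diameter_mean must exceed 2 voxels to be resolvable"
            )
        if not self.anisotropy_stretch > 0:
            raise ValueError("anisotropy_stretch must be > 0")
        if len(self.domain_shape) != 3 or min(self.domain_shape) < 8:
            raise ValueError("domain_shape must be 3D with every side >= 8")
        if self.skin_voxels < 0 or 2 * self.skin_voxels >= min(self.domain_shape) - 4:
            raise ValueError("skin_voxels too large for the domain")


def _paint_ellipsoid(solid: np.ndarray, center: np.ndarray, semi: np.ndarray) -> None:
    """OR an axis-aligned ellipsoid (voxel-center inclusion) into ``solid``."""
    lo = np.maximum(np.floor(center - semi).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi).astype(int) + 1, solid.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) - center[0]) / semi[0]
    yy = (np.arange(lo[1], hi[1]) - center[1]) / semi[1]
    xx = (np.arange(lo[2], hi[2]) - center[2]) / semi[2]
    inside = (
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    ) <= 1.0
    solid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= inside


def _measured_porosity(field: np.ndarray, threshold: float, voxel_size: float) -> float:
    """Porosity (fraction) after the default segmentation at an explicit threshold."""
    vol = VoxelVolume(field, voxel_size, name="bisection")
    params = SegmentationParams(threshold=threshold)
    _, envelope, pore = segment_volume(vol, params)
    return porosity_percent(pore, envelope) / 100.0


def generate_sintered_packing(spec: SyntheticSpec) -> VoxelVolume:
    """Generate a grayscale volume of an overlapping-grain sintered packing.

    Deterministic for a fixed spec (one seeded generator drives all draws).
    Raises ``RuntimeError`` when the target porosity is unreachable for the
    requested grain size / domain combination.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.domain_shape)
    solid = np.zeros(shape, dtype=bool)
    # denser sintered skin, as on real SLS parts: encloses the pore network
    # so the closed-and-filled envelope is the full specimen; flow analyses
    # crop an interior cuboid, so the skin never blocks percolation there
    s = spec.skin_voxels
    if s:
        for a in range(3):
            sl = [slice(None)] * 3
            sl[a] = slice(0, s)
            solid[tuple(sl)] = True
            sl[a] = slice(-s, None)
            solid[tuple(sl)] = True
    target_solid = 1.0 - spec.target_porosity
    n_vox = solid.size

    mean_r_vox = spec.grain_diameter_mean / (2.0 * spec.voxel_size)
    grain_vol = (4.0 / 3.0) * math.pi * mean_r_vox**3 * spec.anisotropy_stretch
    max_attempts = max(
        1000, int(_GRAIN_ATTEMPT_FACTOR * target_solid * n_vox / max(grain_vol, 1.0))
    )

    solid_count = 0
    attempts = 0
    check_every = 32
    while solid_count < target_solid * n_vox:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"target porosity {spec.target_porosity} unreachable after "
                f"{attempts} grain placements (grains too large for the domain?)"
            )
        d = rng.normal(spec.grain_diameter_mean, spec.grain_diameter_sd)
        d = max(d, 2.0 * spec.voxel_size)  # truncate at 2 voxels
        r = d / (2.0 * spec.voxel_size)
        semi = np.array([r * spec.anisotropy_stretch, r, r])
        center = rng.uniform(0.0, 1.0, size=3) * np.array(shape)
        _paint_ellipsoid(solid, center, semi)
        attempts += 1
        if attempts % check_every == 0 or attempts < check_every:
            solid_count = int(solid.sum())
    # blur to form sintering necks between touching grains
    field = ndimage.gaussian_filter(solid.astype(np.float32), spec.neck_blur_sigma)

    # bisection on the binarization threshold so the default segmentation
    # (Otsu + closing + fill) recovers the target porosity
    # bracket stays where the blurred field is well two-phase (extreme
    # thresholds fragment the solid and break the envelope)
    lo, hi = 0.15, 0.85
    phi_lo = _measured_porosity(field, lo, spec.voxel_size)
    phi_hi = _measured_porosity(field, hi, spec.voxel_size)
    if not (phi_lo <= spec.target_porosity <= phi_hi):
        raise RuntimeError(
            f"target porosity {spec.target_porosity} outside the reachable "
            f"range [{phi_lo:.3f}, {phi_hi:.3f}] for this packing"
        )
    t_star = 0.5
    for _ in range(14):
        t_star = 0.5 * (lo + hi)
        phi = _measured_porosity(field, t_star, spec.voxel_size)
        if abs(phi - spec.target_porosity) < 2e-3:
            break
        if phi < spec.target_porosity:
            lo = t_star
        else:
            hi = t_star
    # grayscale mapping: sharp logistic centered on the bisected threshold,
    # so any mid-range threshold (Otsu included) reproduces the calibrated
    # phase split; mild detector-style noise on top
    width = 0.03
    gray = 255.0 / (1.0 + np.exp(-(field - t_star) / width))
    gray = gray + rng.normal(0.0, 3.0, size=shape)
    data = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return VoxelVolume(
        data=data,
        voxel_size=spec.voxel_size,
        name=f"sintered-packing(seed={spec.seed})",
    )


def generate_anisotropic_pair(spec: SyntheticSpec, stretch: float = 2.0):
    """Matched isotropic/anisotropic volumes sharing all other parameters."""
    iso = generate_sintered_packing(replace(spec, anisotropy_stretch=1.0))
    aniso = generate_sintered_packing(replace(spec, anisotropy_stretch=stretch))
    return iso, aniso


# ---------------------------------------------------------------------------
# analytic flow fixtures
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("tube", "slab", "full_duct", "serpentine")

_DEFAULT_DIMS = {
    "tube": {"radius": 10, "cross": 32, "length": 64},
    "slab": {"gap": 8, "width": 192, "length": 48},
    "full_duct": {"height": 16, "width": 16, "length": 32},
    "serpentine": {"channel": 6, "length": 48, "jog": 24, "margin": 4},
}


def _fixture_dims(kind: str, dims: dict | None) -> dict:
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    out = dict(_DEFAULT_DIMS[kind])
    if dims:
        unknown = set(dims) - set(out)
        if unknown:
            raise ValueError(f"unknown {kind} dimensions {sorted(unknown)}")
        out.update(dims)
    if any(v <= 0 for v in out.values()):
        raise ValueError(f"fixture dimensions must be positive, got {out}")
    return out


def generate_fixture(
    kind: str, dims: dict | None = None, voxel_size: float = 7.5
) -> BinaryMask:
    """Pore mask of an analytic fixture; flow is along z in every kind.

    * ``tube`` — circular channel of ``radius`` voxels centered in a
      ``cross``×``cross`` impervious cuboid: k = πr⁴/(8·cross²).
    * ``slab`` — gap of height ``gap`` filling the whole cross-section
      (width ≫ gap): k = gap²/12.
    * ``full_duct`` — fully open rectangular duct (exact series solution).
    * ``serpentine`` — square channel with two right-angle bends; its
      centerline is longer than the domain by ``jog`` voxels, so the
      geometric tortuosity is (length + jog)/length.
    """
    d = _fixture_dims(kind, dims)
    if kind == "tube":
        r, n, nz = d["radius"], d["cross"], d["length"]
        if 2 * r + 2 > n:
            raise ValueError(f"tube radius {r} does not fit cross-section {n}")
        # center on a voxel center so the channel axis is grid-resolvable
        c = n // 2
        yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        disk = (yy**2 + xx**2) <= r**2
        pore = np.broadcast_to(disk, (nz, n, n)).copy()
    elif kind == "slab":
        h, w, nz = d["gap"], d["width"], d["length"]
        pore = np.ones((nz, h, w), dtype=bool)
    elif kind == "full_duct":
        hy, wx, nz = d["height"], d["width"], d["length"]
        pore = np.ones((nz, hy, wx), dtype=bool)
    else:  # serpentine
        w, nz, jog, m = d["channel"], d["length"], d["jog"], d["margin"]
        leg = nz // 3
        if leg < w + 2:
            raise ValueError("serpentine legs shorter than the channel width")
        ny = jog + w + 2 * m
        nx = w + 2 * m
        pore = np.zeros((nz, ny, nx), dtype=bool)
        y0, y1 = m, m + jog  # low and high leg y-offsets
        xs = slice(m, m + w)
        pore[: leg + w, y0 : y0 + w, xs] = True  # inlet leg along z
        pore[leg : leg + w, y0 : y1 + w, xs] = True  # jog along y
        pore[leg:, y1 : y1 + w, xs] = True  # outlet leg along z
    return BinaryMask(pore, voxel_size, "pore")


def fixture_analytics(
    kind: str, dims: dict | None = None, voxel_size: float = 7.5
) -> dict:
    """Closed-form permeability (m² and voxel²) and tortuosity of a fixture."""
    d = _fixture_dims(kind, dims)
    h_m = voxel_size * 1e-6  # voxel edge in m
    if kind == "tube":
        r, n = d["radius"], d["cross"]
        k_vox = math.pi * r**4 / (8.0 * n * n)
        return {"k_voxel2": k_vox, "k_m2": k_vox * h_m**2, "tortuosity": 1.0}
    if kind == "slab":
        h = d["gap"]
        k_vox = h * h / 12.0
        return {"k_voxel2": k_vox, "k_m2": k_vox * h_m**2, "tortuosity": 1.0}
    if kind == "full_duct":
        a = d["height"] / 2.0  # half-height
        b = d["width"] / 2.0  # half-width
        if a > b:
            a, b = b, a
        # exact series for laminar flow in a rectangular duct
        s = sum(
            math.tanh(k * math.pi * b / (2 * a)) / k**5 for k in range(1, 200, 2)
        )
        q_factor = (4.0 * b * a**3 / 3.0) * (1.0 - (192.0 * a / (math.pi**5 * b)) * s)
        area = d["height"] * d["width"]
        k_vox = q_factor / area
        return {"k_voxel2": k_vox, "k_m2": k_vox * h_m**2, "tortuosity": 1.0}
    # serpentine: tortuosity from the centerline path; no closed-form k
    tau = (d["length"] + d["jog"]) / d["length"]
    return {"k_voxel2": None, "k_m2": None, "tortuosity": tau}
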