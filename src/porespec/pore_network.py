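"""Individual-pore analysis and the pore network model (PNM).

The connected pore space is first split into "individual" pores by a
marker-controlled watershed on the negated Euclidean distance transform
(touching pores separate at their necks).  Per-pore statistics (volume,
equivalent diameter, aspect ratio) summarize the clusters; an ellipsoid
model turns a mean local thickness and an aspect-ratio assumption into a
pore volume.  For flow, pores become spheres and pore throats cylinders:
steady incompressible flow with Poiseuille conductance g = πr⁴/(8μL) per
throat is solved with zero net accumulation at every pore, giving absolute
permeability via Darcy's law and a hydraulic tortuosity from the throat
velocity vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from skimage.segmentation import watershed

from .io_volume import AXIS_INDEX, BinaryMask

#: 1 darcy expressed in m²
DARCY_M2 = 9.869233e-13

INLET, OUTLET, INTERNAL = "inlet", "outlet", "internal"


# ---------------------------------------------------------------------------
# watershed separation and per-pore statistics
# ---------------------------------------------------------------------------

@dataclass
class LabeledPores:
    """Watershed-separated pore space: 0 = background, labels 1..n_labels."""

    labels: np.ndarray
    n_labels: int
    voxel_size: float  # μm

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        present = present[present != 0]
        if self.n_labels != present.size or (
            present.size and present.max() != self.n_labels
        ):
            raise ValueError("labels must be contiguous 1..n_labels")


def watershed_separate(pore: BinaryMask, min_separation: int = 2) -> LabeledPores:
    """Split touching pores at their necks by marker-controlled watershed.

    Markers are local maxima of the distance transform, suppressed within
    ``min_separation`` voxels of a stronger maximum (adjacent plateau maxima
    merge into one marker).  Every pore voxel receives a label.  Strongly
    interconnected pore spaces oversegment by nature — the clusters then
    read as "equivalent pores" rather than physical voids.
    """
    if not pore.data.any():
        raise ValueError("pore mask is empty")
    dist = ndimage.distance_transform_edt(pore.data)
    # plateau-preserving local maxima: a voxel is a marker candidate iff no
    # strictly larger EDT value lies within min_separation; connected
    # candidates (e.g. the ridge of a straight channel) merge to one marker
    s = max(int(min_separation), 1)
    ax = np.arange(-s, s + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    footprint = zz * zz + yy * yy + xx * xx <= s * s
    marker_mask = pore.data & (dist >= ndimage.maximum_filter(dist, footprint=footprint))
    markers, _ = ndimage.label(marker_mask, structure=np.ones((3, 3, 3), bool))
    labels = watershed(-dist, markers=markers, mask=pore.data)
    # renumber contiguously (watershed can drop marker ids)
    ids = np.unique(labels)
    ids = ids[ids != 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    labels = remap[labels]
    return LabeledPores(labels=labels, n_labels=int(ids.size), voxel_size=pore.voxel_size)


def _label_aspect_ratio(coords: np.ndarray) -> float:
    """√(λ_min/λ_max) of the voxel-coordinate covariance; 1.0 if degenerate."""
    if coords.shape[0] < 2:
        return 1.0
    cov = np.cov(coords.T)
    eig = np.linalg.eigvalsh(cov)
    if eig[-1] <= 0:
        return 1.0
    return float(np.sqrt(max(eig[0], 0.0) / eig[-1]))


def component_stats(labeled: LabeledPores) -> pd.DataFrame:
    """Per-pore table: id, volume (mm³), equivalent diameter (mm), aspect
    ratio in (0, 1], and centroid (mm).  Volumes sum to the mask volume."""
    if labeled.n_labels < 1:
        raise ValueError("no labels to summarize")
    vox_mm = labeled.voxel_size / 1000.0
    vox_vol = vox_mm**3
    labels = labeled.labels
    objects = ndimage.find_objects(labels)
    rows = []
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        coords = np.argwhere(sub) + np.array([s.start for s in sl])
        vol = coords.shape[0] * vox_vol
        eq_d = (6.0 * vol / math.pi) ** (1.0 / 3.0)
        rows.append(
            {
                "id": lab,
                "volume_mm3": vol,
                "eq_diameter_mm": eq_d,
                "aspect_ratio": _label_aspect_ratio(coords.astype(float)),
                "centroid_z_mm": coords[:, 0].mean() * vox_mm,
                "centroid_y_mm": coords[:, 1].mean() * vox_mm,
                "centroid_x_mm": coords[:, 2].mean() * vox_mm,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ellipsoid pore model
# ---------------------------------------------------------------------------

def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume (4/3)·π·a·b·c of an ellipsoid with semi-axes a, b, c in mm."""
    if a <= 0 or b <= 0 or c <= 0:
        raise ValueError("all semi-axes must be > 0")
    return (4.0 / 3.0) * math.pi * a * b * c


@dataclass(frozen=True)
class EllipsoidModel:
    """An ellipsoidal pore with semi-axes a ≤ b ≤ c (mm).

    Two named shape cases tie the minor semi-axis to a measured mean local
    thickness t: *flattened* (a = t, b = c = 2t, i.e. a = b/2 = c/2) and
    *spherical-ish* (a = b = t, c = 2t, i.e. a = b = c/2).
    """

    a: float
    b: float
    c: float
    shape_case: str = "custom"

    def __post_init__(self) -> None:
        ellipsoid_volume(self.a, self.b, self.c)  # validates positivity

    @property
    def volume_mm3(self) -> float:
        return ellipsoid_volume(self.a, self.b, self.c)

    @classmethod
    def flattened(cls, minor_semi_axis_mm: float) -> "EllipsoidModel":
        t = minor_semi_axis_mm
        return cls(a=t, b=2 * t, c=2 * t, shape_case="flattened")

    @classmethod
    def spherical_ish(cls, minor_semi_axis_mm: float) -> "EllipsoidModel":
        t = minor_semi_axis_mm
        return cls(a=t, b=t, c=2 * t, shape_case="spherical-ish")


# ---------------------------------------------------------------------------
# network extraction
# ---------------------------------------------------------------------------

@dataclass
class PoreNetwork:
    """Spheres-and-cylinders abstraction of a pore space.

    ``centers`` are (n, 3) pore centers in mm (z, y, x); ``tags`` marks
    virtual boundary pores (fixed pressure, zero volume) vs internal ones.
    Throats are cylinders between pore pairs with a radius, a length and a
    unit direction vector used for the velocity bookkeeping.
    """

    centers: np.ndarray  # (n, 3) mm
    radii: np.ndarray  # (n,) mm
    tags: np.ndarray  # (n,) str
    throats: np.ndarray  # (m, 2) int pore indices
    throat_radius: np.ndarray  # (m,) mm
    throat_length: np.ndarray  # (m,) mm
    throat_direction: np.ndarray = field(default=None)  # (m, 3) unit vectors i→j

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        self.tags = np.asarray(self.tags)
        self.throats = np.atleast_2d(np.asarray(self.throats, dtype=int))
        self.throat_radius = np.asarray(self.throat_radius, dtype=float)
        self.throat_length = np.asarray(self.throat_length, dtype=float)
        n = self.centers.shape[0]
        if self.throats.size:
            if (self.throats[:, 0] == self.throats[:, 1]).any():
                raise ValueError("throat endpoints must be distinct pores")
            if self.throats.min() < 0 or self.throats.max() >= n:
                raise ValueError("throat endpoint refers to a nonexistent pore")
        if (self.radii <= 0).any():
            raise ValueError("pore radii must be > 0")
        if self.throat_radius.size and (
            (self.throat_radius <= 0).any() or (self.throat_length <= 0).any()
        ):
            raise ValueError("throat radii and lengths must be > 0")
        if self.throat_direction is None:
            vec = self.centers[self.throats[:, 1]] - self.centers[self.throats[:, 0]]
            norm = np.linalg.norm(vec, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self.throat_direction = vec / norm

    @property
    def n_pores(self) -> int:
        return self.centers.shape[0]

    @property
    def n_throats(self) -> int:
        return self.throats.shape[0]

    def conductances(self, viscosity: float) -> np.ndarray:
        """Poiseuille conduit conductance per throat, SI (m³·Pa⁻¹·s⁻¹).

        Each link is a series of cylinders spanning the full center-to-center
        distance: half-conduits through the two pore bodies (length = pore
        radius, at the body radius) and the neck cylinder over the remaining
        gap at the throat radius, each with Poiseuille resistance 8μl/(πr⁴).
        Virtual boundary pores have zero volume and contribute no body
        segment, so a link between boundary pores is the bare πr⁴/(8μL)
        cylinder.
        """
        r_t = self.throat_radius * 1e-3
        length = self.throat_length * 1e-3
        i, j = self.throats[:, 0], self.throats[:, 1]
        l_i = np.where(self.tags[i] == INTERNAL, self.radii[i], 0.0) * 1e-3
        l_j = np.where(self.tags[j] == INTERNAL, self.radii[j], 0.0) * 1e-3
        l_t = np.maximum(length - l_i - l_j, 0.0)
        r_i = self.radii[i] * 1e-3
        r_j = self.radii[j] * 1e-3
        resistance = (8.0 * viscosity / math.pi) * (
            l_t / r_t**4 + l_i / r_i**4 + l_j / r_j**4
        )
        return 1.0 / np.maximum(resistance, 1e-300)


def _interface_max(
    dist: np.ndarray, labels: np.ndarray, axis: int
) -> dict[tuple[int, int], float]:
    """Max EDT value on each shared label interface, scanning one axis."""
    a = labels.take(range(labels.shape[axis] - 1), axis=axis)
    b = labels.take(range(1, labels.shape[axis]), axis=axis)
    da = dist.take(range(dist.shape[axis] - 1), axis=axis)
    db = dist.take(range(1, dist.shape[axis]), axis=axis)
    touch = (a != b) & (a > 0) & (b > 0)
    if not touch.any():
        return {}
    la, lb = a[touch], b[touch]
    # EDT evaluated on the interface surface: the smaller of the two
    # flanking cell values (the larger one already sits inside a pore body)
    dd = np.minimum(da[touch], db[touch])
    lo = np.minimum(la, lb)
    hi = np.maximum(la, lb)
    out: dict[tuple[int, int], float] = {}
    order = np.lexsort((hi, lo))
    lo, hi, dd = lo[order], hi[order], dd[order]
    boundaries = np.flatnonzero(np.diff(lo) | np.diff(hi))
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries + 1, [lo.size]])
    for s, e in zip(starts, ends):
        out[(int(lo[s]), int(hi[s]))] = float(dd[s:e].max())
    return out


def extract_network(
    labeled: LabeledPores, pore: BinaryMask, axis: str = "z"
) -> PoreNetwork:
    """Build the sphere-and-cylinder network from watershed-separated pores.

    One network pore per label (center = centroid, radius = max EDT inside
    the label); one throat per face-adjacent label pair (radius = max EDT on
    the shared interface, length = the center-to-center distance, floored at
    one voxel).  Labels touching the inlet/outlet faces gain a throat to a
    virtual fixed-pressure boundary pore.
    """
    ax = AXIS_INDEX[axis]
    labels = labeled.labels
    if labels.shape != pore.shape:
        raise ValueError("labels and pore mask shapes differ")
    vox_mm = labeled.voxel_size / 1000.0
    dist = ndimage.distance_transform_edt(pore.data)

    n = labeled.n_labels
    centroids = np.array(ndimage.center_of_mass(pore.data, labels, range(1, n + 1)))
    max_dt = ndimage.labeled_comprehension(
        dist, labels, range(1, n + 1), np.max, float, 0.0
    )
    pore_radii_vox = np.maximum(max_dt, 0.5)

    # internal throats from face adjacency
    iface: dict[tuple[int, int], float] = {}
    for a in range(3):
        for pair, val in _interface_max(dist, labels, a).items():
            iface[pair] = max(iface.get(pair, 0.0), val)

    centers = [centroids]
    radii = [pore_radii_vox]
    tags = [np.full(n, INTERNAL, dtype=object)]
    throats, t_radius, t_length, t_dir = [], [], [], []

    for (li, lj), r_t in iface.items():
        i, j = li - 1, lj - 1
        d = centroids[j] - centroids[i]
        dist_c = float(np.linalg.norm(d))
        # full center-to-center length: watershed pores act as junction
        # points, and the cylinder spans the whole link (subtracting the
        # pore radii collapses most links of an oversegmented network to
        # the floor and erases nearly all viscous resistance)
        length = max(dist_c, 1.0)
        throats.append((i, j))
        t_radius.append(max(r_t, 0.5))
        t_length.append(length)
        t_dir.append(d / dist_c if dist_c > 0 else np.eye(3)[ax])

    # virtual boundary pores
    moved = np.moveaxis(labels, ax, 0)
    moved_d = np.moveaxis(dist, ax, 0)
    extent = labels.shape[ax]
    next_id = n
    axis_unit = np.eye(3)[ax]
    for which, face_lab, face_dist, coord, tag, sign in (
        ("inlet", moved[0], moved_d[0], 0.0, INLET, +1.0),
        ("outlet", moved[-1], moved_d[-1], float(extent), OUTLET, -1.0),
    ):
        touching = np.unique(face_lab)
        touching = touching[touching != 0]
        if touching.size == 0:
            raise ValueError(
                f"no pore label touches the {which} face: network cannot percolate"
            )
        b_center = np.mean(centroids[touching - 1], axis=0)
        b_center[ax] = coord
        b_radius = max(float(face_dist.max()), 0.5)
        centers.append(b_center[None])
        radii.append(np.array([b_radius]))
        tags.append(np.array([tag], dtype=object))
        for lab in touching:
            i = int(lab) - 1
            r_t = max(float(face_dist[face_lab == lab].max()), 0.5)
            length = max(abs(centroids[i][ax] - coord), 1.0)
            throats.append((next_id, i))
            t_radius.append(r_t)
            t_length.append(length)
            t_dir.append(sign * axis_unit)
        next_id += 1

    net = PoreNetwork(
        centers=np.vstack(centers) * vox_mm,
        radii=np.concatenate(radii) * vox_mm,
        tags=np.concatenate(tags),
        throats=np.array(throats, dtype=int),
        throat_radius=np.array(t_radius) * vox_mm,
        throat_length=np.array(t_length) * vox_mm,
        throat_direction=np.array(t_dir, dtype=float),
    )
    _require_percolating_graph(net)
    return net


def _require_percolating_graph(net: PoreNetwork) -> None:
    n = net.n_pores
    if net.n_throats == 0:
        raise ValueError("network has no throats: permeability is zero")
    adj = coo_matrix(
        (np.ones(net.n_throats), (net.throats[:, 0], net.throats[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    inlet_comp = set(comp[net.tags == INLET])
    outlet_comp = set(comp[net.tags == OUTLET])
    if not (inlet_comp & outlet_comp):
        raise ValueError(
            "no inlet–outlet path through the network: permeability is zero"
        )


# ---------------------------------------------------------------------------
# steady Poiseuille flow on the network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermeabilityResult:
    """Absolute permeability with its companion flow quantities."""

    k_m2: float
    tortuosity: float
    total_flux: float  # m³/s
    axis: str
    method: str  # "FE" (voxel Stokes) or "PNM"
    delta_p: float  # Pa
    viscosity: float  # Pa·s

    @property
    def k_darcy(self) -> float:
        return self.k_m2 / DARCY_M2

    def as_dict(self) -> dict:
        return {
            "k_darcy": self.k_darcy,
            "k_m2": self.k_m2,
            "tortuosity": self.tortuosity,
            "total_flux_m3_s": self.total_flux,
            "axis": self.axis,
            "method": self.method,
            "delta_p_Pa": self.delta_p,
            "viscosity_Pa_s": self.viscosity,
        }


def pnm_solve(
    net: PoreNetwork,
    domain_cross_section: float,
    domain_length: float,
    axis: str = "z",
    delta_p: float = 1000.0,
    viscosity: float = 0.001,
) -> tuple[PermeabilityResult, np.ndarray]:
    """Steady network flow: fixed pressures at the virtual boundary pores,
    zero net accumulation at every internal pore.

    ``domain_cross_section`` and ``domain_length`` are the full cuboid
    cross-section (m²) and length (m) used in the Darcy back-out.  Returns
    the permeability result and the per-pore pressure vector (Pa).
    """
    _require_percolating_graph(net)
    ax = AXIS_INDEX[axis]
    g = net.conductances(viscosity)
    n = net.n_pores
    internal = np.flatnonzero(net.tags == INTERNAL)
    fixed_p = np.zeros(n)
    fixed_p[net.tags == INLET] = delta_p
    is_internal = np.zeros(n, dtype=bool)
    is_internal[internal] = True

    idx_of = -np.ones(n, dtype=int)
    idx_of[internal] = np.arange(internal.size)

    if internal.size:
        i, j = net.throats[:, 0], net.throats[:, 1]
        rows, cols, vals = [], [], []
        rhs = np.zeros(internal.size)
        diag = np.zeros(internal.size)
        for a, b in ((i, j), (j, i)):
            a_int = is_internal[a]
            ai = idx_of[a[a_int]]
            np.add.at(diag, ai, g[a_int])
            b_sel = b[a_int]
            b_internal = is_internal[b_sel]
            rows.extend(ai[b_internal])
            cols.extend(idx_of[b_sel[b_internal]])
            vals.extend(-g[a_int][b_internal])
            np.add.at(rhs, ai[~b_internal], g[a_int][~b_internal] * fixed_p[b_sel[~b_internal]])
        if (diag == 0).any():
            bad = internal[np.flatnonzero(diag == 0)[0]]
            raise ValueError(f"internal pore {bad} has no throats: singular system")
        rows.extend(range(internal.size))
        cols.extend(range(internal.size))
        vals.extend(diag)
        lap = coo_matrix((vals, (rows, cols)), shape=(internal.size,) * 2).tocsr()
        p_internal = spsolve(lap, rhs)
        pressures = fixed_p.copy()
        pressures[internal] = p_internal
    else:
        pressures = fixed_p

    q = g * (pressures[net.throats[:, 0]] - pressures[net.throats[:, 1]])  # i→j flow

    inlet_mask = (net.tags[net.throats[:, 0]] == INLET) | (
        net.tags[net.throats[:, 1]] == INLET
    )
    sign = np.where(net.tags[net.throats[:, 0]] == INLET, 1.0, -1.0)
    total_flux = float(np.sum(q[inlet_mask] * sign[inlet_mask]))

    # hydraulic tortuosity from throat velocity vectors
    area = math.pi * (net.throat_radius * 1e-3) ** 2
    speed = np.abs(q) / area
    vec = net.throat_direction * np.sign(q)[:, None]
    axial = float(np.sum(speed * vec[:, ax]))
    if axial == 0:
        raise ValueError("zero net axial flow: tortuosity undefined")
    tau = float(np.sum(speed) / abs(axial))

    k_m2 = total_flux * viscosity * domain_length / (domain_cross_section * delta_p)
    result = PermeabilityResult(
        k_m2=k_m2,
        tortuosity=tau,
        total_flux=total_flux,
        axis=axis,
        method="PNM",
        delta_p=delta_p,
        viscosity=viscosity,
    )
    return result, pressures


def pnm_mass_balance(net: PoreNetwork, pressures: np.ndarray, viscosity: float) -> float:
    """Max |net accumulation| over internal pores, relative to total inflow."""
    g = net.conductances(viscosity)
    q = g * (pressures[net.throats[:, 0]] - pressures[net.throats[:, 1]])
    net_flow = np.zeros(net.n_pores)
    np.subtract.at(net_flow, net.throats[:, 0], q)
    np.add.at(net_flow, net.throats[:, 1], q)
    internal = net.tags == INTERNAL
    if not internal.any():
        return 0.0
    inflow = np.abs(q).sum()
    return float(np.abs(net_flow[internal]).max() / max(inflow, 1e-300))
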