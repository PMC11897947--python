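"""Voxel Stokes flow on a binarized pore space and Darcy permeability.

At micron pore scales and mPa·s viscosities the Reynolds number is far
below one, so creeping (Stokes) flow is solved: −μ∇²u + ∇p = 0, ∇·u = 0.
The discretization is a marker-and-cell staggered grid — pressures at pore
cell centers, velocity components at cell faces — with

* pressure fixed at ``delta_p`` on the inlet face and 0 on the outlet face
  (applied at the face with half-cell spacing, so the pressure drop spans
  exactly the domain length);
* no-slip at every solid voxel and at the four side boundaries of the
  cuboid ("impervious" walls), imposed through ghost values half a cell
  behind the wall (quadratic extrapolation where a fluid neighbor exists,
  linear otherwise);
* zero normal gradient for velocity across the open inlet/outlet planes.

The linear saddle-point system is solved exactly in the velocities (sparse
LU of the three decoupled component Laplacians) with GMRES on the pressure
Schur complement; the reported residual combines the relative momentum
residual and the cross-section flux imbalance and must not exceed ``tol``.
Darcy's law then gives k = Q·μ·L/(A·ΔP) over the full cuboid cross-section
A and length L, and the flow tortuosity is Σ|v| / |Σ v_axis| over pore
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, gmres, splu

from .io_volume import AXIS_INDEX, BinaryMask
from .pore_network import DARCY_M2, PermeabilityResult
from .segmentation import percolating_pore_space

_ACTIVE, _ZERO, _WALL, _NEUMANN = 0, 1, 2, 3


@dataclass
class FlowField:
    """Converged Stokes solution on a pore mask.

    ``velocity`` holds cell-centered components (vz, vy, vx) in m/s in the
    original (z, y, x) orientation; ``plane_fluxes`` the volumetric flux
    (m³/s) through each of the n+1 face planes perpendicular to the flow
    axis, which agree to within the solver tolerance.
    """

    velocity: tuple[np.ndarray, np.ndarray, np.ndarray]
    pressure: np.ndarray  # Pa, 0 on solid
    pore: BinaryMask
    axis: str
    delta_p: float
    viscosity: float
    tol: float
    residual: float
    plane_fluxes: np.ndarray

    @property
    def total_flux(self) -> float:
        return float(self.plane_fluxes.mean())


def _face_masks(pore: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Left/right-cell pore flags and the active-face mask on the w face grid."""
    fs = list(pore.shape)
    fs[w] += 1
    left = np.zeros(fs, dtype=bool)
    right = np.zeros(fs, dtype=bool)
    sl_hi = [slice(None)] * 3
    sl_hi[w] = slice(1, None)
    left[tuple(sl_hi)] = pore
    sl_lo = [slice(None)] * 3
    sl_lo[w] = slice(0, -1)
    right[tuple(sl_lo)] = pore
    active = left & right
    if w == 0:  # open inlet/outlet boundary faces carry unknowns
        active[0] = right[0]
        active[-1] = left[-1]
    return left, right, active


def _shifted(fid: np.ndarray, d: int, step: int, fill: int) -> np.ndarray:
    out = np.full_like(fid, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[d] = slice(1, None)
        dst[d] = slice(0, -1)
    else:
        src[d] = slice(0, -1)
        dst[d] = slice(1, None)
    out[tuple(dst)] = fid[tuple(src)]
    return out


def solve_stokes(
    pore: BinaryMask,
    axis: str = "z",
    delta_p: float = 1000.0,
    viscosity: float = 0.001,
    tol: float = 1e-5,
    max_iter: int = 5000,
    wall_order: int = 2,
) -> FlowField:
    """Solve steady Stokes flow through a percolating pore mask.

    The mask must already be reduced to its percolating components (see
    :func:`porespec.segmentation.percolating_pore_space`); isolated pore
    clusters make the pressure problem singular and raise here.
    """
    ax = AXIS_INDEX[axis]
    perc = percolating_pore_space(pore, axis)  # raises if nothing percolates
    if perc.voxel_count != pore.voxel_count:
        raise ValueError(
            "pore mask contains non-percolating voxels; apply "
            "percolating_pore_space before solving"
        )
    if wall_order not in (1, 2):
        raise ValueError("wall_order must be 1 or 2")

    perm = (ax,) + tuple(i for i in range(3) if i != ax)
    P = np.transpose(pore.data, perm)
    h = pore.voxel_size * 1e-6  # m
    c = viscosity / (h * h)

    n_cells = int(P.sum())
    cid = -np.ones(P.shape, dtype=np.int64)
    cid[P] = np.arange(n_cells)

    actives, fids, lefts, rights = [], [], [], []
    offset = 0
    for w in range(3):
        left, right, active = _face_masks(P, w)
        fid = np.full(active.shape, -1, dtype=np.int64)
        nf = int(active.sum())
        fid[active] = offset + np.arange(nf)
        offset += nf
        actives.append(active)
        fids.append(fid)
        lefts.append(left)
        rights.append(right)
    n_faces = offset

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    g_rows: list[np.ndarray] = []
    g_cols: list[np.ndarray] = []
    g_vals: list[np.ndarray] = []
    rhs = np.zeros(n_faces)
    diag = np.zeros(n_faces)

    def _cell_shift(arr: np.ndarray, w: int, back: bool) -> np.ndarray:
        """Cell index (or -1) on the minus/plus side of each w-face."""
        fs = arr.shape
        out = np.full([s + (1 if i == w else 0) for i, s in enumerate(fs)], -1,
                      dtype=np.int64)
        sl = [slice(None)] * 3
        sl[w] = slice(1, None) if back else slice(0, -1)
        out[tuple(sl)] = arr
        return out

    for w in range(3):
        active = actives[w]
        fid = fids[w]
        f_here = fid[active]
        diag_w = np.full(f_here.size, 6.0 * c)  # 2c per direction baseline

        for d in range(3):
            for step in (-1, +1):
                nb = _shifted(fid, d, step, fill=-2)[active]  # -2 = out of grid
                in_grid = nb != -2
                act = nb >= 0
                inactive = in_grid & ~act
                out = ~in_grid
                if d == w:
                    # normal neighbors: zero at solid faces, Neumann beyond
                    # the open inlet/outlet plane
                    rows.append(f_here[act])
                    cols.append(nb[act])
                    vals.append(np.full(act.sum(), -c))
                    diag_w[out] -= c  # Neumann ghost equals the face value
                    # inactive in-grid: value 0 -> baseline diagonal stands
                else:
                    wall = inactive | (out & (d != 0))
                    neumann = out & (d == 0)
                    rows.append(f_here[act])
                    cols.append(nb[act])
                    vals.append(np.full(act.sum(), -c))
                    diag_w[neumann] -= c
                    if wall_order == 2:
                        opp = _shifted(fid, d, -step, fill=-2)[active]
                        quad = wall & (opp >= 0)
                        lin = wall & ~quad
                        diag_w[quad] += 2.0 * c
                        rows.append(f_here[quad])
                        cols.append(opp[quad])
                        vals.append(np.full(quad.sum(), -c / 3.0))
                        diag_w[lin] += c
                    else:
                        diag_w[wall] += c

        diag[f_here] = diag_w

        # pressure gradient across the face
        cell_m = _cell_shift(cid, w, back=True)[active]
        cell_p = _cell_shift(cid, w, back=False)[active]
        both = (cell_m >= 0) & (cell_p >= 0)
        g_rows.extend([f_here[both], f_here[both]])
        g_cols.extend([cell_p[both], cell_m[both]])
        g_vals.extend([np.full(both.sum(), 1.0 / h), np.full(both.sum(), -1.0 / h)])
        if w == 0:
            inlet = cell_m == -1  # no minus cell: inlet boundary face
            outlet = cell_p == -1
            g_rows.append(f_here[inlet])
            g_cols.append(cell_p[inlet])
            g_vals.append(np.full(inlet.sum(), 2.0 / h))
            rhs[f_here[inlet]] += 2.0 * delta_p / h  # known reservoir pressure
            g_rows.append(f_here[outlet])
            g_cols.append(cell_m[outlet])
            g_vals.append(np.full(outlet.sum(), -2.0 / h))

    rows.append(np.arange(n_faces))
    cols.append(np.arange(n_faces))
    vals.append(diag)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_faces, n_faces),
    ).tocsc()
    G = coo_matrix(
        (np.concatenate(g_vals), (np.concatenate(g_rows), np.concatenate(g_cols))),
        shape=(n_faces, n_cells),
    ).tocsr()

    # divergence: D[c, f] = ±1/h for the plus/minus faces of each pore cell
    d_rows, d_cols, d_vals = [], [], []
    for w in range(3):
        active = actives[w]
        fid = fids[w]
        cell_m = _cell_shift(cid, w, back=True)[active]
        cell_p = _cell_shift(cid, w, back=False)[active]
        f_here = fid[active]
        has_p = cell_p >= 0
        has_m = cell_m >= 0
        d_rows.extend([cell_p[has_p], cell_m[has_m]])
        d_cols.extend([f_here[has_p], f_here[has_m]])
        d_vals.extend(
            [np.full(has_p.sum(), -1.0 / h), np.full(has_m.sum(), 1.0 / h)]
        )
    D = coo_matrix(
        (np.concatenate(d_vals), (np.concatenate(d_rows), np.concatenate(d_cols))),
        shape=(n_cells, n_faces),
    ).tocsr()

    lu = splu(A)
    ainv_f = lu.solve(rhs)
    rhs_p = D @ ainv_f

    def _schur(p: np.ndarray) -> np.ndarray:
        return D @ lu.solve(G @ p)

    S = LinearOperator((n_cells, n_cells), matvec=_schur)
    inner_tol = min(tol, 1e-5) * 1e-3
    restart = 100
    p_vec, info = gmres(
        S, rhs_p, rtol=inner_tol, atol=0.0, restart=restart,
        maxiter=max(1, max_iter // restart),
    )
    u_vec = lu.solve(rhs - G @ p_vec)

    mom_res = np.linalg.norm(A @ u_vec + G @ p_vec - rhs) / np.linalg.norm(rhs)

    # per-plane volumetric fluxes along the flow axis (transposed frame)
    fid0 = fids[0]
    u_grid0 = np.zeros(fid0.shape)
    u_grid0[actives[0]] = u_vec[fid0[actives[0]]]
    plane_fluxes = u_grid0.sum(axis=(1, 2)) * h * h
    mean_q = plane_fluxes.mean()
    if mean_q == 0:
        raise RuntimeError("solver produced zero net flux on a percolating mask")
    flux_spread = float(np.ptp(plane_fluxes) / abs(mean_q))
    residual = float(max(mom_res, flux_spread))
    if info != 0 or residual > tol:
        raise RuntimeError(
            f"Stokes solve did not reach tol={tol:g} within max_iter={max_iter}: "
            f"residual={residual:.3e} (gmres info={info})"
        )

    # cell-centered velocities, back in the original orientation
    vel_t = []
    for w in range(3):
        fid = fids[w]
        grid = np.zeros(fid.shape)
        grid[actives[w]] = u_vec[fid[actives[w]]]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[w] = slice(0, -1)
        hi[w] = slice(1, None)
        v = 0.5 * (grid[tuple(lo)] + grid[tuple(hi)])
        v[~P] = 0.0
        vel_t.append(v)

    inv = np.argsort(perm)
    vel_orig: list[np.ndarray | None] = [None, None, None]
    for orig_dim in range(3):
        comp = vel_t[inv[orig_dim]]
        vel_orig[orig_dim] = np.transpose(comp, inv)
    pressure = np.zeros(P.shape)
    pressure[P] = p_vec
    pressure = np.transpose(pressure, inv)

    return FlowField(
        velocity=tuple(vel_orig),  # type: ignore[arg-type]
        pressure=pressure,
        pore=pore,
        axis=axis,
        delta_p=delta_p,
        viscosity=viscosity,
        tol=tol,
        residual=residual,
        plane_fluxes=plane_fluxes,
    )


def darcy_permeability(field: FlowField, pore: BinaryMask | None = None) -> PermeabilityResult:
    """Back out absolute permeability from a converged field via Darcy's law.

    Q is the cross-section flux (identical across sections within the solve
    tolerance), A the *full* cuboid cross-section and L the cuboid length
    along the flow axis.
    """
    pore = pore or field.pore
    ax = AXIS_INDEX[field.axis]
    h = pore.voxel_size * 1e-6
    q = field.plane_fluxes
    if np.ptp(q) > 10.0 * field.tol * abs(q.mean()):
        raise RuntimeError(
            f"cross-section fluxes disagree by {np.ptp(q) / abs(q.mean()):.2e}: "
            "mass not conserved"
        )
    flux = float(q.mean())
    length = pore.shape[ax] * h
    area = (pore.data.size / pore.shape[ax]) * h * h
    k_m2 = flux * field.viscosity * length / (area * field.delta_p)
    return PermeabilityResult(
        k_m2=k_m2,
        tortuosity=flow_tortuosity(field),
        total_flux=flux,
        axis=field.axis,
        method="FE",
        delta_p=field.delta_p,
        viscosity=field.viscosity,
    )


def flow_tortuosity(field: FlowField) -> float:
    """Σ|v| / |Σ v_axis| over pore voxels; 1 for perfectly straight flow."""
    ax = AXIS_INDEX[field.axis]
    mask = field.pore.data
    vz, vy, vx = field.velocity
    speed = np.sqrt(vz[mask] ** 2 + vy[mask] ** 2 + vx[mask] ** 2)
    axial = float(field.velocity[ax][mask].sum())
    if axial == 0:
        raise ValueError("zero net axial flow: tortuosity undefined")
    tau = float(speed.sum() / abs(axial))
    return tau


def darcy_si_convert(value: float, direction: str = "to_si") -> float:
    """Convert permeability between darcy and m² (1 d = 9.869233e-13 m²)."""
    if value < 0:
        raise ValueError("permeability cannot be negative")
    if direction == "to_si":
        return value * DARCY_M2
    if direction == "to_darcy":
        return value / DARCY_M2
    raise ValueError("direction must be 'to_si' or 'to_darcy'")
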