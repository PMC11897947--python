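# Methods

This note records the models implemented in `porespec`, the numerical
choices behind them, and what the synthetic validation does and does not
demonstrate about real scans.

## Segmentation and porosity

The material mask is `value ≥ threshold` (Otsu by default). Interactive
cleanup of scanner speckle is replaced by a deterministic surrogate:
keeping the largest 26-connected material component. The closed-and-filled
envelope is a morphological closing with a spherical element (default
radius 3 voxels ≈ 22.5 μm at 7.5 μm voxels; the appropriate radius is the
smallest that seals surface pore mouths) followed by filling every
background component not connected to the volume border. Porosity is
100·V_pore/V_envelope with pore = envelope ∖ material; the three masks obey
exact set identities that the tests assert on every input.

Connectivity conventions: 26-connectivity for solids (permissive),
6-connectivity for pore percolation (a conservative notion of a flow
path). Before any flow solve, pore components not touching both faces
perpendicular to the flow axis are removed — they carry no steady flux.

## Local thickness

Local thickness at a voxel is the diameter of the largest sphere fully
inside the phase that contains the voxel. A sphere "fits" iff every voxel
whose center lies strictly inside it belongs to the mask; voxels outside
the image grid impose no constraint. Under this convention the radius
available at a center c equals its Euclidean distance transform value
d(c), so the map is computed exactly by processing the distinct squared
distances (integers, so all comparisons are exact) in decreasing order and
dilating each level set with the strict ball of that radius. The suite
checks voxel-for-voxel agreement with a brute-force sphere-fitting oracle
on random masks up to 24³.

Distribution summaries are model-free: the peak is the argmax of a 3-bin
moving average; the FWHM is obtained by linear interpolation of the raw
counts at half the peak height (2.3548σ for a Gaussian, verified on 10⁶
samples). The default bin width is one voxel diameter; because EDT values
are discrete, one-voxel bins alias the distance levels into a sawtooth,
and 2-voxel bins are recommended when judging modality.

## Pore separation and the network model

Touching pores separate by marker-controlled watershed on the negated
distance transform. Markers are plateau-preserving local maxima: a voxel
is a candidate iff no strictly larger EDT value lies within the
minimum-separation radius (default 2 voxels), and connected candidates
merge into one marker — so the ridge of a straight channel yields a single
marker rather than a fragmented chain. Highly interconnected pore spaces
still oversegment, as watershed methods do on such data; the resulting
clusters are then read as "equivalent pores".

The network has one spherical pore per label (center = centroid, radius =
max EDT inside the label) and one cylindrical throat per face-adjacent
label pair. The throat radius is the largest EDT value *on* the shared
interface (per facet, the smaller of the two flanking-cell values — the
larger one sits inside a pore body). Each link spans the full
center-to-center distance as a series of Poiseuille cylinders: a
half-conduit through each internal pore body (length = pore radius, at the
body radius) plus the neck cylinder over the remaining gap at the throat
radius. This is the standard spheres-and-cylinders conduit; two extremes
bracket it and both fail on oversegmented media (zero-resistance bodies
erase almost all viscous resistance because most center spacings are
smaller than the two body radii; neck-radius cylinders over the full span
over-resist by a similar factor). Virtual inlet/outlet pores carry zero
volume and fixed pressure and contribute no body segment, so an
analytically constructed single throat reproduces Poiseuille's law
exactly, and equal throats in series halve the flux exactly.

Steady flow imposes zero net accumulation at every internal pore
(sparse direct solve; internal mass balance residuals are at rounding
level, asserted ≤ 10⁻¹⁰ of throughput). Hydraulic tortuosity is
Σ|v_throat| / |Σ v_throat,axis| with each throat's velocity q/(πr²)
directed along its pore-center axis.

The per-pore aspect ratio is √(λ_min/λ_max) of the label's
voxel-coordinate covariance — the axis-length ratio of the equivalent
ellipsoid, dimensionless in (0, 1]. The ellipsoid pore model is
V = (4/3)·π·a·b·c with two named shape cases tying the minor semi-axis to
a measured mean local thickness t: flattened (a = t, b = c = 2t) and
near-spherical (a = b = t, c = 2t).

## Voxel Stokes solver

At μm pore scales and mPa·s viscosities the Reynolds number is ≪ 1, so
inertia is dropped and steady incompressible Stokes flow is solved
(−μ∇²u + ∇p = 0, ∇·u = 0); for permeability the two formulations define
the same Darcy constant. Discretization is a staggered marker-and-cell
grid: pressure at pore-cell centers, velocity components at faces.

* Inlet/outlet: pressure fixed at ΔP (default 1 kPa) and 0 on the two
  faces perpendicular to the flow axis, applied with half-cell spacing so
  the drop spans exactly the domain length; velocity has zero normal
  gradient across these open planes.
* Walls: no-slip at every solid voxel and at the four side boundaries
  ("impervious", consistent with surrounding solid material). Tangential
  ghost values sit half a cell behind the wall; a quadratic extrapolation
  (exact for parabolic profiles) is used where a fluid neighbor exists,
  linear otherwise.

The saddle-point system is solved by factorizing the three decoupled
velocity-component momentum operators (sparse LU) and running GMRES on the
pressure Schur complement, which is well conditioned for Stokes; the
velocities then satisfy momentum to rounding. The reported residual is the
larger of the relative momentum residual and the relative spread of the
per-cross-section fluxes, and must fall below the convergence tolerance
(default 10⁻⁵, interpreted as a dimensionless relative criterion).

Accuracy on analytic fixtures (voxel-exact geometry, channels centered on
voxel centers so the axis is grid-resolvable): tube k within 1.5% of
πr⁴/(8A) at r = 10 voxels, slab k within 2% of h²/12, parabolic profile
ratios to 1%, and tube-fixture error decreasing monotonically with radius.
Flow tortuosity Σ|v|/|Σ v_axis| is 1.000 on straight fixtures; on a
serpentine with centerline ratio 1.5 the velocity-weighted value is ~1.43
(streamlines cut corners, so τ lies below the centerline ratio). Sums run
over pore voxels only.

## Synthetic specimens

`generate_sintered_packing` emulates an SLS-sintered polymer matrix:
spherical grains with diameters from a normal distribution (default
60 ± 20 μm, truncated at 2 voxels) are deposited at uniform random centers
— overlaps model fusion — until the solid fraction reaches the target,
then a Gaussian blur (σ = 1 voxel) forms sintering necks. A 2-voxel denser
surface skin encloses the pore network, as the contour-sintered skin of
real SLS parts does; this is what makes the closing+fill envelope cover
the whole specimen even though the interior porosity is fully
interconnected. The binarization threshold is then calibrated by bisection
so that the *default segmentation* of the emitted grayscale volume (a
sharp logistic mapping around the calibrated threshold plus mild detector
noise) reproduces the target porosity; measured porosity is within ±0.005
of a 0.44 target across seeds at 128³, comfortably inside the ±0.02
guarantee the tests assert. One seeded generator drives every draw, so a
given spec is bit-reproducible. `anisotropy_stretch` elongates grains (and
hence pores) along the build axis; stretched specimens show larger
pore-coordinate covariance along z and correspondingly higher k_z than
k_x.

What the generator does *not* emulate: the layered texture of powder-bed
fusion, partially sintered loose particles inside pores, scanner artifacts
(beam hardening, rings), or any thermal physics. Passing tests therefore
demonstrate the correctness of the measurement chain on matched-statistics
geometry, not agreement with any particular scanned specimen — scan-derived
permeabilities also depend on the original solver's discretization and
boundary treatment.

## Pipeline defaults and problem sizes

The pipeline runs segmentation, porosity, both thickness phases, watershed
statistics, and then, per axis, the percolation filter, the Stokes solve
and the PNM solve on a central interior cuboid (margin = skin + 2 voxels
for synthetic input) — permeability is a property of the core pore
network, and the crop mirrors how a subvolume is extracted from a scanned
specimen. Reports are deterministic for a given config and seed;
timings go to the log only. The test suite exercises specimens up to 128³
for porosity control and 48³–64³ for end-to-end flow, sizes at which the
direct-factorization Schur solver is comfortable; the two methods agree on
k within a factor of ~1.5–2.6 there (PNM high), the same discrepancy
pattern paired FE/PNM analyses of sintered matrices report.

## Known limitations

* The Stokes solver's memory is dominated by the sparse LU of the
  momentum blocks; domains much beyond ~10⁶ pore voxels call for a matrix-
  free multigrid instead.
* PNM permeability inherits the cylinder-conduit abstraction: no shape
  factors, no converging/diverging losses; expect same-order, not
  percent-level, agreement with the voxel solve.
* `ray_extent` casts axis-aligned rays only; specimens must be aligned
  before tip-to-tip measurements.
* Thickness maps use voxel-center sphere containment; sub-voxel surface
  positions (partial-volume effects) are not modeled.
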