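# porespec

Pore-space characterization and permeability modeling of X-ray
micro-computed-tomography (μCT) volumes of highly porous sintered solids —
in particular selective-laser-sintered (SLS) polymer dosage forms, whose
~44% interconnected porosity governs how dissolution media wick into the
matrix and hence how fast a drug is released.

Given a grayscale attenuation volume (a scan or a synthetic stand-in), the
package computes, in one reproducible pipeline:

* **Segmentation & porosity** — threshold to a *material* mask; build the
  *closed-and-filled* envelope (morphological closing + fill of interior
  voids); pore space = envelope ∖ material; porosity % = 100·V_pore/V_env.
* **Local thickness** — per-voxel diameter of the largest sphere that fits
  inside the phase and contains the voxel (Hildebrand–Rüegsegger), with
  histogram, peak and FWHM summaries for both the fused matrix and the
  pore network.
* **Pore separation & statistics** — marker-controlled watershed on the
  distance transform; per-pore volume, equivalent diameter and aspect
  ratio √(λ_min/λ_max); an ellipsoid pore model V = (4/3)·π·a·b·c.
* **Absolute permeability & tortuosity, two ways** —
  * a voxel **Stokes** solver (creeping flow on a staggered MAC grid,
    ΔP = 1 kPa across the cuboid, no-slip walls), with Darcy back-out
    k = Q·μ·L/(A·ΔP) and flow tortuosity τ = Σ|v| / |Σ v_axis|;
  * a **pore-network model** (PNM): watershed pores as spheres, throats as
    cylinders with Poiseuille conduit conductances, solved for steady flow
    with zero net accumulation at every pore.
  Permeability is reported in darcy and m² (1 d = 9.869233×10⁻¹³ m²),
  along each requested axis (z = build/longitudinal direction).
* **Dimensional QA** — signed percent deviation from the digital design,
  print-layer counts, and ray-cast tip-to-tip extents of binary masks.

A synthetic-volume module generates sintered-packing stand-ins (overlapping
grains, 60 ± 20 μm diameters, Gaussian sintering necks, a denser surface
skin, calibrated to a target porosity) and analytic flow fixtures (tube,
slab, duct, serpentine) with closed-form permeability/tortuosity used to
validate both solvers.

## Worked example

Run the full pipeline on a synthetic 48³ specimen (7.5 μm voxels, 44%
target porosity, seed 7):

```python
from porespec import PipelineConfig, SyntheticSpec, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticSpec(domain_shape=(48, 48, 48), seed=7),
    output_dir="out",
)
report = run_pipeline(cfg)
print(round(report["porosity_pct"], 1))                     # 43.9
print(round(report["permeability"]["z"]["FE"]["k_darcy"], 1))   # 48.7
print(round(report["permeability"]["z"]["FE"]["tortuosity"], 2))  # 1.13
print(round(report["permeability"]["z"]["PNM"]["k_darcy"], 1))  # 71.8
```

The report says: the segmented specimen has 43.9% porosity (the generator
was asked for 44%); steady Stokes flow along the build axis gives an
absolute permeability of 48.7 d (4.80×10⁻¹¹ m²) with a flow tortuosity of
1.13 (nearly straight flow paths at this porosity), and the much coarser
pore-network abstraction of the same pore space gives 71.8 d — the same
order of magnitude, biased high as cylinder-throat networks typically are.
`out/report.json` additionally holds the thickness summaries (material
peak 0.071 mm, pore peak 0.056 mm here), the pore-cluster table, and the
transverse-axis results.

The same run is available from the shell:

```bash
porespec run --config config.json      # full pipeline
porespec synth -o vol.tif --seed 7     # individual stages: synth, segment,
porespec segment vol.tif -o out/       # thickness, network, flow, qa
porespec qa --measured 8.09 --nominal 8.24   # -> {"deviation_pct": -1.82}
```

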