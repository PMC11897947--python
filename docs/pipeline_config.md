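# Pipeline configuration schema

`porespec run --config config.json` accepts a JSON object with the fields
below (all optional unless noted; exactly one of `input_path` /
`synthetic` is required). Defaults in parentheses.

```jsonc
{
  "input_path": "scan.tif",        // volume on disk (TIFF/raw + sidecar), OR
  "synthetic": {                    // generate a specimen instead
    "domain_shape": [128, 128, 128],
    "voxel_size": 7.5,              // μm
    "grain_diameter_mean": 60.0,    // μm
    "grain_diameter_sd": 20.0,      // μm
    "target_porosity": 0.44,
    "neck_blur_sigma": 1.0,         // voxels
    "anisotropy_stretch": 1.0,      // grain elongation along z
    "skin_voxels": 2,               // denser surface skin thickness
    "seed": 0
  },
  "segmentation": {
    "threshold": "otsu",            // or an explicit grayscale value
    "closing_radius": 3,            // voxels
    "fill_holes": true
  },
  "thickness_bin_width": null,      // mm (null = one voxel diameter)
  "marker_separation": 2,           // voxels, watershed peak suppression
  "axes": ["z", "x"],               // flow directions to solve
  "delta_p": 1000.0,                // Pa
  "viscosity": 0.001,               // Pa·s
  "tol": 1e-5,                      // flow convergence criterion
  "max_iter": 5000,
  "flow_margin": null,              // voxels cropped per face before flow
                                    // (null = skin+2 synthetic, 4 scanned)
  "output_dir": "porespec_out",
  "seed": null                      // overrides synthetic.seed when set
}
```

The report (`report.json`, `report_version` 1) contains `porosity_pct`,
`thickness.{material,pore}.{peak_mm,fwhm_mm}`, `pore_clusters` summary
(full table in `pore_table.csv`), and `permeability.<axis>.{FE,PNM}` with
`k_darcy`, `k_m2`, `tortuosity`, `total_flux_m3_s` and the solve
parameters. Identical config + seed reproduces the report byte for byte.
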