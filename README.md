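# kneevbr

Voxel-based relaxometry (VBR) of knee articular cartilage, exercised end to
end on synthetic phantom cohorts. The package simulates atlas-space knee
phantoms with known relaxation effects, fits per-voxel T1ρ/T2 maps from
multi-echo volumes, registers them into a common space, and runs
covariate-adjusted voxel-wise statistics with compartment summaries plus
distance-transform cartilage thickness.

## Modules

| module | purpose |
| --- | --- |
| `kneevbr.synthetic` | phantom atlases (6 cartilage compartments), ground-truth relaxation fields with injectable group effects, multi-echo signal simulation (Gaussian/Rician noise), per-knee records (covariates, MRI abnormality grades, KOOS items/subscales) |
| `kneevbr.relaxometry` | per-voxel mono-exponential fitting: closed-form log-linear estimator and a vectorized Levenberg–Marquardt fit, plus fit-quality masking |
| `kneevbr.registration` | rigid echo-to-first-echo alignment, identity/affine subject-to-atlas registration, and a plugin contract for external deformable backends |
| `kneevbr.morphometry` | compartment masks and per-sagittal-slice cartilage thickness (2D Euclidean distance transform sampled at skeleton points) |
| `kneevbr.stats` | voxel-wise statistical parametric mapping: covariate-adjusted group differences, Pearson partial correlations, p ≤ α thresholding with connected-component clusters, PSV/APD/avg-r/avg-p compartment summaries, permutation cross-check |
| `kneevbr.cli` | `kneevbr simulate / fit / analyze / report / all` pipeline with YAML configs and hashed manifests |

Sign convention: reported percentage differences are
`100 * (mean_without - mean_with) / mean_without` with covariate-adjusted
group means — a **negative** value means **higher** relaxation times in knees
**with** the abnormality.

## CLI

```sh
kneevbr all --out-dir runs/demo --n-knees 20 --seed 1
# or stage by stage, optionally from a YAML config:
kneevbr simulate --config config.yaml --force
kneevbr fit      --config config.yaml
kneevbr analyze  --config config.yaml --alpha 0.05
kneevbr report   --config config.yaml
```

Outputs under `<out_dir>/`: `cohort/` (atlas + 4D echo series NIfTI + records
CSV), `maps/` (time/S0/r² volumes + fit report), `analysis/` (effect, p and
10·log10(1/p) volumes, cluster table, compartment summary CSVs shaped like the
group-comparison and correlation tables, per-slice thickness CSV), and
`report.md`. Each stage writes a `manifest.json` with SHA-256 hashes and the
config hash; identical configs and seeds reproduce identical artifacts.

Exit codes: 0 ok, 1 runtime error, 2 usage error.

### Registration plugin contract

`register_to_atlas(..., mode="plugin", plugin_cmd=[...])` writes
`moving.nii`/`fixed.nii` to a temp directory, substitutes the placeholders
`{moving}`, `{fixed}`, `{out}` into the command, and expects the executable
to exit 0 after writing `{out}_warped.nii` (the value map on the atlas grid)
and `{out}_disp.nii` (4D displacement field, mm, vector components on the 4th
axis). Nonzero exit or missing outputs raise a `RegistrationError` carrying
the captured stderr.

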