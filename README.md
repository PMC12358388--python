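# ldvdose

Pre-treatment dosimetry for targeted radioligand therapy from a single
dynamic PET/CT study. The pipeline determines voxel distribution volumes by
Logan graphical analysis of the dynamic frames, combines them with an
extrapolated, therapy-scaled arterial input AUC to form a time-integrated
activity (TIA) map, converts TIA to absorbed dose with a local-deposition or
radial-kernel engine, and converts dose to biologically effective dose (BED)
with an extended linear-quadratic model (Lea–Catcheside protraction factor,
repair, clamped repopulation). Per-ROI tables, DVHs, and cohort summaries are
emitted alongside full provenance.

Because clinical dynamic PET data is not redistributable, the package ships a
digital pelvis phantom (`ldvdose.phantom`) with known kinetic ground truth,
tissue densities, ROI masks and a parametric arterial model, so every stage
is testable offline end to end.

## Layout

| module              | role |
| ------------------- | ---- |
| `ldvdose.kinetics`  | decay-incorporated two-tissue compartment model: residue function, closed-form AUC, distribution volume, forward TAC simulation |
| `ldvdose.aif`       | image-derived arterial curve extraction, rise + exponential-sum fitting, analytic therapy-scaled AUC extrapolation |
| `ldvdose.logan`     | voxel-wise Logan transform, delay search by maximum R², LDV/intercept/R²/delay maps |
| `ldvdose.tia_dose`  | TIA maps, HU→density calibration, local/kernel dose engines, per-GBq normalization |
| `ldvdose.radiobiology` | Lea–Catcheside factor, LQ log-survival, BED maps, DVH, ROI statistics |
| `ldvdose.phantom`   | synthetic dynamic study generator with ground truth |
| `ldvdose.report` / `ldvdose.cli` | pipeline orchestration, segmentation, report tables, cohort summaries, CLI |
| `ldvdose.reference` | bundled six-subject reference cohort used as regression fixtures |

## CLI

```sh
# full phantom pipeline: simulate -> aif -> logan -> tia -> dose -> bed -> report
ldvdose run --out-dir out --seed 1

# stage by stage
ldvdose simulate --out-dir sim
ldvdose aif sim/study sim/roi_artery.nii --out-curve aif.csv --out-fit aif.json
ldvdose logan sim/study aif.csv sim/density.nii --out-dir maps
ldvdose tia maps/ldv.nii sim/density.nii 1e9 --out tia.nii
ldvdose dose tia.nii sim/density.nii --mode local --out dose.nii
ldvdose bed dose.nii --out bed.nii
```

`run` accepts a YAML config (`--config`) mirroring
`ldvdose.report.PipelineConfig`; all randomness flows from the config seed
and reruns are bit-identical. Outputs: per-ROI statistics tables (raw and
one-decimal rounded CSVs) for LDV, dose per cycle, dose per GBq and BED,
cumulative DVH CSVs, and a `provenance.json` sidecar.

## Notes

- The external Monte Carlo transport stage of the original workflow is out
  of scope; the kernel/local engines are documented surrogates with energy
  conservation checks. Nuclide constants and the bundled radial kernel live
  in `src/ldvdose/data/` (versioned).
- Kinetics are in minutes internally; radiobiology in days; half-lives are
  converted once at the boundary.
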