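# pulmovent

Longitudinal micro-CT lung quantification for preclinical fibrosis studies:

- **Densitometry** — whole/left/right lung volumes, mean lung attenuation
  (MLA), aeration compartments (%Normo `[-860, -435]` HU, %Hypo
  `(-435, -121)`, %Non `[-121, 121]`, plus an explicit %Other), gas/tissue
  decomposition and tidal volume.
- **Ventilation mapping** — Laplacian-of-Gaussian prefiltered,
  multi-resolution Demons registration of end-expiratory (P02) onto
  end-inspiratory (P01) volumes; voxel-wise specific gas volume
  `SVg = 1000/(HU + 1000) - 1/1.065` (ml/g) and `dSVg = SVg_P01 - SVg_P02`;
  percentile-calibrated thresholds (alpha_I, alpha_E: 5th percentiles of the
  basal inspiratory/expiratory SVg distributions; beta: 25th percentile of
  basal dSVg) driving a three-class voxel classifier
  (Normal / Low / Fibrosis).
- **Cohort pipeline** — per scan-pair reports, fold-changes versus each
  subject's day-0 baseline (%Fibrosis reported raw since its baseline is
  ~0), and group mean ± SEM summary tables.
- **Synthetic phantom cohort** — mass-conserving digital thorax phantoms
  (paired P01/P02 volumes with exact masks, displacement fields, Jacobians
  and lesion labels) standing in for raw animal scans, including a
  longitudinal saline/challenge/treatment cohort simulator.

## Test

```bash
python -m pytest -q tests/
```

The suite is fully self-contained: all imagery is generated at test time by
the phantom module. It finishes in a few minutes on one CPU.

## Command line

```bash
# simulate a longitudinal phantom cohort (volumes, truth files, manifest.csv)
pulmovent simulate --config plan.yaml --out data/ --seed 1

# single-stage tools
pulmovent segment p01.nii.gz mask.nii.gz --threshold-hu -200
pulmovent aeration p01.nii.gz mask.nii.gz aeration.csv
pulmovent register p01.nii.gz p02.nii.gz --out-field field.nii.gz --out-warped warped.nii.gz

# functional analysis
pulmovent calibrate data/manifest.csv thresholds.yaml   # day-0 pairs
pulmovent ventilate p01.nii.gz p02.nii.gz thresholds.yaml --out-prefix out/subj
pulmovent cohort data/manifest.csv --out results/       # full pipeline
```

Every constant (HU compartment boundaries, tissue specific volume,
calibration percentiles, registration and segmentation parameters) is
overridable through a YAML config passed with `--config`; see
`pulmovent.config.AnalysisConfig`.

## Python API

```python
import pulmovent as pv

spec = pv.PhantomSpec(grid_shape=(64, 64, 64), rng_seed=1)
p01, p02, truth = pv.make_phantom_pair(spec, lesions=pv.LesionSpec(count=4))

mask = pv.segment_lungs(p01)
report = pv.aeration_report(p01, mask, "whole")

field = pv.register_pair(p01, p02)
warped = pv.warp_volume(p02, field)
```

## Conventions

- Arrays are indexed `(x, y, z)` with the cranio-caudal axis last; voxel
  indices are 0-based and world coordinates are `origin + index * spacing`.
- Displacement fields live on the fixed (P01) grid and map fixed
  coordinates to moving (P02) coordinates (pull-back warping); units are mm.
- HU values are floats; volumes, labels and fields are read and written as
  NIfTI, tables as CSV, configs as YAML.
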