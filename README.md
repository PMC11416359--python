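# sonomargin

Tested pipeline for comparing resection-margin measurements made on a
segmented intra-operative 3D-ultrasound (US) volume of a resected tongue
specimen with the measurements made on the corresponding histopathology
slides:

* **core model / IO** — label volumes (NRRD / NIfTI), slide stacks
  (TIFF/PNG masks + JSON sidecar), per-elevation mucosal-edge landmarks
  (JSON), long-format measurement tables (CSV), and margin
  classification (clear / close `< 5 mm` / involved);
* **phantom** — a synthetic specimen generator (superellipsoid tissue,
  embedded tumor, up to three tilted ~1.7 mm fiducial channels) with a
  histology transform (uniform linear shrinkage, optional
  volume-preserving stretch and smooth in-plane deformation, 4 mm
  sectioning) and *analytic* ground truth for every downstream stage;
* **correspondence** — two-step slide-to-US-slice matching: specimen
  length divided by the slide count, then inter-fiducial distance
  profiles (scale-compensated for bulk shrinkage) with a strict
  monotonicity constraint solved by dynamic programming; residuals are
  reported, never silently thresholded;
* **measurement** — the mucosal chord + two rays at ±45° partition the
  resection surface into cranial / deep / caudal regions; per
  tumor-bearing slice the three region margins (exact Euclidean
  distance transform on the physical grid) and the tumor thickness
  (extent along the chord normal); per specimen the anterior/posterior
  end margins (tumor-free-slide counting on the histology side, 3D
  closest-surface distance on the US side);
* **agreement** — Shapiro-Wilk normality gate, Pearson/Spearman
  correlation, Bland-Altman mean difference with 95% limits of
  agreement (differences always US − histology), per-region and pooled
  reporting, and an exclusion sensitivity re-analysis.

All distances are physical (mm); voxel/pixel spacings are anisotropic
throughout.

## CLI

```sh
# synthesize a specimen: volume.nrrd, slides/ + sidecar, landmarks, truth
sonomargin phantom generate --seed 4 --out phantom/ --specimen P1 \
    --config cfg.yaml           # optional YAML of PhantomConfig overrides

# match histology slides to US elevations
sonomargin match --us phantom/volume.nrrd --slides phantom/slides \
    --specimen P1 --out corr.json

# measure both modalities
sonomargin measure us --volume phantom/volume.nrrd --corr corr.json \
    --landmarks phantom/us_landmarks.json --specimen P1 --out us.csv
sonomargin measure histo --slides phantom/slides --specimen P1 --out histo.csv

# correlation + Bland-Altman report (CSV, markdown, plots)
sonomargin agree --us us.csv --histo histo.csv --exclude P8 --out report/
```

## Python API sketch

```python
from sonomargin import phantom, pipeline, agreement

cohort = phantom.generate_cohort(10, seed=7, shrinkage=0.2)
pairs = pipeline.cohort_pairs(cohort)
report = agreement.build_report(pairs)
agreement.render_report(report, pairs, "report/")
print(report.pooled.r, report.pooled.mean_diff)
print(agreement.estimate_shrinkage(pairs))
```
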