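# drgvol

Volumetric MRI analysis of mouse dorsal root ganglia (DRG).

DRG hypertrophy is a hallmark of Fabry disease: globotriaosylceramide (Gb3)
accumulating in sensory neurons enlarges the ganglion, and DRG volume
measured by MRI is a candidate non-invasive biomarker for disease
progression and treatment response. In mice the L4 DRG is sub-millimeter,
sits directly on the ventral-lateral cord surface, and shows no intrinsic
T2 contrast against the cord — so it must be delineated *by reference to
the cord itself*. This package implements that analysis end to end for
researchers running small-animal DRG imaging studies:

* **`drgvol.segmentation`** — the cord-referenced delineation pipeline:
  identify the DRG-bearing axial slices, align slices by integer
  dorsal-ventral shifts, average the two cord-only reference slices,
  detect the cord edge (Sobel gradient magnitude, auto threshold 4× mean),
  fill it into a mask, maximum-intensity-project (MIP) the DRG slices,
  zero the cord, and delineate each DRG by relative intensity
  (1.10 × cord mean). The cross-sectional area is

  `CSA = N_px × (FOV_lr / n_lr) × (FOV_dv / n_dv)`

  with the default geometry giving exactly 78.125 µm pixels
  (0.0061035 mm² per pixel) — every CSA is an integer pixel multiple.
* **`drgvol.reliability`** — test–retest agreement: one-way random-effects
  single-measure ICC, Bland–Altman bias and 95% limits of agreement
  (bias ± 1.96 × SD of differences), and per-pair relative differences
  computed on integer pixel counts.
* **`drgvol.cohortstats`** — longitudinal group comparison: group pooling,
  two-sided Student's t-tests, and the endpoint-gated closed testing
  procedure (test the a-priori endpoint first, step back in time only
  while p < α), plus the histology positivity percentage.
* **`drgvol.phantom`** — a synthetic generator standing in for live
  animals: analytic cord/DRG ellipsoids rasterized on the acquisition
  grid, Rician noise, repositioning jitter between test and retest, and
  longitudinal cohorts with group-specific CSA trajectories, all with
  exact ground truth.
* **`drgvol.imaging`** — voxel geometry, axis conventions, NIfTI/TIFF
  stack I/O and CSV measurement tables.

## Worked example

Render a phantom with known ground truth, run the pipeline, and compute a
reliability report from the bundled reference test–retest table:

```sh
$ drgvol simulate --out ph.nii --truth truth.json --seed 4
wrote ph.nii (true px: {'left': 45, 'right': 45})

$ drgvol segment --in ph.nii --out meas.csv --animal-id m1
2 DRG(s) measured -> meas.csv

$ cat meas.csv
animal_id,side,timepoint,group,pixel_count,csa_mm2
m1,left,0.0,unknown,41,0.250244
m1,right,0.0,unknown,41,0.250244
```

Both 45-pixel DRGs (0.2747 mm² truth) are recovered at 41 px
(0.2502 mm²): the filled cord mask includes the detected edge band and
clips a few pixels at the cord–DRG tangency, a deviation within the
partial-volume band of the method (see `docs/methods.md`).

```sh
$ drgvol reliability --in pairs.csv --out report.json
n=10  ICC=0.904  bias=0.0030  LoA=(-0.0597, 0.0657) mm^2
```

On the ten bundled reference pairs (`drgvol.datasets.testretest_table()`),
the ICC of 0.90 indicates that 90% of the measurement variance is
between-DRG rather than scan-to-scan, and the limits of agreement say a
repeat scan of the same DRG lands within about ±0.06 mm² of the first.

The same objects are available as library calls
(`segmentation.run_pipeline`, `reliability.reliability_report`,
`cohortstats.closed_testing`, `phantom.render_cohort`).

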