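# Methods

## Problem and approach

In mice the dorsal root ganglion (DRG) sits directly on the ventral-lateral
surface of the spinal cord and shows no intrinsic T2 contrast against it, so
it cannot be segmented from a single axial slice. The pipeline implemented
here exploits the longitudinal geometry instead: the L4 DRG spans roughly
0.9 mm rostro-caudally (three 0.29 mm slices), while the cord's cross-section
is effectively constant over such a short segment. Two cord-only slices
immediately rostral to the DRG therefore provide a cord template that can be
subtracted from a maximum intensity projection (MIP) of the DRG-bearing
slices, leaving the hyperintense DRG as the dominant residual structure. The
pixel count of the delineated residual, times the exact pixel area, is the
cross-sectional area (CSA) used as a surrogate for DRG volume.

## Geometry

The default acquisition geometry is a 2 × 1.5 × 0.7 cm field of view over a
256 × 192 × 24 matrix: 78.125 × 78.125 µm pixels (pixel area
0.0061035 mm²) and ≈0.2917 mm slices. Pixel sizes are kept exact rather
than rounded to 78 µm, because only the exact value makes measured CSAs
integer multiples of the pixel area — a property the package enforces as an
invariant on every measurement table and uses to recover integer pixel
counts from published CSA values. Arrays are indexed `[slice, dv, lr]`,
0-based, slice axis rostral→caudal, dv axis dorsal→ventral, lr axis
subject-left→subject-right. Slice indices are reported 1-based in
user-facing logs.

## Pipeline stages and numerical choices

1. **Slice selection (auto mode).** Each slice is scored by the summed
   intensity of bright pixels (one stack-wide Otsu threshold) in the two
   ventral-lateral quadrants outside the provisional cord. The provisional
   cord is the Otsu component nearest the image center *of the rostral-most
   slice*, dilated by 2 px: on DRG-bearing slices the DRG touches the cord
   and would merge with that slice's own component, while the rostral slice
   is cord-only by the method's premise. The maximal contiguous run of
   slices scoring above 1.25× the minimum slice score is the DRG run; the
   two slices rostral to it become the references. A slice must also score
   above an absolute floor (20 threshold-equivalents) so isolated noise
   pixels cannot seed a run on a cord-only stack. A single shared threshold
   is used across slices because per-slice Otsu thresholds can flip a
   tissue class sitting exactly at the threshold in and out between
   otherwise identical noiseless slices.
2. **Alignment.** Every slice is registered to the first reference slice by
   the integer dorsal-ventral shift (±10 px search) maximizing binary
   overlap of provisional cord components; ties break toward zero shift. A
   winner at the search boundary aborts the run. Shifts are integer only:
   sub-pixel interpolation would destroy pixel-count quantization.
3. **Reference averaging.** Arithmetic mean of the two reference slices,
   without intensity normalization between them. Only proximal (rostral)
   slices are used, never distal ones — averaging across the > 1 mm span to
   the distal side blurs the cord boundary and degrades edge detection.
4. **Edge detection.** 3 × 3 smoothed-gradient (Sobel) magnitude,
   thresholded at 4× the mean gradient magnitude (configurable). Among the
   resulting edge components, the one whose hole-filling encloses the
   centroid of the central bright blob with the smallest filled area (the
   innermost enclosing contour) is the cord edge. A 3 × 3 morphological
   closing, which bridges ≤ 1 px gaps, is applied only if the raw edge map
   yields no enclosing contour: applied unconditionally it can weld the
   cord contour to nearby residual-fat contours and select their union. No
   closed contour after closing is a hard error — masking is undefined.
5. **Mask, MIP, subtraction.** The closed outline is hole-filled into the
   cord mask (edge pixels included; area must fall in 200–3000 px at the
   default geometry), the DRG slices are max-projected, and the mask is
   zeroed in the MIP.
6. **Delineation.** The original final step was manual, guided only by the
   DRG's higher signal intensity. Auto mode formalizes that criterion:
   threshold = 1.10 × the mean MIP intensity inside the cord mask;
   suprathreshold pixels outside the mask are grouped by 8-connectivity;
   per side, the component overlapping the ventral-lateral quadrant the
   most is selected; components under 5 px are rejected, over 200 px
   flagged. `manual_roi` mode applies the same threshold inside supplied
   per-side rectangles, mirroring the original rectangle-ROI workflow. An
   absent DRG on a side is a reported outcome, not an error.
7. **Measurement.** CSA = pixel count × pixel area, one record per side.
   Left and right DRGs are separate measurement units throughout. The CSA
   is read as the pixel sum of the MIP delineation (the maximal axial
   cross-section under projection); a per-slice largest-section reading
   would be an alternative interpretation and is not implemented.

The pipeline is deterministic given a stack and configuration.

## Phantom generator

Anatomy is analytic: the cord is an elliptic cylinder (semi-axes
1.1 × 1.4 mm), each DRG an ellipsoid placed tangent to the cord boundary
along a ray 35° ventral of lateral, with rostral-caudal semi-axis 0.45 mm so
it intersects three 0.29 mm slices with two cord-only slices rostral.
Rasterization uses the pixel-center rule (a pixel belongs to a structure iff
its center lies inside the analytic boundary), which makes expected pixel
counts exactly computable and gives every recovery test an independent
oracle: any rasterization of a convex region differs from its analytic area
by at most the boundary perimeter in pixels, which is the tolerance the
noiseless tests assert.

Intensities are arbitrary units with the contrast ordering the acquisition
produces: background 100, residual fat 135 (900 before a 0.85 fat-saturation
suppression factor), cord 400, DRG 650, Rician noise σ = 40 (cord SNR 10).
Rician noise is generated as the magnitude of complex Gaussian noise, the
correct magnitude-MRI model; at SNR > 5 its mean is within 2% of nominal,
so high-SNR closed-form checks remain valid. The fat rim is offset 0.45 mm
from the cord surface (epidural fat surrounds the dural sac, not the cord),
which also keeps the cord contour separable from the rim contours.

Repositioning between test and retest scans is modeled as a rigid integer
dorsal-ventral shift (±3 px) plus a global intensity scale (0.9–1.1) with
fresh noise; true pixel counts then differ only through re-rasterization.

**Cohorts.** Group trajectories are piecewise-linear in age: wild-type flat
at 0.28 mm²; untreated Fabry (and its vehicle group) already enlarged at
week 8 (0.30 mm²), rising linearly to 0.35 mm² at week 24; the gene-therapy
group starts at 0.30 mm² and tracks wild-type from week 12. Each animal
carries a persistent log-normal scale (between-animal CV 0.12) and each scan
a log-normal deviation (within-animal CV 0.06), both mean-1. The CVs are
calibrated so that (a) scan-to-scan variation is in the range the
test-retest analysis exhibits and (b) the pooled untreated-Fabry vs
wild-type comparison (n = 8 vs 5, per-animal means) becomes significant
around week 16 in a typical cohort — the detection pattern the trajectories
encode. Per-scan DRG semi-axes are solved by an analytic initialization
(ellipse area = target CSA) refined by bisection on the rasterized pixel
count, targeting `round(target / pixel_area)` pixels: the pure analytic
solve leaves a deterministic, size-dependent rasterization error (up to
−2.3 px near 0.35 mm²) that is identical for every animal of a given size
and would bias group means rather than average out; the count-calibrated
solve removes that bias and makes zero-CV cohorts exactly equal-truth.

**What the phantom does not model.** Bloch-equation signal formation, coil
sensitivity profiles (B1 inhomogeneity of the surface coil), respiratory
motion, vertebrae and nerve roots, partial-volume intensity blending at
structure boundaries (pixels are all-or-nothing), and intra-structure
texture. Passing recovery tests therefore demonstrates the pipeline's
correctness on geometrically faithful, noise-realistic inputs — not its
robustness to the full variability of in-vivo scans, where the final
delineation was a manual judgement.

## Statistics

* **ICC** is the one-way random-effects, single-measure form: with n units
  and k = 2 measurements, `MSB` from the between-unit sum of squares
  (df = n − 1), `MSW` from the within-unit sum (df = n(k − 1)),
  ICC = (MSB − MSW)/(MSB + (k − 1)MSW). Zero total variance returns an
  explicit "undefined" flag rather than a number. Two-way forms and ICC
  confidence intervals are out of scope.
* **Bland–Altman**: differences are test − retest; bias is their mean; the
  SD uses the n − 1 denominator; limits of agreement are bias ± 1.96 × SD
  (normal quantile, not a t-quantile) — the combination that reproduces the
  reference table's printed summary row exactly.
* **Relative difference** is computed on integer pixel counts, not rounded
  CSA values: 100 × (test_px − retest_px)/((test_px + retest_px)/2). This
  definition is inferred — it is the only one that reproduces all ten
  published per-DRG values exactly (e.g. 19.355 = 9/46.5 × 100).
* **Group comparison**: two-sided pooled-variance (Student) t-test, Welch
  behind a flag; degenerate all-equal input returns p = 1 with a flag. The
  closed testing procedure tests the a-priori endpoint week first and steps
  backward in time only while p < α, stopping at the first failure; the
  earliest significant week is the start of the unbroken run ending at the
  endpoint. No additional multiplicity correction is applied beyond this
  gate. A scan-all-weeks variant is deliberately not the default. By
  default the two DRGs of an animal are averaged to one observation per
  animal per week; `per_drg=True` treats them as independent, which
  overstates n and is offered for sensitivity analysis only.
* **Histology positivity** is 100 × positive pixels / total analyzed
  pixels.

Treating left and right DRGs of one animal as independent units in the
test-retest analysis (n = 10) follows the reference table's layout; the
within-animal dependence it ignores is a known caveat.

## Problem sizes in the test suite

The suite exercises full-frame 192 × 256 × 5 stacks; the stochastic
recovery property uses 50 noisy phantoms, the alignment property 100, the
type-I-error property 1000 truth-only cohort replicates (no rendering), and
oracle-equivalence properties 100 random instances each — sizes at which
the Monte-Carlo bands in the assertions are meaningful while the whole
suite runs in well under a minute.

## Known limitations

* The filled cord mask includes the detected edge band, so it overshoots
  the analytic cord by roughly one pixel ring and clips DRG pixels near the
  tangency; measured counts run 2–4 px below truth. This is within the
  partial-volume band the method itself is subject to, and is the reason
  recovery is asserted against perimeter-scaled tolerances rather than
  exact equality.
* Auto slice selection assumes the rostral-most slice is cord-only; stacks
  whose DRG reaches the rostral boundary are rejected rather than handled.
* The delineation threshold (1.10 × cord mean) presumes the DRG is the
  brightest extra-cord structure; confounds with similar intensity (nerve
  roots, vessels) would be delineated indistinguishably, as they were in
  the manual workflow.
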