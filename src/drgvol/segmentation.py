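"""Spinal-cord-referenced DRG delineation and CSA measurement.

The pipeline exploits the fact that in the mouse there is no intrinsic
contrast between the DRG and the spinal cord: the cord outline is instead
taken from the two adjacent cord-only slices on the rostral (proximal) side
of the DRG, where the cord's size and shape are still the same, and that
outline is used to cut the cord out of a maximum intensity projection (MIP)
of the DRG-bearing slices.  Stages:

1. select the DRG-bearing slices and their two rostral reference slices;
2. align all slices to the first reference slice by integer dorsal-ventral
   shifts of the provisional cord component;
3. average the two reference slices into a cord-only image;
4. detect the cord edge on the averaged image with a smoothed-gradient
   (3x3 Sobel) operator;
5. fill the closed edge into a cord mask;
6. maximum-intensity-project the DRG slices;
7. zero the cord mask in the MIP;
8. delineate the DRG on each side of the remaining image and count pixels.

The study performed the final delineation manually, guided only by the
DRG's higher signal intensity; auto mode formalizes that criterion as a
relative intensity threshold (1.10x the cord mean on the MIP) followed by
selection of the connected component adjacent to the cord's ventral-lateral
quadrant.  ``manual_roi`` mode restricts the same thresholding to supplied
per-side rectangles, mirroring the original rectangle-ROI workflow.

Slice indices are 0-based internally; user-facing logs report them 1-based
to match the usual console numbering of axial slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .imaging import CSARecord, SliceStack, VoxelGeometry

__all__ = [
    "SliceSelection",
    "CordOutline",
    "CordMask",
    "DRGDelineation",
    "PipelineError",
    "select_drg_slices",
    "align_dorsoventral",
    "average_reference",
    "detect_cord_edge",
    "fill_cord",
    "project_max",
    "mask_cord",
    "delineate_drg",
    "measure_csa",
    "run_pipeline",
]

#: anatomically plausible cord-mask area, in pixels, at the default geometry
CORD_AREA_BOUNDS_PX = (200, 3000)


class PipelineError(RuntimeError):
    """A pipeline stage could not produce a valid result."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class SliceSelection:
    """Two cord-only reference slices rostral to >=1 contiguous DRG slices."""

    reference_slices: tuple[int, int]
    drg_slices: tuple[int, ...]

    def __post_init__(self) -> None:
        ref, drg = self.reference_slices, self.drg_slices
        if len(ref) != 2 or len(drg) < 1:
            raise ValueError("need exactly 2 reference and >= 1 DRG slices")
        if sorted(drg) != list(range(min(drg), max(drg) + 1)):
            raise ValueError("DRG slices must be contiguous")
        if set(ref) & set(drg):
            raise ValueError("reference and DRG slices must be disjoint")
        if sorted(ref) != [min(drg) - 2, min(drg) - 1]:
            raise ValueError(
                "reference slices must be the two rostral neighbors of the DRG run"
            )

    def validate_against(self, n_slices: int) -> None:
        if min(self.reference_slices) < 0 or max(self.drg_slices) >= n_slices:
            raise ValueError("slice selection exceeds the stack")


@dataclass
class CordOutline:
    edge_pixels: set[tuple[int, int]]  # (dv, lr)
    closed: bool


@dataclass
class CordMask:
    mask: np.ndarray  # bool (n_dv, n_lr)

    def __post_init__(self) -> None:
        m = self.mask
        lab, n = label(m, connectivity=2, return_num=True)
        if n != 1:
            raise ValueError(f"cord mask must be one connected component, got {n}")
        if ndimage.binary_fill_holes(m).sum() != m.sum():
            raise ValueError("cord mask must have no holes")
        lo, hi = CORD_AREA_BOUNDS_PX
        if not lo <= m.sum() <= hi:
            raise ValueError(
                f"cord mask area {int(m.sum())} px outside plausible bounds {lo}-{hi}"
            )

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        dv, lr = np.nonzero(self.mask)
        return float(dv.mean()), float(lr.mean())


@dataclass
class DRGDelineation:
    """Per-side DRG pixel sets on the cord-masked MIP."""

    pixels: dict[str, set[tuple[int, int]]]  # side -> {(dv, lr)}
    delineation_mode: str = "auto"
    flags: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Provisional cord (shared by slice selection and alignment)
# ---------------------------------------------------------------------------

def _provisional_cord(image: np.ndarray) -> np.ndarray:
    """Otsu-thresholded connected component closest to the image center.

    This is deliberately crude: it only needs to localize the cord well
    enough to score quadrants and register slices; the definitive cord
    boundary comes from edge detection on the averaged reference image.
    """
    if image.max() <= image.min():
        return np.zeros(image.shape, dtype=bool)
    binary = image > threshold_otsu(image)
    lab, n = label(binary, connectivity=2, return_num=True)
    if n == 0:
        return np.zeros(image.shape, dtype=bool)
    center = np.array(image.shape) / 2.0
    # prefer the component nearest the image center; break ties by size
    best, best_key = 0, (np.inf, 0.0)
    for p in regionprops(lab):
        d = float(np.hypot(*(np.array(p.centroid) - center)))
        key = (d, -float(p.area))
        if key < best_key:
            best, best_key = p.label, key
    return lab == best


def _quadrant_score(image: np.ndarray, cord: np.ndarray, threshold: float) -> float:
    """Summed intensity of suprathreshold pixels in the two ventral-lateral
    quadrants outside the provisional cord region.

    ``cord`` is the (dilated) provisional cord of the rostral-most slice:
    on DRG-bearing slices the DRG touches the cord, so the slice's own
    central Otsu component would swallow the DRG; the rostral slice is
    cord-only by the pipeline's own premise (two reference slices rostral
    to the DRG) and provides an uncontaminated cord estimate.
    ``threshold`` is shared across slices (stack-wide Otsu) so that a
    tissue class sitting exactly at a per-slice threshold cannot flip in
    and out of the score between slices.
    """
    if not cord.any() or image.max() <= image.min():
        return 0.0
    binary = image > threshold
    dv, lr = np.nonzero(cord)
    cdv, clr = dv.mean(), lr.mean()
    rows = np.arange(image.shape[0])[:, None]
    cols = np.arange(image.shape[1])[None, :]
    ventral = rows > cdv  # dv axis runs dorsal -> ventral
    lateral = (cols < clr) | (cols > clr)  # both sides, excluding the midline col
    region = ventral & lateral & binary & ~cord
    return float(image[region].sum())


# ---------------------------------------------------------------------------
# Stage 1: slice selection
# ---------------------------------------------------------------------------

def select_drg_slices(
    stack: SliceStack,
    mode: str = "auto",
    config_selection: SliceSelection | None = None,
    ratio: float = 1.25,
    abs_floor_px: float = 20.0,
) -> SliceSelection:
    """Identify the DRG-bearing slices and their rostral reference slices.

    Auto mode scores each slice by the summed intensity of bright
    (Otsu-suprathreshold) pixels in the two ventral-lateral quadrants
    outside the (dilated) provisional cord of the rostral-most slice,
    then takes the maximal contiguous run of slices whose score exceeds
    ``ratio`` times the minimum slice score.  A slice must additionally
    score above ``abs_floor_px`` suprathreshold-pixel-equivalents
    (``abs_floor_px`` x the stack-wide Otsu threshold) so that isolated
    noise pixels on cord-only stacks cannot seed a spurious run.  The two
    slices rostral to the run become the reference slices.
    """
    if mode == "config":
        if config_selection is None:
            raise ValueError("config mode requires a selection")
        config_selection.validate_against(stack.geometry.n_slices)
        return config_selection
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    ref_cord = ndimage.binary_dilation(
        _provisional_cord(stack.data[0]), np.ones((3, 3)), iterations=2
    )
    if stack.data.max() > stack.data.min():
        global_thr = float(threshold_otsu(stack.data))
        abs_floor = abs_floor_px * global_thr
    else:
        global_thr, abs_floor = np.inf, np.inf
    scores = np.array(
        [_quadrant_score(sl, ref_cord, global_thr) for sl in stack.data]
    )
    floor = max(ratio * scores.min(), abs_floor)
    above = scores > floor
    if not above.any():
        raise PipelineError("select", "no DRG slice run found (signal too flat)")

    # maximal contiguous run of above-floor slices
    runs: list[tuple[int, int]] = []
    k = 0
    n = len(above)
    while k < n:
        if above[k]:
            j = k
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((k, j))
            k = j + 1
        else:
            k += 1
    start, stop = max(runs, key=lambda r: r[1] - r[0])
    if start < 2:
        raise PipelineError(
            "select", "DRG run touches the rostral stack boundary; "
            "fewer than 2 reference slices available"
        )
    return SliceSelection(
        reference_slices=(start - 2, start - 1),
        drg_slices=tuple(range(start, stop + 1)),
    )


# ---------------------------------------------------------------------------
# Stage 2: alignment
# ---------------------------------------------------------------------------

def align_dorsoventral(
    stack: SliceStack,
    selection: SliceSelection,
    max_shift: int = 10,
) -> tuple[SliceStack, list[int]]:
    """Register every slice to the first reference slice by an integer
    dorsal-ventral shift of its provisional cord component.

    The shift maximizing binary overlap with the reference cord is chosen,
    ties broken toward zero.  A winning shift at the search boundary
    signals gross misalignment and raises.
    """
    selection.validate_against(stack.geometry.n_slices)
    ref = _provisional_cord(stack.data[selection.reference_slices[0]])
    shifts: list[int] = []
    aligned = np.empty_like(stack.data)
    candidates = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s))
    for k in range(stack.geometry.n_slices):
        cord = _provisional_cord(stack.data[k])
        best_s, best_ov = 0, -1
        for s in candidates:  # ordered by |s|: first maximum wins -> ties toward 0
            ov = int((np.roll(cord, s, axis=0) & ref).sum())
            if ov > best_ov:
                best_s, best_ov = s, ov
        if abs(best_s) == max_shift:
            raise PipelineError(
                "align", f"slice {k + 1}: optimal shift at search boundary "
                f"(+/-{max_shift} px); gross misalignment"
            )
        shifts.append(best_s)
        aligned[k] = np.roll(stack.data[k], best_s, axis=0)
    return SliceStack(aligned, stack.geometry), shifts


# ---------------------------------------------------------------------------
# Stages 3-7
# ---------------------------------------------------------------------------

def average_reference(stack: SliceStack, selection: SliceSelection) -> np.ndarray:
    """Pixelwise arithmetic mean of the two reference slices."""
    a, b = selection.reference_slices
    return (stack.data[a] + stack.data[b]) / 2.0


def detect_cord_edge(
    reference_image: np.ndarray,
    threshold: float | str = "auto",
) -> CordOutline:
    """Detect the spinal cord edge on the averaged reference image.

    A 3x3 smoothed-gradient (Sobel) magnitude is thresholded (auto
    threshold = 4x the mean gradient magnitude), gaps of <= 1 px are
    closed morphologically (3x3 closing), and the edge component
    enclosing the centroid of the central bright blob is returned.

    Raises PipelineError if no closed contour encloses the cord, in which
    case masking is undefined and the pipeline must stop.
    """
    img = np.asarray(reference_image, dtype=float)
    gx = ndimage.sobel(img, axis=0, mode="nearest")
    gy = ndimage.sobel(img, axis=1, mode="nearest")
    mag = np.hypot(gx, gy)
    thr = 4.0 * mag.mean() if threshold == "auto" else float(threshold)
    if thr <= 0 or not (mag > thr).any():
        raise PipelineError("edge", "no gradient above threshold (flat image)")
    raw = mag > thr

    blob = _provisional_cord(img)
    if not blob.any():
        raise PipelineError("edge", "no central bright blob to enclose")
    cdv, clr = (int(round(v)) for v in np.mean(np.nonzero(blob), axis=1))

    def innermost_enclosing(edges: np.ndarray) -> np.ndarray | None:
        lab, n = label(edges, connectivity=2, return_num=True)
        best, best_area = None, np.inf
        for i in range(1, n + 1):
            comp = lab == i
            filled = ndimage.binary_fill_holes(comp)
            if filled.sum() <= comp.sum():  # open curve: nothing enclosed
                continue
            if filled[cdv, clr] and filled.sum() < best_area:
                best, best_area = comp, filled.sum()
        return best

    # search the raw edge map first; the 3x3 closing (bridges <= 1 px
    # gaps) is a fallback for broken contours only, because it can also
    # weld a clean cord contour to nearby fat-rim contours
    best_pixels = innermost_enclosing(raw)
    if best_pixels is None:
        best_pixels = innermost_enclosing(
            ndimage.binary_closing(raw, structure=np.ones((3, 3)))
        )
    if best_pixels is None:
        raise PipelineError(
            "edge", "no closed contour encloses the cord after gap closing"
        )
    pts = {(int(a), int(b)) for a, b in zip(*np.nonzero(best_pixels))}
    return CordOutline(edge_pixels=pts, closed=True)


def fill_cord(outline: CordOutline, image_shape: tuple[int, int]) -> CordMask:
    """Fill a closed cord outline into a mask (edge pixels included)."""
    if not outline.closed:
        raise PipelineError("fill", "cord outline is not closed")
    canvas = np.zeros(image_shape, dtype=bool)
    for dv, lr in outline.edge_pixels:
        canvas[dv, lr] = True
    filled = ndimage.binary_fill_holes(canvas)
    if filled.sum() <= canvas.sum():
        raise PipelineError("fill", "outline encloses no interior")
    try:
        return CordMask(filled)
    except ValueError as e:
        raise PipelineError("fill", str(e)) from e


def project_max(stack: SliceStack, selection: SliceSelection) -> np.ndarray:
    """Maximum intensity projection over the DRG-bearing slices."""
    return stack.data[list(selection.drg_slices)].max(axis=0)


def mask_cord(mip: np.ndarray, mask: CordMask) -> np.ndarray:
    """Zero the cord-mask pixels of the MIP; everything else unchanged."""
    if mip.shape != mask.mask.shape:
        raise ValueError("MIP and cord mask shapes disagree")
    out = mip.copy()
    out[mask.mask] = 0.0
    return out


# ---------------------------------------------------------------------------
# Stage 8: delineation + measurement
# ---------------------------------------------------------------------------

def delineate_drg(
    masked_mip: np.ndarray,
    mask: CordMask,
    cord_mean: float,
    rel_threshold: float = 1.10,
    min_px: int = 5,
    max_px: int = 200,
    roi: dict[str, tuple[int, int, int, int]] | None = None,
) -> DRGDelineation:
    """Delineate the left and right DRG on the cord-masked MIP.

    ``cord_mean`` is the mean MIP intensity inside the cord mask *before*
    masking; the intensity criterion is ``rel_threshold * cord_mean``.
    In auto mode (``roi is None``) the suprathreshold pixels outside the
    cord are grouped by 8-connectivity and, per side, the component with
    the largest overlap with the ventral-lateral quadrant adjacent to the
    cord is selected.  Components below ``min_px`` are rejected; larger
    than ``max_px`` are kept but flagged.  In manual_roi mode the same
    thresholding is restricted to the supplied per-side rectangles
    ``(dv0, dv1, lr0, lr1)`` (half-open).

    An absent DRG on a side is a legal outcome: the side's pixel set is
    empty and a flag records it.
    """
    thr = rel_threshold * cord_mean
    above = (masked_mip > thr) & ~mask.mask
    cdv, clr = mask.centroid
    rows = np.arange(masked_mip.shape[0])[:, None]
    cols = np.arange(masked_mip.shape[1])[None, :]
    mode = "auto" if roi is None else "manual_roi"

    pixels: dict[str, set[tuple[int, int]]] = {}
    flags: dict[str, list[str]] = {"left": [], "right": []}
    for side in ("left", "right"):
        lateral = cols < clr if side == "left" else cols > clr
        if roi is not None:
            if side not in roi:
                pixels[side] = set()
                flags[side].append("no ROI supplied")
                continue
            dv0, dv1, lr0, lr1 = roi[side]
            window = np.zeros_like(above)
            window[dv0:dv1, lr0:lr1] = True
            sel = above & window
            if sel.sum() < min_px:
                pixels[side] = set()
                flags[side].append("no component found")
                continue
            pixels[side] = {(int(a), int(b)) for a, b in zip(*np.nonzero(sel))}
        else:
            quadrant = (rows > cdv) & lateral
            lab, n = label(above, connectivity=2, return_num=True)
            best, best_ov = None, 0
            for i in range(1, n + 1):
                comp = lab == i
                if comp.sum() < min_px:
                    continue
                ov = int((comp & quadrant).sum())
                if ov > best_ov:
                    best, best_ov = comp, ov
            if best is None:
                pixels[side] = set()
                flags[side].append("no component found")
                continue
            pixels[side] = {(int(a), int(b)) for a, b in zip(*np.nonzero(best))}
        if len(pixels[side]) > max_px:
            flags[side].append(f"component larger than max_px={max_px}")
    return DRGDelineation(pixels=pixels, delineation_mode=mode, flags=flags)


def measure_csa(
    delineation: DRGDelineation,
    geometry: VoxelGeometry,
    animal_id: str = "unknown",
    timepoint: float = 0.0,
    group: str = "unknown",
) -> list[CSARecord]:
    """Sum delineated pixels into a CSA record per present side."""
    records = []
    for side in ("left", "right"):
        px = delineation.pixels.get(side, set())
        if not px:
            continue
        records.append(
            CSARecord.from_pixels(animal_id, side, timepoint, group, len(px), geometry)
        )
    return records


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def run_pipeline(
    stack: SliceStack,
    selection_mode: str = "auto",
    config_selection: SliceSelection | None = None,
    edge_threshold: float | str = "auto",
    rel_threshold: float = 1.10,
    min_px: int = 5,
    max_px: int = 200,
    roi: dict[str, tuple[int, int, int, int]] | None = None,
    animal_id: str = "unknown",
    timepoint: float = 0.0,
    group: str = "unknown",
) -> tuple[list[CSARecord], dict]:
    """Compose the full delineation pipeline on one stack.

    Returns the per-side CSA records and a dict of intermediate artifacts
    (selection, shifts, reference image, outline, mask, MIP, masked MIP)
    plus a log of parameters for audit.  Stage errors propagate as
    PipelineError with the stage name attached.  A stack without DRG
    slices yields an empty record list rather than an error.
    """
    log: dict = {
        "parameters": {
            "selection_mode": selection_mode,
            "edge_threshold": edge_threshold,
            "rel_threshold": rel_threshold,
            "min_px": min_px,
            "max_px": max_px,
        }
    }
    artifacts: dict = {"log": log}
    try:
        selection = select_drg_slices(stack, selection_mode, config_selection)
    except PipelineError as e:
        if "no DRG slice run" in str(e):
            log["note"] = "no DRG slices"
            return [], artifacts
        raise
    artifacts["selection"] = selection
    log["reference_slices_1based"] = [s + 1 for s in selection.reference_slices]
    log["drg_slices_1based"] = [s + 1 for s in selection.drg_slices]

    aligned, shifts = align_dorsoventral(stack, selection)
    artifacts["shifts"] = shifts
    log["dv_shifts_px"] = shifts

    reference = average_reference(aligned, selection)
    artifacts["reference_image"] = reference
    outline = detect_cord_edge(reference, threshold=edge_threshold)
    artifacts["outline"] = outline
    mask = fill_cord(outline, reference.shape)
    artifacts["cord_mask"] = mask
    log["cord_area_px"] = mask.area_px

    mip = project_max(aligned, selection)
    artifacts["mip"] = mip
    cord_mean = float(mip[mask.mask].mean())
    log["cord_mean_mip"] = cord_mean
    masked = mask_cord(mip, mask)
    artifacts["masked_mip"] = masked

    delineation = delineate_drg(
        masked, mask, cord_mean,
        rel_threshold=rel_threshold, min_px=min_px, max_px=max_px, roi=roi,
    )
    artifacts["delineation"] = delineation
    log["flags"] = delineation.flags

    records = measure_csa(
        delineation, stack.geometry,
        animal_id=animal_id, timepoint=timepoint, group=group,
    )
    return records, artifacts
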