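"""Synthetic axial MRI phantoms of the lumbar spinal cord with attached DRGs.

The generator stands in for the study animals: it renders T2-weighted-like
axial slice stacks in which a bright dorsal root ganglion (DRG) ellipsoid is
attached to the ventral-lateral surface of the spinal cord, as it is in the
mouse (unlike the foraminal position in humans).  Anatomy is modeled with
analytic ellipses/ellipsoids rasterized by the pixel-center rule, which gives
an exact, independent oracle for expected pixel counts; Rician noise (the
magnitude of complex Gaussian noise) models magnitude-MRI noise; repositioning
between test and retest scans is modeled as a rigid integer dorsal-ventral
shift plus a global intensity scale.

Default intensities are arbitrary units chosen to emulate the acquisition's
contrast ordering (DRG > cord > residual fat > background) at a cord SNR of
10: background 100, cord 400, DRG 650, fat 900 before a 0.85 fat-saturation
suppression factor, noise sigma 40.

Coordinates: in-plane positions are in mm with the dv coordinate of array row
``r`` at ``(r + 0.5) * pixel_width_dv`` and similarly for lr; slice ``k`` is
centered at ``(k + 0.5) * slice_thickness`` along the rostral-caudal axis.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import DEFAULT_GEOMETRY, CSARecord, SliceStack, VoxelGeometry

__all__ = [
    "DRGSpec",
    "FatRing",
    "PhantomSpec",
    "PhantomTruth",
    "GroupSpec",
    "CohortSpec",
    "default_phantom_spec",
    "default_cohort_spec",
    "drg_semi_axis_for_area",
    "spec_for_targets",
    "render_phantom",
    "render_test_retest",
    "render_cohort",
    "sample_cohort_truth",
]

#: 5-slice analysis window with the study's in-plane geometry and slice
#: thickness: two cord-only reference slices rostral to a DRG spanning the
#: remaining three (2 * a_rc = 0.9 mm over 0.29 mm slices).
ANALYSIS_GEOMETRY = DEFAULT_GEOMETRY.with_slices(5)


@dataclass(frozen=True)
class DRGSpec:
    """One DRG: an ellipsoid attached to the cord's ventral-lateral surface.

    ``semi_axes_mm`` is (a_dv, a_lr, a_rc); the rostral-caudal extent
    2*a_rc defaults to 0.9 mm so the DRG spans 3 of the 5 analysis
    slices.  ``center_offset_mm`` optionally displaces the DRG center
    relative to the cord-surface attachment point; ``None`` places the
    ellipsoid tangent to the cord boundary along the attachment ray.
    """

    present: bool = True
    semi_axes_mm: tuple[float, float, float] = (0.2985, 0.2985, 0.45)
    center_offset_mm: tuple[float, float] | None = None
    intensity: float = 650.0
    #: angle of the attachment ray, measured from the lateral (+lr)
    #: direction toward ventral (+dv), in degrees
    attach_angle_deg: float = 35.0


@dataclass(frozen=True)
class FatRing:
    """Residual peri-cord fat rim after spectral fat saturation.

    The rim is offset from the cord surface by ``gap_mm`` of
    CSF/connective tissue, as epidural fat surrounds the dural sac
    rather than the cord itself.
    """

    thickness_mm: float = 0.35
    gap_mm: float = 0.45
    intensity: float = 900.0
    suppression_factor: float = 0.85  # fraction of fat signal removed

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression_factor must lie in [0, 1]")

    @property
    def rendered_intensity(self) -> float:
        return self.intensity * (1.0 - self.suppression_factor)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scan."""

    geometry: VoxelGeometry = ANALYSIS_GEOMETRY
    cord_center_mm: tuple[float, float] | None = None  # (dv, lr); None = FOV center
    cord_semi_axes_mm: tuple[float, float] = (1.1, 1.4)  # (a_dv, a_lr)
    cord_intensity: float = 400.0
    background_intensity: float = 100.0
    drg_left: DRGSpec = field(default_factory=DRGSpec)
    drg_right: DRGSpec = field(default_factory=DRGSpec)
    fat_ring: FatRing = field(default_factory=FatRing)
    noise_sigma: float = 40.0
    #: 0-based slice index of the DRG ellipsoid center along rostral-caudal;
    #: None = n_slices - 2 (three caudal slices covered, two rostral free)
    drg_center_slice: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for d in (self.drg_left, self.drg_right):
            if d.present and not (
                d.intensity > self.cord_intensity > self.background_intensity
            ):
                raise ValueError(
                    "intensity ordering violated: need DRG > cord > background"
                )

    def resolved_cord_center(self) -> tuple[float, float]:
        if self.cord_center_mm is not None:
            return self.cord_center_mm
        g = self.geometry
        return (
            g.n_dv / 2.0 * g.pixel_width_dv_mm,
            g.n_lr / 2.0 * g.pixel_width_lr_mm,
        )

    def resolved_center_slice(self) -> float:
        if self.drg_center_slice is not None:
            return self.drg_center_slice
        return self.geometry.n_slices - 2.0


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a rendered phantom."""

    true_pixel_count: dict[str, int]  # per side
    true_csa: dict[str, float]  # mm², = count * pixel_area
    cord_mask: np.ndarray  # bool (n_dv, n_lr), in the rendered frame
    applied_shift: list[int]  # dv shift in px per slice
    seed: int


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The default two-sided analysis phantom (dataclass replace shortcut)."""
    return dataclasses.replace(PhantomSpec(), **overrides) if overrides else PhantomSpec()


def drg_semi_axis_for_area(target_csa_mm2: float, aspect: float = 1.0) -> tuple[float, float]:
    """In-plane semi-axes (a_dv, a_lr) with a_lr = aspect * a_dv whose analytic
    ellipse area pi * a_dv * a_lr equals ``target_csa_mm2``."""
    a_dv = math.sqrt(target_csa_mm2 / (math.pi * aspect))
    return (a_dv, aspect * a_dv)


# ---------------------------------------------------------------------------
# Rasterization primitives (pixel-center rule)
# ---------------------------------------------------------------------------

def _pixel_centers(geometry: VoxelGeometry):
    dv = (np.arange(geometry.n_dv) + 0.5) * geometry.pixel_width_dv_mm
    lr = (np.arange(geometry.n_lr) + 0.5) * geometry.pixel_width_lr_mm
    return dv[:, None], lr[None, :]


def rasterize_ellipse(
    geometry: VoxelGeometry,
    center_dv: float,
    center_lr: float,
    a_dv: float,
    a_lr: float,
) -> np.ndarray:
    """Boolean mask of pixels whose center lies inside the ellipse."""
    dv, lr = _pixel_centers(geometry)
    return ((dv - center_dv) / a_dv) ** 2 + ((lr - center_lr) / a_lr) ** 2 <= 1.0


def _ray_radius(d_dv: float, d_lr: float, a_dv: float, a_lr: float) -> float:
    """Distance from an ellipse center to its boundary along unit ray d."""
    return 1.0 / math.sqrt((d_dv / a_dv) ** 2 + (d_lr / a_lr) ** 2)


def _drg_center(spec: PhantomSpec, side: str, shift_dv_mm: float = 0.0):
    """In-plane DRG center (dv, lr) in mm for one side, after a rigid shift."""
    d = spec.drg_left if side == "left" else spec.drg_right
    cord_dv, cord_lr = spec.resolved_cord_center()
    cord_dv += shift_dv_mm
    th = math.radians(d.attach_angle_deg)
    sign = -1.0 if side == "left" else 1.0
    ray = (math.sin(th), sign * math.cos(th))  # (dv, lr), ventral-lateral
    t_cord = _ray_radius(ray[0], ray[1], *spec.cord_semi_axes_mm)
    bdry = (cord_dv + t_cord * ray[0], cord_lr + t_cord * ray[1])
    if d.center_offset_mm is not None:
        return (bdry[0] + d.center_offset_mm[0], bdry[1] + d.center_offset_mm[1])
    a_dv, a_lr, _ = d.semi_axes_mm
    t_drg = _ray_radius(ray[0], ray[1], a_dv, a_lr)
    return (bdry[0] + t_drg * ray[0], bdry[1] + t_drg * ray[1])


def _check_in_frame(
    geometry: VoxelGeometry, center_dv, center_lr, a_dv, a_lr, margin_px: float = 1.0
) -> None:
    if (
        center_dv - a_dv < margin_px * geometry.pixel_width_dv_mm
        or center_dv + a_dv > (geometry.n_dv - margin_px) * geometry.pixel_width_dv_mm
        or center_lr - a_lr < margin_px * geometry.pixel_width_lr_mm
        or center_lr + a_lr > (geometry.n_lr - margin_px) * geometry.pixel_width_lr_mm
    ):
        raise ValueError("structure overlaps the image border")


def _slice_scales(spec: PhantomSpec, a_rc: float) -> np.ndarray:
    """Per-slice in-plane scale factor of the DRG ellipsoid cross-section
    (0 where the slice-center plane misses the ellipsoid)."""
    g = spec.geometry
    zc = (spec.resolved_center_slice() + 0.5) * g.slice_thickness_mm
    z = (np.arange(g.n_slices) + 0.5) * g.slice_thickness_mm
    u = (z - zc) / a_rc
    return np.sqrt(np.clip(1.0 - u * u, 0.0, None))


def _count_drg_pixels(
    geometry: VoxelGeometry,
    center_dv: float,
    center_lr: float,
    a_dv: float,
    a_lr: float,
    cord_center: tuple[float, float] | None = None,
    cord_semi_axes: tuple[float, float] | None = None,
) -> int:
    """Pixel-center count of an ellipse, optionally excluding cord pixels.

    Operates on the ellipse's bounding box only, so it is cheap enough to
    drive large Monte-Carlo cohorts.
    """
    pw_dv, pw_lr = geometry.pixel_width_dv_mm, geometry.pixel_width_lr_mm
    r0 = max(int((center_dv - a_dv) / pw_dv) - 1, 0)
    r1 = min(int((center_dv + a_dv) / pw_dv) + 2, geometry.n_dv)
    c0 = max(int((center_lr - a_lr) / pw_lr) - 1, 0)
    c1 = min(int((center_lr + a_lr) / pw_lr) + 2, geometry.n_lr)
    dv = (np.arange(r0, r1) + 0.5)[:, None] * pw_dv
    lr = (np.arange(c0, c1) + 0.5)[None, :] * pw_lr
    inside = ((dv - center_dv) / a_dv) ** 2 + ((lr - center_lr) / a_lr) ** 2 <= 1.0
    if cord_center is not None:
        in_cord = (
            ((dv - cord_center[0]) / cord_semi_axes[0]) ** 2
            + ((lr - cord_center[1]) / cord_semi_axes[1]) ** 2
            <= 1.0
        )
        inside &= ~in_cord
    return int(inside.sum())


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _rician(rng: np.random.Generator, noiseless: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return noiseless.copy()
    g1 = rng.normal(0.0, sigma, noiseless.shape)
    g2 = rng.normal(0.0, sigma, noiseless.shape)
    return np.sqrt((noiseless + g1) ** 2 + g2 ** 2)


def render_phantom(
    spec: PhantomSpec, dv_shift_px: int | list[int] = 0
) -> tuple[SliceStack, PhantomTruth]:
    """Render one scan and its ground truth.

    ``dv_shift_px`` shifts the whole anatomy in the dorsal-ventral
    direction by an integer number of pixels, either uniformly or per
    slice (list of length n_slices); per-slice shifts emulate an
    acquisition plane that is not perpendicular to the cord.  The truth
    (cord mask and DRG pixel counts) is reported in the frame of slice 0,
    which is where the alignment stage of the analysis pipeline brings
    every slice.

    The same seed always yields a bit-identical stack and truth.
    """
    g = spec.geometry
    if np.isscalar(dv_shift_px):
        shifts = [int(dv_shift_px)] * g.n_slices
    else:
        shifts = [int(s) for s in dv_shift_px]
        if len(shifts) != g.n_slices:
            raise ValueError("need one dv shift per slice")

    cord_dv0, cord_lr = spec.resolved_cord_center()
    ca_dv, ca_lr = spec.cord_semi_axes_mm
    fat = spec.fat_ring

    stack = np.empty(g.shape, dtype=float)
    sides = [s for s, d in (("left", spec.drg_left), ("right", spec.drg_right)) if d.present]
    scales = {
        s: _slice_scales(spec, (spec.drg_left if s == "left" else spec.drg_right).semi_axes_mm[2])
        for s in sides
    }

    for k in range(g.n_slices):
        shift_mm = shifts[k] * g.pixel_width_dv_mm
        cord_dv = cord_dv0 + shift_mm
        _check_in_frame(g, cord_dv, cord_lr, ca_dv, ca_lr, margin_px=5.0)
        img = np.full((g.n_dv, g.n_lr), spec.background_intensity)
        if fat.thickness_mm > 0 and fat.rendered_intensity > 0:
            outer = rasterize_ellipse(
                g, cord_dv, cord_lr,
                ca_dv + fat.gap_mm + fat.thickness_mm,
                ca_lr + fat.gap_mm + fat.thickness_mm,
            )
            inner = rasterize_ellipse(
                g, cord_dv, cord_lr, ca_dv + fat.gap_mm, ca_lr + fat.gap_mm
            )
            ring = outer & ~inner
            img[ring] = np.maximum(img[ring], fat.rendered_intensity)
        cord = rasterize_ellipse(g, cord_dv, cord_lr, ca_dv, ca_lr)
        img[cord] = spec.cord_intensity
        for side in sides:
            d = spec.drg_left if side == "left" else spec.drg_right
            f = scales[side][k]
            if f <= 0:
                continue
            a_dv, a_lr, _ = d.semi_axes_mm
            cdv, clr = _drg_center(spec, side, shift_mm)
            _check_in_frame(g, cdv, clr, f * a_dv, f * a_lr)
            ell = rasterize_ellipse(g, cdv, clr, f * a_dv, f * a_lr)
            img[ell] = np.maximum(img[ell], d.intensity)
        stack[k] = img

    rng = np.random.default_rng(spec.seed)
    stack = _rician(rng, stack, spec.noise_sigma)

    # truth in the frame of slice 0
    ref_shift_mm = shifts[0] * g.pixel_width_dv_mm
    cord_dv = cord_dv0 + ref_shift_mm
    cord_mask = rasterize_ellipse(g, cord_dv, cord_lr, ca_dv, ca_lr)
    counts: dict[str, int] = {}
    csas: dict[str, float] = {}
    for side in sides:
        d = spec.drg_left if side == "left" else spec.drg_right
        f_max = float(scales[side].max())
        if f_max <= 0:
            counts[side] = 0
        else:
            a_dv, a_lr, _ = d.semi_axes_mm
            cdv, clr = _drg_center(spec, side, ref_shift_mm)
            counts[side] = _count_drg_pixels(
                g, cdv, clr, f_max * a_dv, f_max * a_lr,
                cord_center=(cord_dv, cord_lr), cord_semi_axes=(ca_dv, ca_lr),
            )
        csas[side] = counts[side] * g.pixel_area_mm2

    truth = PhantomTruth(
        true_pixel_count=counts,
        true_csa=csas,
        cord_mask=cord_mask,
        applied_shift=shifts,
        seed=spec.seed,
    )
    return SliceStack(stack, g), truth


def render_test_retest(
    spec: PhantomSpec,
    jitter: dict | None = None,
    seed: int = 0,
) -> tuple[tuple[SliceStack, PhantomTruth], tuple[SliceStack, PhantomTruth]]:
    """Render the same anatomy twice with repositioning between scans.

    The retest scan re-renders the identical anatomy under a drawn rigid
    integer dv shift and a global intensity scale, with fresh noise.  The
    true pixel counts of the two scans differ only through partial-volume
    re-rasterization of the shifted ellipses.

    ``jitter`` keys (defaults): ``dv_shift_px`` inclusive integer range
    (-3, 3), ``intensity_scale`` uniform range (0.9, 1.1).
    """
    jitter = dict(jitter or {})
    lo, hi = jitter.get("dv_shift_px", (-3, 3))
    slo, shi = jitter.get("intensity_scale", (0.9, 1.1))
    rng = np.random.default_rng(seed)
    shift = int(rng.integers(lo, hi + 1))
    scale = float(rng.uniform(slo, shi))

    seed_a = int(rng.integers(0, 2**31 - 1))
    seed_b = int(rng.integers(0, 2**31 - 1))
    test = render_phantom(dataclasses.replace(spec, seed=seed_a))
    retest_spec = dataclasses.replace(
        spec,
        seed=seed_b,
        cord_intensity=spec.cord_intensity * scale,
        background_intensity=spec.background_intensity * scale,
        drg_left=dataclasses.replace(spec.drg_left, intensity=spec.drg_left.intensity * scale),
        drg_right=dataclasses.replace(spec.drg_right, intensity=spec.drg_right.intensity * scale),
        fat_ring=dataclasses.replace(spec.fat_ring, intensity=spec.fat_ring.intensity * scale),
        noise_sigma=spec.noise_sigma * scale,
    )
    retest = render_phantom(retest_spec, dv_shift_px=shift)
    return test, retest


# ---------------------------------------------------------------------------
# Longitudinal cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_animals: int
    mean_csa_by_week: dict[float, float]  # week -> mm²
    between_animal_cv: float = 0.12
    within_animal_cv: float = 0.06

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for cv in (self.between_animal_cv, self.within_animal_cv):
            if not 0.0 <= cv <= 0.5:
                raise ValueError("CVs must lie in [0, 0.5]")

    def mean_at(self, week: float) -> float:
        """Piecewise-linear interpolation of the group trajectory."""
        wk = sorted(self.mean_csa_by_week)
        return float(np.interp(week, wk, [self.mean_csa_by_week[w] for w in wk]))


@dataclass(frozen=True)
class CohortSpec:
    groups: list[GroupSpec]
    weeks: tuple[float, ...] = (8.0, 12.0, 16.0, 20.0, 24.0)
    base: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.weeks[1:], self.weeks)):
            raise ValueError("weeks must be strictly increasing")


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study-calibrated four-group longitudinal design.

    Wild-type DRG CSA is flat at 0.28 mm²; untreated Fabry DRGs are already
    enlarged at week 8 (0.30 mm²) and grow linearly to 0.35 mm² at week 24;
    the vehicle (null-vector) group follows the untreated trajectory; the
    gene-therapy group starts enlarged and tracks wild-type after week 8.
    Between-animal CV 0.18 and within-animal (scan-to-scan) CV 0.06 give a
    between/within SD ratio of 3, i.e. an analytic test-retest ICC of 0.9.
    """
    wt = {w: 0.28 for w in (8.0, 12.0, 16.0, 20.0, 24.0)}
    fabry = {8.0: 0.30, 12.0: 0.3125, 16.0: 0.325, 20.0: 0.3375, 24.0: 0.35}
    treated = {8.0: 0.30, 12.0: 0.28, 16.0: 0.28, 20.0: 0.28, 24.0: 0.28}
    return CohortSpec(
        groups=[
            GroupSpec("wildtype", 5, wt),
            GroupSpec("fabry", 3, fabry),
            GroupSpec("fabry_null", 5, fabry),
            GroupSpec("fabry_gla", 5, treated),
        ],
        base=dataclasses.replace(PhantomSpec(), seed=seed),
        seed=seed,
    )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative log-normal deviate with mean 1 and the given CV."""
    if cv == 0:
        return 1.0
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2)))


def _sample_scan_specs(cohort: CohortSpec):
    """Yield (group, animal_id, week, per-side target CSA, scan seed)."""
    rng = np.random.default_rng(cohort.seed)
    for group in cohort.groups:
        for i in range(group.n_animals):
            animal_id = f"{group.name}-{i + 1:02d}"
            animal_scale = _lognormal_factor(rng, group.between_animal_cv)
            for week in cohort.weeks:
                targets = {
                    side: group.mean_at(week)
                    * animal_scale
                    * _lognormal_factor(rng, group.within_animal_cv)
                    for side in ("left", "right")
                }
                scan_seed = int(rng.integers(0, 2**31 - 1))
                yield group, animal_id, week, targets, scan_seed


#: memoized semi-axis solves, keyed by (base spec, side, target pixel count)
_SOLVE_CACHE: dict = {}


def _noiseless_count(base: PhantomSpec, d: DRGSpec, side: str) -> int:
    """Truth pixel count of one DRG at its tangent placement (maximal
    in-plane cross-section), excluding cord pixels."""
    probe = dataclasses.replace(
        base, **{("drg_left" if side == "left" else "drg_right"): d}
    )
    a_dv, a_lr, _ = d.semi_axes_mm
    cdv, clr = _drg_center(probe, side)
    return _count_drg_pixels(
        base.geometry, cdv, clr, a_dv, a_lr,
        cord_center=base.resolved_cord_center(),
        cord_semi_axes=base.cord_semi_axes_mm,
    )


def spec_for_targets(
    base: PhantomSpec, targets: dict[str, float], seed: int
) -> PhantomSpec:
    """Solve the in-plane DRG semi-axes (isotropic scaling) so the
    rendered DRG carries the target CSA.

    The analytic solve (ellipse area = target) initializes the scale; a
    bisection on the rasterized pixel count then absorbs the grid
    quantization, targeting round(target / pixel_area) pixels.  Without
    this refinement the grid-locked rasterization error would be the
    same for every animal at a given size and would bias cohort means
    instead of averaging out.
    """
    area = base.geometry.pixel_area_mm2

    def scaled(d: DRGSpec, s: float) -> DRGSpec:
        a_dv0, a_lr0, a_rc = d.semi_axes_mm
        return dataclasses.replace(d, semi_axes_mm=(s * a_dv0, s * a_lr0, a_rc))

    def solve(d: DRGSpec, side: str, target: float) -> DRGSpec:
        a_dv0, a_lr0, _ = d.semi_axes_mm
        s0 = math.sqrt(target / (math.pi * a_dv0 * a_lr0))
        target_px = round(target / area)
        cache_key = (base, side, target_px)
        if cache_key in _SOLVE_CACHE:  # count depends only on the integer target
            return _SOLVE_CACHE[cache_key]
        lo, hi = 0.8 * s0, 1.25 * s0
        for _ in range(20):  # bracket the target count
            if _noiseless_count(base, scaled(d, lo), side) <= target_px:
                break
            lo *= 0.9
        for _ in range(20):
            if _noiseless_count(base, scaled(d, hi), side) >= target_px:
                break
            hi *= 1.1
        for _ in range(40):  # count is monotone in the scale
            mid = 0.5 * (lo + hi)
            if _noiseless_count(base, scaled(d, mid), side) >= target_px:
                hi = mid
            else:
                lo = mid
        result = scaled(d, hi)
        _SOLVE_CACHE[cache_key] = result
        return result

    return dataclasses.replace(
        base,
        seed=seed,
        drg_left=solve(base.drg_left, "left", targets["left"]),
        drg_right=solve(base.drg_right, "right", targets["right"]),
    )


def sample_cohort_truth(cohort: CohortSpec) -> list[CSARecord]:
    """Ground-truth CSA table for a cohort without rendering any stacks.

    Pixel counts come from the same bounding-box rasterization the
    renderer uses, so the truth table is identical to the one
    ``render_cohort`` emits for the same spec and seed.
    """
    base = cohort.base
    g = base.geometry
    records: list[CSARecord] = []
    for group, animal_id, week, targets, _ in _sample_scan_specs(cohort):
        spec = spec_for_targets(base, targets, 0)
        for side in ("left", "right"):
            d = spec.drg_left if side == "left" else spec.drg_right
            if not d.present:
                continue
            a_dv, a_lr, _ = d.semi_axes_mm
            cdv, clr = _drg_center(spec, side)
            _check_in_frame(g, cdv, clr, a_dv, a_lr)
            n = _count_drg_pixels(
                g, cdv, clr, a_dv, a_lr,
                cord_center=base.resolved_cord_center(),
                cord_semi_axes=base.cord_semi_axes_mm,
            )
            records.append(
                CSARecord.from_pixels(animal_id, side, week, group.name, n, g)
            )
    return records


def render_cohort(
    cohort: CohortSpec,
) -> tuple[dict[tuple[str, float], tuple[SliceStack, PhantomTruth]], list[CSARecord]]:
    """Render every scan of a longitudinal cohort.

    Returns a mapping ``(animal_id, week) -> (stack, truth)`` plus the
    flat ground-truth CSA table (one record per DRG per scan).
    """
    scans: dict[tuple[str, float], tuple[SliceStack, PhantomTruth]] = {}
    records: list[CSARecord] = []
    g = cohort.base.geometry
    for group, animal_id, week, targets, scan_seed in _sample_scan_specs(cohort):
        spec = spec_for_targets(cohort.base, targets, scan_seed)
        stack, truth = render_phantom(spec)
        scans[(animal_id, week)] = (stack, truth)
        for side, n in truth.true_pixel_count.items():
            records.append(
                CSARecord.from_pixels(animal_id, side, week, group.name, n, g)
            )
    return scans, records
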