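"""Voxel geometry, axis conventions and I/O for axial slice stacks.

Axis convention used throughout the package: a stack is indexed
``[slice, dv, lr]`` with 0-based indices, the slice axis running
rostral -> caudal, the dv axis dorsal -> ventral and the lr axis
subject-left -> subject-right.  All in-plane lengths derive from the
field of view (stated in cm, as on the scanner console) divided by the
matrix size; areas are reported in mm².
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGeometry",
    "SliceStack",
    "CSARecord",
    "DEFAULT_GEOMETRY",
    "pixel_area",
    "read_stack",
    "write_stack",
    "read_measurements",
    "write_measurements",
    "GeometryMismatchError",
    "MeasurementTableError",
]

#: Tolerance, in pixels, for the CSA quantization invariant.  CSA values
#: printed with 3 decimals round-trip to their integer pixel count within
#: 0.082 px at the default geometry; 0.13 px leaves headroom without
#: admitting a genuinely off-grid value.
QUANTIZATION_TOL_PX = 0.13


class GeometryMismatchError(ValueError):
    """File header voxel sizes disagree with the declared geometry."""


class MeasurementTableError(ValueError):
    """A measurement table row violates the CSA quantization invariant."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Acquisition geometry of an axial slice stack.

    Parameters
    ----------
    fov_lr_cm, fov_dv_cm, fov_rc_cm
        Field of view along left-right, dorsal-ventral and
        rostral-caudal, in cm.
    n_lr, n_dv
        In-plane matrix size (read / phase encode).
    n_slices
        Number of axial slices.

    The default study geometry is FOV 2 x 1.5 x 0.7 cm with a
    256 x 192 x 24 matrix, i.e. 78.125 x 78.125 µm pixels and a slice
    thickness of ~0.2917 mm.  Pixel sizes are kept exact (not rounded to
    78 µm): only the exact value makes measured CSAs integer multiples
    of the pixel area.
    """

    fov_lr_cm: float
    fov_dv_cm: float
    fov_rc_cm: float
    n_lr: int
    n_dv: int
    n_slices: int

    def __post_init__(self) -> None:
        for name in ("fov_lr_cm", "fov_dv_cm", "fov_rc_cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name, lo in (("n_lr", 8), ("n_dv", 8), ("n_slices", 5)):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= lo):
                raise ValueError(f"{name} must be an integer >= {lo}, got {v!r}")

    @property
    def pixel_width_lr_mm(self) -> float:
        return 10.0 * self.fov_lr_cm / self.n_lr

    @property
    def pixel_width_dv_mm(self) -> float:
        return 10.0 * self.fov_dv_cm / self.n_dv

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane pixel area in mm²."""
        return self.pixel_width_lr_mm * self.pixel_width_dv_mm

    @property
    def slice_thickness_mm(self) -> float:
        return 10.0 * self.fov_rc_cm / self.n_slices

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape of a conforming stack: (n_slices, n_dv, n_lr)."""
        return (self.n_slices, self.n_dv, self.n_lr)

    def with_slices(self, n_slices: int) -> "VoxelGeometry":
        """Same in-plane geometry over a different rostral-caudal extent,
        keeping the slice thickness fixed."""
        return dataclasses.replace(
            self,
            n_slices=n_slices,
            fov_rc_cm=self.fov_rc_cm * n_slices / self.n_slices,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        return cls(
            fov_lr_cm=float(d["fov_lr_cm"]),
            fov_dv_cm=float(d["fov_dv_cm"]),
            fov_rc_cm=float(d["fov_rc_cm"]),
            n_lr=int(d["n_lr"]),
            n_dv=int(d["n_dv"]),
            n_slices=int(d["n_slices"]),
        )


#: The study's acquisition geometry (axial RARE, 7 T).
DEFAULT_GEOMETRY = VoxelGeometry(
    fov_lr_cm=2.0, fov_dv_cm=1.5, fov_rc_cm=0.7, n_lr=256, n_dv=192, n_slices=24
)


def pixel_area(geometry: VoxelGeometry) -> float:
    """In-plane pixel area in mm², (10·fov_lr/n_lr)·(10·fov_dv/n_dv)."""
    return geometry.pixel_area_mm2


@dataclass
class SliceStack:
    """A 3D axial intensity volume plus its geometry.

    ``data`` is a float array of shape ``(n_slices, n_dv, n_lr)`` with
    finite, non-negative intensities (magnitude MRI contract).
    """

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"stack shape {self.data.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError(
                "negative intensities: magnitude MRI data must be >= 0"
            )


@dataclass(frozen=True)
class CSARecord:
    """One DRG cross-sectional-area measurement.

    The CSA is pixel-quantized: ``csa`` must equal
    ``pixel_count * pixel_area`` of the geometry it was measured under.
    """

    animal_id: str
    side: str  # "left" | "right"
    timepoint: float  # age in weeks
    group: str
    pixel_count: int
    csa: float  # mm²

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.pixel_count < 0:
            raise ValueError("pixel_count must be non-negative")

    @classmethod
    def from_pixels(
        cls,
        animal_id: str,
        side: str,
        timepoint: float,
        group: str,
        pixel_count: int,
        geometry: VoxelGeometry,
    ) -> "CSARecord":
        return cls(
            animal_id=animal_id,
            side=side,
            timepoint=timepoint,
            group=group,
            pixel_count=int(pixel_count),
            csa=int(pixel_count) * geometry.pixel_area_mm2,
        )


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

def write_stack(stack: SliceStack, path: str | Path) -> None:
    """Write a stack to NIfTI-1 (.nii/.nii.gz) or multi-page TIFF (.tif).

    NIfTI stores the volume in (lr, dv, slice) voxel order with voxel
    sizes in mm on the affine, so the geometry is recoverable from the
    header.  TIFF stores one page per slice and carries no slice
    thickness; reading a TIFF requires an explicit geometry.
    """
    path = Path(path)
    g = stack.geometry
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        affine = np.diag(
            [g.pixel_width_lr_mm, g.pixel_width_dv_mm, g.slice_thickness_mm, 1.0]
        )
        img = nib.Nifti1Image(
            np.transpose(stack.data, (2, 1, 0)).astype(np.float64), affine
        )
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), stack.data.astype(np.float32))
    else:
        raise ValueError(f"unsupported stack format: {path.name}")


def read_stack(
    path: str | Path, geometry_override: VoxelGeometry | None = None
) -> SliceStack:
    """Read a NIfTI-1 or multi-page TIFF stack.

    For NIfTI the geometry is derived from the header voxel sizes and
    matrix unless ``geometry_override`` is given, in which case header
    voxel sizes must agree with it within 1%.  TIFF requires
    ``geometry_override``.

    Raises
    ------
    FileNotFoundError
        Missing file.
    GeometryMismatchError
        Header voxel sizes deviate from the declared geometry by >1%.
    ValueError
        Negative intensities (non-magnitude data) or bad format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        arr = np.transpose(np.asarray(img.get_fdata(), dtype=float), (2, 1, 0))
        zooms = img.header.get_zooms()[:3]  # (lr, dv, slice) mm
        n_slices, n_dv, n_lr = arr.shape
        if geometry_override is not None:
            g = geometry_override
            declared = (
                g.pixel_width_lr_mm,
                g.pixel_width_dv_mm,
                g.slice_thickness_mm,
            )
            for z, d, name in zip(zooms, declared, ("lr", "dv", "slice")):
                if abs(z - d) > 0.01 * d:
                    raise GeometryMismatchError(
                        f"header {name} voxel size {z:.6g} mm differs from "
                        f"declared {d:.6g} mm by more than 1%"
                    )
        else:
            g = VoxelGeometry(
                fov_lr_cm=zooms[0] * n_lr / 10.0,
                fov_dv_cm=zooms[1] * n_dv / 10.0,
                fov_rc_cm=zooms[2] * n_slices / 10.0,
                n_lr=n_lr,
                n_dv=n_dv,
                n_slices=n_slices,
            )
        return SliceStack(arr, g)

    if path.suffix in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(str(path)), dtype=float)
        if geometry_override is None:
            raise ValueError("TIFF stacks carry no geometry; pass geometry_override")
        return SliceStack(arr, geometry_override)

    raise ValueError(f"unsupported stack format: {path.name}")


# ---------------------------------------------------------------------------
# Measurement-table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["animal_id", "side", "timepoint", "group", "pixel_count", "csa_mm2"]


def write_measurements(records: Sequence[CSARecord], path: str | Path) -> None:
    """Write CSA records to CSV (RFC-4180, dot decimal, 6-decimal CSA)."""
    df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "side": [r.side for r in records],
            "timepoint": [r.timepoint for r in records],
            "group": [r.group for r in records],
            "pixel_count": [r.pixel_count for r in records],
            "csa_mm2": [f"{r.csa:.6f}" for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_measurements(
    path: str | Path, geometry: VoxelGeometry = DEFAULT_GEOMETRY
) -> list[CSARecord]:
    """Read CSA records from CSV, enforcing the quantization invariant.

    Rows whose ``csa_mm2`` deviates from ``pixel_count * pixel_area`` by
    more than ~0.13 px are rejected with their row index.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementTableError(f"missing columns: {missing}")
    area = geometry.pixel_area_mm2
    out: list[CSARecord] = []
    for i, row in df.iterrows():
        px = int(row["pixel_count"])
        csa = float(row["csa_mm2"])
        if abs(csa - px * area) > QUANTIZATION_TOL_PX * area:
            raise MeasurementTableError(
                f"row {i}: csa {csa} is not pixel_count {px} x pixel area "
                f"{area:.7g} (off-grid by {abs(csa / area - px):.3g} px)"
            )
        out.append(
            CSARecord(
                animal_id=str(row["animal_id"]),
                side=str(row["side"]),
                timepoint=float(row["timepoint"]),
                group=str(row["group"]),
                pixel_count=px,
                csa=csa,
            )
        )
    return out
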