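"""Bundled reference data.

The published test-retest repeatability table: L4 DRG cross-sectional
areas (mm²) of five wild-type mice, both sides, measured twice after
repositioning, under the default acquisition geometry (FOV 2 x 1.5 cm,
matrix 256 x 192).  Values are as printed, i.e. rounded to 3 decimals;
they remain pixel-quantized to within rounding.
"""

from __future__ import annotations

import pandas as pd

from .imaging import DEFAULT_GEOMETRY, VoxelGeometry
from .reliability import TestRetestPair, pair_from_csa

__all__ = ["testretest_table", "testretest_pairs"]

_ROWS = [
    ("No.1", "left", 0.305, 0.323),
    ("No.1", "right", 0.311, 0.317),
    ("No.2", "left", 0.311, 0.256),
    ("No.2", "right", 0.208, 0.183),
    ("No.3", "left", 0.232, 0.208),
    ("No.3", "right", 0.146, 0.134),
    ("No.4", "left", 0.330, 0.385),
    ("No.4", "right", 0.305, 0.281),
    ("No.5", "left", 0.238, 0.269),
    ("No.5", "right", 0.195, 0.195),
]


def testretest_table() -> pd.DataFrame:
    """The reference test-retest CSA table as a DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["animal_id", "side", "test_csa", "retest_csa"]
    )


def testretest_pairs(
    geometry: VoxelGeometry = DEFAULT_GEOMETRY,
) -> list[TestRetestPair]:
    """The reference table as TestRetestPair objects with recovered
    integer pixel counts."""
    return [
        pair_from_csa(f"{animal}-{side}", t, r, geometry)
        for animal, side, t, r in _ROWS
    ]
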