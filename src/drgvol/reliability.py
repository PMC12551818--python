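"""Test-retest agreement statistics for paired CSA measurements.

Implements the one-way random-effects single-measure intraclass
correlation coefficient (ICC), Bland-Altman bias and 95% limits of
agreement (bias +/- 1.96 x SD of the paired differences, sample SD with
the n-1 denominator), and a per-pair relative-difference statistic
computed on the integer pixel counts:

    rel_diff = 100 * (test_px - retest_px) / ((test_px + retest_px) / 2)

Left and right DRGs of one animal are treated as independent units,
matching how per-DRG test-retest tables are laid out; this overstates
the effective n and is noted as a caveat in the package docs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import DEFAULT_GEOMETRY, QUANTIZATION_TOL_PX, VoxelGeometry

__all__ = [
    "TestRetestPair",
    "ReliabilityResult",
    "pair_from_csa",
    "icc_oneway",
    "bland_altman",
    "relative_difference",
    "reliability_report",
]


@dataclass(frozen=True)
class TestRetestPair:
    """Two measurements of the same DRG (animal + side)."""

    unit_id: str
    test_csa: float  # mm²
    retest_csa: float  # mm²
    test_px: int
    retest_px: int


def pair_from_csa(
    unit_id: str,
    test_csa: float,
    retest_csa: float,
    geometry: VoxelGeometry = DEFAULT_GEOMETRY,
) -> TestRetestPair:
    """Build a pair from CSA values, recovering the integer pixel counts.

    CSA values are pixel-quantized; values further than ~0.13 px from an
    integer multiple of the pixel area are rejected.
    """
    area = geometry.pixel_area_mm2
    px = []
    for name, csa in (("test", test_csa), ("retest", retest_csa)):
        n = round(csa / area)
        if abs(csa / area - n) > QUANTIZATION_TOL_PX:
            raise ValueError(
                f"{unit_id} {name} CSA {csa} is not an integer pixel multiple "
                f"of {area:.7g} mm²"
            )
        px.append(int(n))
    return TestRetestPair(unit_id, test_csa, retest_csa, px[0], px[1])


@dataclass
class ReliabilityResult:
    n_units: int
    k: int  # measurements per unit (2)
    ms_between: float  # mm^4
    ms_within: float  # mm^4
    icc: float | None  # None when total variance is zero
    icc_undefined: bool
    bias: float  # mm², mean of test - retest
    sd_diff: float  # mm²
    loa_low: float  # mm²
    loa_high: float  # mm²
    rel_diff_per_unit: list[float] = field(default_factory=list)  # %
    mean_rel_diff: float = 0.0  # %
    mean_test: float = 0.0  # mm²
    mean_retest: float = 0.0  # mm²
    mean_of_pair_means: float = 0.0  # mm²
    pair_means: list[float] = field(default_factory=list)
    pair_diffs: list[float] = field(default_factory=list)


def icc_oneway(
    pairs: list[TestRetestPair],
) -> tuple[float | None, float, float]:
    """One-way random-effects single-measure ICC.

    With k = 2 measurements per unit and n units, the between-unit mean
    square has df = n - 1 and the within-unit mean square df = n(k - 1);
    ICC = (MSB - MSW) / (MSB + (k - 1) MSW).  Returns
    ``(icc, ms_between, ms_within)``; ``icc`` is ``None`` (undefined, not
    a number) when the total variance is zero.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 units")
    x = np.array([[p.test_csa, p.retest_csa] for p in pairs], dtype=float)
    k = x.shape[1]
    grand = x.mean()
    row_means = x.mean(axis=1)
    ms_between = k * ((row_means - grand) ** 2).sum() / (n - 1)
    ms_within = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = ms_between + (k - 1) * ms_within
    if denom == 0:
        return None, ms_between, ms_within
    return (ms_between - ms_within) / denom, ms_between, ms_within


def bland_altman(
    pairs: list[TestRetestPair],
) -> tuple[float, float, float, float, list[float], list[float]]:
    """Bland-Altman bias, SD of differences and 95% limits of agreement.

    Differences are test - retest; returns
    ``(bias, sd_diff, loa_low, loa_high, pair_means, pair_diffs)``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 units")
    t = np.array([p.test_csa for p in pairs])
    r = np.array([p.retest_csa for p in pairs])
    d = t - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return (
        bias, sd, bias - 1.96 * sd, bias + 1.96 * sd,
        list((t + r) / 2.0), list(d),
    )


def relative_difference(pair: TestRetestPair) -> float:
    """Percent difference of the integer pixel counts, relative to the
    pair mean: 100 (test_px - retest_px) / ((test_px + retest_px)/2)."""
    s = pair.test_px + pair.retest_px
    if s <= 0:
        raise ValueError("both pixel counts are zero")
    return 100.0 * (pair.test_px - pair.retest_px) / (s / 2.0)


def reliability_report(
    pairs: list[TestRetestPair],
    plot_dir: str | Path | None = None,
) -> ReliabilityResult:
    """Aggregate ICC, Bland-Altman and relative differences into a report.

    With ``plot_dir`` set, writes ``scatter.png`` (test vs retest with the
    identity line) and ``bland_altman.png`` (bias line, dashed 95% limits
    of agreement).
    """
    icc, msb, msw = icc_oneway(pairs)
    bias, sd, lo, hi, means, diffs = bland_altman(pairs)
    rel = [relative_difference(p) for p in pairs]
    t = [p.test_csa for p in pairs]
    r = [p.retest_csa for p in pairs]
    result = ReliabilityResult(
        n_units=len(pairs), k=2,
        ms_between=msb, ms_within=msw,
        icc=icc, icc_undefined=icc is None,
        bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
        rel_diff_per_unit=rel, mean_rel_diff=float(np.mean(rel)),
        mean_test=float(np.mean(t)), mean_retest=float(np.mean(r)),
        mean_of_pair_means=float(np.mean(means)),
        pair_means=means, pair_diffs=diffs,
    )
    if plot_dir is not None:
        _write_plots(result, t, r, Path(plot_dir))
    return result


def _write_plots(res: ReliabilityResult, test, retest, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(test, retest, color="k")
    span = [min(min(test), min(retest)), max(max(test), max(retest))]
    ax.plot(span, span, "k-", lw=1.5)
    ax.set_xlabel("test CSA (mm$^2$)")
    ax.set_ylabel("retest CSA (mm$^2$)")
    fig.tight_layout()
    fig.savefig(outdir / "scatter.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(res.pair_means, res.pair_diffs, color="k")
    ax.axhline(res.bias, color="k")
    ax.axhline(res.loa_low, color="k", ls="--")
    ax.axhline(res.loa_high, color="k", ls="--")
    ax.set_xlabel("pair mean CSA (mm$^2$)")
    ax.set_ylabel("test $-$ retest (mm$^2$)")
    fig.tight_layout()
    fig.savefig(outdir / "bland_altman.png", dpi=150)
    plt.close(fig)
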