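"""XIC-based quantification across fermentation days.

Relative quantification integrates an extracted ion chromatogram (a
narrow m/z window summed per scan) over the elution window and scales
each compound's per-day areas to the series maximum; absolute
quantification inverts an ordinary-least-squares calibration line fitted
on standards of known concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MZ_MAX, MZ_MIN, Run, scan_times

__all__ = [
    "XicTrace",
    "extract_xic",
    "peak_area",
    "CalibrationCurve",
    "fit_calibration",
    "absolute_concentration",
    "QuantWindow",
    "QuantSeries",
    "relative_series",
    "quant_frame",
    "plot_series",
]

#: Default XIC half-width (Th) around a theoretical m/z.
DEFAULT_XIC_HALF_WIDTH = 0.01


@dataclass
class XicTrace:
    """Per-scan summed intensity of peaks inside one m/z window."""

    mz_lo: float
    mz_hi: float
    rt: np.ndarray
    intensity: np.ndarray


def extract_xic(
    run: Run,
    mz_lo: float,
    mz_hi: float,
    rt_lo: float | None = None,
    rt_hi: float | None = None,
) -> XicTrace:
    """Sum, per scan, the intensities of peaks with m/z in [lo, hi).

    Scans without peaks contribute zero, so the trace covers the whole
    requested retention range.
    """
    if mz_hi <= mz_lo:
        raise ValueError("inverted m/z window")
    if not (MZ_MIN <= mz_lo and mz_hi <= MZ_MAX):
        raise ValueError(f"m/z window must lie within [{MZ_MIN}, {MZ_MAX}]")
    all_rt = scan_times(run.n_scans)
    rt_lo = all_rt[0] if rt_lo is None else rt_lo
    rt_hi = all_rt[-1] if rt_hi is None else rt_hi
    if rt_hi < rt_lo:
        raise ValueError("inverted retention-time window")
    in_rt = (all_rt >= rt_lo) & (all_rt <= rt_hi)
    scans = np.flatnonzero(in_rt)
    sel = (run.mz >= mz_lo) & (run.mz < mz_hi)
    per_scan = np.bincount(run.scan[sel], weights=run.intensity[sel], minlength=run.n_scans)
    return XicTrace(mz_lo, mz_hi, all_rt[scans], per_scan[scans])


def peak_area(trace: XicTrace, rt_lo: float | None = None, rt_hi: float | None = None) -> float:
    """Trapezoidal integral of the trace over retention time (minutes)."""
    rt, y = trace.rt, trace.intensity
    if rt_lo is not None or rt_hi is not None:
        lo = rt_lo if rt_lo is not None else -np.inf
        hi = rt_hi if rt_hi is not None else np.inf
        keep = (rt >= lo) & (rt <= hi)
        rt, y = rt[keep], y[keep]
    if len(rt) < 2:
        raise ValueError("need at least 2 trace points to integrate")
    return float(np.trapezoid(y, rt))


@dataclass(frozen=True)
class CalibrationCurve:
    """area = slope * concentration + intercept, with fit diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero for invertibility")


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """OLS line through (concentration, area) standards."""
    conc = np.array([s[0] for s in standards], dtype=float)
    area = np.array([s[1] for s in standards], dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need standards at >= 2 distinct concentrations")
    fit = stats.linregress(conc, area)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def absolute_concentration(
    area: float, curve: CalibrationCurve
) -> tuple[float, bool]:
    """Invert the calibration line: (area - intercept) / slope.

    Returns (concentration, extrapolated): the flag is set when the
    result falls outside the concentration range of the standards
    (including negative values from areas below the intercept).
    """
    conc = (area - curve.intercept) / curve.slope
    extrapolated = not (curve.conc_range[0] <= conc <= curve.conc_range[1])
    return conc, extrapolated


@dataclass(frozen=True)
class QuantWindow:
    """Where to look for one compound: m/z window and elution window."""

    mz_lo: float
    mz_hi: float
    rt_lo: float
    rt_hi: float

    @classmethod
    def around(
        cls,
        theoretical_mz: float,
        rt_apex: float,
        rt_halfspan: float = 1.5,
        mz_half_width: float = DEFAULT_XIC_HALF_WIDTH,
    ) -> "QuantWindow":
        return cls(
            theoretical_mz - mz_half_width,
            theoretical_mz + mz_half_width,
            rt_apex - rt_halfspan,
            rt_apex + rt_halfspan,
        )


@dataclass
class QuantSeries:
    """Per-(batch, day) values for one compound.

    In relative mode, values are scaled to the series maximum, so they
    lie in [0, 1] with the maximum exactly 1.
    """

    compound: str
    values: "pd.Series"  # index: (batch, day)
    mode: str  # "relative" | "absolute" | "area"


def relative_series(
    runs: Sequence[Run],
    windows: Mapping[str, QuantWindow],
    scale: Mapping[str, float] | None = None,
) -> list[QuantSeries]:
    """Relative XIC quantification of several compounds over all runs.

    Per run, the XIC area inside each compound's window, optionally
    multiplied by that run's normalization factor (``scale`` keyed by
    run label, e.g. the global-median factors) so that injection or
    matrix loading differences do not masquerade as abundance changes;
    technical replicates of a (batch, day) are averaged; the series is
    normalized to its maximum.  An all-zero series is an error (the
    window saw nothing anywhere).
    """
    if not runs:
        raise ValueError("need at least one run")
    out = []
    for cid, w in windows.items():
        rows = {}
        for run in runs:
            trace = extract_xic(run, w.mz_lo, w.mz_hi, w.rt_lo, w.rt_hi)
            area = peak_area(trace)
            if scale is not None:
                area *= scale[run.label]
            rows.setdefault((run.batch, run.day), []).append(area)
        series = pd.Series(
            {key: float(np.mean(v)) for key, v in rows.items()}, name=cid
        ).sort_index()
        peak = series.max()
        if peak <= 0:
            raise ValueError(f"all-zero XIC series for compound {cid!r}")
        out.append(QuantSeries(cid, series / peak, "relative"))
    return out


def quant_frame(series: Sequence[QuantSeries]) -> pd.DataFrame:
    """Long-format quantification report."""
    rows = []
    for s in series:
        for (batch, day), value in s.values.items():
            rows.append(
                {
                    "compound": s.compound,
                    "batch": batch,
                    "day": day,
                    "value": value,
                    "mode": s.mode,
                }
            )
    return pd.DataFrame(rows)


def plot_series(series: Sequence[QuantSeries], path) -> None:
    """Day-vs-value panel per compound, one line per batch."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(series)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 2.8), squeeze=False)
    for ax, s in zip(axes[0], series):
        df = s.values.unstack(level=0)
        for batch in df.columns:
            ax.plot(df.index, df[batch], marker="o", label=str(batch))
        ax.set_title(s.compound, fontsize=9)
        ax.set_xlabel("day")
        ax.set_ylabel(s.mode)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
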