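"""Standardized CGM glycemic metrics and ambulatory glucose profiles.

Implements the consensus clinical summary of continuous glucose traces:
time in ranges (TIR 70-180 mg/dL inclusive, TAR > 180 with a level-2
sub-band > 250, TBR < 70 with a level-2 sub-band < 54), mean / SD /
coefficient of variation, cohort extreme tables, and the ambulatory
glucose profile (AGP) -- percentile curves of glucose and insulin folded
onto a 24-hour axis.

Conventions (fixed and documented):

* range boundaries are inclusive on the in-range side, so TIR + TAR +
  TBR partitions every sample exactly and the three always sum to 100%;
* level-2 bands are reported separately but included in their level-1
  totals;
* SD uses the population convention (divide by n);
* percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .simulate import MINUTES_PER_DAY, SimulationTrace, analysis_window

AGP_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass(frozen=True)
class GlycemicReport:
    """Standard CGM summary of one glucose series.

    Percentages refer to the share of 5-min samples; ``peak``/``nadir``
    are the extreme glucose values in the analysis window.
    """

    tir_pct: float
    tar_pct: float
    tar_level2_pct: float
    tbr_pct: float
    tbr_level2_pct: float
    mean_bg: float
    sd_bg: float
    cv_pct: float
    peak: float
    nadir: float
    n_samples: int
    window: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "tir_pct", "tar_pct", "tar_level2_pct", "tbr_pct",
            "tbr_level2_pct", "mean_bg", "sd_bg", "cv_pct", "peak",
            "nadir", "n_samples")}
        out["window"] = dict(self.window)
        return out


@dataclass(frozen=True)
class AGPProfile:
    """Percentile curves of G and u folded onto a 24-h axis.

    ``bin_start_min`` holds the start minute-of-day of each bin;
    ``glucose`` and ``insulin`` map percentile -> per-bin curve.
    """

    bin_start_min: np.ndarray
    glucose: dict[float, np.ndarray]
    insulin: dict[float, np.ndarray]
    bin_minutes: float

    def glucose_frame(self) -> pd.DataFrame:
        data = {"bin_start_min": self.bin_start_min}
        for p in AGP_PERCENTILES:
            data[f"G_p{p:g}"] = self.glucose[p]
        for p in AGP_PERCENTILES:
            data[f"u_p{p:g}"] = self.insulin[p]
        return pd.DataFrame(data)


def time_in_ranges(g_samples: Sequence[float]) -> dict[str, float]:
    """Percent of samples in the consensus glycemic bands.

    In-range is the closed interval [70, 180] mg/dL; samples exactly on
    a boundary count as in range.
    """
    g = np.asarray(g_samples, dtype=float)
    if g.size == 0:
        raise InvalidInputError("glucose series is empty")
    n = g.size
    return {
        "tir_pct": 100.0 * np.count_nonzero((g >= 70.0) & (g <= 180.0)) / n,
        "tar_pct": 100.0 * np.count_nonzero(g > 180.0) / n,
        "tar_level2_pct": 100.0 * np.count_nonzero(g > 250.0) / n,
        "tbr_pct": 100.0 * np.count_nonzero(g < 70.0) / n,
        "tbr_level2_pct": 100.0 * np.count_nonzero(g < 54.0) / n,
    }


def summary_stats(g_samples: Sequence[float]) -> dict[str, float]:
    """Mean, population SD, CV [%], peak and nadir of a glucose series."""
    g = np.asarray(g_samples, dtype=float)
    if g.size < 2:
        raise InvalidInputError("need at least two samples for summary statistics")
    mean = float(np.mean(g))
    if mean == 0.0:
        raise InvalidInputError("CV undefined for zero-mean series")
    sd = float(np.std(g))  # population convention
    return {
        "mean_bg": mean,
        "sd_bg": sd,
        "cv_pct": 100.0 * sd / mean,
        "peak": float(np.max(g)),
        "nadir": float(np.min(g)),
    }


def glycemic_report(
    g_samples: Sequence[float], window: dict | None = None
) -> GlycemicReport:
    """Full standardized report for one glucose series."""
    g = np.asarray(g_samples, dtype=float)
    ranges = time_in_ranges(g)
    stats = summary_stats(g)
    return GlycemicReport(
        **ranges, **stats, n_samples=int(g.size), window=window or {})


def report_from_trace(
    trace: SimulationTrace, start_day: int = 3
) -> GlycemicReport:
    """Report over a trace's post-learning window (default: day 4 on)."""
    mask = analysis_window(trace, start_day)
    if not np.any(mask):
        raise InvalidInputError(
            f"trace has no samples after day {start_day}")
    window = {
        "start_day": start_day,
        "t_start_min": float(trace.t[mask][0]),
        "t_end_min": float(trace.t[mask][-1]),
        "patient_index": trace.metadata.get("patient_index"),
    }
    return glycemic_report(trace.G[mask], window=window)


_EXTREME_METRICS = ("peak", "mean_bg", "sd_bg", "cv_pct")


def cohort_extremes(reports: Sequence[GlycemicReport]) -> pd.DataFrame:
    """Max/min of peak, mean, SD and CV across a cohort.

    Rows are the four metrics; columns give the extreme values and the
    1-based patient labels attaining them.  Ties resolve to the lowest
    patient index.
    """
    if len(reports) == 0:
        raise InvalidInputError("need at least one report")
    rows = []
    for metric in _EXTREME_METRICS:
        values = np.array([getattr(r, metric) for r in reports])
        i_max = int(np.argmax(values))
        i_min = int(np.argmin(values))
        rows.append({
            "metric": metric,
            "max": values[i_max], "max_patient": i_max + 1,
            "min": values[i_min], "min_patient": i_min + 1,
        })
    return pd.DataFrame(rows).set_index("metric")


def agp_profile(trace: SimulationTrace, bin_minutes: float = 5.0) -> AGPProfile:
    """Ambulatory glucose profile of one trace.

    Samples are grouped by time-of-day (modulo 24 h) into bins of
    ``bin_minutes`` and the 5/25/50/75/95th percentiles of glucose and
    insulin are computed per bin.  The trace must span at least two
    days, otherwise every bin would hold a single observation and the
    percentile spread would be meaningless.
    """
    if bin_minutes <= 0.0 or MINUTES_PER_DAY % bin_minutes != 0.0:
        raise InvalidInputError(
            f"bin_minutes must divide the day, got {bin_minutes!r}")
    span = float(trace.t[-1] - trace.t[0])
    if span < MINUTES_PER_DAY:
        raise InvalidInputError(
            "AGP requires a trace spanning at least two days")
    n_bins = int(MINUTES_PER_DAY / bin_minutes)
    tod = np.mod(trace.t, MINUTES_PER_DAY)
    bins = np.floor(tod / bin_minutes).astype(int)
    glucose = {p: np.empty(n_bins) for p in AGP_PERCENTILES}
    insulin = {p: np.empty(n_bins) for p in AGP_PERCENTILES}
    for b in range(n_bins):
        mask = bins == b
        if not np.any(mask):
            for p in AGP_PERCENTILES:
                glucose[p][b] = np.nan
                insulin[p][b] = np.nan
            continue
        g_pct = np.percentile(trace.G[mask], AGP_PERCENTILES)
        u_pct = np.percentile(trace.u[mask], AGP_PERCENTILES)
        for p, gv, uv in zip(AGP_PERCENTILES, g_pct, u_pct):
            glucose[p][b] = gv
            insulin[p][b] = uv
    return AGPProfile(
        bin_start_min=np.arange(n_bins) * bin_minutes,
        glucose=glucose, insulin=insulin, bin_minutes=float(bin_minutes))


def plot_agp(profile: AGPProfile, ax=None):
    """Convenience AGP plot: median line with shaded interpercentile bands.

    Requires matplotlib (``aidsim[plot]``).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    h = profile.bin_start_min / 60.0
    ax.fill_between(h, profile.glucose[5.0], profile.glucose[95.0],
                    alpha=0.2, label="5-95%")
    ax.fill_between(h, profile.glucose[25.0], profile.glucose[75.0],
                    alpha=0.4, label="25-75%")
    ax.plot(h, profile.glucose[50.0], lw=2, label="median")
    ax.axhspan(70, 180, color="tab:green", alpha=0.08)
    ax.set_xlabel("time of day [h]")
    ax.set_ylabel("glucose [mg/dL]")
    ax.set_xlim(0, 24)
    ax.legend(loc="upper right")
    return ax
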