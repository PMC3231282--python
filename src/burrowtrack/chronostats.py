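"""Chronobiological analysis of displacement time series.

The analysis chain standard for burrow-emergence rhythms:

1. **Binning** — displacement values are summed into 10-min bins to
   filter high-frequency behavioural noise.
2. **Total activity** — the sum of all displacements over the record.
3. **Chi-square (Sokolove–Bushell) periodogram** — for each candidate
   period ``P`` of ``p`` bins, fold the series x_1..x_N into ``p``
   columns h with K_h entries each and column means M_h; with grand
   mean M̄ and biased variance σ̂² = Σ_i (x_i − M̄)²/N,

       Q_P = Σ_h K_h (M_h − M̄)² / σ̂²

   is compared against the χ² quantile at 1−α with p−1 degrees of
   freedom.  The scan covers 20–27 h; the peak is the significant
   period maximizing Q_P, reported with %V — the percentage of total
   variance captured by the folded mean profile.
4. **Waveform analysis** — the series is folded on a standard 24-h
   frame of 144 × 10-min bins aligned to clock time; bin means (±SEM)
   form the mean daily profile, whose re-average is the MESOR (midline
   estimating statistic of rhythm).  Activity phases are maximal runs
   of bins strictly above the MESOR, reported as onset/offset clock
   times (runs wrapping midnight are merged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .rfid import DisplacementSeries

__all__ = [
    "BinnedSeries",
    "PeriodogramResult",
    "WaveformResult",
    "bin_series",
    "total_activity",
    "chi_square_periodogram",
    "waveform",
]

BINS_PER_DAY_10MIN = 144


class DataError(ValueError):
    """Raised when a series cannot support the requested statistic."""


@dataclass(frozen=True)
class BinnedSeries:
    """Displacement summed into fixed clock-aligned bins (cm per bin)."""

    start: pd.Timestamp
    bin_minutes: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise DataError("binned series must be a non-empty 1-D array")
        if np.any(v < 0):
            raise DataError("binned values must be >= 0")
        object.__setattr__(self, "values", v)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(len(self.values)) * self.bin_minutes, unit="min"
        )


@dataclass(frozen=True)
class PeriodogramResult:
    """Chi-square periodogram spectrum with its significance line."""

    periods: np.ndarray  # candidate periods, minutes
    Q: np.ndarray  # statistic per period
    sig: np.ndarray  # chi2 quantile at 1-alpha, df = bins-1
    alpha: float
    peak_period: float | None  # minutes, None if no significant peak
    percent_variance: float | None  # %V at the peak

    def significant_mask(self) -> np.ndarray:
        return self.Q > self.sig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period_min": self.periods, "Q": self.Q, "sig": self.sig}
        )


@dataclass(frozen=True)
class WaveformResult:
    """Mean daily activity profile over 144 bins with MESOR and phases."""

    bin_means: np.ndarray  # 144 values, cm per bin
    bin_sems: np.ndarray
    mesor: float
    phases: list[tuple[str, str]]  # (onset clock time, offset clock time)
    bin_minutes: float = 10.0

    def bin_clock_times(self) -> list[str]:
        return [_fmt_clock(h * self.bin_minutes) for h in range(len(self.bin_means))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clock_time": self.bin_clock_times(),
                "mean_cm": self.bin_means,
                "sem_cm": self.bin_sems,
            }
        )


def _fmt_clock(minutes_of_day: float) -> str:
    m = int(round(minutes_of_day)) % (24 * 60)
    return f"{m // 60:02d}:{m % 60:02d}"


def bin_series(series: DisplacementSeries, bin_minutes: float = 10.0) -> BinnedSeries:
    """Sum displacement values into clock-aligned bins.

    Bins start on multiples of ``bin_minutes`` past midnight; the first
    bin is the one containing the first sample, empty bins in between
    are 0, and a trailing partial bin is dropped.
    """
    if len(series.values) == 0:
        raise DataError("cannot bin an empty series")
    times = pd.DatetimeIndex(series.times)
    step = pd.to_timedelta(bin_minutes, unit="min")
    start = times[0].floor(f"{int(bin_minutes * 60)}s")
    # displacement values stamp interval ends; a value landing exactly on a
    # bin boundary belongs to the preceding bin
    offs = np.asarray((times - start) / step, dtype=float)
    idx = np.ceil(offs).astype(int) - 1
    idx = np.maximum(idx, 0)
    # drop the trailing partial bin unless the record exactly fills it
    n_full = int((times[-1] - start) / step)
    n_bins = max(n_full, 1)
    values = np.zeros(n_bins)
    keep = idx < n_bins
    np.add.at(values, idx[keep], np.asarray(series.values)[keep])
    return BinnedSeries(start=start, bin_minutes=bin_minutes, values=values)


def total_activity(series: DisplacementSeries) -> float:
    """Total locomotor activity: the sum of all displacements (cm)."""
    return float(np.sum(series.values))


def _fold_stats(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Column means M_h and counts K_h of x folded at period p bins."""
    n = len(x)
    h = np.arange(n) % p
    K = np.bincount(h, minlength=p).astype(float)
    M = np.bincount(h, weights=x, minlength=p) / K
    return M, K


def chi_square_periodogram(
    binned: BinnedSeries,
    min_period_hours: float = 20.0,
    max_period_hours: float = 27.0,
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Sokolove–Bushell chi-square periodogram over a period scan.

    Candidate periods run from ``min_period_hours`` to ``max_period_hours``
    at one-bin resolution (10 min by default).  The peak is the candidate
    maximizing Q_P among those exceeding the χ²(1−α, p−1) line; %V is
    the share of total variance explained by the folded profile there.
    """
    x = np.asarray(binned.values, dtype=float)
    n = len(x)
    p_min = int(np.ceil(min_period_hours * 60.0 / binned.bin_minutes))
    p_max = int(np.floor(max_period_hours * 60.0 / binned.bin_minutes))
    if n < 2 * p_max:
        raise DataError(
            f"series of {n} bins too short to scan periods up to "
            f"{p_max} bins (need at least {2 * p_max})"
        )
    grand = x.mean()
    ss_total = float(np.sum((x - grand) ** 2))
    if ss_total == 0:
        raise DataError("zero-variance series: periodogram undefined")
    sigma2 = ss_total / n

    p_bins = np.arange(p_min, p_max + 1)
    Q = np.empty(len(p_bins))
    pct = np.empty(len(p_bins))
    for j, p in enumerate(p_bins):
        M, K = _fold_stats(x, int(p))
        ss_between = float(np.sum(K * (M - grand) ** 2))
        Q[j] = ss_between / sigma2
        pct[j] = 100.0 * ss_between / ss_total
    sig = chi2.ppf(1.0 - alpha, p_bins - 1)
    periods = p_bins * binned.bin_minutes

    above = Q > sig
    if above.any():
        k = int(np.argmax(np.where(above, Q, -np.inf)))
        peak, pv = float(periods[k]), float(pct[k])
    else:
        peak, pv = None, None
    return PeriodogramResult(
        periods=periods, Q=Q, sig=sig, alpha=alpha, peak_period=peak, percent_variance=pv
    )


def waveform(binned: BinnedSeries, bins_per_day: int = BINS_PER_DAY_10MIN) -> WaveformResult:
    """Mean daily activity profile, MESOR and above-MESOR phases.

    Folds the series on a standard 24-h frame aligned to clock time
    (bin h covers clock time [h, h+1) x 10 min past midnight), averages
    across days (days with partial coverage contribute to the bins they
    cover), and reports maximal runs of bins strictly above the MESOR
    as (onset, offset) clock times.
    """
    x = np.asarray(binned.values, dtype=float)
    if len(x) < bins_per_day:
        raise DataError(
            f"waveform needs at least one full day ({bins_per_day} bins); got {len(x)}"
        )
    minutes_per_day = 24 * 60
    if abs(bins_per_day * binned.bin_minutes - minutes_per_day) > 1e-9:
        raise DataError("bins_per_day inconsistent with bin width")
    start_min = binned.start.hour * 60 + binned.start.minute
    offset = int(round(start_min / binned.bin_minutes))
    h = (offset + np.arange(len(x))) % bins_per_day

    means = np.zeros(bins_per_day)
    sems = np.zeros(bins_per_day)
    for b in range(bins_per_day):
        vals = x[h == b]
        means[b] = vals.mean()
        sems[b] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
    mesor = float(means.mean())

    phases = _above_mesor_phases(means, mesor, binned.bin_minutes)
    return WaveformResult(
        bin_means=means,
        bin_sems=sems,
        mesor=mesor,
        phases=phases,
        bin_minutes=binned.bin_minutes,
    )


def _above_mesor_phases(
    means: np.ndarray, mesor: float, bin_minutes: float
) -> list[tuple[str, str]]:
    """Maximal runs strictly above the MESOR, merged across midnight."""
    above = means > mesor
    n = len(above)
    if above.all() or not above.any():
        return []
    # find run starts/ends on the circle
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    runs = []
    for s in starts:
        e = s
        while above[(e + 1) % n]:
            e += 1
        runs.append((s, e % n if e >= n else e))
    phases = []
    for s, e in runs:
        onset = _fmt_clock(s * bin_minutes)
        offset = _fmt_clock(((e + 1) % n) * bin_minutes)  # end of last above bin
        phases.append((onset, offset))
    return phases
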