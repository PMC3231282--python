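"""Standard chronobiology plots: actogram-style time series, periodogram,
waveform with MESOR, and the per-antenna occupancy map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .chronostats import BinnedSeries, PeriodogramResult, WaveformResult
from .layout import AntennaLayout
from .motion import PhotoperiodSchedule

__all__ = [
    "plot_binned_series",
    "plot_periodogram",
    "plot_waveform",
    "plot_occupancy_map",
]


def _shade_nights(ax, times: pd.DatetimeIndex, schedule: PhotoperiodSchedule) -> None:
    days = pd.date_range(times[0].floor("D"), times[-1].ceil("D"), freq="D")
    on = pd.Timedelta(schedule.lights_on + ":00")
    off = pd.Timedelta(schedule.lights_off + ":00")
    for d in days:
        ax.axvspan(d, d + on, color="0.85", zorder=0)
        ax.axvspan(d + off, d + pd.Timedelta("1D"), color="0.85", zorder=0)
    ax.set_xlim(times[0], times[-1])


def plot_binned_series(
    binned: BinnedSeries,
    path,
    *,
    schedule: PhotoperiodSchedule | None = None,
    title: str = "",
) -> None:
    """Binned activity over experimental time, dark phases shaded."""
    fig, ax = plt.subplots(figsize=(10, 3))
    t = binned.times
    if schedule is not None:
        _shade_nights(ax, t, schedule)
    ax.plot(t, binned.values, lw=0.7, color="tab:blue")
    ax.set_ylabel("activity (cm / bin)")
    ax.set_title(title)
    fig.autofmt_xdate()
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_periodogram(result: PeriodogramResult, path, *, title: str = "") -> None:
    """Q statistic over candidate periods with the significance line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.periods / 60.0, result.Q, color="tab:blue", label="Q")
    ax.plot(
        result.periods / 60.0,
        result.sig,
        color="tab:red",
        ls="--",
        label=f"chi2 {100 * (1 - result.alpha):.0f}%",
    )
    if result.peak_period is not None:
        ax.axvline(result.peak_period / 60.0, color="0.4", lw=0.8)
        ax.annotate(
            f"P = {result.peak_period:.0f} min\n%V = {result.percent_variance:.1f}",
            xy=(result.peak_period / 60.0, float(np.max(result.Q))),
            fontsize=8,
        )
    ax.set_xlabel("period (h)")
    ax.set_ylabel("Q")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_waveform(result: WaveformResult, path, *, title: str = "") -> None:
    """Mean daily profile ± SEM, MESOR line, onset/offset arrows."""
    fig, ax = plt.subplots(figsize=(8, 4))
    hours = np.arange(len(result.bin_means)) * result.bin_minutes / 60.0
    ax.fill_between(
        hours,
        result.bin_means - result.bin_sems,
        result.bin_means + result.bin_sems,
        alpha=0.3,
        color="tab:blue",
    )
    ax.plot(hours, result.bin_means, color="tab:blue")
    ax.axhline(result.mesor, color="k", lw=1, label=f"MESOR = {result.mesor:.2f}")
    top = float(np.max(result.bin_means + result.bin_sems)) or 1.0
    for onset, offset in result.phases:
        for clock, color in ((onset, "tab:green"), (offset, "tab:red")):
            h, m = map(int, clock.split(":"))
            ax.annotate(
                "",
                xy=(h + m / 60.0, result.mesor),
                xytext=(h + m / 60.0, top),
                arrowprops=dict(arrowstyle="->", color=color),
            )
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel("activity (cm / bin)")
    ax.set_xlim(0, 24)
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_occupancy_map(
    occupancy: dict[str, dict[int, float]],
    layout: AntennaLayout,
    path,
) -> None:
    """Per-antenna occupancy percentages drawn on the tank footprint."""
    uids = sorted(occupancy)
    fig, axes = plt.subplots(
        len(uids), 1, figsize=(8, 3 * max(len(uids), 1)), squeeze=False
    )
    for ax, uid in zip(axes[:, 0], uids):
        pct = occupancy[uid]
        vals = [pct.get(a.id, 0.0) for a in layout.active_antennas]
        xs = [a.center_xy[0] for a in layout.active_antennas]
        ys = [a.center_xy[1] for a in layout.active_antennas]
        sc = ax.scatter(xs, ys, s=200, c=vals, cmap="viridis", vmin=0)
        for a, v in zip(layout.active_antennas, vals):
            ax.annotate(
                f"{a.id}", a.center_xy, fontsize=6, ha="center", va="center", color="w"
            )
        ax.set_xlim(0, layout.tank.length)
        ax.set_ylim(0, layout.tank.width)
        ax.set_aspect("equal")
        ax.set_title(f"{uid}")
        fig.colorbar(sc, ax=ax, label="% occupancy")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
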