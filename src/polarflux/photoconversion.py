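"""Photoconversion flux quantification.

A photoconvertible probe (mMaple3-style) is switched from green to red in
the perinuclear region of a migrating cell; the red pool then reports
anterograde transport out of the perinuclear region while the green pool
reports retrograde return of unconverted probe.  From per-region intensity
time series the module computes the standard ratio statistics:

* green gain  = (G(t_end) - G(t_conv)) / (G(t0) - G(t_conv))   [retrograde]
* red loss    = (R(t_conv) - R(t_end)) / (R(t_conv) - R(t0))   [anterograde]

evaluated on the perinuclear traces, plus front/rear red-gain curves
normalized to the background intensity at t0, and their ratio as a polarity
index.

All region intensities are background-subtracted (per-frame background-mask
mean) before the ratios are formed, since the raw ratios are offset
sensitive.  Fractions that fall outside [0, 1] under noise are reported raw
with a ``clipped`` flag, never silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
from scipy import ndimage, optimize

from .errors import DataError, DegenerateConversionError

__all__ = [
    "RegionPartition",
    "PhotoconversionSeries",
    "FluxSummary",
    "BiasResult",
    "partition_cell",
    "extract_region_series",
    "green_gain",
    "red_loss",
    "regional_gain_curve",
    "front_rear_bias",
    "summarize_flux",
    "fit_efflux_rate",
]

REGIONS = ("perinuclear", "front", "rear")

#: denominator guard, as a fraction of the trace dynamic range
EPS_FRACTION = 1e-6


@dataclass(frozen=True)
class RegionPartition:
    """Boolean pixel masks splitting a cell into analysis regions.

    Front and rear are disjoint and together cover the cell mask; the
    perinuclear region is a subset of the cell; the background mask is
    outside the cell.  ``migration_axis`` is the unit vector (x, y) defining
    "front".
    """

    cell_mask: np.ndarray
    perinuclear_mask: np.ndarray
    front_mask: np.ndarray
    rear_mask: np.ndarray
    background_mask: np.ndarray
    migration_axis: tuple[float, float]

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell_mask, bool)
        for name in ("perinuclear_mask", "front_mask", "rear_mask",
                     "background_mask"):
            m = np.asarray(getattr(self, name), bool)
            object.__setattr__(self, name, m)
            if m.shape != cell.shape:
                raise DataError(f"{name} shape {m.shape} != cell {cell.shape}")
        object.__setattr__(self, "cell_mask", cell)
        if np.any(self.front_mask & self.rear_mask):
            raise DataError("front and rear masks overlap")
        if np.any((self.front_mask | self.rear_mask) != cell):
            raise DataError("front + rear must exactly cover the cell mask")
        if np.any(self.perinuclear_mask & ~cell):
            raise DataError("perinuclear mask extends outside the cell")
        if np.any(self.background_mask & cell):
            raise DataError("background mask overlaps the cell")


@dataclass(frozen=True)
class PhotoconversionSeries:
    """Green/red per-region intensity time series around a conversion event.

    ``green`` and ``red`` map region name -> intensity trace; ``background``
    is the background-mask trace.  Key times t0 (pre-conversion), t_conv
    (first post-conversion frame) and t_end must lie on the time grid.
    """

    times_s: np.ndarray
    green: dict[str, np.ndarray]
    red: dict[str, np.ndarray]
    background: np.ndarray
    t0_s: float = 0.0
    t_conv_s: float = 45.0
    t_end_s: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if self.t_end_s is None:
            object.__setattr__(self, "t_end_s", float(t[-1]))
        n = t.size
        for ch_name, ch in (("green", self.green), ("red", self.red)):
            for r in REGIONS:
                if r not in ch:
                    raise DataError(f"{ch_name} traces missing region {r!r}")
                arr = np.asarray(ch[r], dtype=float)
                ch[r] = arr
                if arr.shape != (n,):
                    raise DataError(
                        f"{ch_name}/{r} trace length {arr.size} != {n} times")
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if bg.shape != (n,):
            raise DataError("background trace length mismatch")
        for key, name in ((self.t0_s, "t0"), (self.t_conv_s, "t_conv"),
                          (self.t_end_s, "t_end")):
            if not np.isclose(t, key).any():
                raise DataError(f"key time {name} = {key} s not on the time grid")

    def index_of(self, time_s: float) -> int:
        hits = np.flatnonzero(np.isclose(self.times_s, time_s))
        if hits.size == 0:
            raise DataError(f"time {time_s} s not on the grid")
        return int(hits[0])

    def corrected(self, channel: Literal["green", "red"], region: str) -> np.ndarray:
        """Background-subtracted trace (per-frame background mean removed)."""
        ch = self.green if channel == "green" else self.red
        if region not in ch:
            raise DataError(f"unknown region {region!r}")
        return ch[region] - self.background


class BiasResult(NamedTuple):
    """Front/rear polarity index; ``defined`` is False when both gains ~ 0."""

    value: float
    defined: bool


@dataclass(frozen=True)
class FluxSummary:
    """One-row summary of a photoconversion experiment."""

    green_gain_fraction: float
    red_loss_fraction: float
    front_gain_curve: np.ndarray
    rear_gain_curve: np.ndarray
    front_rear_bias: float
    bias_defined: bool
    clipped: bool
    condition: str = ""


def partition_cell(
    cell_mask: np.ndarray,
    nucleus_centroid: tuple[float, float],
    migration_axis: tuple[float, float],
    *,
    nucleus_mask: np.ndarray | None = None,
    perinuclear_mask: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
    annulus_factor: float = 1.5,
) -> RegionPartition:
    """Split a cell mask into front/rear halves plus a perinuclear region.

    Front = cell pixels whose offset from the cell centroid has positive
    projection on ``migration_axis`` (pixels exactly on the dividing line go
    to the rear).  The perinuclear region defaults to an annulus from the
    nucleus boundary out to ``annulus_factor`` x the nucleus equivalent
    radius; pass ``perinuclear_mask`` to override.  ``nucleus_centroid`` and
    ``migration_axis`` are (x, y) = (col, row) pairs.
    """
    cell = np.asarray(cell_mask, bool)
    if not cell.any():
        raise DataError("cell mask is empty")
    ax = np.asarray(migration_axis, float)
    norm = np.linalg.norm(ax)
    if norm == 0 or not np.isfinite(norm):
        raise DataError("migration_axis must be a non-zero vector")
    ax = ax / norm
    cx, cy = float(nucleus_centroid[0]), float(nucleus_centroid[1])
    rr, cc = np.nonzero(cell)
    if not cell[int(round(cy)), int(round(cx))]:
        raise DataError("nucleus centroid lies outside the cell mask")

    cell_cy, cell_cx = rr.mean(), cc.mean()
    yy, xx = np.indices(cell.shape)
    proj = (xx - cell_cx) * ax[0] + (yy - cell_cy) * ax[1]
    front = cell & (proj > 0)
    rear = cell & ~front

    if perinuclear_mask is not None:
        peri = np.asarray(perinuclear_mask, bool) & cell
    else:
        if nucleus_mask is not None:
            nuc = np.asarray(nucleus_mask, bool)
            r_eq = np.sqrt(nuc.sum() / np.pi)
        else:
            nuc = np.zeros_like(cell)
            r_eq = np.sqrt(cell.sum() / np.pi) / 3.0
        dist = np.hypot(xx - cx, yy - cy)
        peri = cell & (dist <= annulus_factor * r_eq) & ~nuc
    if not peri.any():
        raise DataError("perinuclear region is empty")

    if background_mask is None:
        background_mask = ~ndimage.binary_dilation(cell, iterations=2)
    return RegionPartition(
        cell_mask=cell,
        perinuclear_mask=peri,
        front_mask=front,
        rear_mask=rear,
        background_mask=np.asarray(background_mask, bool) & ~cell,
        migration_axis=(float(ax[0]), float(ax[1])),
    )


def extract_region_series(
    stack: np.ndarray,
    partition: RegionPartition,
    *,
    frame_interval_s: float = 15.0,
    t_conv_s: float = 45.0,
    condition: str = "",
) -> PhotoconversionSeries:
    """Per-region mean intensity per frame from a (T, 2, Y, X) image stack.

    Channel 0 is green, channel 1 red.  Front and rear traces exclude the
    perinuclear overlap, so the three regions measure distinct pools.
    Region means are of raw pixel values; background subtraction happens
    downstream in the ratio statistics.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 4 or arr.shape[1] != 2:
        raise DataError(
            f"stack must have shape (T, 2, Y, X); got {arr.shape}")
    if arr.shape[2:] != partition.cell_mask.shape:
        raise DataError("stack frame geometry does not match partition masks")
    masks = {
        "perinuclear": partition.perinuclear_mask,
        "front": partition.front_mask & ~partition.perinuclear_mask,
        "rear": partition.rear_mask & ~partition.perinuclear_mask,
    }
    for name, m in {**masks, "background": partition.background_mask}.items():
        if not m.any():
            raise DataError(f"region mask {name!r} is empty")
    times = np.arange(arr.shape[0]) * float(frame_interval_s)
    green = {r: arr[:, 0][:, m].mean(axis=1) for r, m in masks.items()}
    red = {r: arr[:, 1][:, m].mean(axis=1) for r, m in masks.items()}
    bg = arr[:, 1][:, partition.background_mask].mean(axis=1)
    return PhotoconversionSeries(
        times_s=times, green=green, red=red, background=bg,
        t_conv_s=t_conv_s, condition=condition)


def _guard_eps(*traces: np.ndarray) -> float:
    rng = max(float(np.ptp(t)) for t in traces)
    return max(EPS_FRACTION * rng, np.finfo(float).tiny)


def green_gain(series: PhotoconversionSeries) -> float:
    """Perinuclear green-fluorescence gain fraction (retrograde transport).

    ``(G(t_end) - G(t_conv)) / (G(t0) - G(t_conv))`` on the
    background-subtracted perinuclear green trace; 1 means full return to
    the pre-conversion green level.
    """
    g = series.corrected("green", "perinuclear")
    i0, ic, ie = (series.index_of(t) for t in
                  (series.t0_s, series.t_conv_s, series.t_end_s))
    denom = g[i0] - g[ic]
    if abs(denom) < _guard_eps(g):
        raise DegenerateConversionError(
            "green perinuclear drop across conversion is below the guard "
            "threshold; conversion failed or wrong t_conv")
    return float((g[ie] - g[ic]) / denom)


def red_loss(series: PhotoconversionSeries) -> float:
    """Perinuclear red-fluorescence loss fraction (anterograde transport).

    ``(R(t_conv) - R(t_end)) / (R(t_conv) - R(t0))`` on the
    background-subtracted perinuclear red trace; 1 means complete efflux of
    the converted pool.
    """
    r = series.corrected("red", "perinuclear")
    i0, ic, ie = (series.index_of(t) for t in
                  (series.t0_s, series.t_conv_s, series.t_end_s))
    denom = r[ic] - r[i0]
    if abs(denom) < _guard_eps(r):
        raise DegenerateConversionError(
            "red perinuclear rise across conversion is below the guard "
            "threshold; conversion failed or wrong t_conv")
    return float((r[ic] - r[ie]) / denom)


def regional_gain_curve(
    series: PhotoconversionSeries,
    region: Literal["front", "rear"],
    channel: Literal["red", "green"] = "red",
) -> np.ndarray:
    """Gain of regional intensity over time, normalized to background at t0.

    ``curve(t) = (FI_region(t) - FI_region(t0)) / background(t0)`` on the
    background-subtracted trace of the converted (red) channel by default.
    """
    if region not in ("front", "rear"):
        raise DataError(f"region must be 'front' or 'rear', got {region!r}")
    trace = series.corrected(channel, region)
    i0 = series.index_of(series.t0_s)
    bg0 = float(series.background[i0])
    if bg0 <= 0:
        raise DataError("background intensity at t0 must be positive")
    return (trace - trace[i0]) / bg0


def front_rear_bias(series: PhotoconversionSeries) -> BiasResult:
    """Front gain / rear gain of the red channel at t_end.

    A value > 1 indicates anterograde (front-directed) polarity.  When both
    gains are indistinguishable from zero the bias is undefined and the
    flag is False.
    """
    front = regional_gain_curve(series, "front")
    rear = regional_gain_curve(series, "rear")
    ie = series.index_of(series.t_end_s)
    f, r = float(front[ie]), float(rear[ie])
    eps = _guard_eps(series.corrected("red", "front"),
                     series.corrected("red", "rear"))
    bg0 = float(series.background[series.index_of(series.t0_s)])
    eps /= bg0
    if abs(f) < eps and abs(r) < eps:
        return BiasResult(float("nan"), False)
    if r == 0.0:
        return BiasResult(float("inf") if f > 0 else float("nan"), f != 0.0)
    return BiasResult(f / r, True)


def summarize_flux(series: PhotoconversionSeries) -> FluxSummary:
    """Compute all flux statistics for one series."""
    gg = green_gain(series)
    rl = red_loss(series)
    bias = front_rear_bias(series)
    clipped = not (0.0 <= gg <= 1.0 and 0.0 <= rl <= 1.0)
    return FluxSummary(
        green_gain_fraction=gg,
        red_loss_fraction=rl,
        front_gain_curve=regional_gain_curve(series, "front"),
        rear_gain_curve=regional_gain_curve(series, "rear"),
        front_rear_bias=bias.value,
        bias_defined=bias.defined,
        clipped=clipped,
        condition=series.condition,
    )


def fit_efflux_rate(series: PhotoconversionSeries) -> float:
    """Total perinuclear efflux rate k_pf + k_pr (1/s) from the red decay.

    Fits ``A * exp(-k (t - t_conv)) + C`` to the background-subtracted
    perinuclear red trace from t_conv onward; the offset C absorbs return
    flux.  Returns k >= 0.
    """
    ic = series.index_of(series.t_conv_s)
    t = series.times_s[ic:] - series.t_conv_s
    y = series.corrected("red", "perinuclear")[ic:]
    if t.size < 3:
        raise DataError("need >= 3 post-conversion frames to fit a decay")
    a0 = max(y[0] - y[-1], _guard_eps(y))
    k0 = 1.0 / max(t[-1], 1.0)

    def model(t, a, k, c):
        return a * np.exp(-k * t) + c

    popt, _ = optimize.curve_fit(
        model, t, y, p0=(a0, k0, y[-1]),
        bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]), maxfev=10000)
    return float(popt[1])
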