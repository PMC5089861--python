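"""Forward-migration-index analysis of gradient migration.

Cells migrating on a substrate-bound ligand gradient (haptotaxis) are
tracked over hours; each track yields a forward migration index

    FMI = (net displacement projected on the gradient axis) / path length,

a number in [-1, 1] that is positive for motion up the gradient.  A
population is called haptotaxing when the mean FMI exceeds 0.1 AND the
Student-t 95% confidence interval of the mean lies entirely above 0; a mean
near 0 with a CI crossing 0 is not haptotaxing.  Cells are the statistical
units (one FMI per cell track).

Rose histograms summarize the angular distribution of origin-aligned track
endpoints.  Group comparisons (t-test / one-way ANOVA) are delegated to
scipy.stats and only surfaced here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DataError
from .tracks import Track, compute_track_metrics

__all__ = [
    "HaptotaxisSummary",
    "GRADIENT_AXIS_Y",
    "compute_fmi",
    "fmi_from_positions",
    "summarize_haptotaxis",
    "rose_histogram",
    "rose_plot",
]

#: simulation convention: gradient increases along +y
GRADIENT_AXIS_Y = (0.0, 1.0)

#: decision threshold on the population mean FMI
FMI_THRESHOLD = 0.1


@dataclass(frozen=True)
class HaptotaxisSummary:
    """Population-level haptotaxis decision record."""

    fmi_values: np.ndarray
    mean_fmi: float
    ci_low: float
    ci_high: float
    mean_velocity_um_min: float
    mean_persistence: float
    is_haptotaxing: bool
    rose_histogram: np.ndarray
    rose_bin_edges_rad: np.ndarray
    n_tracks: int
    n_excluded: int
    condition: str = ""


def _unit_axis(axis: Sequence[float]) -> np.ndarray:
    ax = np.asarray(axis, dtype=float)
    n = np.linalg.norm(ax)
    if ax.shape != (2,) or n == 0 or not np.isfinite(n):
        raise DataError("gradient axis must be a non-zero 2-vector")
    return ax / n


def compute_fmi(track: Track, gradient_axis: Sequence[float] = GRADIENT_AXIS_Y,
                *, denominator: Literal["path", "net"] = "path") -> float:
    """Forward migration index of one track.

    Net displacement projected on the gradient axis, divided by the total
    accumulated path length (default) or, behind the ``denominator="net"``
    flag, by the net displacement magnitude (chemotactic-index variant).
    Zero-path tracks return 0 with a warning.
    """
    ax = _unit_axis(gradient_axis)
    disp = track.positions[-1] - track.positions[0]
    steps = np.diff(track.positions, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    denom = path if denominator == "path" else float(np.linalg.norm(disp))
    if denom == 0.0:
        warnings.warn(f"track {track.id!r} has zero displacement; FMI set to 0",
                      stacklevel=2)
        return 0.0
    return float(np.dot(disp, ax) / denom)


def fmi_from_positions(
    positions: np.ndarray,
    gradient_axis: Sequence[float] = GRADIENT_AXIS_Y,
) -> np.ndarray:
    """Vectorized FMI for a (n_tracks, n_points, 2) position array.

    Same statistic as :func:`compute_fmi` with the path-length denominator;
    zero-path tracks yield 0.  Used for large calibration ensembles where
    building Track objects would dominate the run time.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[-1] != 2 or pos.shape[1] < 2:
        raise DataError("positions must have shape (n_tracks, n_points>=2, 2)")
    ax = _unit_axis(gradient_axis)
    disp = pos[:, -1] - pos[:, 0]
    path = np.linalg.norm(np.diff(pos, axis=1), axis=2).sum(axis=1)
    out = np.zeros(pos.shape[0])
    ok = path > 0
    out[ok] = (disp[ok] @ ax) / path[ok]
    return out


def summarize_haptotaxis(
    tracks: Sequence[Track],
    gradient_axis: Sequence[float] = GRADIENT_AXIS_Y,
    *,
    n_bins: int = 16,
    fmi_threshold: float = FMI_THRESHOLD,
    ci_method: Literal["t", "bootstrap"] = "t",
    n_boot: int = 2000,
    seed: int = 0,
    condition: str = "",
) -> HaptotaxisSummary:
    """Mean FMI with 95% CI, haptotaxis call, motility and rose histogram.

    The haptotaxis call is the conjunction ``mean_fmi > fmi_threshold`` and
    ``ci_low > 0``.  The CI is Student-t over per-track FMI by default; a
    percentile bootstrap is available via ``ci_method="bootstrap"``.
    """
    if len(tracks) < 3:
        raise DataError("need >= 3 tracks for a confidence interval")
    fmi = np.array([compute_fmi(t, gradient_axis) for t in tracks])
    mean = float(fmi.mean())
    sd = float(fmi.std(ddof=1))
    n = fmi.size
    if ci_method == "t":
        if sd == 0.0:
            lo = hi = mean
        else:
            lo, hi = stats.t.interval(0.95, df=n - 1, loc=mean,
                                      scale=sd / np.sqrt(n))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(fmi, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
    else:
        raise DataError(f"unknown ci_method {ci_method!r}")

    metrics = [compute_track_metrics(t) for t in tracks]
    mean_v = float(np.mean([m.net_velocity_um_s for m in metrics])) * 60.0
    mean_p = float(np.mean([m.persistence for m in metrics]))
    weights, edges, n_excl = rose_histogram(tracks, n_bins=n_bins)
    return HaptotaxisSummary(
        fmi_values=fmi,
        mean_fmi=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        mean_velocity_um_min=mean_v,
        mean_persistence=mean_p,
        is_haptotaxing=bool(mean > fmi_threshold and lo > 0.0),
        rose_histogram=weights,
        rose_bin_edges_rad=edges,
        n_tracks=n,
        n_excluded=n_excl,
        condition=condition,
    )


def rose_histogram(
    tracks: Sequence[Track],
    n_bins: int = 16,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Normalized angular histogram of origin-aligned track endpoints.

    Endpoint angles are measured counter-clockwise from +x; bins are
    centered so that the cardinal directions fall at bin centers.  Returns
    ``(weights, bin_edges_rad, n_excluded)``; weights sum to 1 and
    zero-displacement tracks are excluded (counted in ``n_excluded``).
    """
    if n_bins < 4:
        raise DataError("n_bins must be >= 4")
    disp = np.array([t.positions[-1] - t.positions[0] for t in tracks])
    norms = np.linalg.norm(disp, axis=1)
    keep = norms > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise DataError("all tracks have zero net displacement")
    ang = np.arctan2(disp[keep, 1], disp[keep, 0])
    width = 2 * np.pi / n_bins
    edges = -np.pi - width / 2 + width * np.arange(n_bins + 1)
    # wrap angles into [edges[0], edges[-1])
    ang = np.mod(ang - edges[0], 2 * np.pi) + edges[0]
    counts, _ = np.histogram(ang, bins=edges)
    return counts / counts.sum(), edges, n_excluded


def rose_plot(weights: np.ndarray, bin_edges_rad: np.ndarray, ax=None):
    """Polar bar chart of a rose histogram (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = (bin_edges_rad[:-1] + bin_edges_rad[1:]) / 2
    ax.bar(centers, weights, width=np.diff(bin_edges_rad), alpha=0.7,
           edgecolor="k")
    return ax
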