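"""Per-track motility metrics and fast/long-range classification.

A tracked object (vesicle or migrating cell) is reduced to three numbers:

* net displacement ``|r(T) - r(0)|`` (µm),
* path length ``sum_i |r_i+1 - r_i|`` (µm),
* duration ``T`` (s),

from which net velocity = displacement / time and persistence =
displacement / total distance.  Vesicles with net velocity > 4 µm/s *and*
persistence > 0.5 (strict inequalities) are classed as fast long-range,
consistent with processive microtubule-based transport; everything else is
short-range.  Thresholds are exposed as parameters.

The time base is the recorded time column, not frame index x nominal
interval, so tracks with dropped frames are handled correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "Track",
    "TrackMetrics",
    "FAST_LONG_RANGE",
    "SHORT_RANGE",
    "compute_track_metrics",
    "classify_motility",
    "origin_align",
    "summarize_population_motility",
]

FAST_LONG_RANGE = "fast_long_range"
SHORT_RANGE = "short_range"

#: default classification thresholds: net velocity (µm/s) and persistence
DEFAULT_V_THRESHOLD = 4.0
DEFAULT_P_THRESHOLD = 0.5


@dataclass(frozen=True)
class Track:
    """Ordered, timed 2-D positions of one object, in physical units.

    ``times`` are seconds (strictly increasing); ``positions`` is an (n, 2)
    array of (x, y) in µm.  ``class_label`` carries generator ground truth
    when the track is synthetic.
    """

    id: str
    times: np.ndarray
    positions: np.ndarray
    condition: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)
        if t.ndim != 1 or t.size < 2:
            raise DataError(f"track {self.id!r}: needs >= 2 timed points")
        if p.shape != (t.size, 2):
            raise DataError(
                f"track {self.id!r}: positions shape {p.shape} does not match "
                f"{t.size} time points")
        if not (np.isfinite(t).all() and np.isfinite(p).all()):
            raise DataError(f"track {self.id!r}: non-finite coordinates or times")
        if np.any(np.diff(t) <= 0):
            raise DataError(f"track {self.id!r}: times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TrackMetrics:
    """Scalar motility summary of one track."""

    track_id: str
    net_displacement_um: float
    path_length_um: float
    duration_s: float
    net_velocity_um_s: float
    persistence: float
    motility_class: str
    condition: str = ""


def compute_track_metrics(
    track: Track,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> TrackMetrics:
    """Net displacement, path length, net velocity, persistence and class.

    Persistence of a zero-path-length (stationary) track is defined as 0 so
    population summaries stay finite; a warning is emitted.
    """
    steps = np.diff(track.positions, axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    duration = float(track.times[-1] - track.times[0])
    if duration <= 0:
        raise DataError(f"track {track.id!r}: zero duration")
    if path == 0.0:
        warnings.warn(
            f"track {track.id!r} has zero path length; persistence set to 0",
            stacklevel=2)
        persistence = 0.0
    else:
        persistence = net / path
    velocity = net / duration
    cls = classify_motility(velocity, persistence, v_threshold, p_threshold)
    return TrackMetrics(
        track_id=track.id,
        net_displacement_um=net,
        path_length_um=path,
        duration_s=duration,
        net_velocity_um_s=velocity,
        persistence=persistence,
        motility_class=cls,
        condition=track.condition,
    )


def classify_motility(
    net_velocity_um_s: float,
    persistence: float,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> str:
    """Fast long-range iff velocity > v_threshold AND persistence > p_threshold.

    Both inequalities are strict: a track sitting exactly on a threshold is
    short-range.
    """
    if v_threshold <= 0 or p_threshold <= 0:
        raise DataError("classification thresholds must be positive")
    if net_velocity_um_s > v_threshold and persistence > p_threshold:
        return FAST_LONG_RANGE
    return SHORT_RANGE


def origin_align(tracks: Iterable[Track]) -> list[Track]:
    """Translate each track so its first position is (0, 0).

    All motility metrics are translation-invariant, so this only affects
    plotting (tracks drawn from a common origin).
    """
    out = []
    for tr in tracks:
        shifted = tr.positions - tr.positions[0]
        out.append(replace(tr, positions=shifted))
    return out


def summarize_population_motility(
    tracks: Sequence[Track],
    v_threshold: float = DEFAULT_V_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Per-condition mean +- SD of velocity and persistence, class fractions.

    Returns a DataFrame keyed by condition with columns ``n``,
    ``velocity_mean``, ``velocity_sd``, ``persistence_mean``,
    ``persistence_sd``, ``frac_fast_long_range``, ``frac_short_range``.
    Class fractions sum to 1 within each condition.
    """
    if not tracks:
        raise DataError("no tracks supplied")
    rows = [compute_track_metrics(t, v_threshold, p_threshold) for t in tracks]
    df = pd.DataFrame([vars(m) for m in rows])
    records = []
    for cond, grp in df.groupby("condition", sort=True):
        n = len(grp)
        records.append({
            "condition": cond,
            "n": n,
            "velocity_mean": grp["net_velocity_um_s"].mean(),
            "velocity_sd": grp["net_velocity_um_s"].std(ddof=1) if n > 1 else 0.0,
            "persistence_mean": grp["persistence"].mean(),
            "persistence_sd": grp["persistence"].std(ddof=1) if n > 1 else 0.0,
            "frac_fast_long_range": (grp["motility_class"] == FAST_LONG_RANGE).mean(),
            "frac_short_range": (grp["motility_class"] == SHORT_RANGE).mean(),
        })
    return pd.DataFrame.from_records(records).set_index("condition")


def metrics_frame(tracks: Sequence[Track], **kw) -> pd.DataFrame:
    """Per-track metrics as a tidy DataFrame (one row per track)."""
    return pd.DataFrame([vars(compute_track_metrics(t, **kw)) for t in tracks])
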