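"""Readers and writers for the package's plain-data formats.

Conventions (enforced here, assumed everywhere else):

* image arrays are indexed (row, col), 0-based; physical coordinates are
  (x, y) in µm with x = col * pixel_size and y = row * pixel_size;
* CSV files are comma-separated UTF-8 with '.' decimal and a header row;
* track tables carry columns track_id, frame, time_s, x_um, y_um and
  optionally condition and class_label;
* tidy intensity series carry (time_s, region, channel, intensity) for
  photoconversion and (time_min, compartment, intensity, condition) for
  recycling.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .colocalization import SpotField
from .errors import DataError
from .photoconversion import REGIONS, PhotoconversionSeries
from .recycling import RecyclingSeries
from .tracks import Track

__all__ = [
    "read_tracks", "write_tracks",
    "read_stack", "write_stack",
    "read_photoconversion_series", "write_photoconversion_series",
    "read_recycling_series", "write_recycling_series",
    "read_spots", "write_spots",
]

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um"]


def write_tracks(tracks: Iterable[Track], path) -> None:
    """Write tracks to CSV (one row per point)."""
    rows = []
    for tr in tracks:
        for f, (t, (x, y)) in enumerate(zip(tr.times, tr.positions)):
            rows.append({
                "track_id": tr.id, "frame": f, "time_s": t,
                "x_um": x, "y_um": y, "condition": tr.condition,
                "class_label": tr.class_label if tr.class_label is not None else "",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    """Read a track table; malformed rows are reported with line numbers."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    bad = df[TRACK_COLUMNS[1:]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise DataError(f"{path}: missing values on line(s) {lines[:20]}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        times = grp["time_s"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise DataError(
                f"{path}: non-monotone times in track {tid!r}")
        cond = str(grp["condition"].iloc[0]) if "condition" in grp else ""
        label = None
        if "class_label" in grp:
            raw = grp["class_label"].iloc[0]
            if isinstance(raw, str) and raw:
                label = raw
        tracks.append(Track(
            id=str(tid), times=times,
            positions=grp[["x_um", "y_um"]].to_numpy(float),
            condition=cond, class_label=label))
    if not tracks:
        raise DataError(f"{path}: no tracks found")
    return tracks


def write_stack(path, stack: np.ndarray, pixel_size_um: float,
                frame_interval_s: float | None = None) -> None:
    """Write an image stack as ImageJ-style TIFF with physical metadata."""
    arr = np.asarray(stack)
    meta = {"unit": "um"}
    if frame_interval_s is not None:
        meta["finterval"] = float(frame_interval_s)
    tifffile.imwrite(
        path, arr.astype(np.float32), imagej=True,
        resolution=(1.0 / pixel_size_um, 1.0 / pixel_size_um),
        metadata=meta)


def read_stack(path, *, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None):
    """Read a TIFF stack; returns (array, pixel_size_um, frame_interval_s).

    Metadata missing from the file falls back to the supplied values with
    a warning; if neither is available the value is None.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        px = None
        dt = None
        try:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            # a resolution without a unit is tifffile's placeholder, not
            # real calibration
            has_unit = unit is not None and getattr(unit.value, "name", "") != "NONE"
            if xres is not None and (has_unit or tf.imagej_metadata):
                num, den = xres.value
                if num:
                    px = den / num
        except (KeyError, AttributeError, ZeroDivisionError):
            px = None
        ij = tf.imagej_metadata or {}
        if "finterval" in ij:
            dt = float(ij["finterval"])
    if px is None:
        if pixel_size_um is not None:
            warnings.warn(f"{path}: no pixel size in file; using configured "
                          f"{pixel_size_um} um", stacklevel=2)
        px = pixel_size_um
    if dt is None and frame_interval_s is not None:
        warnings.warn(f"{path}: no frame interval in file; using configured "
                      f"{frame_interval_s} s", stacklevel=2)
        dt = frame_interval_s
    return arr, px, dt


def write_photoconversion_series(series: PhotoconversionSeries, path) -> None:
    rows = []
    for i, t in enumerate(series.times_s):
        for reg in REGIONS:
            rows.append({"time_s": t, "region": reg, "channel": "green",
                         "intensity": series.green[reg][i]})
            rows.append({"time_s": t, "region": reg, "channel": "red",
                         "intensity": series.red[reg][i]})
        rows.append({"time_s": t, "region": "background", "channel": "mean",
                     "intensity": series.background[i]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_photoconversion_series(path, *, t_conv_s: float = 45.0,
                                condition: str = "") -> PhotoconversionSeries:
    df = pd.read_csv(path)
    need = {"time_s", "region", "channel", "intensity"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: expected columns {sorted(need)}")
    times = np.sort(df["time_s"].unique())

    def trace(region, channel):
        sub = df[(df["region"] == region) & (df["channel"] == channel)]
        sub = sub.sort_values("time_s")
        if len(sub) != times.size:
            raise DataError(f"{path}: incomplete trace for {region}/{channel}")
        return sub["intensity"].to_numpy(float)

    return PhotoconversionSeries(
        times_s=times,
        green={r: trace(r, "green") for r in REGIONS},
        red={r: trace(r, "red") for r in REGIONS},
        background=trace("background", "mean"),
        t_conv_s=t_conv_s, condition=condition)


def write_recycling_series(series: RecyclingSeries, path) -> None:
    rows = []
    for i, t in enumerate(series.times_min):
        rows.append({"time_min": t, "compartment": "membrane",
                     "intensity": series.membrane_FI[i],
                     "condition": series.condition})
        rows.append({"time_min": t, "compartment": "cytoplasm",
                     "intensity": series.cytoplasm_FI[i],
                     "condition": series.condition})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_recycling_series(path) -> RecyclingSeries:
    df = pd.read_csv(path)
    need = {"time_min", "compartment", "intensity"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: expected columns {sorted(need)}")
    times = np.sort(df["time_min"].unique())

    def trace(comp):
        sub = df[df["compartment"] == comp].sort_values("time_min")
        if len(sub) != times.size:
            raise DataError(f"{path}: incomplete {comp} trace")
        return sub["intensity"].to_numpy(float)

    cond = str(df["condition"].iloc[0]) if "condition" in df.columns else ""
    return RecyclingSeries(times_min=times, membrane_FI=trace("membrane"),
                           cytoplasm_FI=trace("cytoplasm"), condition=cond)


def write_spots(field: SpotField, path) -> None:
    df = pd.DataFrame({
        "channel": field.channel,
        "x_um": field.xy[:, 0],
        "y_um": field.xy[:, 1],
    })
    if field.intensities is not None:
        df["intensity"] = field.intensities
    df.to_csv(path, index=False)


def read_spots(path, field_um: float | None = None) -> SpotField:
    df = pd.read_csv(path)
    need = {"channel", "x_um", "y_um"}
    if not need <= set(df.columns):
        raise DataError(f"{path}: expected columns {sorted(need)}")
    channel = str(df["channel"].iloc[0]) if len(df) else ""
    inten = df["intensity"].to_numpy(float) if "intensity" in df.columns else None
    return SpotField(channel=channel,
                     xy=df[["x_um", "y_um"]].to_numpy(float),
                     field_um=field_um, intensities=inten)
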