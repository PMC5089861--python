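"""Object-based colocalization and pixel-based Pearson correlation.

Two complementary readouts of co-occurrence between fluorescence channels:

* object-based: the fraction of spots (vesicle puncta) in one channel that
  have at least one spot of the other channel within a match radius
  ("double-positive" fraction), computed in both directions;
* pixel-based: the Pearson product-moment correlation of the two intensity
  images over a mask (cell mask, to avoid background-driven inflation).

Matching is many-to-one by default — one channel-B spot may validate
several channel-A spots — which matches the double-positive-vesicle
counting convention; a stricter one-to-one assignment mode is available.
No chance-colocalization correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree
from skimage.feature import blob_log

from .errors import DataError

__all__ = [
    "SpotField",
    "ColocResult",
    "DEFAULT_MATCH_RADIUS_UM",
    "detect_spots",
    "match_spots",
    "pearson_coefficient",
]

#: default spot match radius (µm), of the order of a vesicle radius
DEFAULT_MATCH_RADIUS_UM = 0.5


@dataclass(frozen=True)
class SpotField:
    """Point set for one channel: (n, 2) array of (x, y) in µm."""

    channel: str
    xy: np.ndarray
    field_um: float | None = None
    intensities: np.ndarray | None = None
    pair_index: np.ndarray | None = None  # generator ground truth, -1 = unpaired

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "xy", xy)
        if xy.size and not np.isfinite(xy).all():
            raise DataError(f"channel {self.channel!r}: non-finite coordinates")
        if self.intensities is not None:
            inten = np.asarray(self.intensities, dtype=float)
            object.__setattr__(self, "intensities", inten)
            if inten.shape != (xy.shape[0],):
                raise DataError("intensities length does not match spot count")

    @property
    def n(self) -> int:
        return int(self.xy.shape[0])


@dataclass(frozen=True)
class ColocResult:
    """Double-positive fractions in both directions.

    Fractions are NaN with ``defined_* = False`` when the corresponding
    channel is empty (undefined, not zero).
    """

    frac_A_with_B: float
    frac_B_with_A: float
    n_A: int
    n_B: int
    match_radius_um: float
    defined_A: bool
    defined_B: bool
    pearson_r: float | None = None


def detect_spots(
    image: np.ndarray,
    pixel_size_um: float,
    *,
    min_sigma: float = 1.0,
    max_sigma: float = 4.0,
    threshold: float = 0.1,
    channel: str = "",
) -> SpotField:
    """Laplacian-of-Gaussian blob detection; centers returned in µm.

    Sigmas and threshold are in pixel/intensity units of the normalized
    image (scaled to [0, 1] by its max).  Deterministic for fixed input.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DataError("detect_spots expects a single-channel 2-D image")
    if pixel_size_um <= 0:
        raise DataError("pixel_size_um must be positive")
    if min_sigma <= 0 or max_sigma <= 0 or max_sigma < min_sigma:
        raise DataError("sigmas must be positive with max_sigma >= min_sigma")
    peak = img.max()
    if peak <= 0:
        return SpotField(channel=channel, xy=np.empty((0, 2)))
    norm = (img - img.min()) / (peak - img.min())
    blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma,
                     threshold=threshold)
    if blobs.size == 0:
        return SpotField(channel=channel, xy=np.empty((0, 2)))
    # blob_log returns (row, col, sigma); convert to (x, y) µm
    xy = np.column_stack([blobs[:, 1], blobs[:, 0]]) * pixel_size_um
    return SpotField(channel=channel, xy=xy)


def _directional_fraction(src: np.ndarray, ref: np.ndarray, radius: float) -> float:
    tree = cKDTree(ref)
    d, _ = tree.query(src, k=1)
    return float(np.mean(d <= radius))


def match_spots(
    a: SpotField,
    b: SpotField,
    radius: float = DEFAULT_MATCH_RADIUS_UM,
    *,
    mode: Literal["many_to_one", "one_to_one"] = "many_to_one",
) -> ColocResult:
    """Double-positive fractions of two spot fields at a match radius.

    ``frac_A_with_B`` = share of A spots with >= 1 B spot within ``radius``
    (and symmetrically).  In ``one_to_one`` mode each B spot may validate at
    most one A spot (minimum-cost assignment), so both directional counts
    equal the number of matched pairs.
    """
    if radius <= 0:
        raise DataError("match radius must be positive")
    if a.n == 0 and b.n == 0:
        raise DataError("both spot fields are empty; colocalization undefined")
    if a.n == 0 or b.n == 0:
        # a fraction with an empty denominator channel, or no partner
        # channel to match against, is undefined — flagged, not zero
        return ColocResult(math.nan, math.nan, a.n, b.n, radius,
                           defined_A=False, defined_B=False)
    if mode == "many_to_one":
        fa = _directional_fraction(a.xy, b.xy, radius)
        fb = _directional_fraction(b.xy, a.xy, radius)
    elif mode == "one_to_one":
        d = np.linalg.norm(a.xy[:, None, :] - b.xy[None, :, :], axis=2)
        cost = np.where(d <= radius, d, 1e9)
        ri, ci = optimize.linear_sum_assignment(cost)
        n_pairs = int(np.sum(d[ri, ci] <= radius))
        fa, fb = n_pairs / a.n, n_pairs / b.n
    else:
        raise DataError(f"unknown matching mode {mode!r}")
    return ColocResult(fa, fb, a.n, b.n, radius, defined_A=True, defined_B=True)


def pearson_coefficient(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson product-moment correlation of two images over a mask."""
    x = np.asarray(img_a, dtype=float)
    y = np.asarray(img_b, dtype=float)
    if x.shape != y.shape:
        raise DataError("images must share a shape")
    if mask is not None:
        m = np.asarray(mask, bool)
        if m.shape != x.shape:
            raise DataError("mask shape does not match images")
        x, y = x[m], y[m]
    else:
        x, y = x.ravel(), y.ravel()
    if x.size < 2:
        raise DataError("need >= 2 pixels to correlate")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance in one channel; Pearson undefined")
    return float(np.corrcoef(x, y)[0, 1])
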