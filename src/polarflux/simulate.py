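"""Synthetic microscopy-derived inputs with known ground truth.

Every analysis stage in this package can be exercised without microscopy
data: the generators here produce vesicle tracks, photoconversion intensity
series, paired spot fields (and rendered two-channel images), recycling
curves and 24-h migration tracks whose generating parameters are recorded,
so each statistic the pipeline computes has a known expected value.

Models
------
* Vesicle tracks: a two-population mixture of ballistic runs (constant
  speed, random direction, small Gaussian positional jitter) and isotropic
  Brownian motion — the minimal mixture that separates fast long-range from
  short-range motility.
* Photoconversion: three well-mixed compartments (perinuclear P, front F,
  rear R) with first-order exchange,

      dP/dt = -(k_pf + k_pr) P + k_fp F + k_rp R
      dF/dt = k_pf P - k_fp F
      dR/dt = k_pr P - k_rp R

  applied independently to the green and red species; at the conversion
  frame a fraction ``conversion_efficiency`` of green P becomes red P.
  Propagation uses the matrix exponential, which is exact for this linear
  system and conserves total mass per species.
* Spot fields: each channel-A spot is paired to a random channel-B spot
  (within Gaussian jitter) with probability ``overlap_fraction``, otherwise
  placed uniformly but rejected near any B spot, so the expected measured
  co-fraction equals ``overlap_fraction``.
* Recycling: single-exponential cytoplasm -> membrane transfer.
* Migration: a biased persistent random walk — heading diffuses with sd
  ``heading_sd_rad`` per step and each step is
  ``v*dt*(heading_unit + drift_fraction * gradient_unit)`` with the gradient
  along +y; for isotropic initial headings the ensemble-mean FMI is
  approximately ``drift / sqrt(1 + drift^2)``.

All randomness derives from ``SimConfig.seed`` through named child streams,
so identical configs give bit-identical output.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .colocalization import SpotField
from .config import SimConfig
from .errors import ConfigurationError, DataError
from .photoconversion import PhotoconversionSeries, RegionPartition
from .recycling import RecyclingSeries
from .tracks import Track

__all__ = [
    "gen_vesicle_tracks",
    "gen_photoconversion_series",
    "gen_spot_fields",
    "render_spot_images",
    "render_photoconversion_stack",
    "gen_recycling_series",
    "gen_haptotaxis_tracks",
    "haptotaxis_positions",
    "PHOTOCONV_T_CONV_S",
    "PHOTOCONV_T_END_S",
]

PHOTOCONV_FRAME_S = 15.0
PHOTOCONV_T_CONV_S = 45.0
PHOTOCONV_T_END_S = 960.0


# ---------------------------------------------------------------- vesicles

def gen_vesicle_tracks(
    config: SimConfig,
    n_tracks: int,
    condition: str = "simulated",
) -> list[Track]:
    """Mixture of ballistic and diffusive vesicle tracks.

    The first ``round(directed_fraction * n_tracks)`` tracks are ballistic
    at ``directed_speed_um_s`` with per-point Gaussian jitter
    ``jitter_sd_um``; the rest are isotropic Brownian motion with
    coefficient ``diffusion_um2_s``.  ``class_label`` records the
    ground-truth class ("directed" / "diffusive").
    """
    if n_tracks < 1:
        raise ConfigurationError(f"n_tracks must be >= 1 (got {n_tracks})")
    rng = config.rng("vesicle")
    dt = config.frame_interval_s
    nf = config.n_frames
    times = np.arange(nf) * dt
    n_directed = int(round(config.directed_fraction * n_tracks))
    tracks: list[Track] = []
    for i in range(n_tracks):
        start = rng.uniform(0.0, 50.0, size=2)
        if i < n_directed:
            theta = rng.uniform(0.0, 2 * np.pi)
            u = np.array([np.cos(theta), np.sin(theta)])
            pos = start + np.outer(times, u) * config.directed_speed_um_s
            if config.jitter_sd_um > 0:
                pos = pos + rng.normal(0.0, config.jitter_sd_um, size=pos.shape)
            label = "directed"
        else:
            step_sd = np.sqrt(2.0 * config.diffusion_um2_s * dt)
            steps = rng.normal(0.0, step_sd, size=(nf - 1, 2))
            pos = start + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            label = "diffusive"
        tracks.append(Track(id=f"ves_{i:04d}", times=times, positions=pos,
                            condition=condition, class_label=label))
    return tracks


# --------------------------------------------------------- photoconversion

def _exchange_matrix(config: SimConfig) -> np.ndarray:
    return np.array([
        [-(config.k_pf + config.k_pr), config.k_fp, config.k_rp],
        [config.k_pf, -config.k_fp, 0.0],
        [config.k_pr, 0.0, -config.k_rp],
    ])


def initial_green_pools(config: SimConfig) -> np.ndarray:
    """Initial green amounts (P, F, R) used by the photoconversion generator.

    Cells are imaged at baseline, so the green species starts at the
    stationary distribution of the exchange matrix (scaled so the
    perinuclear pool equals ``initial_intensity``), making the
    pre-conversion traces flat.  When no strictly positive stationary
    distribution exists (degenerate rate sets such as absorbing or
    all-zero exchange) the explicit pools (``initial_intensity`` in P,
    ``peripheral_fraction`` of it in each of F and R) are used instead.
    """
    from scipy.linalg import null_space

    ns = null_space(_exchange_matrix(config))
    if ns.shape[1] == 1:
        v = ns[:, 0]
        v = v * np.sign(v[np.argmax(np.abs(v))])
        if np.all(v > 1e-12):
            return v / v[0] * config.initial_intensity
    i0 = config.initial_intensity
    return np.array([i0, config.peripheral_fraction * i0,
                     config.peripheral_fraction * i0])


def gen_photoconversion_series(
    config: SimConfig,
    condition: str = "simulated",
) -> PhotoconversionSeries:
    """Green/red region-intensity series around a perinuclear conversion.

    The time grid is 0..960 s at 15 s spacing.  The green pools start as
    given by :func:`initial_green_pools` (exchange steady state when it
    exists); red starts empty.  At t = 45 s (instantaneous, recorded
    post-conversion) a fraction ``conversion_efficiency`` of green P moves
    to red P.  Observed intensity = compartment amount + background +
    Gaussian noise; the background trace is background + noise.
    """
    rng = config.rng("photoconversion")
    times = np.arange(0.0, PHOTOCONV_T_END_S + PHOTOCONV_FRAME_S / 2,
                      PHOTOCONV_FRAME_S)
    n = times.size
    step = expm(_exchange_matrix(config) * PHOTOCONV_FRAME_S)
    green = np.empty((n, 3))
    red = np.empty((n, 3))
    g = initial_green_pools(config)
    r = np.zeros(3)
    conv_idx = int(round(PHOTOCONV_T_CONV_S / PHOTOCONV_FRAME_S))
    for i in range(n):
        if i > 0:
            g = step @ g
            r = step @ r
        if i == conv_idx:
            moved = config.conversion_efficiency * g[0]
            r = r.copy()
            g = g.copy()
            r[0] += moved
            g[0] -= moved
        green[i] = g
        red[i] = r

    def observe(amounts):
        obs = amounts + config.background_level
        if config.noise_sd > 0:
            obs = obs + rng.normal(0.0, config.noise_sd, size=obs.shape)
        return obs

    g_obs = observe(green)
    r_obs = observe(red)
    bg = np.full(n, config.background_level)
    if config.noise_sd > 0:
        bg = bg + rng.normal(0.0, config.noise_sd, size=n)
    regions = ("perinuclear", "front", "rear")
    return PhotoconversionSeries(
        times_s=times,
        green={reg: g_obs[:, j] for j, reg in enumerate(regions)},
        red={reg: r_obs[:, j] for j, reg in enumerate(regions)},
        background=bg,
        t_conv_s=PHOTOCONV_T_CONV_S,
        condition=condition,
    )


def render_photoconversion_stack(
    series: PhotoconversionSeries,
    partition: RegionPartition,
) -> np.ndarray:
    """Paint a series onto region masks as a (T, 2, Y, X) image stack.

    Each region's pixels carry that region's trace value; everything
    outside the analysis regions carries the background trace.  Region
    means of the result reproduce the series exactly.
    """
    n = series.times_s.size
    shape = partition.cell_mask.shape
    stack = np.empty((n, 2, *shape))
    masks = {
        "perinuclear": partition.perinuclear_mask,
        "front": partition.front_mask & ~partition.perinuclear_mask,
        "rear": partition.rear_mask & ~partition.perinuclear_mask,
    }
    for i in range(n):
        for c, ch in enumerate((series.green, series.red)):
            frame = np.full(shape, series.background[i])
            # perinuclear painted last so it wins where it overlaps a half
            for reg in ("front", "rear", "perinuclear"):
                frame[masks[reg] if reg != "perinuclear"
                      else partition.perinuclear_mask] = ch[reg][i]
            stack[i, c] = frame
    return stack


# ------------------------------------------------------------- spot fields

def gen_spot_fields(
    config: SimConfig,
    n_a: int,
    n_b: int,
    field_um: float,
) -> tuple[SpotField, SpotField]:
    """Paired spot fields with controllable co-occurrence.

    Channel-B spots are uniform in the square field.  Each channel-A spot
    is, with probability ``overlap_fraction``, placed within Gaussian
    jitter (``jitter_sd_um``) of a random B spot; otherwise it is placed
    uniformly, rejecting positions within ``min_separation_um`` of any B
    spot.  ``pair_index`` records the ground-truth pairing (-1 = unpaired).
    """
    if n_a < 0 or n_b < 0:
        raise ConfigurationError("spot counts must be non-negative")
    if field_um <= 0:
        raise ConfigurationError(f"field_um must be > 0 (got {field_um})")
    rng = config.rng("spots")
    b_xy = rng.uniform(0.0, field_um, size=(n_b, 2))
    a_xy = np.empty((n_a, 2))
    pair = np.full(n_a, -1, dtype=int)
    paired = rng.random(n_a) < config.overlap_fraction
    from scipy.spatial import cKDTree
    tree = cKDTree(b_xy) if n_b else None
    for i in range(n_a):
        if paired[i] and n_b:
            j = int(rng.integers(n_b))
            for _ in range(100):
                cand = b_xy[j] + rng.normal(0.0, config.jitter_sd_um, size=2)
                if np.all((cand >= 0) & (cand <= field_um)):
                    break
            else:
                cand = np.clip(b_xy[j], 0.0, field_um)
            a_xy[i] = cand
            pair[i] = j
        else:
            for _ in range(1000):
                cand = rng.uniform(0.0, field_um, size=2)
                if tree is None or tree.query(cand)[0] > config.min_separation_um:
                    a_xy[i] = cand
                    break
            else:
                raise DataError(
                    "field too small to place unpaired spots outside the "
                    f"{config.min_separation_um} um exclusion zone of "
                    f"{n_b} B spots")
    a = SpotField(channel="A", xy=a_xy, field_um=field_um, pair_index=pair)
    b = SpotField(channel="B", xy=b_xy, field_um=field_um)
    return a, b


def render_spot_images(
    fields: tuple[SpotField, SpotField],
    config: SimConfig,
) -> np.ndarray:
    """Render a spot-field pair as a (2, Y, X) image with Poisson noise.

    Each spot becomes a 2-D Gaussian of sigma ``psf_sigma_um`` and peak
    amplitude ``spot_intensity`` on a constant background; Poisson shot
    noise is applied to the whole image.  Raises if any spot lies outside
    the field, listing the offenders.
    """
    a, b = fields
    if a.field_um is None or b.field_um is None or a.field_um != b.field_um:
        raise DataError("both spot fields must carry the same field_um")
    field = float(a.field_um)
    px = config.pixel_size_um
    npx = int(np.ceil(field / px))
    rng = config.rng("render")
    sigma_px = config.psf_sigma_um / px
    out = np.empty((2, npx, npx))
    for c, f in enumerate((a, b)):
        bad = [i for i, (x, y) in enumerate(f.xy)
               if not (0 <= x <= field and 0 <= y <= field)]
        if bad:
            raise DataError(
                f"channel {f.channel!r}: spots outside the field: {bad}")
        img = np.full((npx, npx), config.background_level)
        half = int(np.ceil(4 * sigma_px)) + 1
        for x, y in f.xy:
            cx, cy = x / px, y / px
            x0, x1 = max(0, int(cx) - half), min(npx, int(cx) + half + 1)
            y0, y1 = max(0, int(cy) - half), min(npx, int(cy) + half + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            img[y0:y1, x0:x1] += config.spot_intensity * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px ** 2))
        out[c] = rng.poisson(img)
    return out


# --------------------------------------------------------------- recycling

def gen_recycling_series(
    config: SimConfig,
    times_min,
    condition: str = "simulated",
) -> RecyclingSeries:
    """Single-exponential recycling curves at the requested time points.

    cytoplasm(t) = FI0 * exp(-k t); membrane(t) = FI0 * (1 - exp(-k t)) plus
    Gaussian noise of sd ``noise_sd`` (membrane only, floored at 0).  The
    closed form holds exactly when ``noise_sd = 0``.
    """
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or not np.isclose(t, 0.0).any():
        raise DataError("times_min must be 1-D and include 0")
    rng = config.rng("recycling")
    k = config.recycling_rate_per_min
    fi0 = config.initial_intensity
    cyto = fi0 * np.exp(-k * t)
    mem = fi0 * (1.0 - np.exp(-k * t))
    if config.noise_sd > 0:
        mem = np.maximum(mem + rng.normal(0.0, config.noise_sd, size=t.size), 0.0)
    return RecyclingSeries(times_min=t, membrane_FI=mem, cytoplasm_FI=cyto,
                           condition=condition)


# -------------------------------------------------------------- haptotaxis

def haptotaxis_positions(
    config: SimConfig,
    n_tracks: int,
    n_steps: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Biased persistent random-walk positions, shape (n_tracks, n_steps+1, 2).

    Vectorized core of :func:`gen_haptotaxis_tracks`; tracks start at the
    origin with isotropic initial headings.  Pass an explicit ``rng`` to
    draw several populations from one stream.
    """
    if n_tracks < 1 or n_steps < 1:
        raise ConfigurationError("n_tracks and n_steps must be >= 1")
    if rng is None:
        rng = config.rng("haptotaxis")
    dt = config.migration_step_min
    theta0 = rng.uniform(-np.pi, np.pi, size=(n_tracks, 1))
    dtheta = rng.normal(0.0, config.heading_sd_rad, size=(n_tracks, n_steps))
    theta = theta0 + np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(dtheta, axis=1)[:, :-1]], axis=1)
    step_len = config.migration_speed_um_min * dt
    steps = step_len * np.stack(
        [np.cos(theta), np.sin(theta) + config.drift_fraction], axis=-1)
    pos = np.concatenate(
        [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    return pos


def gen_haptotaxis_tracks(
    config: SimConfig,
    n_tracks: int,
    duration_hr: float = 24.0,
    condition: str = "simulated",
) -> list[Track]:
    """Origin-anchored migration tracks on a +y ligand gradient.

    Duration must be divisible by ``migration_step_min``; the default
    24 h at 15-min steps gives 96 steps per track.
    """
    n_steps_f = duration_hr * 60.0 / config.migration_step_min
    if abs(n_steps_f - round(n_steps_f)) > 1e-9:
        raise ConfigurationError(
            f"duration_hr = {duration_hr} is not divisible by "
            f"migration_step_min = {config.migration_step_min}")
    n_steps = int(round(n_steps_f))
    pos = haptotaxis_positions(config, n_tracks, n_steps)
    times = np.arange(n_steps + 1) * config.migration_step_min * 60.0
    return [Track(id=f"cell_{i:04d}", times=times, positions=pos[i],
                  condition=condition, class_label=None)
            for i in range(n_tracks)]
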