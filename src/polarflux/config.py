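"""Simulation configuration.

All synthetic-data generators draw their parameters from a single
:class:`SimConfig`.  Every source of randomness flows from the explicit
``seed``; sub-generators derive independent child streams deterministically
(seed sequence spawned with a per-generator salt), so identical configs give
bit-identical output.

Default cadences follow the imaging protocols the statistics were designed
for: vesicle movies at 1 frame / 2 s for 60 frames, photoconversion movies at
1 frame / 15 s over 16 min, cell-migration tracking at 15-min steps over
24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = ["SimConfig", "load_sim_config"]


# per-generator salts for independent child RNG streams
_SALTS = {
    "vesicle": 11,
    "photoconversion": 23,
    "spots": 37,
    "render": 41,
    "recycling": 53,
    "haptotaxis": 67,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic microscopy-data generators.

    Parameters
    ----------
    seed
        Base seed for all randomness; required, no hidden global state.
    frame_interval_s, n_frames
        Vesicle-movie cadence (default 2 s x 60 frames).
    pixel_size_um
        Physical pixel size for rendered images (µm/pixel).
    directed_speed_um_s, directed_fraction, diffusion_um2_s, jitter_sd_um
        Vesicle-track mixture: a fraction ``directed_fraction`` of tracks is
        ballistic at ``directed_speed_um_s`` with Gaussian positional jitter
        ``jitter_sd_um``; the rest diffuse isotropically with coefficient
        ``diffusion_um2_s``.
    conversion_efficiency
        Fraction of the green perinuclear pool converted to red at the
        photoconversion frame (~0.7 for mMaple3-style probes).
    k_pf, k_pr, k_fp, k_rp
        Perinuclear<->front / perinuclear<->rear first-order exchange rates
        (1/s) of the three-compartment transport model.
    noise_sd, background_level
        Additive Gaussian intensity noise and constant background offset of
        the observed fluorescence traces.
    overlap_fraction, min_separation_um
        Spot-field co-occurrence: probability that a channel-A spot is paired
        to a channel-B spot; unpaired spots are rejected within
        ``min_separation_um`` of any B spot.
    psf_sigma_um, spot_intensity
        Gaussian point-spread sigma and peak amplitude used when rendering
        spot fields to images.
    recycling_rate_per_min
        Single-exponential cytoplasm->membrane transfer rate (1/min); the
        default gives ~60% recycled at 60 min.
    migration_speed_um_min, heading_sd_rad, drift_fraction, migration_step_min
        Biased persistent random walk for cell migration: heading diffuses
        with sd ``heading_sd_rad`` per step, step vector is
        ``v*dt*(heading_unit + drift_fraction*gradient_unit)`` with the
        gradient along +y.
    initial_intensity, peripheral_fraction
        Initial fluorescence pools: perinuclear pool (and recycling
        cytoplasm) start at ``initial_intensity``; front and rear each start
        at ``peripheral_fraction`` of it.
    """

    seed: int
    frame_interval_s: float = 2.0
    n_frames: int = 60
    pixel_size_um: float = 0.1
    directed_speed_um_s: float = 5.0
    directed_fraction: float = 0.3
    diffusion_um2_s: float = 0.05
    conversion_efficiency: float = 0.7
    k_pf: float = 8e-4
    k_pr: float = 4e-4
    k_fp: float = 3e-4
    k_rp: float = 3e-4
    noise_sd: float = 1.0
    background_level: float = 10.0
    overlap_fraction: float = 0.7
    jitter_sd_um: float = 0.1
    min_separation_um: float = 1.0
    psf_sigma_um: float = 0.15
    spot_intensity: float = 200.0
    recycling_rate_per_min: float = 0.0153
    migration_speed_um_min: float = 0.5
    heading_sd_rad: float = 0.8
    drift_fraction: float = 0.2
    migration_step_min: float = 15.0
    initial_intensity: float = 100.0
    peripheral_fraction: float = 0.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer (got %r)" % (self.seed,))
        nonneg = [
            "frame_interval_s", "pixel_size_um", "directed_speed_um_s",
            "diffusion_um2_s", "k_pf", "k_pr", "k_fp", "k_rp", "noise_sd",
            "background_level", "jitter_sd_um", "min_separation_um",
            "psf_sigma_um", "spot_intensity", "recycling_rate_per_min",
            "migration_speed_um_min", "heading_sd_rad", "drift_fraction",
            "migration_step_min", "initial_intensity",
        ]
        for name in nonneg:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0 (got {v!r})")
        for name in ("directed_fraction", "conversion_efficiency",
                     "overlap_fraction", "peripheral_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1] (got {v!r})")
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2 (got {self.n_frames!r})")
        if self.frame_interval_s <= 0:
            raise ConfigurationError(
                f"frame_interval_s must be > 0 (got {self.frame_interval_s!r})")
        if self.pixel_size_um <= 0:
            raise ConfigurationError(
                f"pixel_size_um must be > 0 (got {self.pixel_size_um!r})")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent child generator for a named sub-generator."""
        if stream not in _SALTS:
            raise ConfigurationError(f"unknown RNG stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_SALTS[stream],))
        )

    def replace(self, **updates) -> "SimConfig":
        from dataclasses import replace as _replace
        return _replace(self, **updates)


def load_sim_config(source: str | Mapping) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML file path or a mapping.

    Unknown keys are rejected to catch typos in configuration files.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {source!r} must hold a mapping")
    known = {f.name for f in fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigurationError("seed is required in the simulation config")
    return SimConfig(**raw)
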