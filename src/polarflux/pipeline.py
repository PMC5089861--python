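"""Pipeline driver: validated config, assay dispatch, run manifest.

Each run reads a :class:`PipelineConfig` (usually from YAML), executes one
assay, writes its outputs under ``output_dir`` and records a machine-
readable manifest (assay, parameters, seed, software version, output file
list) next to them.  Given the same config and seed the output CSV files
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimConfig, load_sim_config
from .errors import ConfigurationError, DataError
from . import colocalization, haptotaxis, io, photoconversion, recycling
from . import simulate, tracks as tracks_mod

logger = logging.getLogger("polarflux")

ASSAYS = ("simulate", "tracks", "photoconv", "coloc", "recycle", "haptotaxis")
SIM_KINDS = ("vesicles", "photoconv", "spots", "recycling", "haptotaxis")

_KNOWN_KEYS = {"assay", "inputs", "output_dir", "seed", "verbosity", "params"}


@dataclass(frozen=True)
class PipelineConfig:
    """One assay run: what to execute, on what, with which parameters."""

    assay: str
    output_dir: str
    seed: int = 0
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ConfigurationError(
                f"unknown assay {self.assay!r}; expected one of {ASSAYS}")


def load_pipeline_config(source: str | Mapping) -> PipelineConfig:
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "assay" not in raw or "output_dir" not in raw:
        raise ConfigurationError("config requires 'assay' and 'output_dir'")
    return PipelineConfig(**raw)


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    params = dict(cfg.params.get("sim", {}))
    params.setdefault("seed", cfg.seed)
    return load_sim_config(params)


def _require_input(cfg: PipelineConfig, key: str) -> Path:
    if key not in cfg.inputs:
        raise ConfigurationError(f"assay {cfg.assay!r} requires input {key!r}")
    p = Path(cfg.inputs[key])
    if not p.exists():
        raise DataError(f"input file not found: {p}")
    return p


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute one assay; returns the manifest dict (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, writer) -> Path:
        p = out / name
        writer(p)
        written.append(name)
        return p

    summary: dict[str, Any] = {}
    try:
        if cfg.assay == "simulate":
            summary = _run_simulate(cfg, emit)
        elif cfg.assay == "tracks":
            trks = io.read_tracks(_require_input(cfg, "tracks"))
            v = float(cfg.params.get("v_threshold", tracks_mod.DEFAULT_V_THRESHOLD))
            pth = float(cfg.params.get("p_threshold", tracks_mod.DEFAULT_P_THRESHOLD))
            metrics = tracks_mod.metrics_frame(trks, v_threshold=v, p_threshold=pth)
            emit("track_metrics.csv", lambda p: metrics.to_csv(p, index=False))
            pop = tracks_mod.summarize_population_motility(trks, v, pth)
            emit("motility_summary.csv", lambda p: pop.to_csv(p))
            summary = {"n_tracks": len(trks)}
        elif cfg.assay == "photoconv":
            series = io.read_photoconversion_series(
                _require_input(cfg, "series"),
                t_conv_s=float(cfg.params.get("t_conv_s", 45.0)))
            flux = photoconversion.summarize_flux(series)
            row = pd.DataFrame([{
                "green_gain_fraction": flux.green_gain_fraction,
                "red_loss_fraction": flux.red_loss_fraction,
                "front_rear_bias": flux.front_rear_bias,
                "bias_defined": flux.bias_defined,
                "clipped": flux.clipped,
            }])
            emit("flux_summary.csv", lambda p: row.to_csv(p, index=False))
            curves = pd.DataFrame({
                "time_s": series.times_s,
                "front_gain": flux.front_gain_curve,
                "rear_gain": flux.rear_gain_curve,
            })
            emit("gain_curves.csv", lambda p: curves.to_csv(p, index=False))
            summary = {"red_loss": flux.red_loss_fraction,
                       "green_gain": flux.green_gain_fraction}
        elif cfg.assay == "coloc":
            a = io.read_spots(_require_input(cfg, "spots_a"))
            b = io.read_spots(_require_input(cfg, "spots_b"))
            radius = float(cfg.params.get(
                "radius_um", colocalization.DEFAULT_MATCH_RADIUS_UM))
            res = colocalization.match_spots(a, b, radius)
            row = pd.DataFrame([{
                "frac_A_with_B": res.frac_A_with_B,
                "frac_B_with_A": res.frac_B_with_A,
                "n_A": res.n_A, "n_B": res.n_B,
                "match_radius_um": res.match_radius_um,
            }])
            emit("coloc_result.csv", lambda p: row.to_csv(p, index=False))
            summary = {"frac_A_with_B": res.frac_A_with_B}
        elif cfg.assay == "recycle":
            series = io.read_recycling_series(_require_input(cfg, "series"))
            rows = [{"time_min": t,
                     "percent_recycled": recycling.percent_recycled(series, t),
                     "percent_remaining": recycling.percent_remaining(series, t)}
                    for t in series.times_min]
            fit = recycling.fit_recycling_rate(series, seed=cfg.seed)
            emit("recycling_percent.csv",
                 lambda p: pd.DataFrame(rows).to_csv(p, index=False))
            emit("recycling_fit.csv", lambda p: pd.DataFrame([fit._asdict()])
                 .to_csv(p, index=False))
            summary = {"rate_per_min": fit.rate_per_min}
        elif cfg.assay == "haptotaxis":
            trks = io.read_tracks(_require_input(cfg, "tracks"))
            axis = tuple(cfg.params.get("gradient_axis", haptotaxis.GRADIENT_AXIS_Y))
            summ = haptotaxis.summarize_haptotaxis(trks, axis)
            decision = {
                "mean_fmi": summ.mean_fmi, "ci_low": summ.ci_low,
                "ci_high": summ.ci_high,
                "mean_velocity_um_min": summ.mean_velocity_um_min,
                "mean_persistence": summ.mean_persistence,
                "is_haptotaxing": summ.is_haptotaxing,
                "n_tracks": summ.n_tracks, "n_excluded": summ.n_excluded,
            }
            emit("haptotaxis_summary.json",
                 lambda p: p.write_text(json.dumps(decision, indent=2)))
            rose = pd.DataFrame({
                "bin_start_rad": summ.rose_bin_edges_rad[:-1],
                "bin_end_rad": summ.rose_bin_edges_rad[1:],
                "weight": summ.rose_histogram,
            })
            emit("rose_histogram.csv", lambda p: rose.to_csv(p, index=False))
            summary = decision
    except (ConfigurationError, DataError):
        raise
    except Exception as exc:  # surface stage + cause for debugging
        raise DataError(f"assay {cfg.assay!r} failed: {exc}") from exc

    manifest = {
        "assay": cfg.assay,
        "seed": cfg.seed,
        "params": cfg.params,
        "inputs": {k: str(v) for k, v in cfg.inputs.items()},
        "outputs": written,
        "version": __version__,
        "summary": _jsonable(summary),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("assay %s complete; outputs: %s", cfg.assay, written)
    return manifest


def _run_simulate(cfg: PipelineConfig, emit) -> dict[str, Any]:
    kind = cfg.params.get("kind")
    if kind not in SIM_KINDS:
        raise ConfigurationError(
            f"simulate requires params.kind in {SIM_KINDS}, got {kind!r}")
    sim = _sim_config(cfg)
    if kind == "vesicles":
        n = int(cfg.params.get("n_tracks", 100))
        trks = simulate.gen_vesicle_tracks(sim, n)
        emit("vesicle_tracks.csv", lambda p: io.write_tracks(trks, p))
        return {"n_tracks": n}
    if kind == "photoconv":
        series = simulate.gen_photoconversion_series(sim)
        emit("photoconversion_series.csv",
             lambda p: io.write_photoconversion_series(series, p))
        return {"n_frames": int(series.times_s.size)}
    if kind == "spots":
        n_a = int(cfg.params.get("n_a", 200))
        n_b = int(cfg.params.get("n_b", 200))
        field_um = float(cfg.params.get("field_um", 40.0))
        a, b = simulate.gen_spot_fields(sim, n_a, n_b, field_um)
        emit("spots_a.csv", lambda p: io.write_spots(a, p))
        emit("spots_b.csv", lambda p: io.write_spots(b, p))
        if cfg.params.get("render", False):
            img = simulate.render_spot_images((a, b), sim)
            emit("spots.tif", lambda p: io.write_stack(p, img, sim.pixel_size_um))
        return {"n_a": n_a, "n_b": n_b}
    if kind == "recycling":
        times = cfg.params.get("times_min", [0, 15, 30, 60])
        series = simulate.gen_recycling_series(sim, np.asarray(times, float))
        emit("recycling_series.csv",
             lambda p: io.write_recycling_series(series, p))
        return {"times_min": list(map(float, times))}
    # haptotaxis
    n = int(cfg.params.get("n_tracks", 150))
    dur = float(cfg.params.get("duration_hr", 24.0))
    trks = simulate.gen_haptotaxis_tracks(sim, n, dur)
    emit("migration_tracks.csv", lambda p: io.write_tracks(trks, p))
    return {"n_tracks": n, "duration_hr": dur}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
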