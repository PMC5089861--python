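# polarflux

Quantification of polarized endosomal transport and directed cell
migration from live-cell microscopy readouts: vesicle-track motility,
photoconversion-based anterograde/retrograde flux, object-based
colocalization, receptor-recycling kinetics, and haptotaxis statistics.

The package is aimed at cell biologists analyzing organelle transport in
migrating cells (for example fibroblasts on fibronectin gradients), where
polarized delivery of endosomal cargo such as α5β1-integrin to the leading
edge is the quantity of interest.  All analysis stages accept plain
CSV/TIFF inputs, and a synthetic-data module generates every input type
with known ground truth, so the whole pipeline is testable at desk scale.

## The statistics

For a tracked object with positions r(t) over duration T:

* **net velocity** v = |r(T) − r(0)| / T  (µm/s)
* **persistence** P = |r(T) − r(0)| / Σᵢ |rᵢ₊₁ − rᵢ|  ∈ [0, 1]

Vesicles with v > 4 µm/s **and** P > 0.5 are classified *fast long-range*
(processive microtubule transport); all others *short-range*.

For a photoconversion experiment (green→red switch of the perinuclear pool
at t_conv = 45 s, imaged to t_end = 16 min), on background-subtracted
perinuclear traces G and R:

* **green gain** (retrograde) = (G(t_end) − G(t_conv)) / (G(t₀) − G(t_conv))
* **red loss** (anterograde) = (R(t_conv) − R(t_end)) / (R(t_conv) − R(t₀))

plus front/rear red-gain curves, normalized to background at t₀, whose
ratio at t_end is a polarity index.

For colocalization, the double-positive fraction is the share of channel-A
puncta with ≥ 1 channel-B punctum within a match radius (default 0.5 µm),
computed in both directions, alongside the pixel Pearson coefficient over
the cell mask.

For recycling, with membrane/cytoplasm intensities M, C:
**% recycled**(t) = 100·M(t)/C(0) and **% remaining**(t) = 100·C(t)/C(0);
a single-exponential model 1 − e^(−kt) is fitted for the rate k.

For haptotaxis, each cell track yields a **forward migration index**
FMI = (net displacement along the gradient) / (path length), and a
population is called haptotaxing when mean FMI > 0.1 **and** the
Student-t 95% CI of the mean lies above 0.

## Worked example

Simulate a 24-h haptotaxis experiment (150 cells, drift 0.2, 15-min
steps) and analyze it:

```python
from polarflux import SimConfig, summarize_haptotaxis
from polarflux import simulate as sim

cfg = SimConfig(seed=1, drift_fraction=0.2, heading_sd_rad=0.8,
                migration_speed_um_min=0.5)
tracks = sim.gen_haptotaxis_tracks(cfg, 150, duration_hr=24.0)
s = summarize_haptotaxis(tracks)
print(f"mean FMI = {s.mean_fmi:.3f}  CI = [{s.ci_low:.3f}, {s.ci_high:.3f}]  "
      f"haptotaxing = {s.is_haptotaxing}")
```

```
mean FMI = 0.211  CI = [0.181, 0.240]  haptotaxing = True
```

The mean FMI ≈ 0.21 sits near the geometric expectation
drift/√(1+drift²) ≈ 0.196 for this walk, the CI excludes 0, so the
population is called haptotaxing.  With `drift_fraction=0` the same
analysis returns a mean FMI near 0 with a CI crossing 0 and a negative
call.

The same workflow runs from the shell:

```bash
polarflux simulate haptotaxis --out sim --seed 1 --n-tracks 150
polarflux haptotaxis --tracks sim/migration_tracks.csv --out results
```

which writes `haptotaxis_summary.json`, `rose_histogram.csv` and a
`manifest.json` recording all parameters.  `polarflux tracks`,
`photoconv`, `coloc` and `recycle` expose the other assays analogously.

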