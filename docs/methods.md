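# Methods

This note documents the models behind the synthetic-data generators, the
exact definitions of the statistics, the numerical choices, and the known
limitations — in that order.

## Motility metrics and classification

A track is an ordered list of timed 2-D positions in µm.  Net velocity is
net displacement over elapsed time (µm/s) and persistence is net
displacement over accumulated path length; both use the recorded time
column rather than frame index × nominal interval, so dropped frames do
not bias the duration.  A stationary track (zero path length) has
persistence defined as 0, with a warning, so population summaries stay
finite.

Classification uses strict inequalities — net velocity > 4 µm/s *and*
persistence > 0.5 for the fast-long-range class — with both thresholds
exposed as parameters.  The thresholds are applied to whole tracks; a
sliding-window variant is deliberately out of scope, and users who need it
can cut tracks upstream.

## Synthetic vesicle tracks

A two-population mixture: a fraction `directed_fraction` of tracks moves
ballistically at `directed_speed_um_s` in a uniformly random direction
with i.i.d. Gaussian positional jitter (`jitter_sd_um`, default 0.1 µm,
roughly a localization error), and the remainder performs isotropic
Brownian motion with diffusion coefficient `diffusion_um2_s` (per-axis
step sd √(2DΔt)).  Default cadence is 1 frame / 2 s × 60 frames.  This
mixture is the simplest process for which both motility metrics have known
expectations — for the diffusive class, E|r(T)| = √(πDT) (Rayleigh), which
the tests use as an oracle — and for which the classifier's ground truth
is exact.  Real vesicle motion switches between states within one track;
the generator does not emulate that, so classification-recovery results
say nothing about state-switching cargo.

## Photoconversion model and flux statistics

Three well-mixed compartments — perinuclear P, front F, rear R — exchange
by first-order kinetics:

    dP/dt = −(k_pf + k_pr) P + k_fp F + k_rp R
    dF/dt =  k_pf P − k_fp F
    dR/dt =  k_pr P − k_rp R

applied independently to green and red species.  Propagation over the
15-s frame interval uses the matrix exponential, which is exact for this
linear system and conserves per-species mass to machine precision.  The
time grid is 0–960 s inclusive at 15 s spacing, so the three key times of
the ratio formulas (0 s pre-conversion, 45 s post-conversion, 16 min end)
all lie on the grid.  Conversion is instantaneous at t = 45 s: a fraction
`conversion_efficiency` (default 0.7, typical of green-to-red
photoconvertible proteins) of green P moves to red P, and the 45 s frame
is recorded post-conversion.

The green species starts at the stationary distribution of the exchange
matrix (scaled so P = `initial_intensity`), because cells are imaged at
baseline; this makes pre-conversion traces flat and keeps the green-gain
fraction in [0, 1] for generic rates.  For degenerate rate sets with no
strictly positive stationary state (absorbing or zero exchange — the
configurations used for closed-form tests) the explicit pools
(`initial_intensity` in P, `peripheral_fraction` of it in F and R) are
used instead.  Observed intensity = compartment amount + constant
background + Gaussian noise; the background trace gets independent noise.

Analysis: all region means are background-subtracted (per-frame background
mean) before the ratio statistics, because the printed ratio formulas are
offset-sensitive.  Green gain and red loss follow the definitions in the
README; when the denominator is below ε = 10⁻⁶ × the trace dynamic range
the conversion is treated as failed and a dedicated error is raised.
Fractions outside [0, 1] (possible under noise) are reported raw with a
`clipped` flag, never silently clipped.  Front/rear gain curves use the
red (converted) channel by default — the green variant is available — and
are normalized as (FI(t) − FI(t₀)) / background(t₀); the
difference-over-background form was chosen over a pure background ratio
because it is exactly zero in the no-transport limit.  The front/rear
bias is the ratio of the two gains at t_end, undefined (flagged) when both
are indistinguishable from zero.  In this model the bias equals k_pf/k_pr
exactly whenever the return rates are symmetric, which the tests exploit.

Cell partition: front = cell pixels with positive projection of the
offset from the cell centroid onto the migration axis (boundary pixels go
to the rear); the perinuclear region defaults to an annulus from the
nucleus boundary to 1.5 × the nucleus equivalent radius, overridable by an
explicit mask.  Front/rear intensity traces exclude the perinuclear
overlap so the three regions measure distinct pools.  Frames are assumed
pre-registered; no bleaching correction is applied.

## Spot fields and colocalization

Channel-B spots are uniform in a square field.  Each channel-A spot is
paired to a uniformly chosen B spot with probability `overlap_fraction`
(independent Bernoulli draws, so the measured co-fraction is binomial
around the target) and offset by Gaussian jitter (`jitter_sd_um`);
unpaired A spots are rejection-sampled outside a `min_separation_um`
exclusion zone (default 1 µm, i.e. twice the default match radius) so
that "unpaired" is unambiguous at the default radius.  Rendering places a
Gaussian of sd `psf_sigma_um` (default 0.15 µm, a typical confocal PSF)
and peak `spot_intensity` per spot on a constant background, then applies
Poisson shot noise.

Matching is many-to-one by default (one B spot may validate several A
spots), matching double-positive counting; a one-to-one minimum-cost
assignment mode is available.  The default match radius is 0.5 µm, of the
order of a vesicle diameter at typical magnification; it is a declared
default, not a calibrated one, and no chance-colocalization correction is
applied.  The Pearson coefficient is the plain product-moment correlation
over masked pixels and should be computed within a cell mask to avoid
background-driven inflation.  Spot detection wraps Laplacian-of-Gaussian
blob detection (scikit-image) with integer-pixel localization, so
positions are accurate to ~0.7 px worst case.

## Recycling kinetics

Generator: cytoplasm FI(t) = FI₀·e^(−kt), membrane FI(t) =
FI₀·(1 − e^(−kt)) (+ Gaussian noise on the membrane trace, floored at 0);
the default k = 0.0153 min⁻¹ puts ~60% of cargo back on the membrane at
60 min, a realistic scale for integrin recycling.  Degradation and slow
(multi-hour) return routes are deliberately not modeled; percent recycled
+ percent remaining = 100 holds exactly only in that degradation-free
setting.  The denominator cytoplasm FI(0) is per-cell.  Rate fitting is
bounded least squares of 1 − e^(−kt) on the recycled fraction with a
residual-resampling percentile bootstrap for the 95% CI (200 resamples by
default); an all-zero series short-circuits to k = 0, and optimizer
failure on pathological series returns a flagged NaN rather than raising.

## Haptotaxis model and decision rule

Migration is a biased persistent random walk: per 15-min step the heading
diffuses with sd `heading_sd_rad` (default 0.8 rad) and the step vector is
v·Δt·(heading_unit + drift·ŷ), with the gradient along +y by convention
and v = 0.5 µm/min by default (a realistic fibroblast speed over 24 h).
For isotropic initial headings the ensemble-mean FMI is approximately
drift/√(1 + drift²) — ≈ 0.196 at drift 0.2 — which serves as the test
oracle.  The generator does not emulate cell–cell collisions, division,
or speed heterogeneity, so calibration results apply to independent
identically distributed tracks only.

FMI uses the accumulated-path-length denominator; a net-displacement
variant sits behind a flag.  The population CI is Student-t over per-track
FMI (cells as units), with a percentile bootstrap option, and the
haptotaxis call is the conjunction mean FMI > 0.1 and CI low > 0.  Rose
histograms bin origin-aligned endpoint angles into bins centered on the
cardinal directions; zero-displacement tracks are excluded and counted.
Group comparisons (t-test, ANOVA) are delegated to scipy.stats.

## Determinism and problem sizes

Every generator draws from a child stream of a single required seed
(seed-sequence spawning with per-generator salts), so identical configs
give bit-identical outputs, and pipeline runs with one seed produce
byte-identical CSVs.  The test suite uses ensembles of 10²–10⁴ tracks
chosen so that each Monte-Carlo oracle's sampling error is several times
smaller than the asserted tolerance; the CI-calibration check uses 1000
simulated populations of 150 tracks.

## Known limitations

Noise levels and background intensities are free parameters with
plausible defaults, not calibrated to any specific instrument.  The
photoconversion compartments are well-mixed (no spatial gradients within
a region), image registration and bleaching are assumed handled upstream,
3-D imaging and realistic cell morphologies are out of scope, and the
spot generator's exclusion-zone construction makes low overlap fractions
slightly sub-uniform in dense fields.
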