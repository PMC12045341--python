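# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a maintainer would want to know. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Photobleach step counting

**Model.** A focus holding N fluorophores emits an integrated intensity
`background + Δi·(survivors)`; each fluorophore's bleach time is
exponential with rate `bleach_rate` (default 0.05 s⁻¹ at the 5-Hz,
200-ms-frame acquisition preset, so a 10-fluorophore focus bleaches out
over tens of seconds with occasional same-frame coincidences). Two
fluorophores bleaching in one frame produce a 2Δi drop and must be counted
as two molecules.

**Step detection.** Greedy binary change-point placement: the split with
the largest residual-sum-of-squares reduction is added while that
reduction exceeds a penalty, followed by boundary re-optimization and
backward pruning (the forward pass can place a slightly offset split and
patch it with a second one; pruning undoes such pairs). The default
penalty is `2.5·σ²·ln n` with σ estimated robustly from first differences
(MAD-based, step-insensitive). The factor was calibrated on its own
experiment — false-positive rate on pure-noise traces versus exactness on
staircases whose steps are 3× the noise SD — where 2.5 dominates both
neighbors (2.0: 3.5% false positives; 3.0: misses a third of 3σ
staircases). The default is scale-equivariant: scaling a trace by c scales
σ² and hence the penalty by c².

**Unit step Δi.** Downward step magnitudes are clustered in 1-D (a gap
larger than 25% of the running cluster mean starts a new cluster); Δi is
the smallest cluster center whose integer multiples explain every step
within `|s − kΔi| ≤ 0.25Δi`, refined by least squares of s ≈ kΔi.
Robustness guards matter in practice: a candidate must be at least 0.6× the
modal cluster center (a sub-unit artifact cluster cannot be the unit), and
steps below half a candidate may remain unexplained as a ≤30% minority —
the counter later drops them as k = 0 artifacts. Without these, one
spurious small step can drive Δi to a tiny value and multiply every count.
Δi is estimated per trace by default (illumination varies across a field);
`count_trace(..., unit_step=...)` accepts a pooled value.

**Counting.** N = Σ round(|step|/Δi) over downward steps; upward steps are
treated as blinking and ignored with a logged warning.

**Resolution limit.** At Δi/noise = 5, change-point enumeration recovers
the exact set of distinct bleach frames reliably (98% in the validation
ensemble) when events are ≥3 frames apart, but 1-frame intermediate levels
sit at the information limit and are merged or split roughly a quarter of
the time. Molecule counts survive such merges — a merged double step is
still counted as two molecules by the kΔi rounding — which is why exact
counting holds at ≥90% on the unconditioned ensemble while exact
change-point enumeration is only asserted for resolvable spacing.

## Dual-channel stoichiometry

Channels are step-counted independently and paired greedily by ascending
registered distance within a 0.32-μm tolerance; the beam-splitter is
emulated as a fixed integer + subpixel offset plus 10-nm residual
misregistration jitter. The primary statistic is the zero-intercept slope
`Σ(a·b)/Σ(a²)` — a focus with zero receptor cannot host its partner, so
the regression is forced through the origin — with the mean of per-focus
ratios, the total-count ratio and an ordinary regression with intercept
reported alongside.

## Single-particle tracking

**Localization.** Candidate peaks are local maxima of the
PSF-matched-filtered image above background + threshold; each is refined by
an unbounded Levenberg–Marquardt fit of `A·exp(−r²/2σ²) + b` with an
analytic Jacobian over a 7×7-pixel window, followed by validation (positive
amplitude, center inside the window, width within 0.25–2× the nominal PSF
σ). The width cap is the operational proxy for rejecting out-of-focus
cytoplasmic objects, which appear blurry. At the tracking preset
(amplitude/noise ≈ 8) the empirical localization error is ~20 nm per axis
with essentially no missed detections; the preset was calibrated once, on a
localization-error experiment, to land in the ~20–25-nm regime typical of
single-fluorophore imaging at these counts.

**Linking.** Greedy nearest-neighbor assignment between consecutive frames
only (no gap closing), pairs accepted in ascending distance inside the
0.320-μm (two-pixel) gate, deterministic tie-break by detection order.
Greedy matching coincides with the minimum-total-distance assignment on
clean crossings (converging paths whose per-frame steps are smaller than
the closest-approach separation) — the regime the gate is designed for —
but demonstrably differs from the optimal assignment in roughly a quarter
of random two-particle Brownian frame pairs, when one detection is nearest
to both predecessors. This is a known limitation of gate-based greedy
linking, accepted for its determinism and auditability.

**MSD and D.** The ensemble MSD pools every displacement pair of every
track (time-and-ensemble average), matching the single population-level D
the analysis reports. D = slope/4 from an unweighted least-squares line
through the origin over the first four lags, reading MSD = 4DΔt literally;
a free-intercept variant (`estimate_D(..., intercept=True)`) absorbs the
static localization-error offset 4σ_loc² and is available but not the
default. With the default, a σ_loc of ~20 nm biases D upward by
≈ 4σ²·Σk/(Δt·Σk²) /4 ≈ +0.01 μm²/s at 15-ms frames — visible in the
recovery experiments and well inside their 10% band. Negative fitted
slopes clamp to D = 0 with the raw slope kept in `raw_slope`.

**Bootstrap.** Whole trajectories are resampled with replacement
(n_boot = 1000 by default) and the pooled MSD → D recomputed per replicate,
vectorized via per-track sufficient statistics (per-lag squared-displacement
sums and pair counts). `method="enumerate"` computes the exact SD of the
bootstrap distribution from all resample multisets with multinomial
weights; it is feasible up to roughly a dozen tracks and anchors the
stochastic bootstrap in tests.

**Track-length note.** Tracks are filtered to 4–12 frames before pooling.
At 15 ms per frame that is 0.06–0.18 s of observation per track; the
frame-count window is taken as authoritative for filtering even where a
duration of 0.4–1.2 s is quoted alongside it, since the two are mutually
inconsistent at 67 Hz.

## Transfer-event detection

**Assignment and crossings.** Each localization maps to the cell label of
its nearest mask pixel. Runs of ≤2 unassigned frames are bridged with the
preceding label (boundary pixels are ambiguous; bridging avoids
double-counted flicker crossings); label changes across longer unassigned
runs are tracking breaks, not crossings, because no crossing frame or
coordinate can be assigned. A crossing is recorded where the bridged label
changes between adjacent cells, its coordinate being the midpoint of the
flanking localizations; a change between non-adjacent cells flags the
track as a teleport artifact and excludes it. Events classify as
bidirectional when any cell is revisited, serial when three or more
distinct cells are visited, else unidirectional; `n_boundaries` counts
distinct cell pairs crossed. Crossing-point proximity to receptor foci
uses a 0.320-μm threshold by default, mirroring the linking gate, and is
exposed as a parameter since no principled value exists at this scale.

**Diffusion of crossing particles** is pure delegation to the spt
machinery, pooled over the crossing tracks and per track.

## Synthetic data

**Camera model.** Emitters render as symmetric 2D Gaussians (integrated
intensity Δi per fluorophore, σ_PSF = 100 nm ≈ 0.63 px) over a constant
background with Gaussian read noise; Poisson shot noise is available but
off by default so closed-form oracles stay simple. Discrete pixel sampling
of the undersampled Gaussian aliases total intensity by ~0.2%, the only
deviation from exact intensity conservation. No TIRF depth, drift, or
motion blur during exposure is modeled: trajectories are sampled
instantaneously at frame times, so MSD-reducing blur effects present in
real EMCCD data are absent, and recovery experiments isolate the
localization-noise bias alone.

**Cells.** Spherocylinders ~0.7 μm wide and 4–7 μm long, rasterized with a
half-pixel coverage margin (the mask covers every pixel the cell touches,
the way segmentation outlines are drawn); overlapping claims resolve to
the nearest axis, keeping labels disjoint. Confinement re-draws steps that
would leave the region (reflective). Genuine physics follows: diffusion
confined in a 0.7-μm-wide planar rod has measurably suppressed MSD (about
−7% at the first lag for boundary-hugging ensembles), so scenario-based
recoveries carry a small negative offset where free-diffusion recoveries
carry the localization-noise positive one.

**Transfer scenarios.** Crossing plans (visit sequences like 1→2→1) are
realized constructively: walks start inside the first cell near the shared
boundary (with the correct raster label — the raster boundary can sit up
to half a pixel from the analytic one), each planned crossing executes
after a short random dwell at the first frame the walk is analytically
within 0.05 μm of the target or already carries its raster label, and
between crossings the walk is reflectively confined to its current cell.
This enforces the planned sequence by construction instead of selecting
mobile walks, keeping the scenario ensemble's fitted D unbiased (the
earlier whole-track rejection sampler inflated it by ~8%). Candidates are
still rejected if the raster-level transition sequence deviates from the
plan, so downstream detection recovers the planted crossings exactly; long
serial walks (a transit across a 0.7-μm cell takes ~100 frames) disable
that raster check and guarantee the plan in the analytic ground truth
only. With n = 39 crossing tracks of 8–16 frames, the four-lag D estimate
carries an irreducible ~8% relative SD — the statistical floor of that
sample size, matching the large uncertainty quoted for the corresponding
experimental population.

**Bleach traces and dual-channel foci** follow the trace model above;
dual-channel foci share one true complex count per focus (exact 1:1),
bleach independently per channel, and carry the beam-splitter registration
offset.

**Density profiles** are sums of Gaussian peaks on a flat baseline with
optional white noise; peaks must be separated by more than twice their
width so each center remains a resolvable extremum.

## Membrane line profiles

Extrema are ranked by topographic prominence — a noise wiggle riding on a
true peak has almost no prominence whatever its height — and each selected
extremum is refined by a parabolic fit over its half-prominence
neighborhood (at least the three samples around the maximum). A fixed
3-point parabola was considered and rejected: at fine sampling the
curvature between adjacent samples vanishes, and with 10% amplitude noise
its center estimate scatters by several sampling steps, whereas the
window-parabola meets sub-half-step RMSE; in the noiseless limit the two
coincide. Membranes are dark on raw cryo-EM profiles, so `polarity`
selects troughs there and peaks on inverted or synthetic profiles — an
explicit flag, never auto-detected. One-way ANOVA is computed from the
sums of squares directly so the degenerate zero-variance/equal-means case
is well defined (F = 0, p = 1); per-measurement pooling is the default for
group comparisons, with per-profile means available to the caller.

## Reproducibility

All randomness flows through numpy Generators seeded from
`SimConfig.rng_seed` or explicit seeds; a single pipeline seed fans out to
per-stage child seeds through a fixed CRC-based derivation
(`derive_seed`), so stages can be re-run in isolation. Identical
configurations reproduce outputs bit for bit, and the demo pipeline's
report is a pure function of (config, seed).

## Problem sizes

The recovery experiments run at the preset population sizes (1,518 OM,
2,848 IM, 39 crossing tracks; 174-focus count summaries; 59 dual-channel
foci; 200-trace counting ensembles), completing in about two minutes on
one CPU; examples and the demo pipeline use a few hundred tracks, which
keeps them interactive while leaving the estimator within a few percent
of the preset truth.

## Known limitations

* Greedy linking is not globally optimal (see above); dense fields or
  fast, closely spaced particles can be mis-linked.
* The planar 2D diffusion model ignores membrane curvature: a particle on
  a 0.7-μm-wide cylinder seen in projection has anisotropic apparent
  diffusion that the generator does not emulate, so the isotropic-recovery
  results bound only the pipeline's estimator error, not projection
  effects in real data.
* Step counting assumes a single shared Δi per trace (or field); strong
  within-trace illumination drift would bias counts and is not modeled.
* Blinking is ignored rather than corrected; prolonged dark states would
  undercount.
* Cell masks are inputs (or synthetic); segmentation from raw
  DIC/phase-contrast images is out of scope.
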