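# omequant

Quantitative-microscopy analysis chain for bacterial **outer-membrane
exchange (OME)** — the process by which contacting *Myxococcus xanthus*
cells recognize kin through the cell-surface receptor TraA and its partner
TraB, transiently fuse their outer membranes, and exchange membrane
proteins and lipids. The package provides tested, reusable implementations
of the five measurements such a study rests on, together with
ground-truthed synthetic data generators that emulate each kind of raw
data, so every estimator can be validated against a known truth:

1. **Photobleach step counting** (`omequant.bleach`) — a focus of N
   fluorophores loses intensity in discrete unit steps Δi, one per
   fluorophore, with occasional coincident 2Δi drops. A greedy
   change-point decomposition with an information-criterion stop, a
   cluster-based Δi estimator, and the count
   N = Σ round(|step|/Δi) give per-focus stoichiometry.
2. **Dual-channel stoichiometry** (`omequant.dualchannel`) — two-color
   (beam-splitter) foci are paired after registration; the inter-channel
   ratio is the zero-intercept least-squares slope
   slope = Σ(a·b)/Σ(a²) of channel-B counts on channel-A counts.
3. **Single-particle tracking** (`omequant.spt`) — symmetric 2D Gaussian
   localization, greedy nearest-neighbor linking inside a 320-nm (2-pixel)
   gate, 4–12-frame track filtering, the time-and-ensemble averaged mean
   squared displacement, and the diffusion coefficient from an
   origin-constrained fit **MSD = 4DΔt** to the first four lags, with a
   bootstrap SD over trajectories (1,000 resamples by default).
4. **Transfer-event detection** (`omequant.events`) — trajectory points
   are assigned to labeled cells; boundary crossings between adjacent
   cells are detected with gap bridging, classified unidirectional /
   bidirectional / serial, their pooled D is measured, and each crossing
   point is tested for proximity to receptor foci.
5. **Membrane line profiles** (`omequant.memprofile`) — OM–OM and OM–IM
   separations from 1-D cryo-EM density profiles via prominence-ranked
   extrema refined to subsample precision, compared across groups by
   one-way ANOVA.

`omequant.synthetic` generates every input type with full ground truth
(bleach traces, Brownian trajectories, rendered TIFF movies, adjacent-cell
transfer scenarios with crossing plans, density profiles), and
`omequant.recovery` packages the parameter-recovery experiments run at the
study's preset conditions (160-nm pixels, 67-Hz tracking, 5-Hz
dual-channel bleaching, Δi/noise = 5).

## Worked example

```python
from omequant.recovery import recover_tracking_D

rec = recover_tracking_D(true_D=0.19, n_tracks=300, seed=42, n_boot=300)
print(f"recovered D = {rec.D:.3f} ± {rec.bootstrap_sd:.3f} μm²/s "
      f"(truth {rec.true_D})")
```

prints

```
recovered D = 0.204 ± 0.007 μm²/s (truth 0.19)
```

Three hundred Brownian trajectories at a true D of 0.19 μm²/s were rendered
as noisy movies, re-localized by Gaussian fitting, linked at the 320-nm
gate, filtered to 4–12 frames and pooled into the ensemble MSD; the
origin-constrained four-lag fit recovers the truth with a small upward
offset contributed by the ~20-nm static localization error (see
`docs/methods.md`). The `examples/` directory holds one short script per
capability (step counting, 1:1 ratio, tracking, transfer events, membrane
profiles), each printing the numbers it computes and what they mean.

A thin command-line interface mirrors the library:

```bash
omequant simulate movie --seed 1 --n 20 --out sim/
omequant track --stack sim/movie.tif --out trk/
omequant msd --tracks trk/tracks.csv --boot 1000 --seed 7 --out est/
omequant demo --seed 0 --out demo_out/   # all stages end to end
```

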