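# trnatrack

Single-molecule tracking analysis of tRNA diffusion and localization in live
bacteria, built as a tested, reusable pipeline with a fully ground-truthed
synthetic-data generator.

Transfer RNA shuttles between ribosomes, synthetases and free diffusion, and
whether most tRNA is free or complex-bound in vivo is measurable by
single-particle tracking: internalized dye-labeled tRNA is imaged under
stroboscopic illumination (1-ms excitation pulses inside 5-ms camera frames),
localized to ~40 nm per axis, and linked into trajectories. This package
implements every computational stage of that experiment:

- **Simulation** (`trnatrack.simulate`) — confined Brownian motion in a
  spherocylindrical cell (3 × 1 µm by default) with strobe motion blur, at
  two fidelity levels: geometric localized tracks (true positions + Gaussian
  localization error) and fully rendered EMCCD-like TIFF movies; plus
  quantized photobleaching traces and uniform / periphery-biased spatial
  point patterns.
- **Localization** (`trnatrack.localize`) — difference-of-Gaussians
  detection and 2D elliptical-Gaussian PSF fitting to sub-pixel positions.
- **Linking** (`trnatrack.linking`) — optimal per-frame-pair assignment
  within a 0.67 µm window and one-frame memory. The window captures ≥ 98 %
  of steps of a species with apparent D = 4 µm²/s at 5 ms:
  P(|Δr| ≤ w) = 1 − exp(−w²/(4 D Δt + 4 s²)).
- **Diffusion inference** (`trnatrack.diffusion`) — per-trajectory apparent
  diffusion coefficients from the first four single-frame steps,
  D\* = Σₖ[(Δxₖ)² + (Δyₖ)²] / (4·4·Δt), which for a free species follows
  Gamma(shape 4, mean D + s²/Δt); γ-mixture decomposition into diffusive
  species (optionally constraining the slow species to ribosomal diffusion,
  0.5 µm²/s); a two-species CDF fit of squared displacements; a
  simulation-based calibration mapping apparent to accurate D; and the tRNA
  cycle diffusion budget.
- **Molecule counting** (`trnatrack.counting`) — photobleaching-step
  analysis with a bleaching-ladder HMM (states k = 0…6, emission
  N(k·u, σ), transitions k → k/k−1), Gaussian step-height pooling to the
  unitary intensity, per-cell counts, and the mean + 3 SD loaded-cell call.
- **Spatial statistics** (`trnatrack.spatial`) — normalization of
  localizations into a unit cell (midline → 0, outline → 1), comparison with
  the analytic projection of a uniform cylinder,
  pdf(ρ) = 4·√(max(1 − ρ², 0))/π, and periphery/mid-cell enrichment with
  bootstrap intervals, split by mobility class and cell-length bin.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data; each writes tables under `results/` and prints what it found:

```bash
python analysis/01_simulate_tracks.py
python analysis/02_link_and_estimate.py
```

```
live field: 762 emitters, 7620 localizations
fixed field: 746 emitters, 7460 localizations
live: 772 usable trajectories, mean D_app = 4.792 um^2/s, slow fraction 7.64%
fixed: 746 usable trajectories, mean D_app = 0.317 um^2/s, slow fraction 99.60%
fixed-cell precision sigma = 0.0796 um (per-axis error 0.0398 um)
```

The fixed-cell control recovers the injected localization error: immobile
emitters give D\* = s²/Δt ≈ 0.32 µm²/s, i.e. σ = √(4·D\*·Δt) ≈ 0.08 µm.
Continuing:

```bash
python analysis/03_diffusion_species.py   # γ-mixture + CDF species fits
python analysis/04_calibrate_diffusion.py # apparent ↔ accurate D curve
python analysis/05_count_molecules.py     # HMM step counting, loading calls
python analysis/06_spatial_distribution.py# unit-cell enrichment
python analysis/07_cycle_budget.py        # diffusion-budget arithmetic
python analysis/08_render_and_localize.py # rendered-movie fidelity check
```

Representative output:

```
constrained gamma mixture (slow pinned to 0.5 um^2/s):
  D_app = 0.50 um^2/s, weight 7.21% (constrained)
  D_app = 5.12 um^2/s, weight 92.79%
apparent(8.1) = 5.217 um^2/s; inverse of that apparent value = 8.10 +/- 0.30 um^2/s
158 traces, 304 decoded steps; molecule count correct in 90.5%
unitary intensity: (8.73 +/- 0.18) a.u. (true 8.7 +/- 2.4)
periphery-biased control (true +33%): measured +33.9% [+32.3, +35.7]
ribosome-bound tRNA: 100,000; searching: 275,000 (bound fraction 26.7%, rounded to 25%)
bound dwell 100 ms -> cycle 400 ms, search 300 ms
whole-cell exploration time at D = 8 um^2/s: 62.5 ms
```

The calibration curve is strongly sublinear at fast diffusion — cellular
confinement, strobe blur, localization noise and the finite linking window
compress a true D of 8.1 µm²/s to an apparent ~5.2 µm²/s under these
conditions — and inverting the curve recovers the true value. See
`docs/methods.md` for the model details and for a discussion of the
mobility-classification selection artifact visible in the spatial output.

A `trnatrack` console command exposes the same stages
(`simulate`, `localize`, `track`, `diffuse`, `calibrate`, `count`,
`spatial`, `demo`) with YAML configs and checksummed output manifests.

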