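# Methods

## Cell geometry and diffusion model

Cells are spherocylinders: a cylinder of radius r capped by hemispheres,
tip-to-tip length L (defaults L = 3 µm, r = 0.5 µm, the canonical *E. coli*
envelope). Emitters perform 3D Brownian motion with reflecting (specular)
boundaries, integrated by Euler–Maruyama substeps of
Δt/substeps_per_frame. Reflection folds the radial overshoot about the
nearest midline point (distance d > r maps to 2r − d along the same radial
direction, iterated for rare large steps); this boundary condition
preserves the uniform equilibrium — verified against the closed-form
stationary moments (transverse variance r²/4 per axis in the cylindrical
part, r²/5 in the caps).

The default substep count is 25 per 5-ms frame (0.2-ms substeps), which
places five substeps inside the 1-ms strobe window so the strobe average is
a faithful motion blur; the residual discretization error in the apparent
diffusion coefficient is below the localization-error contribution for
D ≤ 12 µm²/s.

## Stroboscopic imaging model

The reported per-frame position is the mean of the substep positions inside
the strobe window (the photon-weighted centroid a localizer would estimate).
Two observation routes exist:

- **Geometric**: 2D projection of the strobe-averaged position plus
  independent Gaussian error s per axis (default s = 0.04 µm). The full z
  range projects into the image — no focal sectioning — a stated
  simplification relative to a real microscope's finite depth of field.
- **Photophysical**: emitters render as symmetric 2D Gaussians
  (σ_PSF = 0.13 µm) integrated over 0.0957 µm pixels (0.67 µm / 7), with
  Poisson photon noise whose variance is doubled to approximate the EMCCD
  gain register, Poisson background, EM gain, and Gaussian read noise.
  The photon budget (90 detected photons/strobe, background 2 photons/px,
  gain 20 counts/photon, read noise 15 counts) is a tuned default — chosen
  once so that fitting rendered immobile emitters returns a per-axis error
  of ~40 nm, making the two routes consistent; it is not a measured camera
  calibration.

Localization precision convention: immobilized emitters give
D\*(fixed) = s²/Δt, and σ = √(4·D\*·Δt) = 2s. With s = 0.04 µm this yields
the anchor pair D\*(fixed) = 0.32 µm²/s ↔ σ = 0.08 µm, which the pipeline
reproduces end to end (both routes).

## Localization and linking

Candidates are local maxima of a difference-of-Gaussians bandpass above a
fixed threshold, minimum separation 2 px; each is fit by least squares with
an elliptical Gaussian plus constant background on a 9×9 px window
(≥ 6 σ_PSF). Pixel centers sit on integer coordinates, origin at the
top-left pixel center, x = column; outputs are µm. For symmetric spots the
rotation angle is canonicalized to 0. The photon estimate is
2π·A·w_x·w_y/(px²·gain).

Linking assigns localizations to open tracks per frame pair by minimum
total squared displacement (Hungarian algorithm) among pairs within the
0.67 µm window; unmatched tracks persist one frame (memory 1), and a
displacement bridging a g-frame gap must satisfy w·√(g+1)-style widening
(window × √2 per skipped frame, configurable) since step variance grows
with lag. Ties break deterministically by input order, and the resulting
track set is invariant to row permutations within frames.

## Apparent diffusion coefficients and species decomposition

D\* = Σ_{k=1..4} [(Δx_k)² + (Δy_k)²] / (16 Δt) over a trajectory's first
four single-frame steps; gap-bridged steps are excluded, trajectories with
fewer than four valid steps are dropped (and counted). For a free species
with localization error, D\* ~ Gamma(shape 4, mean D + s²/Δt); the mixture
fit therefore uses fixed-shape-4 gamma components parameterized by their
means, estimated by EM with 10 deterministic restarts. Components may be
constrained to fixed means — 0.5 µm²/s for ribosome-bound tRNA, 2.4 µm²/s
for the ternary complex (exported constants). Histogram least squares is
deliberately not the estimator; at these sample sizes MLE is better
conditioned and the two agree.

The CDF route fits the empirical distribution of single-frame squared
displacements u to 1 − Σ_j A_j exp(−u/(4 D_j Δt + 4 s²)) by least squares
with weights summing to 1, species sorted ascending.

Mobility classes: slow is D\* < 1 µm²/s, a threshold that labels ≥ 99 % of
simulated fixed-cell trajectories slow and ~2 % of a fast 8 µm²/s species.

## Apparent → accurate calibration

For each true D on a grid, the full pipeline runs (simulate 500 cells at
1.5 emitters/cell → link → D\*), the mean apparent D is recorded over 3
replicates, and a monotone PCHIP interpolant plus its inverse map apparent
to accurate D. The propagated uncertainty combines replicate scatter
(through the local inverse slope) and the measurement error in quadrature.
Under the default conditions the response is strongly sublinear:
apparent(8.1 µm²/s) ≈ 5.2 (geometric route) and ≈ 5.6 (photophysical
route, which adds blurred-spot fitting error). The suppression decomposes
into strobe blur (≈ −8 %), confinement of the transverse and axial step
variance (≈ −22 %), and the linking window's truncation of large steps
(≈ −12 %). Published live-cell analyses of this experiment report a
stronger compression (to ≈ 3.5 µm²/s at the same nominal conditions);
whatever additional suppression their processing chain applied is not
derivable from the available description, so this package reports the value
its own, fully specified pipeline produces — the inverse map is exact
against that same pipeline (inverse∘forward returns the grid within
replicate scatter).

## Photobleaching counting

Traces are baseline-subtracted by the mean of the last 10 % of frames. The
bleaching-ladder HMM has states k = 0..6 (emission N(k·u, σ), transitions
k → k with probability (1−p)^k, else k → k−1; the dark state absorbs). σ
comes from the MAD of first differences (robust to the steps themselves), u
from a 40-point log-spaced grid around a robust guess refined by least
squares against the decoded levels, and p from a small grid — all
deterministic and seed-free; the forward likelihood selects (u, p) and
Viterbi decodes the path. The per-cell molecule count is the decoded
initial state: counting completed steps instead would miss molecules still
fluorescent when the movie ends (~7 % of traces at a 3.4 s lifetime over a
12 s window). At the measured operating point (u = 8.7, σ = 2.4, 1–3
molecules) the decoded count is correct in ~93 % of traces.

Decoded step heights are integer multiples of the per-trace u, so the
pooled step-height histogram is much narrower than the emission noise; its
Gaussian center estimates the population unitary intensity (a poor-fit
diagnostic flags bimodal height distributions). Counts are total
fluorescence divided by u. Cells are "loaded" above the control mean + 3 SD
(Gaussian controls self-classify at ~0.13 %).

Lifetimes come from A·exp(−t/τ) + c least squares; bias < 2 % on exact
exponentials for τ ∈ [1, 30] s.

## Unit-cell spatial statistics

A lab-frame localization maps to (|arc position|/(L/2), |transverse
distance|/half-width), with the half-width equal to r on the cylindrical
part and following the hemispherical profile in the caps; points beyond a
50 nm tolerance outside the outline are dropped and counted, points within
tolerance clip to the boundary. The uniform reference on the short axis is
the projected cylinder density pdf(ρ) = 4√(max(1 − ρ², 0))/π (closed-form
CDF used for integrals); endcap contributions to the reference are ignored,
consistent with treating the unit cell as cylindrical. Periphery means
ρ ≥ 0.5 by default — the cutoff is a config parameter, declared rather than
inferred. Enrichment is (observed/uniform − 1)·100 with a seeded
percentile bootstrap (1000 resamples). Cell-length bins are 1.7–2.9 µm
(short, one nucleoid) and 3.1–4.3 µm (long, two); cells between bins are
excluded and counted.

The periphery-biased generator reweights the uniform density by
(ρ/r)^bias; its projected short-axis marginal (and hence the true
enrichment for any bias) is computed by quadrature, and `bias_for_enrichment`
inverts that relation — the oracle used to verify estimator recovery at a
+33 % operating point.

**Selection artifact worth knowing about:** with a spatially uniform
simulation, positions from *slow-classified* trajectories still show a
periphery excess (~+20 % at the default conditions). Fast molecules that
happen to dwell near the caps or lateral wall have confinement-reduced
apparent D and are preferentially misclassified slow, importing a spatial
bias into the slow set. Real experiments control for this with fixed-cell
and translation-inhibited samples; synthetic analyses made with this
package should compare against the matched uniform simulation rather than
assume zero-artifact classification.

## The diffusion budget

With a pool of 375 000 tRNA and 2 sites at each of 50 000 ribosomes,
100 000 tRNA are bound and 275 000 search; at 50 ms per amino acid the
bound dwell is 100 ms, the cycle 100 ms / 25 % (the rounded bound fraction)
= 400 ms and the search budget 300 ms. The whole-cell exploration time uses
MSD(t) = 6Dt against a 3 µm² target — the conventional long-dimension
figure for a 3 × 1 µm cell — giving 62.5 ms at 8 µm²/s.

## Problem sizes and determinism

Default study sizes (500 cells × ~1.5 emitters × 10 frames per condition,
3 calibration replicates, 158–200 photobleaching traces, 10⁴–10⁵-point
spatial samples) were chosen so every analysis runs in seconds to a few
minutes on one core while keeping Monte-Carlo error well below each test's
tolerance. All randomness flows through explicit integer seeds
(numpy Generator); identical seed + config gives bit-identical outputs,
which the pipeline manifest (config hash + per-file checksums) records.

## Known limitations

- No focal sectioning, z-dependent PSF or astigmatism; the full z extent
  projects into the image.
- No photoblinking kinetics beyond the one-frame linking memory; no
  merge/split events; no motion-model (Kalman) linking.
- The HMM collapses simultaneous double bleaches onto consecutive frames;
  step *timing* can be off by a frame even when the count is right.
- Curved midlines are not modeled (synthetic cells are straight);
  normalization supports arbitrary pose but not bent cells.
- The gamma-mixture likelihood assumes independent trajectories; emitters
  re-linked after a broken track contribute twice.
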