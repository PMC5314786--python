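"""Ground-truthed synthetic data for the tracking pipeline.

Two fidelity levels are provided. The *geometric* path
(:func:`simulate_localized_tracks`) produces strobe-averaged true positions
plus independent Gaussian localization error — the fast route used by the
apparent-to-accurate diffusion calibration. The *photophysical* path
(:func:`render_movie`) rasterizes emitters into EMCCD-like image stacks so
the full localization/linking pipeline can be exercised end to end.

The default conditions emulate the live-cell study the package analyses:
spherocylindrical cells of ~3 x 1 um, a mixture of fast (~8 um^2/s) and slow
(~0.5 um^2/s) species at ~1.5 molecules per cell over 500 cells, 1-ms strobes
in 5-ms frames and 40 nm per-axis localization error. Stepwise photobleaching
traces and uniform / periphery-biased spatial point patterns are generated
here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .config import ConfigError, ImagingConfig
from .geometry import CellGeometry, reflect_into

DEFAULT_SUBSTEPS_PER_FRAME = 25  # 0.2-ms substeps: 5 inside a 1-ms strobe


# ---------------------------------------------------------------------------
# Brownian paths in a spherocylinder
# ---------------------------------------------------------------------------

@dataclass
class TruePath:
    """Ground-truth path of one emitter.

    ``frame_positions`` are strobe-averaged (motion-blurred) 3D positions,
    one per frame; ``substep_positions`` the underlying fine-grained path.
    All coordinates are cell-frame um.
    """

    emitter_id: int
    species: str
    D: float
    frame_positions: np.ndarray      # (n_frames, 3)
    substep_positions: np.ndarray    # (n_frames*substeps, 3)
    substep_times: np.ndarray        # (n_frames*substeps,)
    alive: np.ndarray                # (n_frames,) bool


def _strobe_mask(config: ImagingConfig, substeps: int) -> np.ndarray:
    """Which substep indices within a frame fall inside the strobe window."""
    dt_sub = config.frame_interval / substeps
    times = np.arange(substeps) * dt_sub
    mask = times < config.strobe_duration - 1e-12
    if not mask.any():
        mask[0] = True  # the strobe always samples at least the frame start
    return mask


def _simulate_ensemble(geometry: CellGeometry, D: np.ndarray, n_frames: int,
                       config: ImagingConfig, substeps: int,
                       rng: np.random.Generator, unconfined: bool = False,
                       init: np.ndarray | None = None,
                       keep_substeps: bool = False):
    """Vectorized Brownian simulation of many emitters at once.

    Returns (frame_positions (n, n_frames, 3), substep track or None).
    """
    D = np.asarray(D, dtype=float)
    n = D.size
    dt_sub = config.frame_interval / substeps
    if init is None:
        pos = sample_spatial_pattern(geometry, n, mode="uniform",
                                     seed=rng.integers(2 ** 31))
    else:
        pos = np.array(np.atleast_2d(init), dtype=float)
    step_sd = np.sqrt(2.0 * D * dt_sub)[:, None]
    in_strobe = _strobe_mask(config, substeps)
    n_strobe = int(in_strobe.sum())
    frame_sum = np.zeros((n, n_frames, 3))
    sub = np.empty((n, n_frames * substeps, 3)) if keep_substeps else None
    k = 0
    for f in range(n_frames):
        for i in range(substeps):
            if keep_substeps:
                sub[:, k] = pos
            if in_strobe[i]:
                frame_sum[:, f] += pos
            pos = pos + step_sd * rng.standard_normal((n, 3))
            if not unconfined:
                pos = reflect_into(pos, geometry)
            k += 1
    return frame_sum / n_strobe, sub


def simulate_trajectory(geometry: CellGeometry, D: float, n_frames: int,
                        config: ImagingConfig | None = None,
                        substeps_per_frame: int = DEFAULT_SUBSTEPS_PER_FRAME,
                        seed: int | None = None, unconfined: bool = False,
                        bleach_rate: float = 0.0,
                        init: np.ndarray | None = None,
                        species: str | None = None) -> TruePath:
    """Simulate one emitter diffusing in a spherocylinder.

    Brownian increments at ``dt = frame_interval / substeps_per_frame`` with
    specular reflection on the cell surface; the reported per-frame position
    is the mean of the substep positions inside the strobe window (motion
    blur). ``unconfined=True`` removes the boundary (radius -> infinity).
    """
    if D < 0:
        raise ConfigError("D must be >= 0")
    if substeps_per_frame < 1:
        raise ConfigError("substeps_per_frame must be >= 1")
    config = config or ImagingConfig()
    rng = np.random.default_rng(seed)
    frame_pos, sub = _simulate_ensemble(
        geometry, np.array([D]), n_frames, config, substeps_per_frame, rng,
        unconfined=unconfined, init=init, keep_substeps=True)
    if bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / bleach_rate)
        alive = np.arange(n_frames) * config.frame_interval < t_bleach
    else:
        alive = np.ones(n_frames, dtype=bool)
    if species is None:
        species = "immobile" if D == 0 else ("slow" if D < 1.0 else "fast")
    times = np.arange(n_frames * substeps_per_frame) * (
        config.frame_interval / substeps_per_frame)
    return TruePath(emitter_id=0, species=species, D=float(D),
                    frame_positions=frame_pos[0], substep_positions=sub[0],
                    substep_times=times, alive=alive)


# ---------------------------------------------------------------------------
# Photophysical rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedMovie:
    """Image stack plus ground-truth sidecar.

    ``origin`` is the lab-frame position (um) of the centre of pixel (0, 0);
    pixel centres sit on integer coordinates, x = column.
    """

    frames: np.ndarray           # (T, ny, nx) uint16
    origin: tuple
    truth: pd.DataFrame
    config: ImagingConfig


def _pixel_gaussian(x0: float, y0: float, sigma_px: float,
                    ny: int, nx: int) -> np.ndarray:
    """Symmetric Gaussian integrated over unit pixels (fraction per pixel)."""
    xs = np.arange(nx)
    ys = np.arange(ny)
    sq2s = np.sqrt(2.0) * sigma_px
    fx = 0.5 * (special.erf((xs - x0 + 0.5) / sq2s)
                - special.erf((xs - x0 - 0.5) / sq2s))
    fy = 0.5 * (special.erf((ys - y0 + 0.5) / sq2s)
                - special.erf((ys - y0 - 0.5) / sq2s))
    return np.outer(fy, fx)


def render_movie(paths: list[TruePath], geometry: CellGeometry,
                 config: ImagingConfig | None = None,
                 frame_count: int | None = None, seed: int | None = None,
                 shape: tuple[int, int] | None = None, margin_px: int = 6,
                 noise: bool = True) -> RenderedMovie:
    """Rasterize ground-truth paths into an EMCCD-like 16-bit image stack.

    Each live emitter becomes a symmetric 2D Gaussian (sd = ``psf_sigma``)
    integrated over pixels, with Poisson photon noise (variance doubled to
    approximate EMCCD excess noise), Poisson background, EM gain and Gaussian
    read noise. With ``noise=False`` the expected counts are returned
    (rounded to integers). The z coordinate is projected out: no focal
    sectioning is applied.
    """
    config = config or ImagingConfig()
    if config.pixel_size <= 0:
        raise ConfigError("pixel_size must be > 0")
    rng = np.random.default_rng(seed)
    if frame_count is None:
        frame_count = max(p.frame_positions.shape[0] for p in paths) if paths else 1
    ps = config.pixel_size
    # lab-frame xy positions per path
    labs = [geometry.to_lab(p.frame_positions[:, :2]) for p in paths]
    if shape is None:
        if labs:
            allp = np.vstack(labs)
            x0 = allp[:, 0].min() / ps - margin_px
            y0 = allp[:, 1].min() / ps - margin_px
            nx = int(np.ceil((allp[:, 0].max() - allp[:, 0].min()) / ps)) + 2 * margin_px + 1
            ny = int(np.ceil((allp[:, 1].max() - allp[:, 1].min()) / ps)) + 2 * margin_px + 1
        else:
            x0 = y0 = 0.0
            nx = ny = 2 * margin_px + 1
        origin = (x0 * ps, y0 * ps)
    else:
        ny, nx = shape
        origin = (0.0, 0.0)
    truth_rows = []
    frames = np.empty((frame_count, ny, nx), dtype=np.uint16)
    for f in range(frame_count):
        lam = np.full((ny, nx), float(config.background_rate))
        for path, lab in zip(paths, labs):
            if f >= path.frame_positions.shape[0] or not path.alive[f]:
                continue
            x_px = (lab[f, 0] - origin[0]) / ps
            y_px = (lab[f, 1] - origin[1]) / ps
            if not (0 <= x_px <= nx - 1 and 0 <= y_px <= ny - 1):
                raise ConfigError("emitter outside the field of view")
            sigma_px = config.psf_sigma / ps
            lam += config.photons_per_strobe * _pixel_gaussian(
                x_px, y_px, sigma_px, ny, nx)
            truth_rows.append({
                "emitter_id": path.emitter_id, "frame": f,
                "x_um": lab[f, 0], "y_um": lab[f, 1],
                "z_um": path.frame_positions[f, 2],
                "species": path.species, "alive": bool(path.alive[f]),
            })
        if noise:
            # doubled-variance Poisson approximates the EMCCD gain register
            photons = 2.0 * rng.poisson(lam / 2.0)
            counts = config.em_gain * photons + rng.normal(
                0.0, config.read_noise, size=lam.shape)
        else:
            counts = config.em_gain * lam
        frames[f] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(truth_rows, columns=["emitter_id", "frame", "x_um",
                                              "y_um", "z_um", "species", "alive"])
    return RenderedMovie(frames=frames, origin=origin, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Geometric localized tracks (fast path for calibration)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedField:
    """Localization table with ground truth plus the per-cell geometry table."""

    localizations: pd.DataFrame
    cells: pd.DataFrame
    config: ImagingConfig


def simulate_localized_tracks(geometry: CellGeometry,
                              species_mix: list[tuple[float, float]],
                              mean_emitters_per_cell: float = 1.5,
                              n_cells: int = 500,
                              config: ImagingConfig | None = None,
                              n_frames: int = 10,
                              substeps_per_frame: int = DEFAULT_SUBSTEPS_PER_FRAME,
                              seed: int | None = None,
                              unconfined: bool = False,
                              cell_pitch_um: float = 6.0) -> SimulatedField:
    """Simulate strobe-averaged emitter positions plus localization error.

    ``species_mix`` is a list of (D in um^2/s, weight) pairs with weights
    summing to 1. Each cell receives a Poisson number of emitters (mean
    ``mean_emitters_per_cell``); cells are laid out on a square lab-frame
    grid with ``cell_pitch_um`` spacing so fields can be linked globally.
    The observed localization is the 2D projection of the strobe-averaged
    true position plus independent per-axis Gaussian error
    ``config.loc_error_axis``.
    """
    if not species_mix:
        raise ConfigError("species_mix must not be empty")
    weights = np.array([w for _, w in species_mix], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigError("species weights must sum to 1")
    config = config or ImagingConfig()
    rng = np.random.default_rng(seed)

    counts = rng.poisson(mean_emitters_per_cell, size=n_cells)
    n_emitters = int(counts.sum())
    cell_of = np.repeat(np.arange(n_cells), counts)
    side = int(np.ceil(np.sqrt(n_cells)))
    centers = np.column_stack([(np.arange(n_cells) % side) * cell_pitch_um,
                               (np.arange(n_cells) // side) * cell_pitch_um])
    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "length_um": geometry.length, "radius_um": geometry.radius,
        "center_x_um": centers[:, 0], "center_y_um": centers[:, 1],
        "orientation_rad": 0.0,
    })
    if n_emitters == 0:
        cols = ["cell_id", "emitter_id", "species", "D_true", "frame",
                "x_um", "y_um", "x_true_um", "y_true_um"]
        return SimulatedField(pd.DataFrame(columns=cols), cells, config)

    Ds = np.array([d for d, _ in species_mix])
    sp_idx = rng.choice(len(Ds), size=n_emitters, p=weights)
    frame_pos, _ = _simulate_ensemble(geometry, Ds[sp_idx], n_frames, config,
                                      substeps_per_frame, rng,
                                      unconfined=unconfined)
    true_xy = frame_pos[:, :, :2] + centers[cell_of][:, None, :]
    s = config.loc_error_axis
    obs_xy = true_xy + (rng.normal(0.0, s, size=true_xy.shape) if s > 0 else 0.0)

    n_total = n_emitters * n_frames
    loc = pd.DataFrame({
        "cell_id": np.repeat(cell_of, n_frames),
        "emitter_id": np.repeat(np.arange(n_emitters), n_frames),
        "species": np.repeat(
            np.array(["slow" if d < 1.0 else "fast" for d in Ds])[sp_idx], n_frames),
        "D_true": np.repeat(Ds[sp_idx], n_frames),
        "frame": np.tile(np.arange(n_frames), n_emitters),
        "x_um": obs_xy.reshape(n_total, 2)[:, 0],
        "y_um": obs_xy.reshape(n_total, 2)[:, 1],
        "x_true_um": true_xy.reshape(n_total, 2)[:, 0],
        "y_true_um": true_xy.reshape(n_total, 2)[:, 1],
    })
    return SimulatedField(loc, cells, config)


# ---------------------------------------------------------------------------
# Photobleaching traces
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTraceSet:
    """Quantized stepwise photobleaching traces with ground truth."""

    time: np.ndarray                 # (n_frames,) seconds
    traces: np.ndarray               # (n_cells, n_frames)
    true_counts: np.ndarray          # (n_cells,)
    unitary_intensity: float
    bleach_rate: float
    noise_sd: float


def simulate_bleach_traces(n_cells: int, molecules_per_cell,
                           unitary_intensity: float, bleach_rate: float,
                           noise_sd: float, frame_interval: float,
                           n_frames: int | None = None,
                           seed: int | None = None) -> SyntheticTraceSet:
    """Simulate per-cell intensity traces with quantized bleaching steps.

    Each molecule bleaches at an independent exponential time with rate
    ``bleach_rate``; the trace is ``unitary_intensity * n_alive(t)`` plus
    Gaussian noise. ``molecules_per_cell`` may be a scalar (same count in
    every cell) or a length-``n_cells`` sequence.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    counts = np.broadcast_to(np.asarray(molecules_per_cell, dtype=int),
                             (n_cells,)).copy()
    if (counts < 0).any():
        raise ConfigError("molecules_per_cell must be >= 0")
    rng = np.random.default_rng(seed)
    if n_frames is None:
        horizon = 5.0 / bleach_rate if bleach_rate > 0 else 1.0
        n_frames = max(int(np.ceil(horizon / frame_interval)), 10)
    t = np.arange(n_frames) * frame_interval
    traces = np.empty((n_cells, n_frames))
    for c in range(n_cells):
        if counts[c] > 0 and bleach_rate > 0:
            t_bleach = rng.exponential(1.0 / bleach_rate, size=counts[c])
            alive = (t[None, :] < t_bleach[:, None]).sum(axis=0)
        else:
            alive = np.full(n_frames, counts[c])
        traces[c] = unitary_intensity * alive
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=traces.shape)
    return SyntheticTraceSet(time=t, traces=traces, true_counts=counts,
                             unitary_intensity=float(unitary_intensity),
                             bleach_rate=float(bleach_rate),
                             noise_sd=float(noise_sd))


# ---------------------------------------------------------------------------
# Spatial point patterns
# ---------------------------------------------------------------------------

def sample_spatial_pattern(geometry: CellGeometry, n_points: int,
                           mode: str = "uniform", bias: float = 0.0,
                           seed: int | None = None) -> np.ndarray:
    """Sample 3D cell-frame points in the spherocylinder volume.

    ``mode='uniform'`` samples uniformly in the volume (rejection from the
    bounding box). ``mode='periphery_biased'`` reweights the uniform density
    by ``w(rho) = (rho / r)**bias`` where rho is the distance from the
    midline, pushing mass toward the membrane for bias > 0; bias = 0 reduces
    to uniform.
    """
    if n_points < 1:
        raise ConfigError("n_points must be >= 1")
    if mode not in ("uniform", "periphery_biased"):
        raise ConfigError(f"unknown spatial mode: {mode!r}")
    if bias < 0:
        raise ConfigError("bias must be >= 0")
    rng = np.random.default_rng(seed)
    h, r = geometry.length / 2.0, geometry.radius
    out = np.empty((n_points, 3))
    filled = 0
    while filled < n_points:
        m = max(2 * (n_points - filled), 256)
        cand = np.column_stack([rng.uniform(-h, h, m),
                                rng.uniform(-r, r, m),
                                rng.uniform(-r, r, m)])
        d = geometry.axial_distance(cand)
        keep = d <= r
        if mode == "periphery_biased" and bias != 0.0:
            keep &= rng.random(m) < (d / r) ** bias
        cand = cand[keep]
        take = min(len(cand), n_points - filled)
        out[filled:filled + take] = cand[:take]
        filled += take
    return out


def projected_abs_y_pdf(bias: float, grid_size: int = 2001):
    """Marginal pdf of |y|/r for the periphery-biased density (unit radius).

    The biased 3D density in the cylindrical part is proportional to
    rho**bias with rho = sqrt(y^2 + z^2); projecting out z gives
    f(|y|) ∝ ∫_0^sqrt(1-y^2) (y^2 + z^2)^(bias/2) dz. Computed by
    quadrature; returns (y grid, normalized density) — the generator's
    analytic oracle for enrichment tests.
    """
    ys = np.linspace(0.0, 1.0, grid_size)

    def integrand(y):
        zmax = np.sqrt(max(1.0 - y * y, 0.0))
        if zmax == 0.0:
            return 0.0
        val, _ = integrate.quad(lambda z: (y * y + z * z) ** (bias / 2.0),
                                0.0, zmax)
        return val

    dens = np.array([integrand(y) for y in ys])
    norm = np.trapezoid(dens, ys)
    return ys, dens / norm


def true_periphery_fraction(bias: float, cutoff: float = 0.5) -> float:
    """Mass of the biased projected density at |y|/r >= cutoff (quadrature)."""
    ys, dens = projected_abs_y_pdf(bias)
    mask = ys >= cutoff
    return float(np.trapezoid(dens[mask], ys[mask]))


def bias_for_enrichment(target_pct: float, cutoff: float = 0.5) -> float:
    """Radial bias exponent whose periphery enrichment equals ``target_pct``.

    Enrichment is the percent deviation of the periphery mass from the
    uniform reference (bias = 0). Solved by bisection.
    """
    base = true_periphery_fraction(0.0, cutoff)

    def f(b):
        return (true_periphery_fraction(b, cutoff) / base - 1.0) * 100.0 - target_pct

    return float(optimize.brentq(f, 0.0 if target_pct >= 0 else -5.0,
                                 20.0 if target_pct >= 0 else 0.0, xtol=1e-4))
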