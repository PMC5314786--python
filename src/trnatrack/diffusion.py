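"""Apparent diffusion coefficients, species decomposition and calibration.

The apparent diffusion coefficient D_app of a trajectory is its mean squared
displacement truncated to the first four single-frame steps,

    D_app = sum_k [(dx_k)^2 + (dy_k)^2] / (4 n dt),   n = 4,

which for a single free species with per-axis localization error s follows a
gamma distribution with shape n and mean D + s^2/dt. Confinement in the
~3 x 1 um cell, motion blur from the 1-ms strobe and the localization error
all bias D_app away from the true D; :func:`calibrate` quantifies that bias
by running the full simulate -> link -> estimate pipeline over a grid of
true D values and inverting the resulting monotone response.

Species decomposition fits the D_app distribution to a mixture of
shape-4 gamma components (optionally with fixed means, e.g. the ribosomal
0.5 um^2/s), and the distribution of single-frame squared displacements to a
multi-exponential CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

from .config import ImagingConfig, TrackingConfig
from .geometry import CellGeometry
from .linking import Trajectory, link
from .simulate import simulate_localized_tracks

GAMMA_SHAPE_DEFAULT = 4
MOBILITY_THRESHOLD_DEFAULT = 1.0  # um^2/s; D_app below this is "slow"


# ---------------------------------------------------------------------------
# Per-trajectory estimates
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    se_um2: np.ndarray
    n_pairs: np.ndarray


def msd(trajectory: Trajectory, max_lag: int, dt: float) -> MSDCurve:
    """Time-averaged MSD over all frame pairs at each lag; gaps excluded
    naturally because lags are counted in frames."""
    if len(trajectory) < 2:
        raise ValueError("trajectory needs at least 2 localizations")
    span = int(trajectory.frames[-1] - trajectory.frames[0])
    if max_lag > span:
        warnings.warn("max_lag exceeds trajectory span; truncating")
        max_lag = span
    lags, vals, ses, ns = [], [], [], []
    fr = trajectory.frames
    for lag in range(1, max_lag + 1):
        sq = []
        # match frame pairs exactly lag frames apart
        pos = {f: i for i, f in enumerate(fr)}
        for i, f in enumerate(fr):
            j = pos.get(f + lag)
            if j is not None:
                d = trajectory.xy[j] - trajectory.xy[i]
                sq.append(float(d @ d))
        if sq:
            sq = np.array(sq)
            lags.append(lag * dt)
            vals.append(sq.mean())
            ses.append(sq.std(ddof=1) / np.sqrt(len(sq)) if len(sq) > 1 else np.nan)
            ns.append(len(sq))
    return MSDCurve(np.array(lags), np.array(vals), np.array(ses),
                    np.array(ns, dtype=int))


def ensemble_msd(trajectories: list[Trajectory], max_lag: int,
                 dt: float) -> MSDCurve:
    """Pool squared displacements from many trajectories per lag."""
    sq = {lag: [] for lag in range(1, max_lag + 1)}
    for tr in trajectories:
        pos = {f: i for i, f in enumerate(tr.frames)}
        for lag in range(1, max_lag + 1):
            for i, f in enumerate(tr.frames):
                j = pos.get(f + lag)
                if j is not None:
                    d = tr.xy[j] - tr.xy[i]
                    sq[lag].append(float(d @ d))
    lags, vals, ses, ns = [], [], [], []
    for lag in range(1, max_lag + 1):
        if sq[lag]:
            a = np.array(sq[lag])
            lags.append(lag * dt)
            vals.append(a.mean())
            ses.append(a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else np.nan)
            ns.append(len(a))
    return MSDCurve(np.array(lags), np.array(vals), np.array(ses),
                    np.array(ns, dtype=int))


@dataclass
class DiffusionEstimate:
    traj_id: int
    D_app: float
    n_steps: int
    mobility_class: str  # "slow" | "fast"


def apparent_D(trajectory: Trajectory, n_steps: int = 4, dt: float = 0.005,
               mobility_threshold: float = MOBILITY_THRESHOLD_DEFAULT
               ) -> DiffusionEstimate | None:
    """Truncated-MSD apparent diffusion coefficient of one trajectory.

    Uses the first ``n_steps`` *single-frame* steps (gap-bridged steps are
    skipped, not rescaled). Returns None when fewer than ``n_steps`` valid
    steps exist — such trajectories are excluded from the D_app distribution.
    """
    dfr = np.diff(trajectory.frames)
    dxy = np.diff(trajectory.xy, axis=0)
    single = dfr == 1
    sq = (dxy[single] ** 2).sum(axis=1)
    if len(sq) < n_steps:
        return None
    sq = sq[:n_steps]
    D = float(sq.sum() / (4.0 * n_steps * dt))
    cls = "slow" if D < mobility_threshold else "fast"
    return DiffusionEstimate(trajectory.traj_id, D, n_steps, cls)


def apparent_D_table(trajectories: list[Trajectory], n_steps: int = 4,
                     dt: float = 0.005,
                     mobility_threshold: float = MOBILITY_THRESHOLD_DEFAULT
                     ) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        est = apparent_D(tr, n_steps=n_steps, dt=dt,
                         mobility_threshold=mobility_threshold)
        if est is not None:
            rows.append({"traj_id": est.traj_id, "D_app_um2_s": est.D_app,
                         "n_steps": est.n_steps, "class": est.mobility_class,
                         "cell_id": tr.cell_id if tr.cell_id is not None else -1})
    return pd.DataFrame(rows, columns=["traj_id", "D_app_um2_s", "n_steps",
                                       "class", "cell_id"])


def precision_from_fixed(D_fixed: float, dt: float) -> float:
    """Localization precision sigma from the fixed-cell apparent D.

    Immobilized emitters give D_app = sigma^2 / (4 dt), so
    sigma = sqrt(4 D_fixed dt). In this convention sigma equals twice the
    per-axis single-localization error s (D_app mean = s^2/dt = sigma^2/(4dt)).
    """
    if D_fixed < 0 or dt < 0:
        raise ValueError("inputs must be >= 0")
    return float(np.sqrt(4.0 * D_fixed * dt))


# ---------------------------------------------------------------------------
# Gamma-mixture decomposition of the D_app distribution
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    n_species: int
    means: np.ndarray          # per-species mean apparent D (um^2/s)
    weights: np.ndarray
    constrained: np.ndarray    # bool per species
    shape: int
    log_likelihood: float
    converged: bool

    def sorted(self) -> "MixtureFit":
        order = np.argsort(self.means)
        return MixtureFit(self.n_species, self.means[order],
                          self.weights[order], self.constrained[order],
                          self.shape, self.log_likelihood, self.converged)


def _gamma_logpdf(x: np.ndarray, mean: float, shape: int) -> np.ndarray:
    # Gamma with fixed shape parameterized by its mean: scale = mean/shape
    return stats.gamma.logpdf(x, a=shape, scale=max(mean, 1e-12) / shape)


def fit_gamma_mixture(D_values, m: int = 2, shape: int = GAMMA_SHAPE_DEFAULT,
                      constraints: dict[int, float] | None = None,
                      n_restarts: int = 10, max_iter: int = 500,
                      tol: float = 1e-9, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood fit of sum_j A_j Gamma(shape, mean=D_j) by EM.

    ``constraints`` maps species index (after ascending-mean ordering of the
    initialization) to a fixed mean, e.g. ``{0: 0.5}`` pins the slow species
    to ribosomal-complex diffusion. Multi-start EM with a deterministic seed;
    the best run by log-likelihood is returned, species sorted by mean.
    """
    x = np.asarray(D_values, dtype=float)
    x = x[x > 0]
    if len(x) < 50:
        raise ValueError("need at least 50 positive D_app values")
    if m not in (1, 2, 3):
        raise ValueError("m must be 1, 2 or 3")
    constraints = constraints or {}
    rng = np.random.default_rng(seed)
    best = None
    qs = np.quantile(x, np.linspace(0.15, 0.85, m))
    for restart in range(n_restarts):
        means = qs * (1.0 if restart == 0 else rng.uniform(0.5, 2.0, size=m))
        for j, v in constraints.items():
            means[j] = v
        weights = np.full(m, 1.0 / m)
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            logp = np.array([np.log(max(weights[j], 1e-300))
                             + _gamma_logpdf(x, means[j], shape)
                             for j in range(m)])
            mx = logp.max(axis=0)
            lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
            ll = float(lse.sum())
            resp = np.exp(logp - lse)
            weights = resp.mean(axis=1)
            for j in range(m):
                if j in constraints:
                    means[j] = constraints[j]
                else:
                    denom = resp[j].sum()
                    if denom > 0:
                        means[j] = float(resp[j] @ x / denom)
            if abs(ll - prev_ll) < tol * (1 + abs(ll)):
                converged = True
                break
            prev_ll = ll
        fit = MixtureFit(m, means.copy(), weights.copy(),
                         np.array([j in constraints for j in range(m)]),
                         shape, ll, converged)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best.sorted()


# ---------------------------------------------------------------------------
# CDF fit of single-frame squared displacements
# ---------------------------------------------------------------------------

@dataclass
class CDFFit:
    D: np.ndarray              # per-species D (um^2/s), ascending
    weights: np.ndarray
    offset_um2: float          # 4 s^2 noise offset used in the model
    residual_norm: float
    ok: bool


def squared_displacements(trajectories: list[Trajectory]) -> np.ndarray:
    """All single-frame squared displacements pooled over trajectories."""
    out = []
    for tr in trajectories:
        dfr = np.diff(tr.frames)
        dxy = np.diff(tr.xy, axis=0)
        sq = (dxy[dfr == 1] ** 2).sum(axis=1)
        out.append(sq)
    return np.concatenate(out) if out else np.array([])


def fit_cdf(sq_disp, m: int = 2, s_axis: float = 0.04,
            dt: float = 0.005) -> CDFFit:
    """Least-squares fit of the empirical CDF of squared displacements.

    Model: F(u) = 1 - sum_j A_j exp(-u / (4 D_j dt + 4 s_axis^2)) with
    sum A_j = 1 — each species contributes an exponential tail whose decay
    constant combines diffusion over one frame and the localization error at
    both ends. Species are returned in ascending D order.
    """
    u = np.sort(np.asarray(sq_disp, dtype=float))
    if len(u) < 200:
        raise ValueError("need at least 200 squared displacements")
    if u[0] == u[-1]:
        return CDFFit(np.full(m, np.nan), np.full(m, np.nan),
                      4 * s_axis ** 2, np.inf, ok=False)
    emp = (np.arange(1, len(u) + 1) - 0.5) / len(u)
    offset = 4.0 * s_axis ** 2

    def model(params):
        Ds = params[:m]
        if m == 1:
            A = np.array([1.0])
        else:
            raw = params[m:]
            A = np.concatenate([raw, [1.0 - raw.sum()]])
        tau = 4.0 * Ds * dt + offset
        F = 1.0 - (A[None, :] * np.exp(-u[:, None] / tau[None, :])).sum(axis=1)
        return F, A

    def resid(params):
        F, A = model(params)
        pen = 0.0
        if m > 1 and (A < 0).any():
            pen = 1e3 * np.abs(A[A < 0]).sum()
        return F - emp + pen

    mean_u = u.mean()
    D0 = np.maximum((mean_u - offset) / (4 * dt), 1e-3)
    if m == 1:
        x0 = np.array([D0])
    else:
        scale = np.geomspace(0.1, 2.0, m)
        x0 = np.concatenate([D0 * scale, np.full(m - 1, 1.0 / m)])
    lb = np.concatenate([np.zeros(m), np.zeros(m - 1)])
    ub = np.concatenate([np.full(m, np.inf), np.ones(m - 1)])
    res = optimize.least_squares(resid, x0, bounds=(lb, ub))
    F, A = model(res.x)
    Ds = res.x[:m]
    order = np.argsort(Ds)
    return CDFFit(Ds[order], A[order], offset,
                  float(np.linalg.norm(F - emp)), ok=res.success)


# ---------------------------------------------------------------------------
# Apparent -> accurate calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    true_D: np.ndarray
    apparent_mean: np.ndarray
    apparent_sd: np.ndarray      # sd over replicate runs
    _forward: PchipInterpolator = field(repr=False)
    _inverse: PchipInterpolator = field(repr=False)

    def apparent(self, true_D: float) -> float:
        return float(self._forward(true_D))

    def accurate(self, apparent_D: float,
                 apparent_err: float = 0.0) -> tuple[float, float]:
        """Invert the calibration: accurate D and a propagated uncertainty.

        The uncertainty combines, in quadrature, the replicate scatter of
        the calibration (mapped through the local inverse slope) and the
        measurement error of the apparent value.
        """
        val = float(self._inverse(apparent_D))
        slope = float(self._inverse.derivative()(apparent_D))
        local_sd = float(np.interp(apparent_D, self.apparent_mean,
                                   self.apparent_sd))
        err = abs(slope) * float(np.hypot(local_sd, apparent_err))
        return val, err


class CalibrationError(RuntimeError):
    pass


def calibrate(true_D_grid, geometry: CellGeometry,
              config: ImagingConfig | None = None,
              tracking: TrackingConfig | None = None,
              n_cells: int = 500, mean_per_cell: float = 1.5,
              n_frames: int = 10, replicates: int = 3,
              n_steps: int = 4, seed: int = 0, unconfined: bool = False,
              substeps_per_frame: int | None = None) -> CalibrationCurve:
    """Map true D to mean apparent D by running the full pipeline per grid point.

    For every true D on the (increasing) grid and every replicate:
    simulate geometric localized tracks in the given cell geometry, link
    them with the displacement-window tracker, compute per-trajectory
    four-step apparent D values and record their mean. A monotone PCHIP
    interpolant provides the forward map and its inverse.
    """
    grid = np.asarray(true_D_grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("true_D_grid must be strictly increasing")
    config = config or ImagingConfig()
    tracking = tracking or TrackingConfig()
    means = np.empty((len(grid), replicates))
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(grid) * replicates) % (2 ** 31)
    k = 0
    for i, D in enumerate(grid):
        for rep in range(replicates):
            kwargs = {}
            if substeps_per_frame is not None:
                kwargs["substeps_per_frame"] = substeps_per_frame
            field_ = simulate_localized_tracks(
                geometry, [(float(D), 1.0)], mean_per_cell, n_cells,
                config=config, n_frames=n_frames, seed=int(seeds[k]),
                unconfined=unconfined, **kwargs)
            k += 1
            trajs = link(field_.localizations, tracking)
            tab = apparent_D_table(trajs, n_steps=n_steps,
                                   dt=config.frame_interval)
            if len(tab) == 0:
                raise CalibrationError(f"no usable trajectories at D={D}")
            means[i, rep] = tab["D_app_um2_s"].mean()
    mean = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1) if replicates > 1 else np.zeros(len(grid))
    if not np.all(np.diff(mean) > 0):
        raise CalibrationError(
            "apparent D not strictly increasing along the grid; "
            f"grid={grid.tolist()}, apparent={mean.tolist()} — increase "
            "n_cells/replicates or thin the grid")
    forward = PchipInterpolator(grid, mean, extrapolate=True)
    inverse = PchipInterpolator(mean, grid, extrapolate=True)
    return CalibrationCurve(grid, mean, sd, forward, inverse)


# ---------------------------------------------------------------------------
# Diffusion-budget arithmetic for the tRNA cycle
# ---------------------------------------------------------------------------

@dataclass
class CycleBudget:
    aa_time_s: float
    ribosomes: int
    pool: int
    sites_per_ribosome: int
    bound: int
    searching: int
    bound_fraction: float          # exact bound/pool
    bound_fraction_rounded: float  # the rounded value the cycle uses
    bound_time_s: float
    cycle_time_s: float
    search_time_s: float
    exploration_time_s: float
    cell_dims_um: tuple


def cycle_budget(aa_time: float = 0.050, ribosomes: int = 50_000,
                 pool: int = 375_000, sites: int = 2,
                 bound_fraction_rounded: float = 0.25, D: float = 8.0,
                 cell_dims: tuple = (3.0, 1.0),
                 msd_target_um2: float | None = None) -> CycleBudget:
    """Back-of-envelope tRNA cycle: is diffusion rate-limiting for translation?

    With two tRNA sites occupied at every ribosome, ``bound = sites *
    ribosomes`` of the cellular tRNA pool are ribosome-bound and the rest
    search by diffusion. The ribosome-bound dwell is ``sites * aa_time``;
    dividing by the (rounded) bound fraction gives the full cycle, the
    remainder being search-and-charging. The exploration time is when the 3D
    MSD ``6 D t`` reaches ``msd_target_um2`` (by default the long cell
    dimension's numeric value in um^2, the conventional whole-cell target
    for a 3 x 1 um cell).
    """
    if pool < sites * ribosomes:
        raise ValueError("pool must cover all ribosome sites")
    if D <= 0:
        raise ValueError("exploration time undefined for D = 0")
    bound = sites * ribosomes
    searching = pool - bound
    bound_time = sites * aa_time
    cycle = bound_time / bound_fraction_rounded
    search = cycle - bound_time
    if msd_target_um2 is None:
        msd_target_um2 = float(max(cell_dims))
    exploration = msd_target_um2 / (6.0 * D)
    return CycleBudget(aa_time, ribosomes, pool, sites, bound, searching,
                       bound / pool, bound_fraction_rounded, bound_time,
                       cycle, search, exploration, tuple(cell_dims))
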