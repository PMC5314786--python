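"""Counting internalized molecules from single-cell photobleaching traces.

A cell loaded with k fluorophores photobleaches in quantized downward steps
of one unitary intensity u. A hidden Markov model with states k = 0..K
(emission Normal(k*u, sd), transitions k -> k and k -> k-1 only, with a
shared per-frame single-molecule bleach probability) is fit over a
deterministic grid of u and decoded by Viterbi; the decoded down-transitions
give the step heights. Pooling step heights over many cells and fitting the
histogram with a single Gaussian gives the population unitary intensity,
which converts total cellular fluorescence into molecules per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


class TraceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Baseline and lifetime
# ---------------------------------------------------------------------------

def subtract_baseline(trace: np.ndarray, plateau_fraction: float = 0.1
                      ) -> tuple[np.ndarray, float]:
    """Subtract the post-bleach plateau (mean of the last fraction of frames).

    Returns (baseline-subtracted trace, baseline). The plateau window must
    contain at least one frame.
    """
    trace = np.asarray(trace, dtype=float)
    n_tail = int(round(len(trace) * plateau_fraction))
    if n_tail < 1:
        raise TraceError("trace shorter than the plateau window")
    baseline = float(trace[-n_tail:].mean())
    return trace - baseline, baseline


@dataclass
class LifetimeFit:
    tau_s: float
    tau_ci_s: tuple
    amplitude: float
    offset: float
    ok: bool


def fit_lifetime(time_s: np.ndarray, trace: np.ndarray) -> LifetimeFit:
    """Photobleaching lifetime from a single-exponential (+ offset) fit.

    Nonlinear least squares of A exp(-t/tau) + c; a non-decaying trace
    (fitted A <= 0 or failed convergence) is flagged rather than raised.
    The CI is the ~95% interval from the tau covariance entry.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(trace, dtype=float)
    a0 = float(y[0] - y[-1])
    if a0 <= 0:
        return LifetimeFit(np.nan, (np.nan, np.nan), a0, float(y[-1]), ok=False)
    span = t[-1] - t[0]
    tau0 = max(span / 5.0, (t[1] - t[0]))

    def model(t, A, tau, c):
        return A * np.exp(-t / tau) + c

    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[a0, tau0, y[-1]],
            bounds=([0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
    except Exception:
        return LifetimeFit(np.nan, (np.nan, np.nan), np.nan, np.nan, ok=False)
    A, tau, c = popt
    if A <= 0 or not np.isfinite(tau):
        return LifetimeFit(np.nan, (np.nan, np.nan), A, c, ok=False)
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return LifetimeFit(float(tau), (tau - 1.96 * se, tau + 1.96 * se),
                       float(A), float(c), ok=True)


# ---------------------------------------------------------------------------
# HMM step counting
# ---------------------------------------------------------------------------

@dataclass
class StepFitResult:
    state_path: np.ndarray     # molecule count per frame, non-increasing
    step_heights: np.ndarray   # one entry per decoded down-transition
    unitary: float             # fitted u (nan when no steps decodable)
    unitary_sd: float
    n_steps: int               # decoded down-steps within the trace
    n_molecules: int           # decoded initial state (molecules present)
    log_likelihood: float
    ok: bool


def _ladder_transitions(p: float, K: int):
    """Log stay/down probabilities of the bleaching ladder.

    From state k the chain stays with prob (1-p)**k (no molecule bleaches)
    or drops to k-1 otherwise (one or more bleach events, collapsed onto a
    single down-step); the dark state k = 0 is absorbing.
    """
    stay = (1.0 - p) ** np.arange(K + 1)
    stay = np.clip(stay, 1e-12, 1.0)
    stay[0] = 1.0
    down = np.maximum(1.0 - stay, 1e-300)
    return np.log(stay), np.log(down)


def _ladder_forward_batch(y: np.ndarray, us: np.ndarray, sd: float, p: float,
                          max_molecules: int) -> np.ndarray:
    """Forward log-likelihood for every candidate u at once.

    Emission is Normal(k*u, sd) for states k = 0..K; returns shape (len(us),).
    """
    K = max_molecules
    n = len(y)
    levels = us[:, None] * np.arange(K + 1)[None, :]     # (G, K+1)
    log_norm = np.log(sd * np.sqrt(2 * np.pi))
    log_stay, log_down = _ladder_transitions(p, K)
    alpha = -0.5 * ((y[0] - levels) / sd) ** 2 - log_norm - np.log(K + 1)
    for i in range(1, n):
        prev_stay = alpha + log_stay
        prev_down = np.full_like(alpha, -np.inf)
        prev_down[:, :-1] = alpha[:, 1:] + log_down[1:]
        m = np.maximum(prev_stay, prev_down)
        trans = m + np.log(np.exp(prev_stay - m) + np.exp(prev_down - m))
        alpha = trans - 0.5 * ((y[i] - levels) / sd) ** 2 - log_norm
    mx = alpha.max(axis=1)
    return mx + np.log(np.exp(alpha - mx[:, None]).sum(axis=1))


def _ladder_loglik_and_path(y: np.ndarray, u: float, sd: float, p: float,
                            max_molecules: int):
    """Forward log-likelihood and Viterbi path for a single u."""
    K = max_molecules
    n = len(y)
    ll = float(_ladder_forward_batch(y, np.array([u]), sd, p, K)[0])
    levels = np.arange(K + 1) * u
    log_norm = np.log(sd * np.sqrt(2 * np.pi))
    log_em = -0.5 * ((y[:, None] - levels[None, :]) / sd) ** 2 - log_norm
    log_stay, log_down = _ladder_transitions(p, K)
    delta = log_em[0] - np.log(K + 1)
    back = np.zeros((n, K + 1), dtype=np.int8)  # 1 = came from k+1
    for i in range(1, n):
        cand_stay = delta + log_stay
        cand_down = np.full(K + 1, -np.inf)
        cand_down[:-1] = delta[1:] + log_down[1:]
        take_down = cand_down > cand_stay
        delta = np.where(take_down, cand_down, cand_stay) + log_em[i]
        back[i] = take_down
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = path[i] + (1 if back[i, path[i]] else 0)
    return ll, path


def hmm_steps(trace: np.ndarray, max_molecules: int = 6,
              frame_interval: float | None = None,
              u_grid_size: int = 40,
              p_grid=(0.002, 0.005, 0.01, 0.02, 0.05)) -> StepFitResult:
    """Fit the bleaching-ladder HMM to a baseline-subtracted trace.

    u is searched over ``u_grid_size`` log-spaced values around a robust
    initial guess (the larger of the biggest single-frame drop and the
    initial level divided by the candidate state count); the noise sd is
    estimated from first differences; the per-frame bleach probability over
    a small grid. The (u, p) pair maximizing the forward likelihood wins and
    the Viterbi path provides the decoded molecule count and step heights.
    Deterministic and seed-free.
    """
    y = np.asarray(trace, dtype=float)
    if len(y) < 4:
        raise TraceError("trace too short for step fitting")
    d = np.diff(y)
    # MAD about the median diff: robust to the bleaching steps themselves
    sd = float(np.median(np.abs(d - np.median(d))) / (np.sqrt(2) * 0.6745))
    # initial level from the first frames only (the first bleach may be early)
    top = float(np.median(y[:3]))
    if sd <= 0:
        sd = max(1e-3 * max(abs(top), 1.0), 1e-9)
    if top <= 2.5 * sd:
        # effectively empty cell: nothing to count
        return StepFitResult(np.zeros(len(y), dtype=int), np.array([]),
                             np.nan, np.nan, 0, 0, -np.inf, ok=False)
    drops = -np.diff(y)
    big_drop = float(drops.max()) if len(drops) else 0.0
    u0_candidates = [top / k for k in range(1, max_molecules + 1)]
    u0 = max(big_drop, min(u0_candidates))
    u0 = float(np.clip(u0, top / max_molecules, top))
    u_grid = np.geomspace(u0 / 2.5, min(u0 * 2.5, top * 1.2), u_grid_size)
    u_grid = u_grid[top / u_grid <= max_molecules + 0.5]
    if len(u_grid) == 0:
        u_grid = np.array([top / max_molecules])
    best = None
    for p in p_grid:
        lls = _ladder_forward_batch(y, u_grid, sd, p, max_molecules)
        j = int(np.argmax(lls))
        if best is None or lls[j] > best[0]:
            best = (float(lls[j]), float(u_grid[j]), p)
    _, u, p = best
    ll, path = _ladder_loglik_and_path(y, u, sd, p, max_molecules)
    # refine u by least squares against the decoded levels, then re-decode
    den = float(path @ path)
    if den > 0:
        u_ref = float(path @ y) / den
        if top / u_ref <= max_molecules + 0.5 and u_ref > 0:
            ll, path = _ladder_loglik_and_path(y, u_ref, sd, p, max_molecules)
            u = u_ref
    steps = np.nonzero(np.diff(path) < 0)[0]
    heights = np.array([u * (path[i] - path[i + 1]) for i in steps])
    return StepFitResult(path, heights, float(u), float(sd),
                         int(path[0] - path[-1]), int(path[0]), ll, ok=True)


# ---------------------------------------------------------------------------
# Unitary intensity and per-cell counts
# ---------------------------------------------------------------------------

@dataclass
class UnitaryFit:
    center: float
    width: float
    amplitude: float
    residual_rms: float
    good_fit: bool


def unitary_intensity(step_heights, n_bins: int | None = None,
                      residual_threshold: float = 0.2) -> UnitaryFit:
    """Gaussian fit to the step-height histogram.

    Free parameters: position, width, amplitude. ``good_fit`` flags whether
    the relative residual RMS is below ``residual_threshold`` — a bimodal
    height distribution (e.g. frequent double steps) fails this diagnostic.
    """
    h = np.asarray(step_heights, dtype=float)
    if len(h) < 30:
        raise ValueError("need at least 30 step heights")
    if np.ptp(h) == 0:
        return UnitaryFit(float(h[0]), 0.0, float(len(h)), 0.0, True)
    if n_bins is None:
        n_bins = max(int(np.sqrt(len(h))), 8)
    counts, edges = np.histogram(h, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, mu, sig, amp):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    p0 = [float(np.mean(h)), float(np.std(h)) or 1.0, float(counts.max())]
    popt, _ = optimize.curve_fit(gauss, centers, counts, p0=p0,
                                 bounds=([edges[0], 1e-9, 0],
                                         [edges[-1], np.ptp(h), np.inf]),
                                 maxfev=20000)
    resid = counts - gauss(centers, *popt)
    rel_rms = float(np.sqrt(np.mean(resid ** 2)) / max(counts.max(), 1))
    return UnitaryFit(float(popt[0]), float(abs(popt[1])), float(popt[2]),
                      rel_rms, rel_rms <= residual_threshold)


def count_molecules(total_cell_fluorescence: float, u: float) -> float:
    """Molecules per cell = total fluorescence / unitary intensity."""
    if u <= 0:
        raise ValueError("unitary intensity must be > 0")
    return float(total_cell_fluorescence) / float(u)


# ---------------------------------------------------------------------------
# Loaded-cell classification
# ---------------------------------------------------------------------------

def classify_loaded(cell_values, control_values) -> pd.DataFrame:
    """Flag cells whose fluorescence per area exceeds control mean + 3 sd.

    ``control_values`` are non-electroporated cells; at least 10 are
    required. Zero-variance controls degrade the threshold to the control
    mean (flagged via the returned threshold).
    """
    control = np.asarray(control_values, dtype=float)
    if len(control) < 10:
        raise ValueError("need at least 10 control cells")
    vals = np.asarray(cell_values, dtype=float)
    threshold = float(control.mean() + 3.0 * control.std(ddof=1))
    return pd.DataFrame({
        "cell_id": np.arange(len(vals)),
        "fluorescence_per_area": vals,
        "loaded": vals > threshold,
        "threshold": threshold,
    })
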