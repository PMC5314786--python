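"""Unit-cell spatial statistics of tracked molecules.

Localizations are mapped into a normalized *unit cell*: the absolute
distance along the midline scaled to [0, 1] (0 = mid-cell, 1 = pole) and the
absolute perpendicular distance scaled by the local half-width (0 = midline,
1 = outline). Pooled unit-cell positions are compared against the analytic
projection of a uniform density in a cylinder,

    pdf(rho) = 4 sqrt(max(1 - rho^2, 0)) / pi,   rho = |y| / r,

and summarized as percent enrichment of the periphery (rho >= cutoff) and
mid-cell (rho < cutoff) regions relative to that uniform reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry


def uniform_pdf(rho) -> np.ndarray:
    """Projected density of a uniform cylinder on the normalized short axis."""
    rho_arr = np.asarray(rho, dtype=float)
    if np.any((rho_arr < 0) | (rho_arr > 1)):
        raise ValueError("rho must lie in [0, 1]")
    out = 4.0 * np.sqrt(np.maximum(1.0 - rho_arr ** 2, 0.0)) / np.pi
    return out if out.ndim else float(out)


def uniform_cdf(rho) -> np.ndarray:
    """Closed-form integral of :func:`uniform_pdf` from 0 to rho."""
    rho_arr = np.asarray(rho, dtype=float)
    if np.any((rho_arr < 0) | (rho_arr > 1)):
        raise ValueError("rho must lie in [0, 1]")
    out = (2.0 / np.pi) * (rho_arr * np.sqrt(1.0 - rho_arr ** 2)
                           + np.arcsin(rho_arr))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Normalization into the unit cell
# ---------------------------------------------------------------------------

def normalize_positions(points_xy: np.ndarray, geometry: CellGeometry,
                        tolerance: float = 0.05) -> tuple[pd.DataFrame, int]:
    """Map lab-frame 2D points into unit-cell coordinates.

    x_norm = |midline arc position| / (L/2); y_norm = |perpendicular
    distance| / local half-width (radius on the cylindrical part, the
    hemispherical profile inside the caps). Points farther outside the
    outline than ``tolerance`` (um) are dropped; points within tolerance are
    clipped onto the outline. Returns (table, n_dropped).
    """
    pts = geometry.to_cell(np.atleast_2d(points_xy))
    x, y = pts[:, 0], pts[:, 1]
    half_len = geometry.length / 2.0
    w = geometry.local_half_width(x)
    # outside tolerance: beyond the pole or beyond the local outline
    out_x = np.abs(x) > half_len + tolerance
    out_y = np.abs(y) > w + tolerance
    # inside caps the half-width shrinks to 0 at the pole; guard w = 0 there
    keep = ~(out_x | out_y)
    x, y, w = x[keep], y[keep], np.maximum(w[keep], 1e-12)
    x_norm = np.clip(np.abs(x) / half_len, 0.0, 1.0)
    y_norm = np.clip(np.abs(y) / w, 0.0, 1.0)
    df = pd.DataFrame({"x_norm": x_norm, "y_norm": y_norm})
    return df, int((~keep).sum())


# ---------------------------------------------------------------------------
# Enrichment relative to the uniform reference
# ---------------------------------------------------------------------------

@dataclass
class SpatialSummary:
    cutoff: float
    n_positions: int
    observed_periphery: float
    observed_midcell: float
    uniform_periphery: float
    uniform_midcell: float
    enrichment_periphery_pct: float
    enrichment_midcell_pct: float
    ci_periphery_pct: tuple
    ci_midcell_pct: tuple
    hist_density: np.ndarray
    hist_edges: np.ndarray
    bin_label: str = ""


def enrichment(y_norm, cutoff: float = 0.5, n_bins: int = 20,
               n_boot: int = 1000, seed: int = 0,
               bin_label: str = "") -> SpatialSummary:
    """Periphery / mid-cell enrichment of normalized short-axis positions.

    Enrichment is (observed fraction / uniform fraction - 1) * 100 where the
    uniform fractions integrate the analytic cylinder pdf; the bootstrap CI
    (percentile, seeded) resamples positions.
    """
    y = np.asarray(y_norm, dtype=float)
    if len(y) < 100:
        raise ValueError("need at least 100 positions")
    uni_peri = 1.0 - uniform_cdf(cutoff)
    uni_mid = uniform_cdf(cutoff)
    obs_peri = float((y >= cutoff).mean())
    obs_mid = 1.0 - obs_peri
    if obs_peri == 0.0 or obs_mid == 0.0:
        pass  # empty region: the corresponding enrichment is -100% exactly
    enr_p = (obs_peri / uni_peri - 1.0) * 100.0
    enr_m = (obs_mid / uni_mid - 1.0) * 100.0
    rng = np.random.default_rng(seed)
    boots = rng.choice(y, size=(n_boot, len(y)), replace=True)
    bp = (boots >= cutoff).mean(axis=1)
    ci_p = tuple(np.percentile((bp / uni_peri - 1.0) * 100.0, [2.5, 97.5]))
    ci_m = tuple(np.percentile(((1 - bp) / uni_mid - 1.0) * 100.0, [2.5, 97.5]))
    dens, edges = np.histogram(y, bins=n_bins, range=(0, 1), density=True)
    return SpatialSummary(cutoff, len(y), obs_peri, obs_mid, uni_peri,
                          uni_mid, float(enr_p), float(enr_m), ci_p, ci_m,
                          dens, edges, bin_label)


def bin_by_length(cells: pd.DataFrame, positions: pd.DataFrame,
                  short_bin: tuple = (1.7, 2.9), long_bin: tuple = (3.1, 4.3),
                  cutoff: float = 0.5, seed: int = 0,
                  hist_bins: int = 20) -> dict:
    """Partition unit-cell positions into short/long cell-length bins.

    ``cells`` needs columns cell_id, length_um; ``positions`` needs cell_id,
    x_norm, y_norm. Cells outside both printed bins are excluded (their
    position count is reported). Returns per-bin SpatialSummary objects plus
    2D (x_norm, y_norm) histograms.
    """
    lengths = cells.set_index("cell_id")["length_um"]
    pos = positions.copy()
    pos["length_um"] = pos["cell_id"].map(lengths)
    out = {"excluded_positions": 0, "bins": {}}
    for label, (lo, hi) in (("short", short_bin), ("long", long_bin)):
        sel = pos[(pos["length_um"] >= lo) & (pos["length_um"] <= hi)]
        if len(sel) >= 100:
            summary = enrichment(sel["y_norm"].to_numpy(), cutoff=cutoff,
                                 seed=seed, bin_label=label)
        else:
            summary = None
        h2d, xe, ye = np.histogram2d(sel["x_norm"], sel["y_norm"],
                                     bins=hist_bins, range=[[0, 1], [0, 1]],
                                     density=len(sel) > 0)
        out["bins"][label] = {"summary": summary, "hist2d": h2d,
                              "x_edges": xe, "y_edges": ye,
                              "n_positions": len(sel)}
    in_any = ((pos["length_um"] >= short_bin[0]) & (pos["length_um"] <= short_bin[1])) | \
             ((pos["length_um"] >= long_bin[0]) & (pos["length_um"] <= long_bin[1]))
    out["excluded_positions"] = int((~in_any).sum())
    return out


def length_bin_label(length_um: float, short_bin: tuple = (1.7, 2.9),
                     long_bin: tuple = (3.1, 4.3)) -> str:
    if short_bin[0] <= length_um <= short_bin[1]:
        return "short"
    if long_bin[0] <= length_um <= long_bin[1]:
        return "long"
    return "excluded"


def slow_fast_split(positions: pd.DataFrame, estimates: pd.DataFrame,
                    threshold: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split unit-cell positions into slow / fast sets by trajectory D_app.

    ``positions`` must carry traj_id; ``estimates`` maps traj_id to
    D_app_um2_s. Returns (slow positions, fast positions, slow fraction by
    trajectory). Slow means D_app < threshold (1 um^2/s by default, under
    which 90% of fixed-cell control trajectories fall).
    """
    d = estimates.set_index("traj_id")["D_app_um2_s"]
    pos = positions.copy()
    pos["D_app_um2_s"] = pos["traj_id"].map(d)
    pos = pos.dropna(subset=["D_app_um2_s"])
    slow = pos[pos["D_app_um2_s"] < threshold]
    fast = pos[pos["D_app_um2_s"] >= threshold]
    frac_slow = float((d < threshold).mean()) if len(d) else np.nan
    return slow, fast, frac_slow
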