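"""Spot detection and sub-pixel localization by elliptical-Gaussian fitting.

Candidates come from a difference-of-Gaussians bandpass followed by local
maxima above a fixed intensity threshold; each candidate is then fit with a
2D elliptical Gaussian plus constant background (free parameters: x/y
position, x/y width, rotation angle, amplitude, background) on a small
window. Pixel centres sit on integer coordinates with the origin at the
top-left pixel centre and x = column; all outputs are in um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .config import ImagingConfig


@dataclass
class Localization:
    frame: int
    x_um: float
    y_um: float
    width_x_um: float
    width_y_um: float
    theta_rad: float
    amplitude: float
    background: float
    photons: float
    fit_ok: bool


def detect_candidates(frame: np.ndarray, band_low_px: float = 1.0,
                      band_high_px: float = 3.0,
                      intensity_threshold: float = 0.0,
                      min_separation_px: int = 2) -> np.ndarray:
    """Difference-of-Gaussians bandpass + thresholded local maxima.

    Returns candidate pixel positions as an (n, 2) array of (x, y) = (col,
    row). A flat frame, or a threshold no maximum clears, yields an empty
    array. Maxima closer than ``min_separation_px`` collapse to the
    brightest one.
    """
    if band_low_px >= band_high_px:
        raise ValueError("band_low_px must be < band_high_px")
    img = np.asarray(frame, dtype=float)
    bp = ndimage.gaussian_filter(img, band_low_px) - \
        ndimage.gaussian_filter(img, band_high_px)
    if bp.max() - bp.min() < 1e-12:
        return np.empty((0, 2), dtype=int)
    if not np.isfinite(intensity_threshold):
        if intensity_threshold > 0:
            return np.empty((0, 2), dtype=int)
        intensity_threshold = bp.min()
    peaks = peak_local_max(bp, min_distance=min_separation_px,
                           threshold_abs=intensity_threshold,
                           exclude_border=False)
    if peaks.size == 0:
        return np.empty((0, 2), dtype=int)
    return peaks[:, ::-1]  # (row, col) -> (x, y)


def _elliptical_gaussian(coords, x0, y0, sx, sy, theta, amp, bg):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + bg


def fit_spot(frame: np.ndarray, guess_xy: tuple, window_px: int = 9,
             frame_index: int = 0, config: ImagingConfig | None = None,
             width_equal_tol: float = 1e-3) -> Localization:
    """Least-squares elliptical-Gaussian fit on a window around ``guess_xy``.

    The window must lie fully inside the frame. Failures (non-finite pixels,
    zero contrast, non-convergence) return ``fit_ok=False``. For effectively
    symmetric spots (relative width difference below ``width_equal_tol``)
    the rotation angle is canonicalized to 0.
    """
    config = config or ImagingConfig()
    ps = config.pixel_size
    img = np.asarray(frame, dtype=float)
    gx, gy = int(round(guess_xy[0])), int(round(guess_xy[1]))
    half = window_px // 2
    if (gx - half < 0 or gy - half < 0 or gx + half >= img.shape[1]
            or gy + half >= img.shape[0]):
        raise ValueError("fit window not fully inside the frame")
    win = img[gy - half:gy + half + 1, gx - half:gx + half + 1]
    bad = Localization(frame_index, np.nan, np.nan, np.nan, np.nan, 0.0,
                       0.0, 0.0, 0.0, fit_ok=False)
    if not np.isfinite(win).all():
        return bad
    yy, xx = np.mgrid[gy - half:gy + half + 1, gx - half:gx + half + 1]
    bg0 = float(win.min())
    amp0 = float(win.max() - bg0)
    if amp0 <= 0:
        return bad
    w0 = max(config.psf_sigma / ps, 0.8)
    p0 = np.array([gx, gy, w0, w0, 0.0, amp0, bg0])
    lb = [gx - half, gy - half, 0.3, 0.3, -np.pi / 2, 0.0, -np.inf]
    ub = [gx + half, gy + half, window_px, window_px, np.pi / 2,
          np.inf, np.inf]

    def resid(p):
        return (_elliptical_gaussian((xx, yy), *p) - win).ravel()

    try:
        res = optimize.least_squares(resid, p0, bounds=(lb, ub))
    except Exception:
        return bad
    x0, y0, sx, sy, theta, amp, bg = res.x
    if not res.success or amp <= 0:
        return bad
    if abs(sx - sy) <= width_equal_tol * max(sx, sy):
        theta = 0.0
    wx_um, wy_um = sx * ps, sy * ps
    photons = 2.0 * np.pi * amp * wx_um * wy_um / (ps ** 2 * config.em_gain)
    return Localization(frame_index, x0 * ps, y0 * ps, wx_um, wy_um,
                        float(theta), float(amp), float(bg),
                        float(photons), fit_ok=True)


def localize_frame(frame: np.ndarray, frame_index: int = 0,
                   config: ImagingConfig | None = None,
                   band_low_px: float = 1.0, band_high_px: float = 3.0,
                   intensity_threshold: float = 0.0,
                   window_px: int = 9) -> list[Localization]:
    """Detect candidates in one frame and fit each; out-of-window candidates
    near the border are skipped."""
    out = []
    img = np.asarray(frame)
    half = window_px // 2
    for x, y in detect_candidates(img, band_low_px, band_high_px,
                                  intensity_threshold):
        if (x - half < 0 or y - half < 0 or x + half >= img.shape[1]
                or y + half >= img.shape[0]):
            continue
        loc = fit_spot(img, (x, y), window_px=window_px,
                       frame_index=frame_index, config=config)
        if loc.fit_ok:
            out.append(loc)
    return out


def localize_stack(frames: np.ndarray, config: ImagingConfig | None = None,
                   discard_first: int = 0, **kwargs) -> pd.DataFrame:
    """Localize every frame of a stack into a table.

    ``discard_first`` drops initial frames (the pre-bleaching period of an
    acquisition). Columns: frame, x_um, y_um, wx_um, wy_um, theta_rad,
    amplitude, background, photons, fit_ok.
    """
    rows = []
    for f in range(discard_first, frames.shape[0]):
        for loc in localize_frame(frames[f], frame_index=f, config=config,
                                  **kwargs):
            rows.append({
                "frame": loc.frame, "x_um": loc.x_um, "y_um": loc.y_um,
                "wx_um": loc.width_x_um, "wy_um": loc.width_y_um,
                "theta_rad": loc.theta_rad, "amplitude": loc.amplitude,
                "background": loc.background, "photons": loc.photons,
                "fit_ok": loc.fit_ok,
            })
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "wx_um",
                                       "wy_um", "theta_rad", "amplitude",
                                       "background", "photons", "fit_ok"])
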