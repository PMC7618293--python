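"""Spot detection and sub-pixel PSF fitting on raw movie frames.

Candidate emitters are found by a difference-of-Gaussians band-pass
followed by local-maximum selection against a robust (MAD-based) noise
threshold; sub-pixel positions come from least-squares fits of a symmetric
2D Gaussian in a small window around each candidate.

Coordinates are micrometers with the origin at the field top-left and
pixel centers at (i + 0.5) * pixel_um; frames are 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

SPOT_COLUMNS = [
    "frame",
    "x_um",
    "y_um",
    "amplitude",
    "background",
    "fit_sigma_um",
    "rms_residual",
]


def detect_spots(
    frames: np.ndarray,
    pixel_um: float,
    dog_sigmas: tuple[float, float] = (1.0, 2.0),
    threshold_snr: float = 8.0,
) -> pd.DataFrame:
    """Difference-of-Gaussians candidate detection.

    Returns pixel-resolution candidates as a frame with columns
    ``frame, x_px, y_px, x_um, y_um, dog_response``.  The threshold is
    ``threshold_snr`` times the robust noise SD (1.4826 * MAD) of the
    band-passed frame; all-zero frames simply yield no candidates.
    """
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    if frames.ndim != 3 or frames.size == 0:
        raise ValueError("frames must be a non-empty (n, y, x) stack")
    s1, s2 = dog_sigmas
    if not 0 < s1 < s2:
        raise ValueError("dog_sigmas must satisfy 0 < small < large")
    rows = []
    for f, img in enumerate(frames):
        dog = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)
        mad = np.median(np.abs(dog - np.median(dog)))
        noise = 1.4826 * mad
        if noise == 0 and dog.max() <= 0:
            continue
        thresh = threshold_snr * noise
        maxima = (dog == ndimage.maximum_filter(dog, size=3)) & (dog > thresh)
        ys, xs = np.nonzero(maxima)
        for y, x in zip(ys, xs):
            rows.append(
                {
                    "frame": f,
                    "x_px": int(x),
                    "y_px": int(y),
                    "x_um": (x + 0.5) * pixel_um,
                    "y_um": (y + 0.5) * pixel_um,
                    "dog_response": float(dog[y, x]),
                }
            )
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "x_um", "y_um", "dog_response"])


def _gauss2d(params: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    x0, y0, sigma, amp, off = params
    return off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))


def fit_psf(
    frames: np.ndarray,
    candidates: pd.DataFrame,
    pixel_um: float,
    window_px: int = 7,
) -> pd.DataFrame:
    """Least-squares symmetric 2D Gaussian fit around each candidate.

    Candidates whose window is clipped by the frame edge are skipped with a
    warning in the log; non-converged or degenerate fits (flat windows,
    fitted center outside the window) are dropped and counted.  Returns
    sub-pixel spots with columns ``frame, x_um, y_um, amplitude,
    background, fit_sigma_um, rms_residual``.
    """
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    half = window_px // 2
    rows = []
    n_clipped = n_failed = 0
    yy, xx = np.mgrid[0:window_px, 0:window_px].astype(float)
    for rec in candidates.itertuples():
        img = frames[int(rec.frame)]
        cy, cx = int(rec.y_px), int(rec.x_px)
        if cy - half < 0 or cx - half < 0 or cy + half + 1 > img.shape[0] or cx + half + 1 > img.shape[1]:
            n_clipped += 1
            continue
        win = img[cy - half : cy + half + 1, cx - half : cx + half + 1]
        off0 = float(win.min())
        amp0 = float(win.max() - off0)
        if amp0 <= 0:  # saturated/flat window has no peak to fit
            n_failed += 1
            continue
        p0 = np.array([half, half, 1.3, amp0, off0])
        try:
            res = least_squares(
                lambda p: (_gauss2d(p, yy, xx) - win).ravel(),
                p0,
                bounds=([0, 0, 0.3, 0, -np.inf], [window_px, window_px, window_px, np.inf, np.inf]),
                max_nfev=200,
            )
        except Exception:
            n_failed += 1
            continue
        x0, y0, sigma, amp, off = res.x
        if not res.success or amp <= 0 or not (0 < x0 < window_px - 1) or not (0 < y0 < window_px - 1):
            n_failed += 1
            continue
        rms = float(np.sqrt(np.mean(res.fun**2)))
        rows.append(
            {
                "frame": int(rec.frame),
                "x_um": (cx - half + x0 + 0.5) * pixel_um,
                "y_um": (cy - half + y0 + 0.5) * pixel_um,
                "amplitude": float(amp),
                "background": float(off),
                "fit_sigma_um": float(sigma) * pixel_um,
                "rms_residual": rms,
            }
        )
    if n_clipped:
        log.warning("fit_psf: %d candidates skipped (window clipped by frame edge)", n_clipped)
    if n_failed:
        log.info("fit_psf: %d fits dropped (non-converged or degenerate)", n_failed)
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def localize(
    frames: np.ndarray,
    pixel_um: float,
    dog_sigmas: tuple[float, float] = (1.0, 2.0),
    threshold_snr: float = 8.0,
    window_px: int = 7,
) -> pd.DataFrame:
    """Detect + fit in one call; returns a localization table.

    Output columns match the simulator's localization tables
    (``frame, x_um, y_um, intensity, precision_um``), with intensity the
    integrated Gaussian volume and precision a Thompson-style estimate
    sigma / sqrt(photons).
    """
    cands = detect_spots(frames, pixel_um, dog_sigmas, threshold_snr)
    spots = fit_psf(frames, cands, pixel_um, window_px)
    if spots.empty:
        return pd.DataFrame(columns=["frame", "x_um", "y_um", "intensity", "precision_um"])
    photons = 2.0 * math.pi * spots["amplitude"] * (spots["fit_sigma_um"] / pixel_um) ** 2
    precision = spots["fit_sigma_um"] / np.sqrt(np.maximum(photons, 1.0))
    return pd.DataFrame(
        {
            "frame": spots["frame"],
            "x_um": spots["x_um"],
            "y_um": spots["y_um"],
            "intensity": photons,
            "precision_um": precision,
        }
    )
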