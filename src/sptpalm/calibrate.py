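"""Apparent-to-accurate diffusion calibration and binding-time estimates.

Confinement inside a ~1-um-wide cell, motion blur over the camera
exposure, and localization error all distort per-track apparent diffusion
coefficients: localization noise inflates D* by sigma^2/dt, while
confinement and blur depress it increasingly for fast molecules.  The
mapping from the true (accurate) coefficient D_acc to the expected
apparent D* under a stated cell geometry and acquisition model is built by
Brownian-dynamics simulation on a grid of true values and inverted by
monotone interpolation.

The non-specific DNA-binding time fraction follows the time-average model
D_intact = (1 - f_ns) * D_free: a protein that spends a fraction f_ns of
its time transiently bound to the (effectively immobile) chromosome shows
a proportionally reduced long-time diffusion coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .geometry import CellGeometry
from .simulate import AcquisitionModel, simulate_confined_dstar


def default_calibration_geometry() -> CellGeometry:
    """Midpoint of the 2-3 um cell-size class at the standard radius."""
    return CellGeometry(length_um=2.5, radius_um=0.45)


def default_calibration_acquisition() -> AcquisitionModel:
    return AcquisitionModel()


DEFAULT_D_GRID = np.geomspace(0.05, 20.0, 20)


@dataclass
class CalibrationTable:
    """Monotone map d_true -> expected apparent D* with Monte-Carlo SE."""

    d_true: np.ndarray
    dstar_expected: np.ndarray
    se: np.ndarray
    geometry: CellGeometry
    acquisition: AcquisitionModel
    smoothed: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"d_true": self.d_true, "dstar_expected": self.dstar_expected, "se": self.se}
        )


def build_calibration(
    geometry: CellGeometry | None = None,
    acq: AcquisitionModel | None = None,
    d_grid: np.ndarray = DEFAULT_D_GRID,
    n_tracks_per_point: int = 5000,
    seed: int | None = None,
    n_replicates: int = 4,
) -> CalibrationTable:
    """Simulate the expected apparent D* for each true D on a grid.

    For each grid point, ``n_tracks_per_point`` tracks are simulated in the
    stated geometry/acquisition (split over ``n_replicates`` independent
    seeds for the Monte-Carlo SE) and summarized by the single-species
    maximum-likelihood apparent coefficient, the step-count-weighted mean
    of per-track D*.  A table rendered non-monotone by Monte-Carlo noise is
    isotonically smoothed with a warning.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(d_grid <= 0) or np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be positive and strictly increasing")
    geometry = geometry or default_calibration_geometry()
    acq = acq or default_calibration_acquisition()
    rng = np.random.default_rng(seed)
    per_rep = max(n_tracks_per_point // n_replicates, 1)

    expected = np.empty_like(d_grid)
    se = np.empty_like(d_grid)
    for i, d in enumerate(d_grid):
        reps = []
        for _ in range(n_replicates):
            rec = simulate_confined_dstar(
                geometry, acq, d, per_rep, seed=rng.integers(2**31)
            )
            w = rec["n_steps"].to_numpy(dtype=float)
            reps.append(np.sum(w * rec["dstar"]) / np.sum(w))
        reps = np.array(reps)
        expected[i] = reps.mean()
        se[i] = reps.std(ddof=1) / np.sqrt(n_replicates)

    smoothed = False
    if np.any(np.diff(expected) <= 0):
        from sklearn.isotonic import IsotonicRegression

        warnings.warn(
            "calibration table non-monotone at Monte-Carlo noise level; "
            "applying isotonic smoothing",
            stacklevel=2,
        )
        iso = IsotonicRegression(increasing=True)
        expected = iso.fit_transform(d_grid, expected)
        # strictify plateaus so the inverse interpolant is well defined
        eps = 1e-9 * max(expected.max(), 1.0)
        for j in range(1, expected.size):
            if expected[j] <= expected[j - 1]:
                expected[j] = expected[j - 1] + eps
        smoothed = True

    return CalibrationTable(
        d_true=d_grid,
        dstar_expected=expected,
        se=se,
        geometry=geometry,
        acquisition=acq,
        smoothed=smoothed,
    )


def invert_calibration(
    table: CalibrationTable, dstar_observed: float
) -> tuple[float, float]:
    """Accurate D for an observed apparent D*, with propagated SE.

    Monotone (PCHIP) interpolation of the inverse map; refuses to
    extrapolate outside the tabulated D* range.
    """
    lo, hi = table.dstar_expected[0], table.dstar_expected[-1]
    if not lo <= dstar_observed <= hi:
        raise ValueError(
            f"dstar_observed={dstar_observed} outside calibrated range "
            f"[{lo:.4g}, {hi:.4g}]; extend d_grid instead of extrapolating"
        )
    inv = PchipInterpolator(table.dstar_expected, table.d_true)
    d_acc = float(inv(dstar_observed))
    # propagate the table SE through the local slope of the forward map
    slope = float(PchipInterpolator(table.d_true, table.dstar_expected)(d_acc, 1))
    se_local = float(np.interp(d_acc, table.d_true, table.se))
    se_d = se_local / slope if slope > 0 else float("inf")
    return d_acc, se_d


# ----------------------------------------------------------------------
# physiology


def fns_estimate(d_intact: float, d_free: float) -> float:
    """Fraction of time spent transiently bound to the chromosome.

    f_ns = 1 - D_intact / D_free, from the reduced long-time mobility of a
    protein in cells with an intact nucleoid relative to DNA-free
    conditions.  Scale-invariant in (D_intact, D_free).
    """
    if d_intact <= 0 or d_free <= 0:
        raise ValueError("diffusion coefficients must be positive")
    if d_intact > d_free:
        raise ValueError("d_intact must not exceed d_free (model violated)")
    return 1.0 - d_intact / d_free


def round_to_nearest_ten_percent(fraction: float) -> float:
    """Report a fraction the way '~70%' statements round: nearest ten percent."""
    return round(fraction * 10.0) / 10.0


def compare_conditions(
    fit_a, fit_b
) -> pd.DataFrame:
    """Per-species amplitude changes between two fitted conditions (A -> B).

    Components are matched by ascending apparent D.  Returns absolute
    changes in percentage points and relative changes in percent of the
    condition-A amplitude.  If the component counts differ, the
    overlapping slowest components are matched with a warning.
    """
    comps_a = sorted(fit_a.model.components, key=lambda c: c.d_app)
    comps_b = sorted(fit_b.model.components, key=lambda c: c.d_app)
    k = min(len(comps_a), len(comps_b))
    if len(comps_a) != len(comps_b):
        warnings.warn(
            f"component counts differ ({len(comps_a)} vs {len(comps_b)}); "
            f"matching the {k} slowest",
            stacklevel=2,
        )
    rows = []
    for ca, cb in zip(comps_a[:k], comps_b[:k]):
        da_pp = (cb.amplitude - ca.amplitude) * 100.0
        rows.append(
            {
                "species": ca.name,
                "amplitude_a": ca.amplitude,
                "amplitude_b": cb.amplitude,
                "delta_pp": da_pp,
                "relative_change_percent": 100.0 * (cb.amplitude - ca.amplitude) / ca.amplitude,
                "d_app_a": ca.d_app,
                "d_app_b": cb.d_app,
            }
        )
    return pd.DataFrame(rows)


def amplitude_change(amplitude_a: float, amplitude_b: float) -> tuple[float, float]:
    """Absolute (percentage points) and relative (%) change A -> B."""
    if not 0 < amplitude_a <= 1 or not 0 <= amplitude_b <= 1:
        raise ValueError("amplitudes must be fractions in (0, 1]")
    delta_pp = (amplitude_b - amplitude_a) * 100.0
    rel = 100.0 * (amplitude_b - amplitude_a) / amplitude_a
    return delta_pp, rel
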