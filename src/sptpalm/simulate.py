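"""Ground-truthed synthetic sptPALM data.

Molecules are photoactivated sparsely, diffuse in 3D inside a reflective
spherocylinder (optionally further confined to a sphere, emulating
condensate-bound molecules), are observed as the exposure-averaged 2D
projection of their sub-frame positions ("motion blur"), perturbed by
Gaussian localization error, and photobleach geometrically.  The output is
a localization table in the same format the detection/linking stages emit,
plus a ground-truth object that maps every localization back to its
molecule and diffusive state.

Two fast paths bypass the full spatial simulation where only apparent
diffusion coefficients are needed: :func:`sample_dstar_records` draws
per-track D* values directly from the free-diffusion sampling distribution
(gamma with shape = step count), and :func:`simulate_confined_dstar`
propagates batches of molecules in a single cell for calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import CellGeometry

#: frame interval matching the acquisition used throughout (seconds)
DEFAULT_FRAME_INTERVAL_S = 0.01064
#: typical PAmCherry localization precision (micrometers, per axis)
DEFAULT_LOC_ERROR_UM = 0.035


@dataclass(frozen=True)
class DiffusionState:
    """One diffusive species of the simulated mixture."""

    name: str
    d_true: float  # accurate diffusion coefficient, um^2/s
    fraction: float  # mixture weight
    zone: str = "whole_cell"  # whole_cell | nucleoid | nucleoid_periphery
    confinement_radius_um: float | None = None

    def __post_init__(self) -> None:
        if self.d_true < 0:
            raise ValueError("d_true must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def validate_states(states: list[DiffusionState]) -> None:
    if not states:
        raise ValueError("states must be non-empty")
    total = sum(s.fraction for s in states)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"state fractions must sum to 1 (got {total})")


@dataclass(frozen=True)
class AcquisitionModel:
    """Camera/photophysics model of the tracking-PALM acquisition."""

    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    exposure_s: float = DEFAULT_FRAME_INTERVAL_S
    n_substeps: int = 10
    loc_error_um: float = DEFAULT_LOC_ERROR_UM
    bleach_prob: float = 0.13
    activation_rate: float = 0.03
    n_frames: int = 1000
    pixel_um: float = 0.1
    psf_sigma_um: float = 0.13
    photons_mean: float = 400.0
    background_mean: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")
        if self.exposure_s > self.frame_interval_s + 1e-15:
            raise ValueError("exposure_s must not exceed frame_interval_s")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")
        for name in ("bleach_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.loc_error_um < 0 or self.activation_rate < 0:
            raise ValueError("rates and errors must be non-negative")


@dataclass
class GroundTruth:
    """Per-track truth emitted alongside a simulated localization table."""

    tracks: pd.DataFrame  # truth_track_id, cell_id, state, start_frame, n_frames
    positions: dict[int, np.ndarray]  # track id -> (n_frames_alive, 3) local frame
    cells: list[CellGeometry]


LOC_COLUMNS = [
    "frame",
    "x_um",
    "y_um",
    "intensity",
    "precision_um",
    "cell_id",
    "truth_track_id",
    "truth_state",
]


# ----------------------------------------------------------------------
# propagation primitives


def _reflect_sphere(
    pos: np.ndarray, center: np.ndarray, radius: np.ndarray
) -> np.ndarray:
    """Mirror points back inside per-molecule confinement spheres."""
    rel = pos - center
    rho = np.sqrt(np.sum(rel**2, axis=-1))
    outside = rho > radius
    if not np.any(outside):
        return pos
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = (2.0 * radius - rho) / rho
    scale = np.where(rho > 0, scale, 1.0)
    # a single mirror can overshoot for long steps; clamp those onto the shell
    new = center + rel * scale[..., None]
    rel2 = new - center
    rho2 = np.sqrt(np.sum(rel2**2, axis=-1))
    bad = rho2 > radius
    if np.any(bad):
        shrink = (radius * (1 - 1e-9)) / np.where(rho2 > 0, rho2, 1.0)
        new = np.where(bad[..., None], center + rel2 * shrink[..., None], new)
    return np.where(outside[..., None], new, pos)


def _propagate_substep(
    cell: CellGeometry,
    pos: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
    conf_center: np.ndarray | None = None,
    conf_radius: np.ndarray | None = None,
) -> np.ndarray:
    """One Brownian sub-step with reflective boundaries, vectorized over molecules."""
    step = rng.normal(0.0, 1.0, size=pos.shape) * sigma[:, None]
    new = cell.reflect_inside(pos + step)
    if conf_center is not None:
        new = _reflect_sphere(new, conf_center, conf_radius)
    return new


# ----------------------------------------------------------------------
# full spatial simulation


def simulate_tracks(
    cells: list[CellGeometry],
    states: list[DiffusionState],
    acq: AcquisitionModel,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate photoactivated molecules in every cell.

    Each activated molecule draws a diffusive state by mixture fraction and
    an initial position uniform in that state's zone, performs reflected
    Brownian sub-steps inside the spherocylinder, and is observed once per
    frame as the mean (x, y) of its intra-exposure sub-positions plus
    Gaussian localization noise; it survives each frame with probability
    ``1 - bleach_prob``.

    Returns the localization table (columns ``frame, x_um, y_um, intensity,
    precision_um, cell_id, truth_track_id, truth_state``, field
    coordinates) and the ground truth.
    """
    validate_states(states)
    if seed is None:
        seed = acq.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fractions = np.array([s.fraction for s in states])
    dt_sub = acq.exposure_s / acq.n_substeps
    rows: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    positions: dict[int, np.ndarray] = {}
    next_track_id = 0

    for cell in cells:
        # number of molecules activated over the movie, with their start frames
        n_act = rng.poisson(acq.activation_rate, size=acq.n_frames)
        start_frames = np.repeat(np.arange(acq.n_frames), n_act)
        n_mol = start_frames.size
        if n_mol == 0:
            continue
        state_idx = rng.choice(len(states), size=n_mol, p=fractions)
        # geometric survival: number of observed frames >= 1
        lifetimes = rng.geometric(max(acq.bleach_prob, 1e-12), size=n_mol)
        lifetimes = np.minimum(lifetimes, acq.n_frames - start_frames)

        pos = np.empty((n_mol, 3))
        for i in range(n_mol):
            pos[i] = cell.sample_position(states[state_idx[i]].zone, rng)
        d = np.array([states[i].d_true for i in state_idx])
        sigma = np.sqrt(2.0 * d * dt_sub)
        conf_r = np.array(
            [
                states[i].confinement_radius_um
                if states[i].confinement_radius_um is not None
                else np.inf
                for i in state_idx
            ]
        )
        conf_c = pos.copy()

        t_max = int(lifetimes.max())
        obs = np.full((n_mol, t_max, 3), np.nan)
        for t in range(t_max):
            alive = lifetimes > t
            if not np.any(alive):
                break
            acc = np.zeros((int(alive.sum()), 3))
            p = pos[alive]
            for _ in range(acq.n_substeps):
                p = _propagate_substep(
                    cell, p, sigma[alive], rng, conf_c[alive], conf_r[alive]
                )
                acc += p
            # dead time between exposure end and next frame start (zero by default)
            dead = acq.frame_interval_s - acq.exposure_s
            if dead > 1e-15:
                s_dead = np.sqrt(2.0 * d[alive] * dead)
                p = _propagate_substep(cell, p, s_dead, rng, conf_c[alive], conf_r[alive])
            pos[alive] = p
            obs[alive, t] = acc / acq.n_substeps

        for i in range(n_mol):
            tid = next_track_id
            next_track_id += 1
            n_fr = int(lifetimes[i])
            true_xyz = obs[i, :n_fr]
            positions[tid] = true_xyz
            truth_rows.append(
                dict(
                    truth_track_id=tid,
                    cell_id=cell.cell_id,
                    state=states[state_idx[i]].name,
                    start_frame=int(start_frames[i]),
                    n_frames=n_fr,
                )
            )
            xy_field = cell.to_field(true_xyz[:, :2])
            noisy = xy_field + rng.normal(0.0, acq.loc_error_um, size=xy_field.shape)
            rows.append(
                pd.DataFrame(
                    {
                        "frame": start_frames[i] + np.arange(n_fr),
                        "x_um": noisy[:, 0],
                        "y_um": noisy[:, 1],
                        "intensity": rng.poisson(acq.photons_mean, n_fr).astype(float),
                        "precision_um": acq.loc_error_um,
                        "cell_id": cell.cell_id,
                        "truth_track_id": tid,
                        "truth_state": states[state_idx[i]].name,
                    }
                )
            )

    if rows:
        table = pd.concat(rows, ignore_index=True)
        table = table.sort_values(["frame", "truth_track_id"], kind="stable").reset_index(
            drop=True
        )
    else:
        table = pd.DataFrame(columns=LOC_COLUMNS)
    truth = GroundTruth(
        tracks=pd.DataFrame(
            truth_rows,
            columns=["truth_track_id", "cell_id", "state", "start_frame", "n_frames"],
        ),
        positions=positions,
        cells=list(cells),
    )
    return table, truth


# ----------------------------------------------------------------------
# fast apparent-D* samplers


def sample_track_lengths(
    n_tracks: int,
    rng: np.random.Generator,
    mean_steps: float = 10.6,
    min_steps: int = 4,
) -> np.ndarray:
    """Geometric step counts conditioned on ``min_steps``.

    The observed-track duration is geometric (memoryless bleaching), so the
    number of displacements beyond the minimum is geometric as well; the
    continuation probability is set so the conditional mean matches
    ``mean_steps``.
    """
    if mean_steps <= min_steps:
        raise ValueError("mean_steps must exceed min_steps")
    p = 1.0 / (mean_steps - min_steps + 1.0)  # mean of (n - min) = (1-p)/p
    return min_steps + rng.geometric(p, size=n_tracks) - 1


def sample_dstar_records(
    amplitudes: np.ndarray,
    dstars: np.ndarray,
    n_tracks: int,
    seed: int | np.random.Generator | None = None,
    mean_steps: float = 10.6,
    min_steps: int = 4,
    state_names: list[str] | None = None,
) -> pd.DataFrame:
    """Draw per-track apparent diffusion coefficients from the mixture model.

    For a free n-step track, D* follows a gamma distribution with shape n
    and mean equal to the species' apparent D; the returned frame is ready
    for :func:`sptpalm.dstar.fit_mixture`, with a ``truth_state`` column for
    recovery tests.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    dstars = np.asarray(dstars, dtype=float)
    if abs(amplitudes.sum() - 1.0) > 1e-9:
        raise ValueError("amplitudes must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = rng.choice(len(amplitudes), size=n_tracks, p=amplitudes)
    n = sample_track_lengths(n_tracks, rng, mean_steps=mean_steps, min_steps=min_steps)
    d = dstars[comp]
    x = rng.gamma(shape=n, scale=d / n)
    names = state_names or [f"species_{k}" for k in range(len(amplitudes))]
    return pd.DataFrame(
        {
            "track_id": np.arange(n_tracks),
            "n_steps": n,
            "dstar": x,
            "cell_id": -1,
            "truth_state": [names[c] for c in comp],
        }
    )


def simulate_confined_dstar(
    cell: CellGeometry,
    acq: AcquisitionModel,
    d_true: float,
    n_tracks: int,
    seed: int | np.random.Generator | None = None,
    mean_steps: float = 10.6,
    min_steps: int = 4,
) -> pd.DataFrame:
    """Apparent D* of ``n_tracks`` molecules diffusing in one cell.

    Batch-propagates all molecules concurrently (uniform initial positions,
    reflective spherocylinder, motion blur over ``acq.n_substeps``,
    per-axis localization noise) and evaluates D* from the 2D projected
    displacements.  This is the engine behind the D*-to-accurate-D
    calibration.
    """
    if d_true < 0:
        raise ValueError("d_true must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = sample_track_lengths(n_tracks, rng, mean_steps, min_steps)
    n_frames = n_steps + 1
    t_max = int(n_frames.max())
    dt_sub = acq.exposure_s / acq.n_substeps
    sigma = np.full(n_tracks, math.sqrt(2.0 * d_true * dt_sub))

    pos = np.empty((n_tracks, 3))
    for i in range(0, n_tracks, 4096):  # chunked rejection sampling, uniform in cell
        j = min(i + 4096, n_tracks)
        m = j - i
        got = 0
        buf = np.empty((m, 3))
        L2, R = cell.length_um / 2.0, cell.radius_um
        while got < m:
            cand = rng.uniform([-L2, -R, -R], [L2, R, R], size=(2 * (m - got) + 16, 3))
            ok = cand[cell.contains(cand)]
            take = min(m - got, ok.shape[0])
            buf[got : got + take] = ok[:take]
            got += take
        pos[i:j] = buf

    obs = np.full((n_tracks, t_max, 2), np.nan)
    for t in range(t_max):
        alive = n_frames > t
        if not np.any(alive):
            break
        p = pos[alive]
        acc = np.zeros_like(p)
        for _ in range(acq.n_substeps):
            p = _propagate_substep(cell, p, sigma[alive], rng)
            acc += p
        dead = acq.frame_interval_s - acq.exposure_s
        if dead > 1e-15:
            p = _propagate_substep(cell, p, np.sqrt(2.0 * d_true * dead) * np.ones(p.shape[0]), rng)
        pos[alive] = p
        obs[alive, t] = acc[:, :2] / acq.n_substeps

    obs += rng.normal(0.0, acq.loc_error_um, size=obs.shape)
    disp2 = np.nansum(np.diff(obs, axis=1) ** 2, axis=2)
    valid = ~np.isnan(np.diff(obs[:, :, 0], axis=1))
    ssd = np.where(valid, disp2, 0.0).sum(axis=1)
    dstar = ssd / (4.0 * n_steps * acq.frame_interval_s)
    return pd.DataFrame(
        {
            "track_id": np.arange(n_tracks),
            "n_steps": n_steps,
            "dstar": dstar,
            "cell_id": cell.cell_id,
        }
    )


# ----------------------------------------------------------------------
# rendering


def render_frames(
    true_positions: pd.DataFrame,
    acq: AcquisitionModel,
    field_um: tuple[float, float],
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render a uint16 movie from true emitter positions.

    ``true_positions`` needs columns ``frame, x_um, y_um`` (one row per
    active emitter per frame).  Each emitter contributes a pixel-integrated
    2D Gaussian of expected total intensity ``acq.photons_mean``; Poisson
    noise is applied to signal plus ``acq.background_mean``.  Emitters
    outside the field are clipped with a warning.
    """
    import warnings

    from scipy.special import erf

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nx = int(round(field_um[0] / acq.pixel_um))
    ny = int(round(field_um[1] / acq.pixel_um))
    n_frames = int(true_positions["frame"].max()) + 1 if len(true_positions) else 1
    movie = np.zeros((n_frames, ny, nx), dtype=float)

    outside = (
        (true_positions["x_um"] < 0)
        | (true_positions["x_um"] > field_um[0])
        | (true_positions["y_um"] < 0)
        | (true_positions["y_um"] > field_um[1])
    )
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} emitter positions outside the field were clipped",
            stacklevel=2,
        )
        true_positions = true_positions[~outside]

    s = acq.psf_sigma_um * math.sqrt(2.0)
    edges = np.arange(nx + 1) * acq.pixel_um
    edges_y = np.arange(ny + 1) * acq.pixel_um
    for f, x0, y0 in zip(
        true_positions["frame"].to_numpy(dtype=int),
        true_positions["x_um"].to_numpy(),
        true_positions["y_um"].to_numpy(),
    ):
        fx = 0.5 * (erf((edges - x0) / s)[1:] - erf((edges - x0) / s)[:-1])
        fy = 0.5 * (erf((edges_y - y0) / s)[1:] - erf((edges_y - y0) / s)[:-1])
        movie[f] += acq.photons_mean * np.outer(fy, fx)

    movie = rng.poisson(movie + acq.background_mean)
    return np.clip(movie, 0, 65535).astype(np.uint16)
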