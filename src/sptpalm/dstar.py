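"""Apparent diffusion coefficients and gamma-mixture fitting.

The apparent diffusion coefficient of a track with n frame-to-frame
displacements d_1..d_n is

    D* = (1 / (4 n dt)) * sum_j d_j^2 .

For free 2D diffusion each squared displacement is exponential, so D* of an
n-step track follows a gamma distribution with shape n and scale D/n (mean
D).  A heterogeneous population is therefore a mixture over species k (with
amplitudes A_k and apparent coefficients D_k) and over the track-length
distribution w_n:

    f(x) = sum_k A_k sum_n w_n Gamma(x; shape=n, scale=D_k/n).

Fitting maximizes the exact per-track likelihood (each record uses its own
step count as the gamma shape, capped at ``n_max``) via EM with closed-form
updates; a histogram least-squares path is provided as well.  Species
amplitudes carry bootstrap errors from track-level resampling, model order
is selected by BIC plus a runs test on binned residuals, and band purities
quantify how cleanly D* thresholds separate the species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

DEFAULT_MIN_STEPS = 4
DEFAULT_N_MAX = 30
HIST_RANGE = (0.0, 3.0)
HIST_BIN_WIDTH = 0.05

RECORD_COLUMNS = ["track_id", "n_steps", "dstar", "cell_id"]


# ----------------------------------------------------------------------
# model containers


@dataclass(frozen=True)
class MixtureComponent:
    name: str
    amplitude: float
    d_app: float  # apparent diffusion coefficient, um^2/s
    fixed: bool = False


@dataclass(frozen=True)
class MixtureModel:
    """K-component track-length-weighted gamma mixture over D*."""

    components: tuple[MixtureComponent, ...]
    length_weights: dict[int, float]  # n_steps -> probability
    frame_interval_s: float = 0.01064

    def __post_init__(self) -> None:
        amp = sum(c.amplitude for c in self.components)
        if abs(amp - 1.0) > 1e-6:
            raise ValueError(f"amplitudes must sum to 1 (got {amp})")
        if any(c.d_app <= 0 for c in self.components):
            raise ValueError("component d_app must be positive")
        w = sum(self.length_weights.values())
        if not self.length_weights or abs(w - 1.0) > 1e-6:
            raise ValueError("length_weights must be non-empty and sum to 1")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def d_apps(self) -> np.ndarray:
        return np.array([c.d_app for c in self.components])


@dataclass
class FitResult:
    model: MixtureModel
    loglik: float
    bic: float
    n_tracks: int
    n_params: int
    method: str
    residuals: pd.DataFrame  # bin_center, observed_density, expected_density, residual
    runs_p: float
    converged: bool
    n_iter: int
    bootstrap_sd_amplitude: dict[str, float] | None = None  # percentage points
    bootstrap_sd_d: dict[str, float] | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.model.components:
            rows.append(
                {
                    "species": c.name,
                    "amplitude": c.amplitude,
                    "d_app_um2_s": c.d_app,
                    "fixed": c.fixed,
                    "boot_sd_amplitude_pp": (self.bootstrap_sd_amplitude or {}).get(
                        c.name, np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# D* computation


def compute_dstar(
    tracks: pd.DataFrame,
    frame_interval_s: float,
    min_steps: int = DEFAULT_MIN_STEPS,
) -> tuple[pd.DataFrame, int]:
    """Per-track apparent diffusion coefficients.

    ``tracks`` has columns ``track_id, frame, x_um, y_um`` (``cell_id``
    optional).  Only displacements between consecutive frames count; a
    displacement spanning a linking gap is excluded.  Tracks retaining
    fewer than ``min_steps`` displacements are dropped and counted.

    Returns (records, n_dropped) where records has columns
    ``track_id, n_steps, dstar, cell_id``.
    """
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be positive")
    recs = []
    n_dropped = 0
    has_cell = "cell_id" in tracks.columns
    for tid, g in tracks.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        fr = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        consec = np.diff(fr) == 1
        d2 = np.sum(np.diff(xy, axis=0) ** 2, axis=1)[consec]
        n = d2.size
        if n < min_steps:
            n_dropped += 1
            continue
        recs.append(
            {
                "track_id": tid,
                "n_steps": n,
                "dstar": float(d2.sum() / (4.0 * n * frame_interval_s)),
                "cell_id": int(g["cell_id"].iloc[0]) if has_cell else -1,
            }
        )
    records = pd.DataFrame(recs, columns=RECORD_COLUMNS)
    return records, n_dropped


def empirical_length_weights(
    n_steps: np.ndarray, n_max: int = DEFAULT_N_MAX
) -> dict[int, float]:
    """Empirical step-count distribution with counts above ``n_max`` pooled."""
    n = np.minimum(np.asarray(n_steps, dtype=int), n_max)
    vals, counts = np.unique(n, return_counts=True)
    total = counts.sum()
    return {int(v): float(c) / total for v, c in zip(vals, counts)}


# ----------------------------------------------------------------------
# densities


def mixture_pdf(model: MixtureModel, x: np.ndarray | float) -> np.ndarray | float:
    """Mixture density over apparent diffusion coefficients (x >= 0)."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x_arr)
    for c in model.components:
        for n, w in model.length_weights.items():
            out += c.amplitude * w * stats.gamma.pdf(x_arr, a=n, scale=c.d_app / n)
    return out if np.ndim(x) else float(out[0])


def mixture_cdf(model: MixtureModel, x: np.ndarray | float) -> np.ndarray | float:
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x_arr)
    for c in model.components:
        for n, w in model.length_weights.items():
            out += c.amplitude * w * stats.gamma.cdf(x_arr, a=n, scale=c.d_app / n)
    return out if np.ndim(x) else float(out[0])


def _component_band_mass(
    d_app: float, length_weights: dict[int, float], lo: float, hi: float
) -> float:
    """Length-weighted gamma CDF mass of one component in [lo, hi)."""
    m = 0.0
    for n, w in length_weights.items():
        m += w * (
            stats.gamma.cdf(hi, a=n, scale=d_app / n)
            - stats.gamma.cdf(lo, a=n, scale=d_app / n)
        )
    return m


# ----------------------------------------------------------------------
# EM fitting


def _quantile_init(x: np.ndarray, k: int) -> np.ndarray:
    """Deterministic, scale-aware initial D values."""
    if k == 1:
        q = [50.0]
    elif k == 2:
        q = [20.0, 90.0]
    elif k == 3:
        q = [20.0, 50.0, 90.0]
    else:
        q = list(np.linspace(10.0, 95.0, k))
    d0 = np.percentile(x, q)
    return np.maximum(d0, 1e-6)


def _loglik_matrix(
    x: np.ndarray, m: np.ndarray, d: np.ndarray, base: np.ndarray
) -> np.ndarray:
    """log gamma density per record (rows) and component (cols)."""
    return base[:, None] - np.outer(m, np.log(d)) - np.outer(m * x, 1.0 / d)


def fit_mixture(
    records: pd.DataFrame,
    k_species: int,
    fixed: list[tuple[int, float]] | None = None,
    init: np.ndarray | None = None,
    method: str = "mle",
    n_max: int = DEFAULT_N_MAX,
    init_amplitudes: np.ndarray | None = None,
    frame_interval_s: float = 0.01064,
    max_iter: int = 2000,
    tol: float = 1e-8,
    species_names: list[str] | None = None,
) -> FitResult:
    """Fit a K-species gamma mixture to per-track D* records.

    ``fixed`` pins components (by index after ascending-D ordering of the
    initial values) at given apparent D; their amplitudes remain free.
    ``method`` is ``"mle"`` (EM on the per-track likelihood, default) or
    ``"histogram_lsq"`` (least squares on the binned D* histogram).
    Deterministic given data and initialization; amplitudes are returned
    sorted by ascending D.
    """
    if k_species < 1:
        raise ValueError("k_species must be >= 1")
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    x = np.maximum(records["dstar"].to_numpy(dtype=float), 1e-12)
    m = np.minimum(records["n_steps"].to_numpy(dtype=int), n_max).astype(float)
    N = x.size

    d0 = np.sort(np.asarray(init, dtype=float)) if init is not None else _quantile_init(x, k_species)
    if d0.size != k_species:
        raise ValueError("init must provide one D per species")
    fixed = fixed or []
    fixed_mask = np.zeros(k_species, dtype=bool)
    for idx, dval in fixed:
        fixed_mask[idx] = True
        d0 = d0.copy()
        d0[idx] = dval
    a0 = (
        np.asarray(init_amplitudes, dtype=float)
        if init_amplitudes is not None
        else np.full(k_species, 1.0 / k_species)
    )

    length_weights = empirical_length_weights(records["n_steps"].to_numpy(), n_max)

    if method == "mle":
        amps, ds, ll, converged, n_iter = _fit_em(
            x, m, d0, a0, fixed_mask, max_iter=max_iter, tol=tol
        )
    elif method == "histogram_lsq":
        amps, ds, converged, n_iter = _fit_histogram_lsq(
            records, d0, a0, fixed_mask, length_weights
        )
        logf = _loglik_matrix(
            x, m, ds, (m - 1.0) * np.log(x) - gammaln(m) + m * np.log(m)
        )
        ll = float(np.sum(_logsumexp_rows(logf + np.log(np.maximum(amps, 1e-300)))))
    else:
        raise ValueError(f"unknown method {method!r}")
    if not converged:
        warnings.warn(
            f"mixture fit did not converge in {n_iter} iterations; "
            "returning best iterate",
            stacklevel=2,
        )

    order = np.argsort(ds)
    amps, ds, fixed_mask = amps[order], ds[order], fixed_mask[order]
    names = species_names or _default_names(k_species)
    comps = tuple(
        MixtureComponent(name=names[i], amplitude=float(amps[i]), d_app=float(ds[i]), fixed=bool(fixed_mask[i]))
        for i in range(k_species)
    )
    model = MixtureModel(
        components=comps, length_weights=length_weights, frame_interval_s=frame_interval_s
    )
    n_params = (k_species - 1) + int(np.sum(~fixed_mask))
    bic = -2.0 * ll + n_params * np.log(N)
    residuals = _binned_residuals(records, model)
    runs_p = runs_test(residuals["residual"].to_numpy())
    return FitResult(
        model=model,
        loglik=ll,
        bic=float(bic),
        n_tracks=N,
        n_params=n_params,
        method=method,
        residuals=residuals,
        runs_p=runs_p,
        converged=converged,
        n_iter=n_iter,
    )


def _default_names(k: int) -> list[str]:
    if k == 1:
        return ["single"]
    if k == 2:
        return ["slow", "fast"]
    if k == 3:
        return ["very_slow", "slow", "fast"]
    return [f"species_{i}" for i in range(k)]


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    mx = np.max(a, axis=1, keepdims=True)
    return (mx + np.log(np.sum(np.exp(a - mx), axis=1, keepdims=True)))[:, 0]


def _fit_em(
    x: np.ndarray,
    m: np.ndarray,
    d0: np.ndarray,
    a0: np.ndarray,
    fixed_mask: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    base = (m - 1.0) * np.log(x) - gammaln(m) + m * np.log(m)
    d = d0.astype(float).copy()
    a = a0 / a0.sum()
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logf = _loglik_matrix(x, m, d, base) + np.log(np.maximum(a, 1e-300))
        ll_rows = _logsumexp_rows(logf)
        ll = float(ll_rows.sum())
        r = np.exp(logf - ll_rows[:, None])  # responsibilities
        a = r.mean(axis=0)
        wn = r * m[:, None]
        denom = wn.sum(axis=0)
        num = (wn * x[:, None]).sum(axis=0)
        d_new = np.where(denom > 0, num / np.maximum(denom, 1e-300), d)
        d = np.where(fixed_mask, d, np.maximum(d_new, 1e-9))
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    # final log-likelihood at the returned parameters
    logf = _loglik_matrix(x, m, d, base) + np.log(np.maximum(a, 1e-300))
    ll = float(_logsumexp_rows(logf).sum())
    return a, d, ll, converged, it


def _fit_histogram_lsq(
    records: pd.DataFrame,
    d0: np.ndarray,
    a0: np.ndarray,
    fixed_mask: np.ndarray,
    length_weights: dict[int, float],
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    from scipy.optimize import minimize

    edges = np.arange(HIST_RANGE[0], HIST_RANGE[1] + HIST_BIN_WIDTH / 2, HIST_BIN_WIDTH)
    obs, _ = np.histogram(records["dstar"], bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = d0.size
    free_idx = np.where(~fixed_mask)[0]

    def unpack(theta):
        logits = np.concatenate([theta[: k - 1], [0.0]])
        a = np.exp(logits - logits.max())
        a /= a.sum()
        d = d0.copy()
        d[free_idx] = np.exp(theta[k - 1 :])
        return a, d

    def objective(theta):
        a, d = unpack(theta)
        model_pdf = np.zeros_like(centers)
        for ak, dk in zip(a, d):
            for n, w in length_weights.items():
                model_pdf += ak * w * stats.gamma.pdf(centers, a=n, scale=dk / n)
        return float(np.sum((obs - model_pdf) ** 2))

    theta0 = np.concatenate(
        [np.log(np.maximum(a0[: k - 1], 1e-6) / max(a0[-1], 1e-6)), np.log(d0[free_idx])]
    )
    res = minimize(objective, theta0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-12})
    a, d = unpack(res.x)
    return a, d, bool(res.success), int(res.nit)


# ----------------------------------------------------------------------
# residual diagnostics


def _binned_residuals(records: pd.DataFrame, model: MixtureModel) -> pd.DataFrame:
    edges = np.arange(HIST_RANGE[0], HIST_RANGE[1] + HIST_BIN_WIDTH / 2, HIST_BIN_WIDTH)
    obs, _ = np.histogram(records["dstar"], bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    expected = np.asarray(mixture_pdf(model, centers))
    return pd.DataFrame(
        {
            "bin_center": centers,
            "observed_density": obs,
            "expected_density": expected,
            "residual": obs - expected,
        }
    )


def runs_test(residuals: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test p-value on residual signs.

    A well-specified model leaves binned residuals with randomly
    alternating signs; systematic misfit produces long same-sign runs and a
    small p-value.  Normal approximation; zero residuals are dropped.
    """
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 1.0
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ----------------------------------------------------------------------
# model selection


def select_model(
    records: pd.DataFrame,
    max_k: int = 3,
    frame_interval_s: float = 0.01064,
    n_max: int = DEFAULT_N_MAX,
) -> list[FitResult]:
    """Fit k = 1..max_k species and rank by BIC (best first).

    For k = 3 the very-slow component's D is fixed at the slowest D of the
    two-species fit — the stepwise protocol used when a minor fast species
    must be resolved on top of two dominant slow ones.
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    fits: list[FitResult] = []
    fit2: FitResult | None = None
    for k in range(1, max_k + 1):
        if k == 3 and fit2 is not None:
            d_vslow = fit2.model.d_apps[0]
            init = np.array([d_vslow, np.median(records["dstar"]), np.percentile(records["dstar"], 90)])
            f = fit_mixture(
                records, 3, fixed=[(0, float(d_vslow))], init=np.sort(init),
                frame_interval_s=frame_interval_s, n_max=n_max,
            )
        else:
            f = fit_mixture(records, k, frame_interval_s=frame_interval_s, n_max=n_max)
        if k == 2:
            fit2 = f
        fits.append(f)
    return sorted(fits, key=lambda f: f.bic)


# ----------------------------------------------------------------------
# bootstrap


def bootstrap_amplitudes(
    records: pd.DataFrame,
    fit: FitResult,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Track-level bootstrap of fitted amplitudes and free D values.

    Resamples records with replacement ``n_boot`` times, refits the same
    model specification (same fixed components, initialized at the point
    estimate), and returns per-species standard deviations of the
    amplitudes (percentage points) and of the free apparent D values.
    Failed resample fits are excluded with a warning if they exceed 5%.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(fit.model.components)
    fixed = [
        (i, c.d_app) for i, c in enumerate(fit.model.components) if c.fixed
    ]
    names = [c.name for c in fit.model.components]
    d_init = fit.model.d_apps
    a_init = fit.model.amplitudes
    amps = np.full((n_boot, k), np.nan)
    ds = np.full((n_boot, k), np.nan)
    n_fail = 0
    n = len(records)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resample = records.iloc[idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = fit_mixture(
                    resample, k, fixed=fixed, init=d_init, init_amplitudes=a_init,
                    frame_interval_s=fit.model.frame_interval_s, species_names=names,
                )
            amps[b] = f.model.amplitudes
            ds[b] = f.model.d_apps
        except Exception:
            n_fail += 1
    if n_fail > 0.05 * n_boot:
        warnings.warn(f"{n_fail}/{n_boot} bootstrap fits failed", stacklevel=2)
    sd_amp = np.nanstd(amps, axis=0, ddof=1) * 100.0
    sd_d = np.nanstd(ds, axis=0, ddof=1)
    free = {c.name for c in fit.model.components if not c.fixed}
    return (
        {names[i]: float(sd_amp[i]) for i in range(k)},
        {names[i]: float(sd_d[i]) for i in range(k) if names[i] in free},
    )


# ----------------------------------------------------------------------
# band purity


def band_purity(
    model: MixtureModel, thresholds: list[float]
) -> pd.DataFrame:
    """Species composition of D* threshold bands.

    For bands [0, t1), [t1, t2), ..., [t_last, inf) returns
    P(species k | D* in band) from the areas under the fitted
    length-weighted gamma curves.  Bands with zero total mass are flagged
    with NaN purities.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    edges = [0.0] + thresholds + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        masses = np.array(
            [
                c.amplitude * _component_band_mass(c.d_app, model.length_weights, lo, hi)
                for c in model.components
            ]
        )
        total = masses.sum()
        if total <= 0:
            warnings.warn(f"band [{lo}, {hi}) has zero mass", stacklevel=2)
            purity = np.full(len(masses), np.nan)
        else:
            purity = masses / total
        row = {"band_lo": lo, "band_hi": hi, "band_mass": total}
        for c, p in zip(model.components, purity):
            row[c.name] = p
        rows.append(row)
    return pd.DataFrame(rows)
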