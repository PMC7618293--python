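"""Pipeline configuration and orchestration.

A single validated configuration object (unknown keys rejected) drives the
stage chain simulate -> [render/localize] -> link -> D* -> fit -> heatmap.
Every stage writes its outputs into the run directory and registers them in
a provenance manifest with SHA-256 hashes, the run seed, and the fully
materialized configuration, so any stage can be re-executed in isolation
and reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import cellmap, dstar, io
from . import simulate as sim
from .geometry import sample_cells
from .link import DEFAULT_MAX_DISP_UM, DEFAULT_MAX_GAP, assign_to_cells
from .link import link as link_tracks

log = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StateConfig(_Strict):
    name: str
    d_true: float = Field(ge=0)
    fraction: float = Field(ge=0, le=1)
    zone: str = "whole_cell"
    confinement_radius_um: float | None = None


class AcquisitionConfig(_Strict):
    frame_interval_s: float = sim.DEFAULT_FRAME_INTERVAL_S
    exposure_s: float | None = None  # defaults to frame_interval_s (no dead time)
    n_substeps: int = 10
    loc_error_um: float = sim.DEFAULT_LOC_ERROR_UM
    bleach_prob: float = 0.13
    activation_rate: float = 0.03
    n_frames: int = 1000
    pixel_um: float = 0.1
    psf_sigma_um: float = 0.13
    photons_mean: float = 400.0
    background_mean: float = 5.0

    def build(self) -> sim.AcquisitionModel:
        d = self.model_dump()
        if d["exposure_s"] is None:
            d["exposure_s"] = d["frame_interval_s"]
        return sim.AcquisitionModel(**d)


class SimulateConfig(_Strict):
    n_cells: int = 40
    length_range_um: tuple[float, float] = (2.0, 3.0)
    radius_um: float = 0.45
    nucleoid_fraction: float = 0.8
    states: list[StateConfig] = [
        StateConfig(name="very_slow", d_true=0.05, fraction=0.41, zone="nucleoid"),
        StateConfig(name="slow", d_true=0.25, fraction=0.47),
        StateConfig(name="fast", d_true=1.5, fraction=0.12),
    ]
    acquisition: AcquisitionConfig = AcquisitionConfig()
    render: bool = False


class LinkConfig(_Strict):
    max_disp_um: float = DEFAULT_MAX_DISP_UM
    max_gap: int = DEFAULT_MAX_GAP


class FitConfig(_Strict):
    k_species: int = 3
    fix_vslow_from_k2: bool = True
    n_boot: int = 0
    min_steps: int = dstar.DEFAULT_MIN_STEPS
    n_max: int = dstar.DEFAULT_N_MAX


class HeatmapConfig(_Strict):
    thresholds: list[float] = [0.31, 0.7]
    length_range_um: tuple[float, float] = (2.0, 3.0)
    grid: tuple[int, int] = cellmap.DEFAULT_GRID


class PipelineConfig(_Strict):
    """Full pipeline configuration; all randomness flows from ``seed``."""

    seed: int = 0
    out_dir: str = "run"
    verbosity: str = "INFO"
    simulate: SimulateConfig = SimulateConfig()
    link: LinkConfig = LinkConfig()
    fit: FitConfig = FitConfig()
    heatmap: HeatmapConfig = HeatmapConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(io.load_config(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    Writes ``localizations.csv``, ``outlines.json``, ``tracks.csv``,
    ``dstar_records.csv``, ``fit.json``, per-band heatmap CSVs plus a
    rendered PNG, the materialized configuration, counters, and
    ``manifest.json`` with hashes of every artifact.  A stage failure
    raises with the stage named; artifacts already written are retained.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.verbosity)
    rng = np.random.default_rng(config.seed)
    artifacts: dict[str, str] = {}
    counters: dict[str, float] = {}
    io.dump_config(config.model_dump(mode="json"), out / "config.yaml")
    artifacts["config"] = "config.yaml"

    stage = "simulate"
    try:
        sc = config.simulate
        cells = sample_cells(
            sc.n_cells,
            sc.length_range_um,
            sc.radius_um,
            seed=rng,
            nucleoid_fraction=sc.nucleoid_fraction,
        )
        states = [sim.DiffusionState(**s.model_dump()) for s in sc.states]
        acq = sc.acquisition.build()
        locs, truth = sim.simulate_tracks(cells, states, acq, seed=rng)
        io.write_table(locs, out / "localizations.csv")
        io.write_outlines(cells, out / "outlines.json")
        artifacts["localizations"] = "localizations.csv"
        artifacts["outlines"] = "outlines.json"
        counters["n_cells"] = len(cells)
        counters["n_truth_tracks"] = len(truth.tracks)
        if sc.render:
            field = max(c.center_xy_um[0] for c in cells) + 2.0
            movie = sim.render_frames(locs, acq, (field, field), seed=rng)
            io.write_movie(movie, out / "movie.tif", acq.pixel_um, acq.frame_interval_s)
            artifacts["movie"] = "movie.tif"

        stage = "link"
        tracks = link_tracks(locs, config.link.max_disp_um, config.link.max_gap)
        outlines = io.read_outlines(out / "outlines.json")
        tracks, n_discarded = assign_to_cells(tracks, outlines)
        io.write_table(tracks, out / "tracks.csv")
        artifacts["tracks"] = "tracks.csv"
        counters["n_tracks_linked"] = int(tracks["track_id"].nunique())
        counters["n_tracks_outside_cells"] = n_discarded

        stage = "dstar"
        records, n_dropped = dstar.compute_dstar(
            tracks, acq.frame_interval_s, config.fit.min_steps
        )
        io.write_table(records, out / "dstar_records.csv")
        artifacts["dstar_records"] = "dstar_records.csv"
        counters["n_tracks_below_min_steps"] = n_dropped
        counters["n_dstar_records"] = len(records)

        stage = "fit"
        fc = config.fit
        if fc.k_species == 3 and fc.fix_vslow_from_k2:
            fits = dstar.select_model(records, max_k=3, frame_interval_s=acq.frame_interval_s, n_max=fc.n_max)
            fit = next(f for f in fits if len(f.model.components) == 3)
        else:
            fit = dstar.fit_mixture(
                records, fc.k_species, frame_interval_s=acq.frame_interval_s, n_max=fc.n_max
            )
        if fc.n_boot >= 2:
            sd_amp, sd_d = dstar.bootstrap_amplitudes(
                records, fit, n_boot=fc.n_boot, seed=rng
            )
            fit.bootstrap_sd_amplitude = sd_amp
            fit.bootstrap_sd_d = sd_d
        io.write_json(_fit_to_dict(fit), out / "fit.json")
        artifacts["fit"] = "fit.json"

        stage = "heatmap"
        hc = config.heatmap
        maps = cellmap.band_heatmap(
            tracks, records, outlines, hc.thresholds, hc.length_range_um, hc.grid
        )
        for i, hm in enumerate(maps):
            np.savetxt(out / f"heatmap_band{i}.csv", hm.grid, delimiter=",", fmt="%.6g")
            artifacts[f"heatmap_band{i}"] = f"heatmap_band{i}.csv"
        cellmap.plot_heatmaps(maps, str(out / "heatmaps.png"))
        artifacts["heatmaps_png"] = "heatmaps.png"
        io.write_json(
            [
                {
                    "band": [hm.band[0], None if np.isinf(hm.band[1]) else hm.band[1]],
                    "n_tracks": hm.n_tracks,
                    "n_localizations": hm.n_localizations,
                    "n_cells": hm.n_cells,
                }
                for hm in maps
            ],
            out / "heatmap_meta.json",
        )
        artifacts["heatmap_meta"] = "heatmap_meta.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "counters": counters,
        "artifacts": {
            k: {"path": v, "sha256": _sha256(out / v)} for k, v in artifacts.items()
        },
    }
    io.write_json(manifest, out / "manifest.json", sig=12)
    return out


def _fit_to_dict(fit: dstar.FitResult) -> dict:
    return {
        "components": [
            {
                "name": c.name,
                "amplitude": c.amplitude,
                "d_app_um2_s": c.d_app,
                "fixed": c.fixed,
            }
            for c in fit.model.components
        ],
        "length_weights": {str(k): v for k, v in fit.model.length_weights.items()},
        "frame_interval_s": fit.model.frame_interval_s,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "n_tracks": fit.n_tracks,
        "method": fit.method,
        "runs_test_p": fit.runs_p,
        "bootstrap_sd_amplitude_pp": fit.bootstrap_sd_amplitude,
        "bootstrap_sd_d": fit.bootstrap_sd_d,
    }
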