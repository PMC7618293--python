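"""File formats and validation.

Plain-text interchange formats shared by all stages:

- localization tables: CSV with ``frame, x_um, y_um, intensity,
  precision_um`` (+ optional ``cell_id, truth_track_id, truth_state``)
- track tables: CSV with ``track_id, frame, x_um, y_um, cell_id``
- D* record tables: CSV with ``track_id, n_steps, dstar, cell_id``
- cell outlines: JSON list of ``{cell_id, polygon, length_um, radius_um}``
- movies: single-channel 16-bit TIFF with a JSON metadata sidecar
  (``pixel_um``, ``frame_interval_s``)

Numeric CSV output uses 6 significant digits so reruns diff cleanly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"

LOC_REQUIRED = ["frame", "x_um", "y_um"]
TRACK_REQUIRED = ["track_id", "frame", "x_um", "y_um"]
RECORD_REQUIRED = ["track_id", "n_steps", "dstar"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _round_sig(x, sig: int = 6):
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    if isinstance(x, (float, np.floating)):
        if not math.isfinite(x):
            return float(x)
        return float(f"{x:.{sig}g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _round_sig(x.tolist(), sig)
    return x


def write_json(obj, path: str | Path, sig: int = 6) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_round_sig(obj, sig), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_outlines(cells, path: str | Path) -> None:
    """Serialize CellGeometry objects (or prebuilt dicts) to outline JSON."""
    out = []
    for c in cells:
        if isinstance(c, dict):
            out.append(c)
        else:
            out.append(
                {
                    "cell_id": c.cell_id,
                    "polygon": c.outline_polygon().tolist(),
                    "length_um": c.length_um,
                    "radius_um": c.radius_um,
                }
            )
    write_json(out, path)


def read_outlines(path: str | Path) -> list[dict]:
    data = read_json(path)
    if not isinstance(data, list):
        raise ValueError(f"{path}: outline JSON must be a list of cells")
    return data


def write_movie(frames: np.ndarray, path: str | Path, pixel_um: float, frame_interval_s: float) -> None:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint16))
    write_json(
        {"pixel_um": pixel_um, "frame_interval_s": frame_interval_s},
        path.with_suffix(".json"),
    )


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    import tifffile

    path = Path(path)
    meta_path = path.with_suffix(".json")
    meta = read_json(meta_path) if meta_path.exists() else {}
    return tifffile.imread(path), meta


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ----------------------------------------------------------------------
# validation


def _validate_csv(path: Path, errors: list[str]) -> str:
    df = pd.read_csv(path, nrows=50)
    cols = set(df.columns)
    for kind, req in (
        ("records", RECORD_REQUIRED),
        ("tracks", TRACK_REQUIRED),
        ("localizations", LOC_REQUIRED),
    ):
        if set(req) <= cols:
            return kind
    # best guess at intent for the error message
    if "track_id" in cols and "dstar" not in cols:
        missing = sorted(set(TRACK_REQUIRED) - cols)
        errors.append(f"track CSV missing columns: {', '.join(missing)}")
        return "tracks"
    missing = sorted(set(LOC_REQUIRED) - cols)
    errors.append(f"localization CSV missing columns: {', '.join(missing)}")
    return "localizations"


def _validate_outlines(path: Path, errors: list[str]) -> None:
    from shapely.geometry import Polygon

    data = read_json(path)
    if not isinstance(data, list):
        errors.append("outline JSON must be a list")
        return
    for o in data:
        if not isinstance(o, dict) or "cell_id" not in o or "polygon" not in o:
            errors.append("outline entries need cell_id and polygon")
            continue
        poly = Polygon(o["polygon"])
        if not poly.is_valid:
            errors.append(f"cell_id {o['cell_id']}: invalid (self-intersecting?) polygon")
        elif poly.area <= 0:
            errors.append(f"cell_id {o['cell_id']}: degenerate polygon")


def validate_files(paths: list[str | Path]) -> list[dict]:
    """Schema/structure checks for pipeline inputs.

    Never raises on content problems: each entry of the returned report
    carries ``path``, detected ``kind``, ``ok`` and an ``errors`` list.
    """
    report = []
    for p in paths:
        p = Path(p)
        errors: list[str] = []
        kind = "unknown"
        try:
            if not p.exists():
                errors.append("file not found")
            elif p.suffix == ".csv":
                kind = _validate_csv(p, errors)
            elif p.suffix == ".json":
                kind = "outlines"
                _validate_outlines(p, errors)
            elif p.suffix in (".tif", ".tiff"):
                kind = "movie"
                _, meta = read_movie(p)
                for key in ("pixel_um", "frame_interval_s"):
                    if key not in meta:
                        errors.append(f"metadata sidecar missing {key}")
            elif p.suffix in (".yaml", ".yml"):
                kind = "config"
                load_config(p)
            else:
                errors.append(f"unrecognized file type {p.suffix!r}")
        except Exception as exc:  # malformed file, not a crash
            errors.append(f"unreadable: {exc}")
        report.append({"path": str(p), "kind": kind, "ok": not errors, "errors": errors})
    return report
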