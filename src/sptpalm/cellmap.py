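"""Normalized cell coordinates and mobility-band spatial heatmaps.

Each localization of a track is projected into the coordinate frame of its
cell: ``l`` in [0, 1] along the long axis (poles at 0 and 1) and ``r`` in
[-1, 1] across the short axis, normalized by the local half-width of the
outline.  Tracks are assigned to a D* mobility band by their single
per-track apparent diffusion coefficient, and the localizations of each
band are accumulated into a density-normalized (l, r) histogram across all
selected cells.  Because the pole ordering of an outline is arbitrary,
maps are mirror-symmetrized along l (and r) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

log = logging.getLogger(__name__)

DEFAULT_GRID = (50, 20)  # (l, r) bins
DEFAULT_LENGTH_RANGE_UM = (2.0, 3.0)  # the ~2-nucleoid size class


@dataclass
class CellFrame:
    """Geometry of one outline, precomputed for coordinate projection."""

    cell_id: int
    centroid: np.ndarray
    axis: np.ndarray  # unit vector of the long axis
    s_min: float
    s_max: float
    polygon: Polygon

    @property
    def length(self) -> float:
        return self.s_max - self.s_min


def _polygon_frame(cell_id: int, polygon_xy: np.ndarray) -> CellFrame:
    """Principal axis of a polygon from its area second moments."""
    poly = Polygon(polygon_xy)
    c = np.array(poly.centroid.coords[0])
    # second moments of the polygon area via the shoelace decomposition
    x = polygon_xy[:, 0] - c[0]
    y = polygon_xy[:, 1] - c[1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    if cross.sum() < 0:  # clockwise outline: flip so moments are positive
        cross = -cross
    ixx = np.sum(cross * (y**2 + y * y1 + y1**2)) / 12.0
    iyy = np.sum(cross * (x**2 + x * x1 + x1**2)) / 12.0
    ixy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    cov = np.array([[iyy, ixy], [ixy, ixx]])
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    s = (polygon_xy - c) @ axis
    return CellFrame(
        cell_id=cell_id,
        centroid=c,
        axis=axis,
        s_min=float(s.min()),
        s_max=float(s.max()),
        polygon=poly,
    )


def build_frames(outlines: list[dict]) -> dict[int, CellFrame]:
    return {
        o["cell_id"]: _polygon_frame(o["cell_id"], np.asarray(o["polygon"], dtype=float))
        for o in outlines
    }


def to_cell_coords(
    xy: np.ndarray, frame: CellFrame
) -> tuple[np.ndarray, np.ndarray, int]:
    """Project field-coordinate points into (l, r) for one cell.

    ``l`` is the projection onto the principal axis scaled by the cell
    length; ``r`` the perpendicular offset scaled by the local half-width
    (the half-chord of the outline at that axial position).  Points outside
    the outline are clipped into range and counted.

    Returns (l, r, n_clipped).
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    rel = xy - frame.centroid
    s = rel @ frame.axis
    perp_axis = np.array([-frame.axis[1], frame.axis[0]])
    t = rel @ perp_axis

    l = (s - frame.s_min) / max(frame.length, 1e-12)
    r = np.empty_like(t)
    reach = frame.length  # chord probe longer than any half-width
    for i in range(xy.shape[0]):
        anchor = frame.centroid + s[i] * frame.axis
        chord = LineString(
            [anchor - reach * perp_axis, anchor + reach * perp_axis]
        ).intersection(frame.polygon)
        half_width = chord.length / 2.0 if not chord.is_empty else 0.0
        r[i] = t[i] / half_width if half_width > 0 else np.sign(t[i])

    out_of_range = (l < 0) | (l > 1) | (r < -1) | (r > 1)
    n_clipped = int(out_of_range.sum())
    return np.clip(l, 0.0, 1.0), np.clip(r, -1.0, 1.0), n_clipped


@dataclass
class Heatmap:
    """Density-normalized localization map in normalized cell coordinates."""

    grid: np.ndarray  # (n_l, n_r), sums to 1 unless empty
    l_edges: np.ndarray
    r_edges: np.ndarray
    band: tuple[float, float]
    n_cells: int
    n_tracks: int
    n_localizations: int

    @property
    def empty(self) -> bool:
        return self.n_localizations == 0


def band_heatmap(
    tracks: pd.DataFrame,
    records: pd.DataFrame,
    outlines: list[dict],
    thresholds: list[float] = (0.31, 0.7),
    length_range_um: tuple[float, float] = DEFAULT_LENGTH_RANGE_UM,
    grid: tuple[int, int] = DEFAULT_GRID,
    mirror_l: bool = True,
    mirror_r: bool = True,
) -> list[Heatmap]:
    """One heatmap per D* band across the selected cell population.

    ``tracks`` is the track table (``track_id, frame, x_um, y_um,
    cell_id``), ``records`` the per-track D* table, ``outlines`` the cell
    outline list (with ``length_um`` per cell).  Cells are filtered to
    ``length_range_um``; each track contributes all its localizations to
    the band its D* falls in.  Bands are [0, t1), [t1, t2), ...,
    [t_last, inf).  Empty bands yield flagged empty heatmaps.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    sel_ids = {
        o["cell_id"]
        for o in outlines
        if length_range_um[0] <= o.get("length_um", np.nan) <= length_range_um[1]
    }
    frames = build_frames([o for o in outlines if o["cell_id"] in sel_ids])

    merged = tracks.merge(records[["track_id", "dstar"]], on="track_id", how="inner")
    merged = merged[merged["cell_id"].isin(sel_ids)]

    # project once per cell
    coords = {}
    for cid, g in merged.groupby("cell_id"):
        l, r, n_clip = to_cell_coords(g[["x_um", "y_um"]].to_numpy(), frames[cid])
        if n_clip:
            log.info("band_heatmap: %d localizations clipped to cell %d boundary", n_clip, cid)
        coords[cid] = pd.DataFrame({"l": l, "r": r, "dstar": g["dstar"].to_numpy(),
                                    "track_id": g["track_id"].to_numpy()}, index=g.index)
    allc = pd.concat(coords.values()) if coords else pd.DataFrame(columns=["l", "r", "dstar", "track_id"])

    edges = [0.0] + thresholds + [np.inf]
    l_edges = np.linspace(0.0, 1.0, grid[0] + 1)
    r_edges = np.linspace(-1.0, 1.0, grid[1] + 1)
    maps = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = allc[(allc["dstar"] >= lo) & (allc["dstar"] < hi)]
        h, _, _ = np.histogram2d(sub["l"], sub["r"], bins=[l_edges, r_edges])
        if mirror_l:
            h = 0.5 * (h + h[::-1, :])
        if mirror_r:
            h = 0.5 * (h + h[:, ::-1])
        total = h.sum()
        if total > 0:
            h = h / total
        else:
            log.warning("band_heatmap: band [%g, %g) is empty", lo, hi)
        maps.append(
            Heatmap(
                grid=h,
                l_edges=l_edges,
                r_edges=r_edges,
                band=(lo, hi),
                n_cells=len(sel_ids),
                n_tracks=int(sub["track_id"].nunique()),
                n_localizations=int(len(sub)),
            )
        )
    return maps


def plot_heatmaps(maps: list[Heatmap], path: str) -> None:
    """Render the band heatmaps side by side to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(maps), 1, figsize=(6, 2 * len(maps)), squeeze=False)
    for ax, hm in zip(axes[:, 0], maps):
        ax.imshow(
            hm.grid.T,
            origin="lower",
            aspect="auto",
            extent=[0, 1, -1, 1],
            cmap="inferno",
        )
        hi = "inf" if np.isinf(hm.band[1]) else f"{hm.band[1]:g}"
        ax.set_title(f"D* in [{hm.band[0]:g}, {hi}) um^2/s  ({hm.n_tracks} tracks)")
        ax.set_xlabel("l (normalized long axis)")
        ax.set_ylabel("r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
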