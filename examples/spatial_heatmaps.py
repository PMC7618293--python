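"""Map mobility bands onto normalized cell coordinates.

Simulates two populations — a near-immobile species confined to the
nucleoid region and a fast species exploring the whole cell — then builds
per-band spatial heatmaps in normalized (l, r) cell coordinates, the way
track maps are averaged across hundreds of rod-shaped cells.
"""

import numpy as np

from sptpalm import (
    AcquisitionModel,
    CellGeometry,
    DiffusionState,
    band_heatmap,
    compute_dstar,
    simulate_tracks,
)

cells = [
    CellGeometry(2.5, 0.45, nucleoid_fraction=0.8, cell_id=i,
                 center_xy_um=(3.0 + 4.0 * i, 3.0), orientation_rad=0.5 * i)
    for i in range(15)
]
states = [
    DiffusionState("chromosomal", d_true=0.02, fraction=0.5, zone="nucleoid"),
    DiffusionState("free", d_true=1.5, fraction=0.5, zone="whole_cell"),
]
acq = AcquisitionModel(activation_rate=0.1, n_frames=1500)
locs, truth = simulate_tracks(cells, states, acq, seed=5)

tracks = locs.rename(columns={"truth_track_id": "track_id"})
records, _ = compute_dstar(tracks, acq.frame_interval_s)
outlines = [
    {"cell_id": c.cell_id, "polygon": c.outline_polygon().tolist(),
     "length_um": c.length_um, "radius_um": c.radius_um}
    for c in cells
]

maps = band_heatmap(tracks, records, outlines, thresholds=[0.31],
                    length_range_um=(2.0, 3.0))
for hm in maps:
    hi = "inf" if np.isinf(hm.band[1]) else f"{hm.band[1]:g}"
    l_centers = 0.5 * (hm.l_edges[:-1] + hm.l_edges[1:])
    central = np.abs(l_centers - 0.5) < 0.4
    print(
        f"band D* in [{hm.band[0]:g}, {hi}): {hm.n_tracks} tracks, "
        f"{hm.n_localizations} localizations, "
        f"{100 * hm.grid[central].sum():.0f}% of mass in the central 80% of "
        "the cell length"
    )
print("\nthe slow band concentrates in the nucleoid region (center), while")
print("the fast band fills the cell — the spatial signature that separates")
print("chromosome-associated from freely diffusing molecules.")
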