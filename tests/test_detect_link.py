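import numpy as np
import pandas as pd
import pytest

from sptpalm.detect import detect_spots, fit_psf, localize
from sptpalm.geometry import CellGeometry
from sptpalm.link import assign_to_cells, link, link_accuracy
from sptpalm.simulate import AcquisitionModel, DiffusionState, render_frames, simulate_tracks

PIXEL = 0.1


def render_single(x_um, y_um, photons=1000.0, background=5.0, seed=0, n_frames=1):
    acq = AcquisitionModel(photons_mean=photons, background_mean=background)
    pos = pd.DataFrame(
        {"frame": np.arange(n_frames), "x_um": x_um, "y_um": y_um}
    )
    return render_frames(pos, acq, (3.2, 3.2), seed=seed)


class TestDetection:
    def test_single_emitter_found_within_one_pixel(self):
        movie = render_single([1.63], [2.11], seed=1)
        cands = detect_spots(movie, PIXEL)
        assert len(cands) == 1
        assert abs(cands["x_um"].iloc[0] - 1.63) < PIXEL
        assert abs(cands["y_um"].iloc[0] - 2.11) < PIXEL

    def test_pure_noise_false_positive_rate(self):
        acq = AcquisitionModel(background_mean=5.0)
        frames = np.random.default_rng(2).poisson(5.0, size=(100, 32, 32)).astype(float)
        cands = detect_spots(frames, PIXEL, threshold_snr=8.0)
        frames_with_hits = cands["frame"].nunique() if len(cands) else 0
        assert frames_with_hits <= 5  # >= 95% of frames clean

    def test_two_resolved_emitters(self):
        pos = pd.DataFrame({"frame": [0, 0], "x_um": [0.8, 2.4], "y_um": [1.6, 1.6]})
        acq = AcquisitionModel(photons_mean=1000.0, background_mean=5.0)
        movie = render_frames(pos, acq, (3.2, 3.2), seed=3)
        cands = detect_spots(movie, PIXEL)
        assert len(cands) == 2

    def test_all_zero_frames_empty_result(self):
        cands = detect_spots(np.zeros((3, 16, 16)), PIXEL)
        assert cands.empty


class TestPsfFit:
    def test_near_noiseless_recovery(self):
        x0, y0 = 1.63, 2.11
        movie = render_single([x0], [y0], photons=1e6, background=0.0, seed=4)
        cands = detect_spots(movie, PIXEL)
        spots = fit_psf(movie, cands, PIXEL)
        assert len(spots) == 1
        assert abs(spots["x_um"].iloc[0] - x0) < 0.02 * PIXEL
        assert abs(spots["y_um"].iloc[0] - y0) < 0.02 * PIXEL

    def test_precision_scales_with_photons(self):
        """Repeated 1000-photon fits scatter near sigma/sqrt(N)."""
        x0, y0 = 1.63, 2.11
        errs = []
        for seed in range(60):
            movie = render_single([x0], [y0], photons=1000.0, background=2.0, seed=seed)
            spots = localize(movie, PIXEL)
            if len(spots) == 1:
                errs.append(spots["x_um"].iloc[0] - x0)
        assert len(errs) > 50
        sd = np.std(errs)
        theory = 0.13 / np.sqrt(1000.0)  # psf sigma / sqrt(photons)
        assert theory / 2 < sd < theory * 2

    def test_flat_window_dropped(self):
        frames = np.full((1, 16, 16), 100.0)
        cands = pd.DataFrame({"frame": [0], "x_px": [8], "y_px": [8],
                              "x_um": [0.85], "y_um": [0.85], "dog_response": [1.0]})
        spots = fit_psf(frames, cands, PIXEL)
        assert spots.empty

    def test_edge_window_skipped(self):
        movie = render_single([0.05], [0.05], seed=5)
        cands = pd.DataFrame({"frame": [0], "x_px": [0], "y_px": [0],
                              "x_um": [0.05], "y_um": [0.05], "dog_response": [1.0]})
        spots = fit_psf(movie, cands, PIXEL)
        assert spots.empty


class TestLinking:
    def test_simple_pair_links(self):
        locs = pd.DataFrame(
            {"frame": [0, 1], "x_um": [1.0, 1.1], "y_um": [1.0, 1.0]}
        )
        tracks = link(locs, max_disp_um=0.8)
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 2

    def test_over_threshold_pair_not_linked(self):
        locs = pd.DataFrame(
            {"frame": [0, 1], "x_um": [1.0, 2.0], "y_um": [1.0, 1.0]}
        )
        tracks = link(locs, max_disp_um=0.8)
        assert tracks.empty  # two singletons, both below min_length

    def test_gap_closing(self):
        locs = pd.DataFrame(
            {"frame": [0, 2, 4], "x_um": [1.0, 1.05, 1.1], "y_um": [1.0, 1.0, 1.0]}
        )
        assert link(locs, max_gap=0).empty
        tracks = link(locs, max_gap=1)
        assert tracks["track_id"].nunique() == 1
        assert len(tracks) == 3

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        locs = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(20), 3),
                "x_um": rng.uniform(0, 10, 60),
                "y_um": rng.uniform(0, 10, 60),
            }
        )
        t1 = link(locs)
        t2 = link(locs.sample(frac=1.0, random_state=0))
        k1 = {tuple(sorted(map(tuple, g[["frame", "x_um", "y_um"]].to_numpy())))
              for _, g in t1.groupby("track_id")}
        k2 = {tuple(sorted(map(tuple, g[["frame", "x_um", "y_um"]].to_numpy())))
              for _, g in t2.groupby("track_id")}
        assert k1 == k2

    def test_no_localization_in_two_tracks_and_frames_increase(self):
        rng = np.random.default_rng(12)
        locs = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(50), 2),
                "x_um": rng.uniform(0, 5, 100),
                "y_um": rng.uniform(0, 5, 100),
            }
        )
        tracks = link(locs)
        key = tracks[["frame", "x_um", "y_um"]].apply(tuple, axis=1)
        assert key.is_unique
        for _, g in tracks.groupby("track_id"):
            assert np.all(np.diff(g["frame"]) >= 1)

    @staticmethod
    def _sparse_movie(activation_rate, seed):
        cells = [
            CellGeometry(3.0, 0.45, center_xy_um=(3.0 + 4.0 * i, 3.0), cell_id=i)
            for i in range(5)
        ]
        states = [
            DiffusionState("slow", 0.2, 0.6),
            DiffusionState("fast", 1.5, 0.4),
        ]
        acq = AcquisitionModel(activation_rate=activation_rate, n_frames=3000)
        locs, _ = simulate_tracks(cells, states, acq, seed=seed)
        return locs

    def test_ground_truth_link_accuracy_sparse(self):
        """At sparse activation (~0.08 active molecules per cell) >= 99% of
        links connect localizations of the same true molecule."""
        locs = self._sparse_movie(0.01, seed=13)
        tracks = link(locs)
        assert link_accuracy(tracks, locs) >= 0.99

    def test_majority_state_recovery_at_default_density(self):
        """At the default activation density (~0.23 simultaneously active
        molecules per cell) >= 99% of linked tracks carry a strict majority
        of localizations from a single true molecule, so the per-track
        mobility label remains recoverable."""
        locs = self._sparse_movie(0.03, seed=13)
        tracks = link(locs)
        good = tot = 0
        for _, g in tracks.groupby("track_id"):
            tot += 1
            if g["truth_track_id"].value_counts().iloc[0] / len(g) > 0.5:
                good += 1
        assert good / tot >= 0.99


class TestCellAssignment:
    OUTLINES = [
        {"cell_id": 0, "polygon": [[0, 0], [2, 0], [2, 1], [0, 1]]},
        {"cell_id": 1, "polygon": [[5, 0], [7, 0], [7, 1], [5, 1]]},
    ]

    def _track(self, xs, ys):
        return pd.DataFrame(
            {"track_id": 0, "frame": range(len(xs)), "x_um": xs, "y_um": ys,
             "cell_id": -1}
        )

    def test_fully_inside(self):
        out, n = assign_to_cells(self._track([0.5, 0.6], [0.5, 0.5]), self.OUTLINES)
        assert (out["cell_id"] == 0).all() and n == 0

    def test_fully_outside_discarded(self):
        out, n = assign_to_cells(self._track([3.5, 3.6], [0.5, 0.5]), self.OUTLINES)
        assert out.empty and n == 1

    def test_majority_rule(self):
        out, n = assign_to_cells(
            self._track([0.5, 0.6, 0.7, 3.0, 3.1], [0.5] * 5), self.OUTLINES
        )
        assert (out["cell_id"] == 0).all() and n == 0

    def test_boundary_counts_inside(self):
        out, n = assign_to_cells(self._track([0.0, 0.1], [0.5, 0.5]), self.OUTLINES)
        assert (out["cell_id"] == 0).all()
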