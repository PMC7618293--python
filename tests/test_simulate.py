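import numpy as np
import pandas as pd
import pytest

from sptpalm.geometry import CellGeometry
from sptpalm.simulate import (
    AcquisitionModel,
    DiffusionState,
    render_frames,
    sample_dstar_records,
    sample_track_lengths,
    simulate_confined_dstar,
    simulate_tracks,
)

DT = 0.01064
BIG_CELL = CellGeometry(length_um=200.0, radius_um=50.0)  # effectively unconfined


def free_acq(**kw):
    defaults = dict(loc_error_um=0.0, n_substeps=1, n_frames=3000)
    defaults.update(kw)
    return AcquisitionModel(**defaults)


class TestAcquisitionModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            AcquisitionModel(exposure_s=0.02, frame_interval_s=0.01)
        with pytest.raises(ValueError):
            AcquisitionModel(n_substeps=0)
        with pytest.raises(ValueError):
            AcquisitionModel(bleach_prob=1.5)
        with pytest.raises(ValueError):
            DiffusionState("x", d_true=-1.0, fraction=1.0)


class TestFreeDiffusionLimits:
    def test_step_variance_matches_2ddt(self):
        """Unconfined, noise-free: per-axis frame-to-frame variance = 2 D dt."""
        rec = simulate_confined_dstar(BIG_CELL, free_acq(), 1.0, 8000, seed=1)
        # D* has mean D; equivalently mean squared step is 4 D dt
        n_total = rec["n_steps"].sum()
        mean_d = np.average(rec["dstar"], weights=rec["n_steps"])
        se = 1.0 / np.sqrt(n_total)  # relative SE of a mean of exponentials
        assert mean_d == pytest.approx(1.0, abs=3 * se)

    def test_msd_linear_in_lag(self):
        """MSD(tau) = 4 D tau for the 2D projection of free 3D motion."""
        cells = [CellGeometry(length_um=200.0, radius_um=50.0)]
        states = [DiffusionState("free", d_true=0.5, fraction=1.0)]
        acq = free_acq(activation_rate=0.2, bleach_prob=0.02, n_frames=500)
        locs, truth = simulate_tracks(cells, states, acq, seed=2)
        msds = {}
        for lag in (1, 2, 4):
            sq = []
            for tid, g in locs.groupby("truth_track_id"):
                xy = g[["x_um", "y_um"]].to_numpy()
                if len(xy) > lag:
                    sq.append(np.sum((xy[lag:] - xy[:-lag]) ** 2, axis=1))
            sq = np.concatenate(sq)
            msds[lag] = (sq.mean(), sq.std(ddof=1) / np.sqrt(len(sq)))
        for lag, (m, se) in msds.items():
            assert m == pytest.approx(4 * 0.5 * lag * DT, abs=3 * se)

    def test_localization_error_offset(self):
        """With noise sigma and no blur, E[D*] = D + sigma^2/dt."""
        acq = free_acq(loc_error_um=0.035)
        rec = simulate_confined_dstar(BIG_CELL, acq, 0.5, 8000, seed=3)
        expected = 0.5 + 0.035**2 / DT
        mean_d = np.average(rec["dstar"], weights=rec["n_steps"])
        se = expected / np.sqrt(rec["n_steps"].sum())
        assert mean_d == pytest.approx(expected, abs=4 * se)


class TestTrackStatistics:
    def test_bleaching_gives_geometric_lengths(self):
        cells = [CellGeometry(length_um=3.0, radius_um=0.45)]
        states = [DiffusionState("s", d_true=0.2, fraction=1.0)]
        acq = AcquisitionModel(bleach_prob=0.1, activation_rate=0.3, n_frames=3000)
        _, truth = simulate_tracks(cells, states, acq, seed=4)
        # exclude truncation by movie end
        t = truth.tracks[truth.tracks.start_frame < 2500]
        mean = t["n_frames"].mean()
        se = t["n_frames"].std(ddof=1) / np.sqrt(len(t))
        assert mean == pytest.approx(10.0, abs=4 * se)

    def test_state_fractions_binomial(self):
        cells = [CellGeometry(length_um=3.0, radius_um=0.45)]
        states = [
            DiffusionState("a", 0.1, 0.3),
            DiffusionState("b", 0.5, 0.7),
        ]
        acq = AcquisitionModel(activation_rate=0.5, n_frames=2000)
        _, truth = simulate_tracks(cells, states, acq, seed=5)
        n = len(truth.tracks)
        frac_a = (truth.tracks["state"] == "a").mean()
        assert frac_a == pytest.approx(0.3, abs=4 * np.sqrt(0.3 * 0.7 / n))

    def test_fraction_validation(self):
        cells = [CellGeometry(length_um=3.0, radius_um=0.45)]
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_tracks(cells, [DiffusionState("a", 0.1, 0.5)], AcquisitionModel())

    def test_seeded_determinism_bit_identical(self):
        cells = [CellGeometry(length_um=3.0, radius_um=0.45)]
        states = [DiffusionState("s", 0.3, 1.0)]
        acq = AcquisitionModel(activation_rate=0.2, n_frames=500)
        a, _ = simulate_tracks(cells, states, acq, seed=6)
        b, _ = simulate_tracks(cells, states, acq, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_confined_msd_plateau(self):
        """A state confined to radius 0.1 um plateaus below (2*0.1)^2."""
        cells = [CellGeometry(length_um=3.0, radius_um=0.45)]
        states = [
            DiffusionState("conf", d_true=1.0, fraction=1.0, confinement_radius_um=0.1)
        ]
        acq = AcquisitionModel(
            loc_error_um=0.0, n_substeps=2, activation_rate=0.2, bleach_prob=0.02,
            n_frames=1000,
        )
        locs, truth = simulate_tracks(cells, states, acq, seed=7)
        lag = 20
        sq = []
        for tid, g in locs.groupby("truth_track_id"):
            xyz = truth.positions[tid]
            if len(xyz) > lag:
                sq.append(np.sum((xyz[lag:, :2] - xyz[:-lag, :2]) ** 2, axis=1))
        msd = np.concatenate(sq).mean()
        assert msd < (2 * 0.1) ** 2


class TestDstarSampler:
    def test_track_length_mean(self):
        rng = np.random.default_rng(8)
        n = sample_track_lengths(100_000, rng, mean_steps=10.6, min_steps=4)
        assert n.min() >= 4
        assert n.mean() == pytest.approx(10.6, abs=0.1)

    def test_component_fractions(self):
        rec = sample_dstar_records([0.41, 0.47, 0.12], [0.15, 0.33, 0.99], 50_000, seed=9)
        frac = rec["truth_state"].value_counts(normalize=True)
        assert frac["species_0"] == pytest.approx(0.41, abs=0.01)
        assert frac["species_2"] == pytest.approx(0.12, abs=0.01)

    def test_per_component_mean(self):
        rec = sample_dstar_records([1.0], [0.5], 50_000, seed=10)
        assert rec["dstar"].mean() == pytest.approx(0.5, abs=0.01)


class TestRendering:
    def test_single_emitter_peak(self):
        acq = AcquisitionModel(background_mean=0.0, photons_mean=1000.0)
        pos = pd.DataFrame({"frame": [0], "x_um": [1.25], "y_um": [0.85]})
        movie = render_frames(pos, acq, (2.0, 2.0), seed=0)
        peak = np.unravel_index(np.argmax(movie[0]), movie[0].shape)
        assert peak == (8, 12)  # pixel containing (1.25, 0.85) at 0.1 um/px

    def test_zero_emitters_pure_background(self):
        acq = AcquisitionModel(background_mean=7.0)
        movie = render_frames(pd.DataFrame(columns=["frame", "x_um", "y_um"]), acq, (2.0, 2.0), seed=1)
        assert movie.mean() == pytest.approx(7.0, abs=0.3)

    def test_out_of_field_emitters_warn(self):
        acq = AcquisitionModel()
        pos = pd.DataFrame({"frame": [0, 0], "x_um": [1.0, 5.0], "y_um": [1.0, 1.0]})
        with pytest.warns(UserWarning, match="clipped"):
            render_frames(pos, acq, (2.0, 2.0), seed=2)
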