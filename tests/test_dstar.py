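import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from sptpalm import dstar, sample_dstar_records
from sptpalm.dstar import (
    MixtureComponent,
    MixtureModel,
    band_purity,
    bootstrap_amplitudes,
    compute_dstar,
    fit_mixture,
    mixture_pdf,
    runs_test,
    select_model,
)

DT = 0.01064


def make_track(displacements_um, dt_frames=None):
    """Build a track table from a list of (dx, dy) displacements."""
    xy = np.vstack([[0.0, 0.0], np.cumsum(displacements_um, axis=0)])
    frames = np.arange(len(xy)) if dt_frames is None else np.asarray(dt_frames)
    return pd.DataFrame(
        {"track_id": 0, "frame": frames, "x_um": xy[:, 0], "y_um": xy[:, 1]}
    )


class TestComputeDstar:
    def test_hand_evaluated_formula(self):
        """Four 0.2-um displacements at dt = 10.64 ms give D* = 0.9398."""
        tracks = make_track([(0.2, 0.0)] * 4)
        records, n_drop = compute_dstar(tracks, DT)
        assert n_drop == 0
        assert records["n_steps"].iloc[0] == 4
        assert records["dstar"].iloc[0] == pytest.approx(
            (4 * 0.04) / (4 * 4 * DT), rel=1e-12
        )
        assert records["dstar"].iloc[0] == pytest.approx(0.9398, abs=5e-5)

    def test_stationary_molecule(self):
        tracks = make_track([(0.0, 0.0)] * 5)
        records, _ = compute_dstar(tracks, DT)
        assert records["dstar"].iloc[0] == 0.0

    def test_short_tracks_dropped_and_counted(self):
        tracks = make_track([(0.1, 0.0)] * 3)
        records, n_drop = compute_dstar(tracks, DT, min_steps=4)
        assert records.empty and n_drop == 1

    def test_gap_displacements_excluded(self):
        # frames 0,1,2,4,5,6: the 2->4 jump must not contribute
        tracks = make_track([(0.1, 0.0)] * 5, dt_frames=[0, 1, 2, 4, 5, 6])
        records, _ = compute_dstar(tracks, DT)
        assert records["n_steps"].iloc[0] == 4

    def test_unbiased_for_free_diffusion(self):
        rec = sample_dstar_records([1.0], [0.5], 100_000, seed=20)
        se = 0.5 / np.sqrt(np.sum(rec["n_steps"]))
        assert np.average(rec["dstar"], weights=rec["n_steps"]) == pytest.approx(
            0.5, abs=3 * se
        )


class TestMixturePdf:
    def test_normalization_and_mean(self, literature_model):
        total, _ = quad(lambda x: mixture_pdf(literature_model, x), 0, 80, limit=300)
        assert total == pytest.approx(1.0, abs=1e-4)
        mean, _ = quad(lambda x: x * mixture_pdf(literature_model, x), 0, 80, limit=300)
        expected = np.sum(literature_model.amplitudes * literature_model.d_apps)
        assert mean == pytest.approx(expected, rel=1e-4)

    def test_shape_one_is_exponential(self):
        model = MixtureModel(
            components=(MixtureComponent("s", 1.0, 0.4),), length_weights={1: 1.0}
        )
        x = np.linspace(0.01, 3, 50)
        assert np.allclose(mixture_pdf(model, x), stats.expon.pdf(x, scale=0.4))

    def test_simulated_dstar_matches_closed_form(self):
        """KS agreement between simulated fixed-n D* and the gamma density."""
        rng = np.random.default_rng(21)
        n, d = 4, 0.5
        x = rng.gamma(shape=n, scale=d / n, size=100_000)
        res = stats.kstest(x, lambda v: stats.gamma.cdf(v, a=n, scale=d / n))
        assert res.pvalue > 0.01

    def test_empty_length_weights_rejected(self):
        with pytest.raises(ValueError):
            MixtureModel(components=(MixtureComponent("s", 1.0, 0.4),), length_weights={})


class TestFitMixture:
    def test_single_species_mle_equals_weighted_mean(self):
        """Gamma MLE with known shape: D-hat is the step-weighted mean D*."""
        rec = sample_dstar_records([1.0], [0.5], 5000, seed=22)
        fit = fit_mixture(rec, 1)
        oracle = np.average(rec["dstar"], weights=np.minimum(rec["n_steps"], 30))
        assert fit.model.amplitudes[0] == pytest.approx(1.0, abs=1e-12)
        assert fit.model.d_apps[0] == pytest.approx(oracle, abs=1e-6)

    def test_three_species_parameter_recovery(self, three_species_records, three_species_fit):
        """Amplitudes within 2 points, D within 10% at 20k tracks."""
        f = three_species_fit
        for a, truth in zip(f.model.amplitudes, (0.41, 0.47, 0.12)):
            assert a == pytest.approx(truth, abs=0.02)
        for d, truth in zip(f.model.d_apps, (0.15, 0.33, 0.99)):
            assert d == pytest.approx(truth, rel=0.10)

    def test_fixing_at_truth_leaves_free_parameters(self, three_species_records, three_species_fit):
        fixed = fit_mixture(
            three_species_records, 3, fixed=[(0, 0.15)],
            init=np.array([0.15, 0.33, 0.99]),
        )
        free = three_species_fit
        for a, b in zip(fixed.model.amplitudes, free.model.amplitudes):
            assert a == pytest.approx(b, abs=0.02)
        for a, b in zip(fixed.model.d_apps[1:], free.model.d_apps[1:]):
            assert a == pytest.approx(b, rel=0.05)

    def test_order_invariance(self, three_species_records):
        shuffled = three_species_records.sample(frac=1.0, random_state=1)
        f1 = fit_mixture(three_species_records, 3)
        f2 = fit_mixture(shuffled, 3)
        assert np.allclose(f1.model.amplitudes, f2.model.amplitudes, atol=1e-9)
        assert np.allclose(f1.model.d_apps, f2.model.d_apps, atol=1e-9)

    def test_amplitudes_sum_to_one(self, three_species_fit):
        assert three_species_fit.model.amplitudes.sum() == pytest.approx(1.0, abs=1e-9)

    def test_histogram_lsq_agrees_roughly(self, three_species_records):
        f = fit_mixture(three_species_records, 3, method="histogram_lsq")
        for a, truth in zip(f.model.amplitudes, (0.41, 0.47, 0.12)):
            assert a == pytest.approx(truth, abs=0.06)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture(pd.DataFrame(columns=["n_steps", "dstar"]), 1)


class TestModelSelection:
    def test_bic_prefers_one_species_on_single_species_data(self):
        rec = sample_dstar_records([1.0], [0.4], 10_000, seed=23)
        fits = select_model(rec, max_k=3)
        assert len(fits[0].model.components) == 1

    def test_bic_prefers_three_species_on_three_species_data(self, three_species_records):
        fits = select_model(three_species_records, max_k=3)
        assert len(fits[0].model.components) == 3

    def test_two_species_fit_leaves_structured_residuals(self, three_species_records):
        f2 = fit_mixture(three_species_records, 2)
        assert f2.runs_p < 0.05
        f3 = fit_mixture(three_species_records, 3)
        assert f3.runs_p > 0.05

    def test_runs_test_on_alternating_and_blocked_signs(self):
        alternating = np.tile([1.0, -1.0], 20)
        blocked = np.concatenate([np.ones(20), -np.ones(20)])
        assert runs_test(alternating) < 0.05  # too regular is also non-random
        assert runs_test(blocked) < 1e-6
        rng = np.random.default_rng(0)
        assert runs_test(rng.normal(size=200)) > 0.05


class TestBootstrap:
    def test_two_resamples_finite(self, three_species_records, three_species_fit):
        sd_amp, sd_d = bootstrap_amplitudes(
            three_species_records, three_species_fit, n_boot=2, seed=1
        )
        for v in sd_amp.values():
            assert np.isfinite(v) and v >= 0

    def test_doubling_data_shrinks_sd(self):
        rec = sample_dstar_records([0.41, 0.47, 0.12], [0.15, 0.33, 0.99], 4000, seed=24)
        fit = fit_mixture(rec, 3)
        sd1, _ = bootstrap_amplitudes(rec, fit, n_boot=40, seed=2)
        doubled = pd.concat([rec, rec], ignore_index=True)
        fit2 = fit_mixture(doubled, 3)
        sd2, _ = bootstrap_amplitudes(doubled, fit2, n_boot=40, seed=3)
        ratios = [sd2[k] / sd1[k] for k in sd1]
        # expect ~1/sqrt(2) = 0.71; allow bootstrap noise at 40 resamples
        assert np.mean(ratios) == pytest.approx(0.71, abs=0.25)


class TestBandPurity:
    def test_single_component_purity_one(self):
        model = MixtureModel(
            components=(MixtureComponent("s", 1.0, 0.4),), length_weights={10: 1.0}
        )
        bp = band_purity(model, [0.31, 0.7])
        assert np.allclose(bp["s"], 1.0)

    def test_well_separated_components(self):
        model = MixtureModel(
            components=(
                MixtureComponent("lo", 0.5, 0.01),
                MixtureComponent("hi", 0.5, 10.0),
            ),
            length_weights={10: 1.0},
        )
        bp = band_purity(model, [1.0])
        assert bp["lo"].iloc[0] > 0.999
        assert bp["hi"].iloc[1] > 0.999

    def test_purities_sum_to_one_per_band(self, literature_model):
        bp = band_purity(literature_model, [0.31, 0.7])
        sums = bp[["very_slow", "slow", "fast"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_literature_band_dominance(self, literature_model):
        """Thresholds 0.31/0.7: each band is dominated by its species,
        consistent with the reported ~61/83/87% band compositions."""
        bp = band_purity(literature_model, [0.31, 0.7])
        assert bp["very_slow"].iloc[0] > 0.5
        assert bp["slow"].iloc[1] > 0.5
        assert bp["fast"].iloc[2] > 0.5

    def test_bad_thresholds_rejected(self, literature_model):
        with pytest.raises(ValueError):
            band_purity(literature_model, [0.7, 0.31])
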