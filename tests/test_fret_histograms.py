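"""Histogram building/averaging, the staged global fit, corrections, ANOVA."""

import numpy as np
import pytest

from gatefret import synthetic_data as sd
from gatefret._util import InsufficientDataError, InvalidInputError
from gatefret.fret_histograms import (
    DEFAULT_BIN_EDGES,
    FretHistogram,
    GaussianComponent,
    ProtocolError,
    anova_amplitudes,
    average_replicates,
    build_histogram,
    compute_anisotropy,
    fit_staged_mixture,
    histograms_from_samples,
    mixture_curve,
    orientation_correct,
)
from tests.conftest import STATE_MEANS, STATE_WIDTHS


class TestBuildHistogram:
    def test_counts_per_bin(self):
        h = build_histogram([0.1, 0.1, 0.9], bin_edges=[0.0, 0.5, 1.0])
        assert list(h.frequencies) == [2.0, 1.0]

    def test_empty_input_gives_zero_frequencies(self):
        h = build_histogram([], bin_edges=[0.0, 0.5, 1.0])
        assert h.total == 0.0

    def test_conservation_with_out_of_range_logging(self, rng):
        vals = rng.normal(0.76, 0.1, 200)
        h = build_histogram(vals)
        assert h.total + h.n_out_of_range == 200

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(Exception):
            build_histogram([0.5], bin_edges=[0.0, 0.6, 0.4])


class TestAverageReplicates:
    def test_identical_replicates_have_zero_sem(self):
        h = build_histogram([0.3, 0.7], bin_edges=[0.0, 0.5, 1.0])
        avg = average_replicates([h, h, h])
        assert np.allclose(avg.sem, 0.0)

    def test_two_replicate_arithmetic(self):
        edges = [0.0, 0.5, 1.0]
        a = FretHistogram(bin_edges=edges, frequencies=[0.0, 2.0])
        b = FretHistogram(bin_edges=edges, frequencies=[2.0, 0.0])
        avg = average_replicates([a, b])
        assert np.allclose(avg.frequencies, [1.0, 1.0])
        assert np.allclose(avg.sem, [1.0, 1.0])

    def test_mean_histogram_integrates_to_mean_count(self):
        spec = sd.MixtureSpec(components=[(0.6, 0.2, 1.0)], n_per_replicate=150,
                              n_replicates=3, seed=4)
        reps = [build_histogram(v, bin_edges=np.linspace(-0.5, 1.5, 41))
                for v in sd.sample_mixture(spec)]
        avg = average_replicates(reps)
        assert avg.total == pytest.approx(np.mean([r.total for r in reps]))

    def test_mismatched_edges_rejected(self):
        a = build_histogram([0.5], bin_edges=[0.0, 0.5, 1.0])
        b = build_histogram([0.5], bin_edges=[0.0, 0.4, 1.0])
        with pytest.raises(InvalidInputError):
            average_replicates([a, b])


class TestStagedFit:
    def test_recovers_study_component_means(self, staged_fit):
        fitted = [c.mean for c in staged_fit.components]
        for got, want in zip(fitted, STATE_MEANS):
            assert got == pytest.approx(want, abs=0.03)

    def test_recovers_widths_reasonably(self, staged_fit):
        for c, want in zip(staged_fit.components, STATE_WIDTHS):
            assert c.width == pytest.approx(want, rel=0.30)

    def test_single_component_data_leaves_other_amplitudes_small(self):
        samples = {
            "alone": sd.sample_mixture(sd.MixtureSpec(
                components=[(0.76, 0.24, 1.0)], seed=21)),
            "also-closed": sd.sample_mixture(sd.MixtureSpec(
                components=[(0.76, 0.24, 1.0)], seed=22)),
        }
        fit = fit_staged_mixture(histograms_from_samples(samples), seed=1)
        amps = fit.condition_amplitudes["also-closed"].mean(axis=0)
        assert amps[1] + amps[2] <= 0.05 * amps.sum()

    def test_noiseless_model_curve_fits_with_zero_residual(self):
        comps = [GaussianComponent(0.76, 0.24, 120.0),
                 GaussianComponent(0.59, 0.16, 50.0),
                 GaussianComponent(0.45, 0.31, 30.0)]
        edges = DEFAULT_BIN_EDGES
        curve = mixture_curve(edges, comps)
        alone_curve = mixture_curve(edges, [GaussianComponent(0.76, 0.24, 200.0)])
        hist_set = {
            "alone": [FretHistogram(bin_edges=edges, frequencies=alone_curve)],
            "mix": [FretHistogram(bin_edges=edges, frequencies=curve)],
        }
        fit = fit_staged_mixture(hist_set, seed=0)
        assert fit.rss_per_stage[2] < 1e-6 * curve.sum() ** 2
        for got, want in zip([c.mean for c in fit.components], STATE_MEANS):
            assert got == pytest.approx(want, abs=0.005)

    def test_missing_alone_condition_raises(self, study_histograms):
        subset = {k: v for k, v in study_histograms.items() if k != "alone"}
        with pytest.raises(ProtocolError):
            fit_staged_mixture(subset)

    def test_three_gaussian_rss_beats_single_gaussian(self, study_histograms,
                                                      staged_fit):
        from gatefret.model_selection import compare_k_fits
        rss = compare_k_fits(study_histograms, k_values=(1,), seed=3)
        assert staged_fit.rss_per_stage[2] < rss[1]


class TestOrientationCorrection:
    def test_identity_on_alone(self):
        alone = np.array([0.7, 0.2, 0.1])
        assert np.allclose(orientation_correct(alone, alone), alone)

    def test_worked_arithmetic(self):
        out = orientation_correct([0.6, 0.3, 0.1], [1.0, 0.0, 0.0])
        assert np.allclose(out, [0.2, 0.6, 0.2])

    def test_preserves_total_of_normalised_amplitudes(self):
        alone = np.array([0.8, 0.15, 0.05])
        cond = np.array([0.5, 0.3, 0.2])
        assert orientation_correct(cond, alone).sum() == pytest.approx(1.0)

    def test_negative_results_floored_with_warning(self):
        with pytest.warns(UserWarning):
            out = orientation_correct([0.2, 0.8, 0.0], [1.0, 0.0, 0.0])
        assert out[0] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            orientation_correct([1.0, 0.0], [1.0, 0.0, 0.0])


class TestAnovaAmplitudes:
    def test_identical_replicates_zero_sem(self):
        mean, sem = anova_amplitudes(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert np.allclose(sem, 0.0)

    def test_single_group_matches_mean_and_sd_formula(self):
        mean, sem = anova_amplitudes(np.array([[0.2], [0.4], [0.6]]))
        assert mean[0] == pytest.approx(0.4)
        assert sem[0] == pytest.approx(0.2 / np.sqrt(3))

    def test_pooled_sem_across_conditions(self):
        groups = {"a": np.array([[0.2], [0.4]]), "b": np.array([[0.5], [0.7]])}
        means, sems = anova_amplitudes(groups)
        # both groups share SD -> pooled MS_within = 0.02, SEM = sqrt(0.02/2)
        assert sems["a"][0] == pytest.approx(np.sqrt(0.02 / 2))
        assert means["b"][0] == pytest.approx(0.6)

    def test_single_replicate_rejected(self):
        with pytest.raises(InsufficientDataError):
            anova_amplitudes(np.array([[1.0, 2.0]]))


class TestAnisotropy:
    @pytest.mark.parametrize("ipar,iperp,g,expected", [
        (3.0, 3.0, 1.0, 0.0),
        (5.0, 0.0, 1.0, 1.0),
        (2.0, 1.0, 1.0, 0.25),
    ])
    def test_known_values(self, ipar, iperp, g, expected):
        assert compute_anisotropy(ipar, iperp, g) == pytest.approx(expected)

    def test_g_factor_scales_perpendicular_channel(self):
        assert compute_anisotropy(4.0, 1.0, G=4.0) == pytest.approx(0.0)

    def test_spectral_window_averaging(self):
        wl = np.array([510.0, 520.0, 530.0, 615.0])
        ipar = np.array([2.0, 2.0, 2.0, 9.0])
        iperp = np.array([1.0, 1.0, 1.0, 1.0])
        r = compute_anisotropy(ipar, iperp, 1.0, wavelengths=wl, window=(515, 525))
        assert r == pytest.approx(0.25)

    def test_zero_total_intensity_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_anisotropy(0.0, 0.0)


class TestOrientationCorrectionProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
           st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
           st.floats(0.1, 5.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_linear_in_condition_amplitudes(self, cond, alone, scale):
        cond = np.asarray(cond)
        alone = np.asarray(alone)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            a = orientation_correct(cond * scale, alone * scale)
            b = orientation_correct(cond, alone) * scale
        # linearity holds wherever the non-negativity floor is inactive
        raw = 2.0 * (cond - 0.5 * alone)
        mask = raw >= 0
        assert np.allclose(a[mask], b[mask], atol=1e-9)
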