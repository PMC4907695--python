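"""Tight-binding isotherm, exponential fits, and small conversions."""

import numpy as np
import pytest

from gatefret import synthetic_data as sd
from gatefret._util import InvalidInputError
from gatefret.ensemble_assays import (
    AtpaseAssay,
    FretCalibration,
    KineticTrace,
    TitrationSeries,
    atpase_turnover,
    efret_to_distance,
    fit_exponentials,
    fit_tight_binding,
    proximity_ratio,
    tight_binding_model,
)


class TestTightBindingModel:
    def test_zero_ligand_is_baseline(self):
        assert tight_binding_model(1.0, 0.47, 10.0, 23.5, 0.0) == pytest.approx(1.0)

    def test_stoichiometric_limit_at_zero_kd(self):
        f = tight_binding_model(1.0, 0.47, 10.0, 0.0, np.array([10.0, 50.0]))
        assert np.allclose(f, 1.0 - 0.47)

    def test_matches_quadratic_root_oracle(self):
        # oracle: physical root of c^2 - c(E0+s+KD) + E0*s = 0; F = F0 - Bmax*c/E0
        F0, Bmax, E0, KD, s = 1.0, 0.47, 10.0, 23.5, 23.5
        roots = np.roots([1.0, -(E0 + s + KD), E0 * s])
        c = min(r for r in roots if 0 <= r <= min(E0, s) + 1e-9)
        assert tight_binding_model(F0, Bmax, E0, KD, s) == pytest.approx(
            F0 - Bmax * c / E0, rel=1e-12)

    def test_monotone_non_increasing_in_ligand(self):
        s = np.linspace(0.0, 500.0, 200)
        f = tight_binding_model(1.0, 0.47, 10.0, 23.5, s)
        assert np.all(np.diff(f) <= 1e-12)

    def test_continuous_at_zero_kd(self):
        s = np.array([1.0, 5.0, 25.0])
        f0 = tight_binding_model(1.0, 0.5, 10.0, 0.0, s)
        feps = tight_binding_model(1.0, 0.5, 10.0, 1e-8, s)
        assert np.allclose(f0, feps, atol=1e-4)


class TestFitTightBinding:
    def test_noiseless_recovery_is_exact(self):
        series = sd.generate_titration(sd.TitrationSpec())
        fit = fit_tight_binding(series)
        assert fit.KD == pytest.approx(23.5, rel=1e-3)
        assert fit.Bmax == pytest.approx(0.47, rel=1e-3)
        assert fit.F0 == pytest.approx(1.0, rel=1e-3)

    def test_weak_depletion_limit_agrees_with_hyperbola(self):
        # E0 << KD: the quadratic collapses to F0 - Bmax*s/(s+KD)
        KD = 500.0
        spec = sd.TitrationSpec(E0=0.1, KD=KD, concentrations=np.array(
            [0, 50, 100, 200, 400, 800, 1600, 3200, 6400.0]))
        fit = fit_tight_binding(sd.generate_titration(spec))
        assert fit.KD == pytest.approx(KD, rel=0.01)

    def test_flat_data_flag_kd_unidentifiable(self):
        series = TitrationSeries(s=np.array([0.0, 10.0, 50.0, 200.0]),
                                 F=np.ones(4), E0=10.0)
        fit = fit_tight_binding(series)
        assert abs(fit.Bmax) < 1e-3
        assert not fit.kd_identifiable

    def test_noisy_recovery_small_bias_across_seeds(self):
        kds = []
        for seed in range(25):
            spec = sd.TitrationSpec(noise_sd=0.005, seed=seed)   # ~1% of span
            kds.append(fit_tight_binding(sd.generate_titration(spec)).KD)
        assert np.mean(kds) == pytest.approx(23.5, rel=0.02)

    def test_too_few_concentrations_rejected(self):
        series = TitrationSeries(s=np.array([0.0, 10.0, 10.0, 10.0]),
                                 F=np.array([1.0, 0.9, 0.9, 0.9]), E0=10.0)
        with pytest.raises(InvalidInputError):
            fit_tight_binding(series)


class TestFitExponentials:
    def test_single_rate_and_t_half(self):
        tr = sd.generate_decay(sd.DecaySpec(rates=(0.1,), amplitudes=(1.0,),
                                            duration=60.0))
        fit = fit_exponentials(tr, n_components=1)
        assert fit.rates[0] == pytest.approx(0.1, rel=1e-4)
        assert fit.t_half == pytest.approx(np.log(2) / 0.1, rel=1e-4)

    def test_fixed_rate_constrains_and_second_rate_recovers(self):
        tr = sd.generate_decay(sd.DecaySpec(rates=(0.5, 0.05),
                                            amplitudes=(0.6, 0.4), duration=120.0))
        fit = fit_exponentials(tr, n_components=2, fixed_rates={0: 0.5})
        assert fit.rates[0] == 0.5
        assert min(fit.rates) == pytest.approx(0.05, rel=0.01)

    def test_normalised_amplitudes_sum_to_one(self):
        tr = sd.generate_decay(sd.DecaySpec(rates=(0.5, 0.05),
                                            amplitudes=(0.6, 0.4), duration=120.0))
        fit = fit_exponentials(tr, n_components=2)
        assert fit.normalised_amplitudes.sum() == pytest.approx(1.0)

    def test_matches_log_linear_regression_on_noiseless_data(self):
        k_true, a_true = 0.25, 2.0
        tr = sd.generate_decay(sd.DecaySpec(rates=(k_true,), amplitudes=(a_true,),
                                            offset=0.0, duration=20.0))
        fit = fit_exponentials(tr, n_components=1)
        slope, intercept = np.polyfit(tr.time, np.log(tr.F), 1)
        assert fit.rates[0] == pytest.approx(-slope, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(np.exp(intercept), rel=1e-6)


class TestConversions:
    @pytest.mark.parametrize("fd,fa,expected", [
        (1.0, 1.0, 0.5), (1.0, 0.0, 0.0), (300.0, 700.0, 0.7)])
    def test_proximity_ratio(self, fd, fa, expected):
        assert proximity_ratio(fd, fa) == pytest.approx(expected)

    def test_proximity_ratio_zero_total_rejected(self):
        with pytest.raises(InvalidInputError):
            proximity_ratio(0.0, 0.0)

    def test_atpase_turnover_unit_slope(self):
        assert atpase_turnover(AtpaseAssay(slope=0.00622, enzyme_conc=1e-6)) == \
            pytest.approx(1.0)

    def test_atpase_turnover_inverse_in_enzyme(self):
        one = atpase_turnover(AtpaseAssay(slope=0.01, enzyme_conc=1e-6))
        two = atpase_turnover(AtpaseAssay(slope=0.01, enzyme_conc=2e-6))
        assert one == pytest.approx(2 * two)

    def test_distance_at_half_transfer_is_r0(self):
        assert efret_to_distance(0.5, FretCalibration(R0=6.0)) == pytest.approx(6.0)

    def test_closed_state_distance(self):
        assert efret_to_distance(0.76) == pytest.approx(4.95, abs=0.01)

    def test_distance_monotone_decreasing_in_e(self):
        es = np.linspace(0.05, 0.95, 50)
        rs = [efret_to_distance(e) for e in es]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_efficiency_domain_enforced(self):
        with pytest.raises(ValueError):
            efret_to_distance(1.0)


def test_decay_time_axis_must_increase():
    with pytest.raises(InvalidInputError):
        KineticTrace(time=np.array([0.0, 0.0, 1.0]), F=np.zeros(3))


class TestTightBindingProperties:
    """Hypothesis property checks on the isotherm itself."""

    from hypothesis import given, settings, strategies as st

    @given(
        bmax=st.floats(0.01, 10.0),
        e0=st.floats(0.1, 1000.0),
        kd=st.floats(0.0, 1000.0),
        s_max=st.floats(1.0, 1e5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, bmax, e0, kd, s_max):
        s = np.linspace(0.0, s_max, 50)
        f = tight_binding_model(1.0, bmax, e0, kd, s)
        assert np.all(np.diff(f) <= 1e-9 * (1.0 + bmax))
        # bound fraction never exceeds stoichiometry: F stays above F0 - Bmax
        assert np.all(f >= 1.0 - bmax - 1e-9 * (1.0 + bmax))
        assert f[0] == pytest.approx(1.0)

    @given(e=st.floats(0.01, 0.99))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_distance_round_trip(self, e):
        r = efret_to_distance(e, FretCalibration(R0=6.0))
        e_back = 1.0 / (1.0 + (r / 6.0) ** 6)
        assert e_back == pytest.approx(e, rel=1e-9)
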