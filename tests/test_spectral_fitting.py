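"""Loss-spectrum deconvolution, Δε normalisation, recrystallization onset."""

import warnings

import numpy as np
import pytest

from glasspharm.dielectric_models import (
    ConductivityTerm,
    LossSpectrum,
    RelaxationProcess,
    composite_loss,
    tau_max,
)
from glasspharm.spectral_fitting import (
    DeltaEpsSeries,
    FitPlan,
    ProcessPlan,
    SpectrumFit,
    detect_recrystallization_onset,
    extract_relaxation_points,
    fit_loss_spectrum,
    normalize_delta_eps,
)
from glasspharm.synthetic_data import BDSScenario, simulate_delta_eps_series


def _spectrum(processes, cond, f, T=312.0):
    return LossSpectrum(T, f, composite_loss(processes, cond, f))


class TestFitLossSpectrum:
    def test_recovers_single_debye(self, freq_grid):
        p = RelaxationProcess("alpha", "HN", 3.0, 1e-3, 1.0, 1.0)
        fit = fit_loss_spectrum(_spectrum([p], None, freq_grid),
                                FitPlan([ProcessPlan("alpha", "HN")]))
        c = fit.component("alpha")
        assert fit.converged
        assert c.delta_eps == pytest.approx(3.0, rel=1e-3)
        assert c.tau_hn == pytest.approx(1e-3, rel=1e-3)

    def test_recovers_hn_with_conductivity(self, freq_grid):
        # five free parameters: delta_eps, tau, a, b, sigma_dc
        p = RelaxationProcess("alpha", "HN", 2.0, 1e-2, 0.8, 0.6)
        fit = fit_loss_spectrum(
            _spectrum([p], ConductivityTerm(1e-12), freq_grid),
            FitPlan([ProcessPlan("alpha", "HN")], fit_conductivity=True),
        )
        c = fit.component("alpha")
        for got, want in [(c.delta_eps, 2.0), (c.tau_hn, 1e-2), (c.a, 0.8),
                          (c.b, 0.6), (fit.conductivity.sigma_dc, 1e-12)]:
            assert got == pytest.approx(want, rel=0.01)

    def test_two_processes_four_decades_apart(self, freq_grid):
        pa = RelaxationProcess("alpha", "HN", 4.0, 1.0, 0.87, 0.55)
        pb = RelaxationProcess("beta", "CC", 0.3, 1e-5, 0.35, 1.0)
        fit = fit_loss_spectrum(
            _spectrum([pa, pb], None, freq_grid),
            FitPlan([ProcessPlan("alpha", "HN"), ProcessPlan("beta", "CC")]),
        )
        assert tau_max(fit.component("alpha")) == pytest.approx(tau_max(pa), rel=0.02)
        assert tau_max(fit.component("beta")) == pytest.approx(tau_max(pb), rel=0.02)

    def test_noisy_recovery_within_five_percent(self, freq_grid):
        rng = np.random.default_rng(42)
        p = RelaxationProcess("alpha", "HN", 2.0, 1e-2, 0.8, 0.6)
        y = composite_loss([p], None, freq_grid)
        y = y * np.exp(0.02 * rng.standard_normal(y.size))
        fit = fit_loss_spectrum(LossSpectrum(312.0, freq_grid, y),
                                FitPlan([ProcessPlan("alpha", "HN")]))
        c = fit.component("alpha")
        for got, want in [(c.delta_eps, 2.0), (c.tau_hn, 1e-2), (c.a, 0.8), (c.b, 0.6)]:
            assert got == pytest.approx(want, rel=0.05)

    def test_fixed_parameters_are_respected(self, freq_grid):
        p = RelaxationProcess("beta", "CC", 0.5, 1e-4, 0.4, 1.0)
        fit = fit_loss_spectrum(
            _spectrum([p], None, freq_grid),
            FitPlan([ProcessPlan("beta", "CC", fix={"tau_hn": 1e-4, "a": 0.4})]),
        )
        c = fit.component("beta")
        assert c.tau_hn == 1e-4 and c.a == 0.4
        assert c.delta_eps == pytest.approx(0.5, rel=1e-6)

    def test_too_few_points_rejected(self):
        f = np.logspace(0, 2, 6)
        p = RelaxationProcess("alpha", "HN", 1.0, 1e-1, 1.0, 1.0)
        with pytest.raises(ValueError):
            fit_loss_spectrum(_spectrum([p], None, f), FitPlan([ProcessPlan("alpha", "HN")]))

    def test_empty_plan_rejected(self, freq_grid):
        p = RelaxationProcess("alpha", "HN", 1.0, 1e-1, 1.0, 1.0)
        with pytest.raises(ValueError):
            fit_loss_spectrum(_spectrum([p], None, freq_grid), FitPlan([]))


class TestExtractRelaxationPoints:
    def test_cc_component_passes_tau_through(self, freq_grid):
        p = RelaxationProcess("beta", "CC", 0.5, 2e-4, 0.4, 1.0)
        fit = SpectrumFit(250.0, [p], ConductivityTerm(0.0), 0.0, True)
        pts = extract_relaxation_points([fit])
        assert pts.loc[0, "tau_s"] == 2e-4  # CC: tau_max == tau_hn

    def test_alpha_and_alpha_prime_stay_distinct(self):
        pa = RelaxationProcess("alpha", "HN", 4.0, 1e-2, 0.8, 0.6)
        pap = RelaxationProcess("alpha_prime", "HN", 1.0, 1e-2, 0.8, 0.6)
        fit = SpectrumFit(330.0, [pa, pap], ConductivityTerm(0.0), 0.0, True)
        pts = extract_relaxation_points([fit])
        assert set(pts["label"]) == {"alpha", "alpha_prime"}

    def test_unconverged_fits_are_excluded_with_warning(self):
        p = RelaxationProcess("alpha", "HN", 4.0, 1e-2, 0.8, 0.6)
        good = SpectrumFit(320.0, [p], ConductivityTerm(0.0), 0.0, True)
        bad = SpectrumFit(322.0, [p], ConductivityTerm(0.0), 9.9, False)
        with pytest.warns(UserWarning, match="unconverged"):
            pts = extract_relaxation_points([good, bad])
        assert list(pts["T_K"]) == [320.0]


class TestNormalizeDeltaEps:
    def test_constant_series_normalises_to_one(self):
        s = DeltaEpsSeries("alpha", np.arange(300, 340, 4.0), np.full(10, 3.3))
        out = normalize_delta_eps(s)
        np.testing.assert_allclose(out.delta_eps, 1.0)

    def test_reference_arithmetic(self):
        s = DeltaEpsSeries("alpha", np.array([312.0, 330.0]), np.array([4.0, 1.0]))
        out = normalize_delta_eps(s, T_ref=312.0)
        assert out.delta_eps[1] == pytest.approx(0.25)

    def test_default_reference_is_312K(self):
        s = DeltaEpsSeries("alpha", np.arange(300, 340, 2.0), np.linspace(5, 3, 20))
        assert s.T_ref == 312.0
        out = normalize_delta_eps(s)
        assert np.interp(312.0, out.temperatures, out.delta_eps) == pytest.approx(1.0)

    def test_idempotent(self):
        s = DeltaEpsSeries("alpha", np.arange(300, 340, 2.0), np.linspace(5, 3, 20))
        once = normalize_delta_eps(s)
        twice = normalize_delta_eps(once)
        np.testing.assert_allclose(twice.delta_eps, once.delta_eps)

    def test_reference_outside_range_rejected(self):
        s = DeltaEpsSeries("alpha", np.arange(320, 340, 2.0), np.linspace(5, 3, 10))
        with pytest.raises(ValueError):
            normalize_delta_eps(s, T_ref=300.0)


class TestRecrystallizationOnset:
    def test_flat_series_has_no_onset(self):
        s = DeltaEpsSeries("alpha", np.arange(310, 343, 2.0), np.full(17, 4.0))
        assert detect_recrystallization_onset(s) is None

    def test_sigmoidal_drop_onset_within_1K_of_generator(self):
        scenario = BDSScenario(noise_rel=0.0)
        series = simulate_delta_eps_series(scenario, 10.0)
        onset = detect_recrystallization_onset(normalize_delta_eps(series))
        assert onset == pytest.approx(scenario.recryst_onsets[10.0], abs=1.0)

    def test_partial_drop_same_onset(self):
        # the residual amorphous fraction does not move the onset
        T = np.arange(310.0, 343.0, 2.0)
        for resid in (0.05, 0.4):
            v = resid + (1 - resid) / (1 + np.exp((T - 335.0) / 1.0))
            s = DeltaEpsSeries("alpha", T, 4.0 * v)
            onset = detect_recrystallization_onset(s)
            assert onset == pytest.approx(333.0, abs=1.0)

    def test_scale_invariance(self):
        scenario = BDSScenario(noise_rel=0.0)
        series = simulate_delta_eps_series(scenario, 20.0)
        o1 = detect_recrystallization_onset(series)
        scaled = DeltaEpsSeries("alpha", series.temperatures, 7.3 * series.delta_eps)
        assert detect_recrystallization_onset(scaled) == pytest.approx(o1, abs=1e-9)

    def test_too_few_points_rejected(self):
        s = DeltaEpsSeries("alpha", np.array([310.0, 312, 314, 316.0]), np.full(4, 1.0))
        with pytest.raises(ValueError):
            detect_recrystallization_onset(s)
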