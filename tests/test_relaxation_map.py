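"""VFT/Arrhenius fitting, Tg, fragility and coupling-model classification."""

import numpy as np
import pytest

from glasspharm.relaxation_map import (
    ArrheniusParams,
    VFTParams,
    arrhenius_tau,
    classify_secondary,
    fit_arrhenius,
    fit_vft,
    fragility,
    primitive_relaxation_time,
    tg_from_tau,
    vft_tau,
)

# the printed structural-relaxation parameters of amorphous aripiprazole
ARP_VFT = VFTParams(-15.73, 248.0, 2257.0)
ARP_BETA = ArrheniusParams(-17.57, 80.4)
ARP_GAMMA = ArrheniusParams(-12.39, 23.8)

LIQUID_GRID = np.arange(310.0, 342.1, 2.0)
GLASSY_GRID = np.arange(153.0, 303.1, 10.0)


def finite_difference_steepness(params: VFTParams, Tg: float, h: float = 1e-5) -> float:
    """Central finite difference of log10 tau with respect to Tg/T at Tg."""
    def logtau_of_x(x):  # x = Tg/T
        return np.log10(vft_tau(params, Tg / x))

    return (logtau_of_x(1 + h) - logtau_of_x(1 - h)) / (2 * h)


class TestFitVFT:
    def test_three_exact_points_recovered_algebraically(self):
        p = VFTParams(-12.0, 200.0, 1500.0)
        T = np.array([250.0, 280.0, 320.0])
        fit = fit_vft(np.column_stack([T, vft_tau(p, T)]))
        assert fit.T0 == pytest.approx(200.0, abs=1e-6)
        assert fit.D == pytest.approx(1500.0, rel=1e-7)
        assert fit.log10_tau_inf == pytest.approx(-12.0, abs=1e-7)

    def test_liquid_grid_refit_recovers_vogel_temperature(self):
        pts = np.column_stack([LIQUID_GRID, vft_tau(ARP_VFT, LIQUID_GRID)])
        fit = fit_vft(pts)
        assert fit.T0 == pytest.approx(248.0, abs=0.1)

    def test_noisy_refit_within_two_kelvin(self):
        rng = np.random.default_rng(4)
        tau = vft_tau(ARP_VFT, LIQUID_GRID) * np.exp(0.02 * rng.standard_normal(LIQUID_GRID.size))
        fit = fit_vft(np.column_stack([LIQUID_GRID, tau]))
        assert fit.T0 == pytest.approx(248.0, abs=2.0)

    def test_reports_standard_errors(self):
        pts = np.column_stack([LIQUID_GRID, vft_tau(ARP_VFT, LIQUID_GRID)])
        fit = fit_vft(pts)
        assert fit.stderr is not None and len(fit.stderr) == 3


class TestTgFromTau:
    def test_printed_parameters_give_303K(self):
        assert round(tg_from_tau(ARP_VFT, 100.0)) == 303

    def test_constructed_inversion(self):
        # choose D so that Tg - T0 = 50 exactly at log10 tau_g - log10 tau_inf = 14
        D = 50.0 * np.log(10.0) * 14.0
        p = VFTParams(-12.0, 200.0, D)
        assert tg_from_tau(p, 100.0) == pytest.approx(250.0, abs=1e-9)

    def test_round_trip_identity(self):
        Tg = tg_from_tau(ARP_VFT, 100.0)
        assert vft_tau(ARP_VFT, Tg) == pytest.approx(100.0, rel=1e-9)

    def test_unreachable_tau_rejected(self):
        with pytest.raises(ValueError):
            tg_from_tau(ARP_VFT, 1e-20)


class TestFragility:
    def test_strong_glass_limit(self):
        # T0 -> 0: Arrhenius behaviour, m_p = log10(tau_g / tau_inf)
        p = VFTParams(-15.73, 1e-9, 2257.0)
        Tg = tg_from_tau(p, 100.0)
        m = fragility(p, Tg).m_p
        assert m == pytest.approx(2.0 + 15.73, rel=1e-6)

    def test_closed_form_matches_finite_difference(self):
        Tg = tg_from_tau(ARP_VFT, 100.0)
        m = fragility(ARP_VFT, Tg).m_p
        assert m == pytest.approx(finite_difference_steepness(ARP_VFT, Tg), rel=1e-3)

    def test_finite_difference_on_random_parameter_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = VFTParams(rng.uniform(-18, -10), rng.uniform(150, 270), rng.uniform(800, 4000))
            Tg = tg_from_tau(p, 100.0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fragility(p, Tg).m_p
            assert m == pytest.approx(finite_difference_steepness(p, Tg), rel=1e-3)

    def test_monotone_in_vogel_temperature(self):
        ms = []
        for T0 in (200.0, 230.0, 260.0):
            p = VFTParams(-15.73, T0, 2257.0)
            Tg = tg_from_tau(p, 100.0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ms.append(fragility(p, Tg).m_p)
        assert ms[0] < ms[1] < ms[2]

    def test_tg_below_T0_rejected(self):
        with pytest.raises(ValueError):
            fragility(ARP_VFT, 240.0)


class TestFitArrhenius:
    @pytest.mark.parametrize(
        "params,ea", [(ARP_BETA, 80.4), (ARP_GAMMA, 23.8)], ids=["beta", "gamma"]
    )
    def test_glassy_grid_refit(self, params, ea):
        pts = np.column_stack([GLASSY_GRID, arrhenius_tau(params, GLASSY_GRID)])
        fit = fit_arrhenius(pts)
        assert fit.Ea == pytest.approx(ea, abs=0.1)
        assert fit.log10_tau_inf == pytest.approx(params.log10_tau_inf, abs=0.01)

    def test_two_points_determine_the_line(self):
        p = ArrheniusParams(-14.0, 50.0)
        T = np.array([200.0, 260.0])
        fit = fit_arrhenius(np.column_stack([T, arrhenius_tau(p, T)]))
        assert fit.Ea == pytest.approx(50.0, rel=1e-9)

    def test_degenerate_temperatures_rejected(self):
        with pytest.raises(ValueError):
            fit_arrhenius(np.array([[250.0, 1e-4], [250.0, 1e-4], [250.0, 1e-4]]))


class TestCouplingModel:
    def test_zero_coupling_identity(self):
        assert primitive_relaxation_time(3.7, 1.0) == pytest.approx(3.7, rel=1e-15)

    def test_fixed_point_at_tc(self):
        for beta in (0.3, 0.55, 0.9):
            assert primitive_relaxation_time(2e-12, beta) == pytest.approx(2e-12, rel=1e-12)

    def test_reference_evaluation(self):
        # tau_alpha = 100 s, beta = 0.55 -> tau_0 ~ 6.85e-5 s
        assert primitive_relaxation_time(100.0, 0.55) == pytest.approx(6.8464e-5, rel=1e-4)

    def test_tau0_never_exceeds_tau_alpha(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            tau_a = 10.0 ** rng.uniform(-11, 3)
            beta = rng.uniform(0.2, 1.0)
            tau0 = primitive_relaxation_time(tau_a, beta)
            assert tau0 <= tau_a * (1 + 1e-12)

    def test_constructed_jg_process_classified_jg(self):
        # build a secondary process lying exactly on the coupling prediction
        beta_kww = 0.55
        T = LIQUID_GRID
        tau_a = vft_tau(ARP_VFT, T)
        tau0 = primitive_relaxation_time(tau_a, beta_kww)
        sec = fit_arrhenius(np.column_stack([T, tau0]))
        res = classify_secondary(sec, np.column_stack([T, tau_a]), beta_kww)
        assert res.classification == "JG"

    def test_fast_process_classified_non_jg(self):
        beta_kww = 0.55
        T = LIQUID_GRID
        tau_a = vft_tau(ARP_VFT, T)
        tau0 = primitive_relaxation_time(tau_a, beta_kww)
        sec = fit_arrhenius(np.column_stack([T, tau0 * 1e-4]))  # 4 decades faster
        res = classify_secondary(sec, np.column_stack([T, tau_a]), beta_kww)
        assert res.classification == "non_JG"

    def test_classification_flips_monotonically_with_tolerance(self):
        beta_kww = 0.55
        T = LIQUID_GRID
        tau_a = vft_tau(ARP_VFT, T)
        tau0 = primitive_relaxation_time(tau_a, beta_kww)
        sec = fit_arrhenius(np.column_stack([T, tau0 * 10**-1.5]))  # offset 1.5 decades
        labels = [
            classify_secondary(sec, np.column_stack([T, tau_a]), beta_kww,
                               tolerance_decades=tol).classification
            for tol in (0.5, 1.0, 1.6, 2.5, 4.0)
        ]
        joined = "".join("J" if l == "JG" else "n" for l in labels)
        assert joined == "nnJJJ"

    def test_empty_alpha_points_rejected(self):
        with pytest.raises(ValueError):
            classify_secondary(ARP_BETA, np.empty((0, 2)), 0.55)
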