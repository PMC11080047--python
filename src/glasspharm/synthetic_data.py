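"""Seeded generators for dielectric loss surfaces and DSC traces.

The generators emulate the statistical structure the analysis pipeline
assumes for an amorphous drug confined in mesoporous silica, with
defaults set to the study conditions for aripiprazole (ARP) in Syloid
244FP silica:

* α-relaxation times from the VFT law (log10 τ∞ = −15.73, T0 = 248.0 K,
  D = 2257 K), β/γ from Arrhenius (−17.57, 80.4 kJ/mol) and
  (−12.39, 23.8 kJ/mol);
* α-peak breadth β_KWW falling linearly from 0.55 (pure drug) to 0.4
  (50 wt % silica);
* dielectric strength scaled by the drug mass fraction, suppressed above
  a loading-dependent recrystallization onset (333/327/325/337 K at
  10/20/30/40 wt %, no recrystallization at 0 or 50 wt %) by a sigmoid
  drop to a residual amorphous fraction that grows with loading;
* temperature grids 153–308 K (5 K) and 310–342 K (2 K), frequency grid
  10⁻¹–10⁶ Hz;
* DSC traces with a logistic ΔCp step at Tg = 307 K whose height falls
  linearly to zero at the 65 wt % monomolecular loading capacity, a
  crystallization exotherm whose tangent onset is V-shaped in loading
  (357 K for the pure drug, vertex at 27.3 wt %), and four overlapping
  Gaussian melting endotherms whose tangent onsets sit at 406, 410, 414
  and 421 K (forms IV, III, II, I).

Noise is multiplicative log-normal on ε″ and additive Gaussian on heat
flow; all randomness flows through an explicit seed, so identical
(scenario, seed) pairs give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dielectric_models import (
    ConductivityTerm,
    KWWShape,
    LossSpectrum,
    RelaxationProcess,
    composite_loss,
    kww_loss,
    tau_hn_from_tau_max,
)
from .relaxation_map import ArrheniusParams, VFTParams, arrhenius_tau, vft_tau
from .spectral_fitting import DeltaEpsSeries

__all__ = [
    "BDSScenario",
    "DSCScenario",
    "MeltingForm",
    "simulate_bds",
    "simulate_dsc",
    "simulate_delta_eps_series",
    "recrystallization_factor",
]

#: Width (K) of the sigmoidal dielectric-strength drop at recrystallization.
RECRYST_SIGMOID_WIDTH = 1.0


def _default_recryst_onsets() -> dict[float, float]:
    return {10.0: 333.0, 20.0: 327.0, 30.0: 325.0, 40.0: 337.0}


@dataclass
class BDSScenario:
    """Parameters of a synthetic broadband-dielectric measurement campaign."""

    vft: VFTParams = field(default_factory=lambda: VFTParams(-15.73, 248.0, 2257.0))
    arr_beta: ArrheniusParams = field(default_factory=lambda: ArrheniusParams(-17.57, 80.4))
    arr_gamma: ArrheniusParams = field(default_factory=lambda: ArrheniusParams(-12.39, 23.8))
    compositions: tuple[float, ...] = (0.0,)
    beta_kww_pure: float = 0.55
    beta_kww_50: float = 0.40
    delta_eps0: float = 4.0          # alpha strength of the pure drug
    delta_eps_beta0: float = 0.15
    delta_eps_gamma0: float = 0.40
    a_beta: float = 0.35             # CC width of the beta process
    a_gamma: float = 0.30
    b_alpha: float = 0.55            # HN asymmetry of the alpha process
    alpha_shape: str = "hn"          # "hn" or "kww"
    sigma_dc_ref: float = 1e-12      # S/m at T_ref_conductivity
    T_ref_conductivity: float = 312.0
    recryst_onsets: dict[float, float] = field(default_factory=_default_recryst_onsets)
    glassy_grid: tuple[float, float, float] = (153.0, 308.0, 5.0)
    liquid_grid: tuple[float, float, float] = (310.0, 342.0, 2.0)
    freq_decades: tuple[float, float] = (-1.0, 6.0)
    points_per_decade: int = 8
    noise_rel: float = 0.02
    seed: int = 42

    def frequencies(self) -> np.ndarray:
        lo, hi = self.freq_decades
        n = int(round((hi - lo) * self.points_per_decade)) + 1
        return np.logspace(lo, hi, n)

    def temperatures(self, regime: str) -> np.ndarray:
        lo, hi, step = self.glassy_grid if regime == "glassy" else self.liquid_grid
        return np.arange(lo, hi + 0.5 * step, step)

    def beta_kww(self, w: float) -> float:
        """Stretching exponent at silica loading w, linear between the anchors."""
        frac = np.clip(w / 50.0, 0.0, 1.0)
        return float(self.beta_kww_pure + (self.beta_kww_50 - self.beta_kww_pure) * frac)

    def alpha_hn_shape(self, w: float) -> tuple[float, float]:
        """HN (a, b) matching the β_KWW breadth through ab ≈ β_KWW^1.23."""
        ab = self.beta_kww(w) ** 1.23
        a = min(ab / self.b_alpha, 1.0)
        return a, self.b_alpha

    def residual_amorphous(self, w: float) -> float:
        """Amorphous fraction left after recrystallization; grows with loading."""
        return float(np.clip(0.2 + 0.01 * (w - 10.0), 0.05, 0.9))

    def onset(self, w: float) -> float | None:
        return self.recryst_onsets.get(float(w))


def recrystallization_factor(
    T: np.ndarray | float, onset: float | None, residual: float,
    width: float = RECRYST_SIGMOID_WIDTH,
) -> np.ndarray | float:
    """Fraction of the α dielectric strength surviving at temperature T.

    1 below the onset, sigmoidal drop (logistic of width ``width``
    centred at onset + 2·width) to the residual amorphous fraction.
    """
    if onset is None:
        return np.ones_like(np.asarray(T, dtype=float)) if np.ndim(T) else 1.0
    T = np.asarray(T, dtype=float)
    out = residual + (1.0 - residual) / (1.0 + np.exp((T - onset - 2.0 * width) / width))
    return float(out) if out.ndim == 0 else out


def _sigma_dc(scenario: BDSScenario, T: float) -> float:
    """DC conductivity tied to structural mobility: σ ∝ 1/τ_α."""
    if T <= scenario.vft.T0 + 5.0:
        return 0.0
    tau_ref = vft_tau(scenario.vft, scenario.T_ref_conductivity)
    tau = vft_tau(scenario.vft, T)
    return scenario.sigma_dc_ref * tau_ref / tau


def simulate_bds(scenario: BDSScenario, seed: int | None = None) -> list[LossSpectrum]:
    """Generate loss spectra for every (composition, temperature) pair.

    Glassy-grid spectra contain the β and γ processes; liquid-grid
    spectra add the α process (strength suppressed above the
    recrystallization onset) and the DC-conductivity term.
    Deterministic given (scenario, seed).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    f = scenario.frequencies()
    spectra: list[LossSpectrum] = []
    for w in scenario.compositions:
        drug = 1.0 - w / 100.0
        a_alpha, b_alpha = scenario.alpha_hn_shape(w)
        sample = f"ARP_{w:g}pct"
        for regime in ("glassy", "liquid"):
            for T in scenario.temperatures(regime):
                procs = []
                if regime == "liquid":
                    tau_a = vft_tau(scenario.vft, T)
                    de_a = (
                        scenario.delta_eps0 * drug
                        * recrystallization_factor(T, scenario.onset(w), scenario.residual_amorphous(w))
                    )
                    if scenario.alpha_shape == "kww":
                        alpha_loss = kww_loss(KWWShape(scenario.beta_kww(w), tau_a, de_a), f)
                    else:
                        tau_hn = tau_hn_from_tau_max(tau_a, a_alpha, b_alpha)
                        procs.append(RelaxationProcess("alpha", "HN", de_a, tau_hn, a_alpha, b_alpha))
                        alpha_loss = None
                    cond = ConductivityTerm(sigma_dc=_sigma_dc(scenario, T))
                else:
                    alpha_loss = None
                    cond = ConductivityTerm(0.0)
                procs.append(
                    RelaxationProcess(
                        "beta", "CC", scenario.delta_eps_beta0 * drug,
                        arrhenius_tau(scenario.arr_beta, T), scenario.a_beta,
                    )
                )
                procs.append(
                    RelaxationProcess(
                        "gamma", "CC", scenario.delta_eps_gamma0 * drug,
                        arrhenius_tau(scenario.arr_gamma, T), scenario.a_gamma,
                    )
                )
                loss = composite_loss(procs, cond, f)
                if alpha_loss is not None:
                    loss = loss + alpha_loss
                if scenario.noise_rel > 0:
                    loss = loss * np.exp(scenario.noise_rel * rng.standard_normal(f.size))
                spectra.append(
                    LossSpectrum(
                        temperature=float(T), frequencies=f.copy(), loss=loss,
                        sample_id=sample, silica_wt_pct=float(w),
                    )
                )
    return spectra


def simulate_delta_eps_series(
    scenario: BDSScenario, w: float, seed: int | None = None
) -> DeltaEpsSeries:
    """Δε_α(T) over the liquid grid, straight from the scenario law.

    This is the series a perfect spectral deconvolution would recover;
    it carries the same sigmoidal recrystallization drop as the spectra.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    T = scenario.temperatures("liquid")
    drug = 1.0 - w / 100.0
    de = scenario.delta_eps0 * drug * recrystallization_factor(
        T, scenario.onset(w), scenario.residual_amorphous(w)
    )
    if scenario.noise_rel > 0:
        de = de * np.exp(scenario.noise_rel * rng.standard_normal(T.size))
    return DeltaEpsSeries("alpha", T, de)


@dataclass(frozen=True)
class MeltingForm:
    """One polymorph's melting endotherm: Gaussian with tangent onset
    center − 2σ."""

    label: str
    onset: float
    sigma: float
    weight: float  # share of the total melting enthalpy

    @property
    def center(self) -> float:
        return self.onset + 2.0 * self.sigma


def _default_melting_forms() -> tuple[MeltingForm, ...]:
    # onsets from the pure-drug melting multiplet; widths from the
    # (onset, peak) pairs of the reference forms via sigma = (peak - onset)/2
    return (
        MeltingForm("IV", 406.0, 1.00, 0.25),
        MeltingForm("III", 410.0, 1.75, 0.50),
        MeltingForm("II", 414.0, 1.05, 0.15),
        MeltingForm("I", 421.0, 1.25, 0.10),
    )


@dataclass
class DSCScenario:
    """Parameters of a synthetic DSC heating experiment."""

    silica_wt_pct: float = 0.0
    Tg: float = 307.0
    tg_width: float = 2.0            # K, logistic step width
    delta_cp0: float = 0.35          # J/(g K), pure drug
    w_mlc: float = 65.0              # wt % silica where delta_cp hits zero
    Tc_pure: float = 357.0           # K, pure-drug exotherm tangent onset
    w_critical: float = 27.3         # wt %, vertex of the Tc(w) V-shape
    tc_slope_down: float = -1.1      # K per wt %, below the vertex
    tc_slope_up: float = 1.0         # K per wt %, above the vertex
    exo_sigma: float = 4.0           # K
    exo_enthalpy: float = 60.0       # J/g of drug
    melt_enthalpy: float = 95.0      # J/g of drug
    melting_forms: tuple[MeltingForm, ...] = field(default_factory=_default_melting_forms)
    baseline_offset: float = 0.0     # W/g
    baseline_slope: float = -2e-4    # W/g per K
    heating_rate: float = 10.0       # K/min
    T_start: float = 280.0
    T_end: float = 434.0
    T_step: float = 0.1
    noise_frac: float = 0.005        # additive noise SD as fraction of exo peak
    seed: int = 42

    def delta_cp(self, w: float | np.ndarray) -> float | np.ndarray:
        """ΔCp per total sample mass: linear in loading, zero at the MLC."""
        out = self.delta_cp0 * np.clip(1.0 - np.asarray(w, dtype=float) / self.w_mlc, 0.0, None)
        return float(out) if out.ndim == 0 else out

    def tc_onset(self, w: float | np.ndarray) -> float | np.ndarray:
        """V-shaped crystallization onset versus loading."""
        w = np.asarray(w, dtype=float)
        vertex_tc = self.Tc_pure + self.tc_slope_down * self.w_critical
        out = np.where(
            w <= self.w_critical,
            self.Tc_pure + self.tc_slope_down * w,
            vertex_tc + self.tc_slope_up * (w - self.w_critical),
        )
        return float(out) if out.ndim == 0 else out


def simulate_dsc(scenario: DSCScenario, seed: int | None = None) -> "DSCTrace":
    """Generate one DSC heating trace (exothermic-positive heat flow).

    Components: linear baseline, logistic ΔCp step at Tg, Gaussian
    crystallization exotherm (tangent onset at ``tc_onset``), Gaussian
    melting endotherms for each polymorph form, additive Gaussian noise.
    Deterministic given (scenario, seed).
    """
    from .dsc_analysis import DSCTrace  # deferred to avoid an import cycle

    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    w = scenario.silica_wt_pct
    drug = 1.0 - w / 100.0
    rate_s = scenario.heating_rate / 60.0
    T = np.arange(scenario.T_start, scenario.T_end + 0.5 * scenario.T_step, scenario.T_step)

    hf = scenario.baseline_offset + scenario.baseline_slope * (T - T[0])

    # glass-transition step: Cp rises by delta_cp, so the exo-positive
    # heat flow drops by delta_cp * heating rate
    step = scenario.delta_cp(w) * rate_s
    d = scenario.tg_width / 2.0
    hf = hf - step / (1.0 + np.exp(-(T - scenario.Tg) / d))

    exo_peak_amp = 0.0
    if scenario.delta_cp(w) > 0 and drug > 0:
        tc = scenario.tc_onset(w)
        center = tc + 2.0 * scenario.exo_sigma
        exo_peak_amp = scenario.exo_enthalpy * drug * rate_s / (scenario.exo_sigma * math.sqrt(2 * math.pi))
        hf = hf + exo_peak_amp * np.exp(-0.5 * ((T - center) / scenario.exo_sigma) ** 2)

        total_w = sum(fm.weight for fm in scenario.melting_forms)
        for fm in scenario.melting_forms:
            H = scenario.melt_enthalpy * drug * fm.weight / total_w
            amp = H * rate_s / (fm.sigma * math.sqrt(2 * math.pi))
            hf = hf - amp * np.exp(-0.5 * ((T - fm.center) / fm.sigma) ** 2)

    if scenario.noise_frac > 0:
        scale = exo_peak_amp if exo_peak_amp > 0 else max(step, 1e-6)
        hf = hf + scenario.noise_frac * scale * rng.standard_normal(T.size)

    return DSCTrace(
        temperatures=T, heat_flow=hf, heating_rate=scenario.heating_rate,
        sample_id=f"ARP_{w:g}pct", silica_wt_pct=float(w), drug_mass_fraction=drug if drug > 0 else 1.0,
    )
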