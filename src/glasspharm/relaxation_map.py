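"""Temperature dependence of relaxation times and derived glass metrics.

The structural (α) relaxation time of a fragile glass-former follows the
Vogel–Fulcher–Tammann law

    τ(T) = τ_inf · exp(D / (T − T0)),        D in kelvin,

from which the kinetic glass-transition temperature Tg = T(τ_α = 100 s)
and the fragility (steepness index)

    m_p = d log10 τ / d(Tg/T) |_{T=Tg} = (D / ln 10) · Tg / (Tg − T0)²

are derived in closed form.  Secondary (β, γ) relaxations in the glass
are Arrhenius, τ(T) = τ_inf · exp(Ea / R T).  The coupling model links
the α-process to its Johari–Goldstein precursor through the primitive
relaxation time τ_0 = t_c^n · τ_α^(1−n) with n = 1 − β_KWW and
t_c = 2 ps; a secondary process whose Arrhenius extrapolation above Tg
continues τ_0(T) is classified as JG, otherwise as non-JG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GAS_CONSTANT",
    "T_C_SECONDS",
    "VFTParams",
    "ArrheniusParams",
    "FragilityResult",
    "CouplingResult",
    "fit_vft",
    "vft_tau",
    "tg_from_tau",
    "fragility",
    "fit_arrhenius",
    "arrhenius_tau",
    "primitive_relaxation_time",
    "classify_secondary",
]

LN10 = np.log(10.0)

#: Gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Onset time of intermolecular coupling for small molecules, seconds.
T_C_SECONDS = 2e-12


@dataclass(frozen=True)
class VFTParams:
    """VFT parameters: τ(T) = 10^log10_tau_inf · exp(D/(T − T0)).

    ``D`` carries units of kelvin (not the dimensionless strength
    D′ = D/T0).  ``stderr`` holds asymptotic standard errors
    (log10_tau_inf, T0, D) when the parameters come from a fit.
    """

    log10_tau_inf: float
    T0: float
    D: float
    stderr: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0 K")
        if self.D <= 0:
            raise ValueError("D must be > 0 K")
        if self.log10_tau_inf >= 0:
            raise ValueError("log10_tau_inf must be < 0 (sub-second attempt time)")


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius parameters: τ(T) = 10^log10_tau_inf · exp(Ea/(R·T)).

    ``Ea`` in kJ/mol.
    """

    log10_tau_inf: float
    Ea: float
    stderr: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.Ea <= 0:
            raise ValueError("Ea must be > 0")


@dataclass(frozen=True)
class FragilityResult:
    m_p: float
    Tg_used: float


@dataclass
class CouplingResult:
    n: float
    t_c: float
    temperatures: np.ndarray
    tau_0: np.ndarray
    tau_secondary: np.ndarray
    mean_offset_decades: float
    classification: str  # "JG" | "non_JG"


def vft_tau(params: VFTParams, T: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the VFT law; T must exceed T0."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= params.T0):
        raise ValueError("VFT law is only defined for T > T0")
    out = 10.0**params.log10_tau_inf * np.exp(params.D / (T - params.T0))
    return float(out) if out.ndim == 0 else out


def fit_vft(points: Sequence[tuple[float, float]] | np.ndarray) -> VFTParams:
    """Least-squares VFT fit of (T, τ) data on log10 τ.

    log10 τ = log10 τ_inf + D / (ln10 · (T − T0)).  The start is chosen
    by a coarse T0 grid search (the model is linear in the other two
    parameters at fixed T0), then refined with bounded least squares
    keeping T0 below the lowest data temperature.  Requires ≥ 4 points
    spanning ≥ 2 decades in τ (3 exact points determine the curve and
    are accepted for algebraic recovery).
    """
    pts = np.asarray(points, dtype=float)
    T, tau = pts[:, 0], pts[:, 1]
    if T.size < 3:
        raise ValueError("need at least 3 (T, tau) points")
    if T.size > 3 and np.ptp(np.log10(tau)) < 2.0:
        warnings.warn("tau span < 2 decades; VFT fit may be ill-conditioned", stacklevel=2)
    logtau = np.log10(tau)

    # grid search on T0 with linear solve for the remaining two parameters
    T0_hi = T.min() - 1.0
    best = None
    for T0_try in np.linspace(max(T0_hi - 150.0, 1.0), T0_hi - 0.5, 300):
        u = 1.0 / (T - T0_try)
        A = np.column_stack([np.ones_like(u), u])
        coef, res, *_ = np.linalg.lstsq(A, logtau, rcond=None)
        sse = float(np.sum((A @ coef - logtau) ** 2))
        if best is None or sse < best[0]:
            best = (sse, T0_try, coef)
    _, T0_0, (c0, c1) = best

    def resid(x: np.ndarray) -> np.ndarray:
        lti, T0, D = x
        return lti + D / (LN10 * (T - T0)) - logtau

    x0 = np.array([c0, T0_0, max(c1 * LN10, 1.0)])
    lo = [-30.0, 1.0, 1.0]
    hi = [-0.5, T0_hi, 1e5]
    x0 = np.clip(x0, lo, hi)
    result = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not result.success:
        warnings.warn("VFT fit did not fully converge", stacklevel=2)

    stderr = None
    dof = T.size - 3
    if dof > 0:
        try:
            J = result.jac
            cov = np.linalg.inv(J.T @ J) * 2.0 * result.cost / dof
            stderr = tuple(float(s) for s in np.sqrt(np.diag(cov)))
        except np.linalg.LinAlgError:
            stderr = None
    lti, T0, D = result.x
    return VFTParams(float(lti), float(T0), float(D), stderr=stderr)


def tg_from_tau(params: VFTParams, tau_g: float = 100.0) -> float:
    """Glass-transition temperature from the convention Tg = T(τ_α = tau_g).

    Closed-form VFT inversion:
    Tg = T0 + D / (ln10 · (log10 tau_g − log10 τ_inf)).
    """
    log_ratio = np.log10(tau_g) - params.log10_tau_inf
    if log_ratio <= 0:
        raise ValueError("tau_g must exceed the pre-exponential time")
    return params.T0 + params.D / (LN10 * log_ratio)


def fragility(params: VFTParams, Tg: float) -> FragilityResult:
    """Steepness index m_p = (D/ln10) · Tg / (Tg − T0)² at T = Tg.

    Physical glass-formers fall between m_p = 16 (strong, the Arrhenius
    limit) and ≈ 200 (very fragile); values outside trigger a warning.
    """
    if Tg <= params.T0:
        raise ValueError("Tg must be above the Vogel temperature T0")
    m_p = (params.D / LN10) * Tg / (Tg - params.T0) ** 2
    if not 16.0 <= m_p <= 200.0:
        warnings.warn(f"fragility m_p = {m_p:.1f} outside the physical range [16, 200]",
                      stacklevel=2)
    return FragilityResult(m_p=float(m_p), Tg_used=float(Tg))


def arrhenius_tau(params: ArrheniusParams, T: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the Arrhenius law (Ea in kJ/mol)."""
    T = np.asarray(T, dtype=float)
    out = 10.0**params.log10_tau_inf * np.exp(params.Ea * 1e3 / (GAS_CONSTANT * T))
    return float(out) if out.ndim == 0 else out


def fit_arrhenius(points: Sequence[tuple[float, float]] | np.ndarray) -> ArrheniusParams:
    """Linear least squares of log10 τ versus 1/T.

    Ea = slope · ln10 · R, reported in kJ/mol.
    """
    pts = np.asarray(points, dtype=float)
    T, tau = pts[:, 0], pts[:, 1]
    if T.size < 2:
        raise ValueError("need at least 2 (T, tau) points")
    x = 1.0 / T
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate temperature spread")
    logtau = np.log10(tau)
    if T.size > 2:
        (slope, intercept), cov = np.polyfit(x, logtau, 1, cov=True)
        se = np.sqrt(np.diag(cov))
        stderr = (float(se[1]), float(se[0] * LN10 * GAS_CONSTANT / 1e3))
    else:
        slope, intercept = np.polyfit(x, logtau, 1)
        stderr = None
    Ea = slope * LN10 * GAS_CONSTANT / 1e3
    if Ea <= 0:
        raise ValueError("fitted activation energy is non-positive")
    return ArrheniusParams(float(intercept), float(Ea), stderr=stderr)


def primitive_relaxation_time(
    tau_alpha: np.ndarray | float, beta_kww: float, t_c: float = T_C_SECONDS
) -> np.ndarray | float:
    """Coupling-model primitive relaxation time τ_0 = t_c^n · τ_α^(1−n).

    n = 1 − β_KWW is the coupling parameter.  τ_0 approximates the
    Johari–Goldstein relaxation time; τ_0 = τ_α when β = 1 and
    τ_0 = t_c at τ_α = t_c for any β.
    """
    if not 0 < beta_kww <= 1:
        raise ValueError("beta_kww must be in (0, 1]")
    tau_alpha = np.asarray(tau_alpha, dtype=float)
    if np.any(tau_alpha <= 0):
        raise ValueError("tau_alpha must be > 0")
    n = 1.0 - beta_kww
    out = t_c**n * tau_alpha**beta_kww
    return float(out) if out.ndim == 0 else out


def classify_secondary(
    secondary_fit: ArrheniusParams,
    alpha_points: Sequence[tuple[float, float]] | np.ndarray,
    beta_kww: float,
    tolerance_decades: float = 1.0,
    t_c: float = T_C_SECONDS,
) -> CouplingResult:
    """Classify a secondary relaxation as Johari–Goldstein or not.

    The glassy-state Arrhenius fit of the secondary process is
    extrapolated to the α-point temperatures above Tg and compared with
    the coupling-model prediction τ_0(T); mean |Δ log10 τ| within
    ``tolerance_decades`` means the secondary process is the
    continuation of the primitive relaxation, i.e. JG.
    """
    pts = np.asarray(alpha_points, dtype=float)
    if pts.size == 0:
        raise ValueError("alpha_points must not be empty")
    T, tau_a = pts[:, 0], pts[:, 1]
    tau0 = primitive_relaxation_time(tau_a, beta_kww, t_c=t_c)
    tau_sec = arrhenius_tau(secondary_fit, T)
    offset = float(np.mean(np.abs(np.log10(tau0) - np.log10(tau_sec))))
    return CouplingResult(
        n=1.0 - beta_kww,
        t_c=t_c,
        temperatures=T,
        tau_0=np.atleast_1d(tau0),
        tau_secondary=np.atleast_1d(tau_sec),
        mean_offset_decades=offset,
        classification="JG" if offset <= tolerance_decades else "non_JG",
    )
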