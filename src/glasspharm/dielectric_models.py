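"""Forward models for broadband dielectric loss spectra.

The imaginary part of the complex permittivity, ``eps'' (ω)``, of a
glass-forming material is modelled as a sum of relaxation processes —
Havriliak–Negami (HN) for the asymmetric structural (alpha) relaxation,
Cole–Cole (CC, the symmetric b=1 limit of HN) for secondary (beta, gamma)
relaxations — plus a DC-conductivity contribution from residual ionic
impurities.  The module also provides the peak relaxation time
``tau_max`` derived from HN shape parameters and the frequency-domain
Kohlrausch–Williams–Watts (KWW) stretched-exponential loss shape.

Conventions
-----------
* Spectra are stored against ordinary frequency ``f`` in Hz; the angular
  frequency is ``ω = 2π f`` throughout.
* Only the loss (imaginary) part is modelled; the high-frequency limit
  ``eps_inf`` is carried as metadata by fit results, never as a model term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "EPS0",
    "PROCESS_LABELS",
    "RelaxationProcess",
    "ConductivityTerm",
    "LossSpectrum",
    "KWWShape",
    "KWWQuadratureError",
    "hn_loss",
    "composite_loss",
    "tau_max",
    "kww_loss",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12

#: Recognised relaxation-process labels, ordered slow to fast.
PROCESS_LABELS = ("alpha", "alpha_prime", "beta", "gamma")


class KWWQuadratureError(RuntimeError):
    """Raised when the oscillatory KWW quadrature fails to converge."""


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class RelaxationProcess:
    """One relaxation process of the loss spectrum.

    Parameters
    ----------
    label : str
        One of ``alpha``, ``alpha_prime``, ``beta``, ``gamma``.
    model : str
        ``"HN"`` (free asymmetry ``b``) or ``"CC"`` (``b`` fixed at 1).
    delta_eps : float
        Dielectric strength Δε (> 0), proportional to the number density
        of actively reorienting dipoles.
    tau_hn : float
        HN relaxation time τ_HN in seconds (> 0).
    a : float
        Symmetric broadening exponent, 0 < a ≤ 1.
    b : float
        Asymmetric broadening exponent, 0 < b ≤ 1; exactly 1 for CC.
    """

    label: str
    model: str
    delta_eps: float
    tau_hn: float
    a: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in PROCESS_LABELS:
            raise ValueError(f"unknown process label {self.label!r}")
        if self.model not in ("HN", "CC"):
            raise ValueError(f"model must be 'HN' or 'CC', got {self.model!r}")
        _check_positive("delta_eps", self.delta_eps)
        _check_positive("tau_hn", self.tau_hn)
        if not 0 < self.a <= 1:
            raise ValueError(f"a must be in (0, 1], got {self.a}")
        if not 0 < self.b <= 1:
            raise ValueError(f"b must be in (0, 1], got {self.b}")
        if self.model == "CC" and self.b != 1.0:
            raise ValueError("Cole-Cole requires b = 1 exactly")


@dataclass(frozen=True)
class ConductivityTerm:
    """DC-conductivity loss term ``σ_dc / (ε0 · ω^s)``.

    ``s_exp = 1`` is the ohmic default; the exponent may be lowered for
    electrode-blocking or hopping-dominated spectra.
    """

    sigma_dc: float = 0.0
    s_exp: float = 1.0
    eps0: float = EPS0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_dc) or self.sigma_dc < 0:
            raise ValueError(f"sigma_dc must be >= 0, got {self.sigma_dc}")
        if not 0 < self.s_exp <= 1.2:
            raise ValueError(f"s_exp must be in (0, 1.2], got {self.s_exp}")


@dataclass
class LossSpectrum:
    """Dielectric loss ε″(f) at a single temperature.

    ``frequencies`` must be strictly increasing and in Hz.
    """

    temperature: float
    frequencies: np.ndarray
    loss: np.ndarray
    sample_id: str = ""
    silica_wt_pct: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        if self.frequencies.shape != self.loss.shape:
            raise ValueError("frequencies and loss must have the same length")
        if self.frequencies.ndim != 1:
            raise ValueError("spectrum arrays must be one-dimensional")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if not 0 <= self.silica_wt_pct <= 100:
            raise ValueError("silica_wt_pct must be in [0, 100]")


@dataclass(frozen=True)
class KWWShape:
    """Frequency-domain stretched-exponential (KWW) loss shape.

    The time-domain decay is φ(t) = exp[−(t/τ)^β]; β = 1 is the Debye
    limit, smaller β broadens the loss peak.
    """

    beta_kww: float
    tau_kww: float
    delta_eps: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.beta_kww <= 1:
            raise ValueError(f"beta_kww must be in (0, 1], got {self.beta_kww}")
        _check_positive("tau_kww", self.tau_kww)
        _check_positive("delta_eps", self.delta_eps)


def _as_freq_array(frequencies: Iterable[float]) -> np.ndarray:
    f = np.asarray(list(frequencies) if not isinstance(frequencies, np.ndarray) else frequencies, dtype=float)
    if np.any(f <= 0) or not np.all(np.isfinite(f)):
        raise ValueError("frequencies must be finite and > 0")
    return f


def hn_loss(process: RelaxationProcess, frequencies: Iterable[float]) -> np.ndarray:
    """Havriliak–Negami dielectric loss ε″(ω) = −Im[Δε / (1 + (iωτ)^a)^b].

    Evaluated through the real closed form

        ε″ = Δε · sin(b·θ) / (1 + 2 x cos(πa/2) + x²)^(b/2),
        x = (ωτ)^a,  θ = atan2(x sin(πa/2), 1 + x cos(πa/2)),

    which is non-negative and single-peaked in log f for all valid
    (a, b).  With a = b = 1 this is the Debye loss with peak height
    Δε/2 at ωτ = 1.
    """
    f = _as_freq_array(frequencies)
    w = 2.0 * np.pi * f
    x = (w * process.tau_hn) ** process.a
    half = 0.5 * np.pi * process.a
    theta = np.arctan2(x * np.sin(half), 1.0 + x * np.cos(half))
    mod = (1.0 + 2.0 * x * np.cos(half) + x * x) ** (0.5 * process.b)
    return process.delta_eps * np.sin(process.b * theta) / mod


def composite_loss(
    processes: Sequence[RelaxationProcess],
    conductivity: ConductivityTerm | None,
    frequencies: Iterable[float],
) -> np.ndarray:
    """Sum of the individual process losses plus the conductivity term."""
    f = _as_freq_array(frequencies)
    total = np.zeros_like(f)
    for proc in processes:
        total += hn_loss(proc, f)
    if conductivity is not None and conductivity.sigma_dc > 0:
        w = 2.0 * np.pi * f
        total += conductivity.sigma_dc / (conductivity.eps0 * w**conductivity.s_exp)
    return total


def tau_max(process: RelaxationProcess) -> float:
    """Relaxation time at the loss-peak maximum of an HN process.

    τ_max = τ_HN · [sin(aπ / (2 + 2b))]^(−1/a) · [sin(abπ / (2 + 2b))]^(1/a)

    For b = 1 (Debye and Cole–Cole) the two sine factors cancel and
    τ_max = τ_HN exactly.
    """
    a, b = process.a, process.b
    if b == 1.0:
        return process.tau_hn
    s1 = math.sin(a * math.pi / (2.0 * (1.0 + b)))
    s2 = math.sin(a * b * math.pi / (2.0 * (1.0 + b)))
    return process.tau_hn * s1 ** (-1.0 / a) * s2 ** (1.0 / a)


def tau_hn_from_tau_max(tau_peak: float, a: float, b: float) -> float:
    """Inverse of :func:`tau_max`: HN time giving a loss peak at ``tau_peak``."""
    if b == 1.0:
        return tau_peak
    s1 = math.sin(a * math.pi / (2.0 * (1.0 + b)))
    s2 = math.sin(a * b * math.pi / (2.0 * (1.0 + b)))
    return tau_peak * s1 ** (1.0 / a) * s2 ** (-1.0 / a)


def kww_loss(
    shape: KWWShape,
    frequencies: Iterable[float],
    *,
    epsrel: float = 1e-10,
    tail_eps: float = 1e-18,
) -> np.ndarray:
    """Frequency-domain KWW loss via the one-sided cosine transform.

    Using φ(t) = exp[−(t/τ)^β] and integrating the one-sided Fourier
    transform of −dφ/dt by parts,

        ε″(ω) = Δε · ω · ∫₀^∞ φ(t) cos(ωt) dt .

    The integral is evaluated per frequency with adaptive oscillatory
    (cosine-weighted Clenshaw–Curtis) quadrature on [0, t_cut], where
    t_cut = τ · (ln 1/tail_eps)^(1/β) truncates the integrand at
    φ = tail_eps.  Reduces to the Debye loss at β = 1.

    Raises
    ------
    KWWQuadratureError
        If the quadrature error estimate exceeds the requested relative
        tolerance by more than an order of magnitude (with an absolute
        floor far below any measurable loss).
    """
    f = _as_freq_array(frequencies)
    tau, beta, de = shape.tau_kww, shape.beta_kww, shape.delta_eps
    t_cut = tau * math.log(1.0 / tail_eps) ** (1.0 / beta)

    def phi(t: float) -> float:
        return math.exp(-((t / tau) ** beta))

    out = np.empty_like(f)
    for i, fi in enumerate(f):
        w = 2.0 * math.pi * fi
        res = quad(
            phi, 0.0, t_cut, weight="cos", wvar=w,
            epsabs=0.0, epsrel=epsrel, limit=400, maxp1=100, full_output=1,
        )
        val, abserr = res[0], res[1]
        ier = res[2].get("ier", 0) if len(res) > 2 and isinstance(res[2], dict) else 0
        abs_floor = 1e-10 * de / max(w, 1.0)
        if ier not in (0, 2) and abserr > max(10 * epsrel * abs(val), abs_floor):
            raise KWWQuadratureError(
                f"KWW quadrature failed at f={fi:g} Hz "
                f"(beta={beta}, tau={tau:g}): ier={ier}, abserr={abserr:g}, value={val:g}"
            )
        out[i] = de * w * val
    return out
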