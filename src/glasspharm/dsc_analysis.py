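"""DSC thermogram analysis: glass transition, exotherms, melting peaks.

Heat flow is stored exothermic-positive in W/g; readers accept an
``exo_up`` flag and normalise on input.  The heat-capacity scale follows
from Cp = (dQ/dt)/(dT/dt), so a heat-flow step of height h at a heating
rate r (K/min) corresponds to ΔCp = h/(r/60) in J/(g K).

Onsets use the classical tangent construction: intersection of the
steepest leading-edge tangent with the baseline.  For a Gaussian peak of
centre c and width σ the construction has the closed form
onset = c − 2σ (tangent at the inflection point c − σ).  Overlapping
melting endotherms are separated by least-squares multi-Gaussian
deconvolution over a linear baseline, and onsets are computed per
deconvolved component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DSCTrace",
    "GlassTransitionEvent",
    "GaussianComponent",
    "ThermalEvent",
    "detect_glass_transition",
    "detect_exotherm_onset",
    "deconvolve_melting",
    "tangent_onset",
]

#: Form labels assigned to exactly four melting components by ascending
#: centre temperature (form IV melts lowest, form I highest).
FOUR_FORM_ORDER = ("IV", "III", "II", "I")


@dataclass
class DSCTrace:
    """One DSC heating trace; heat flow exothermic-positive, W/g."""

    temperatures: np.ndarray
    heat_flow: np.ndarray
    heating_rate: float  # K/min
    sample_id: str = ""
    silica_wt_pct: float = 0.0
    drug_mass_fraction: float = 1.0
    normalized_to_drug: bool = False

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.temperatures.shape != self.heat_flow.shape:
            raise ValueError("temperature and heat-flow lengths differ")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.heating_rate <= 0:
            raise ValueError("heating_rate must be > 0 K/min")
        if not 0 < self.drug_mass_fraction <= 1:
            raise ValueError("drug_mass_fraction must be in (0, 1]")

    @property
    def rate_K_per_s(self) -> float:
        return self.heating_rate / 60.0

    def window(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.temperatures >= lo) & (self.temperatures <= hi)
        if m.sum() < 10:
            raise ValueError(f"window [{lo}, {hi}] K contains fewer than 10 points")
        return self.temperatures[m], self.heat_flow[m]


@dataclass(frozen=True)
class GlassTransitionEvent:
    Tg_onset: float
    Tg_mid: float
    delta_cp: float  # J/(g K)


@dataclass(frozen=True)
class GaussianComponent:
    """One deconvolved thermal peak: A·exp(−(T−center)²/2σ²) over baseline.

    ``area`` is the enthalpy in J/g, signed (endotherms negative in the
    exothermic-positive convention).
    """

    center: float
    sigma: float
    area: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class ThermalEvent:
    kind: str  # "exotherm" | "endotherm"
    onset: float
    peak: float
    area: float  # J/g

    def __post_init__(self) -> None:
        if self.onset > self.peak:
            raise ValueError("onset must not exceed the peak temperature")


def _linfit(T: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    c = np.polyfit(T, y, 1)
    resid = y - np.polyval(c, T)
    return c, float(np.std(resid))


def _smooth_for_gradient(T: np.ndarray, y: np.ndarray, width_K: float = 1.0) -> np.ndarray:
    """Savitzky–Golay smoothing over ~width_K kelvin, for derivative
    estimates that would otherwise amplify point noise."""
    from scipy.signal import savgol_filter

    step = float(np.median(np.diff(T)))
    window = int(round(width_K / step)) | 1  # odd
    if window < 5 or window >= y.size:
        return y
    return savgol_filter(y, window, polyorder=2)


def detect_glass_transition(
    trace: DSCTrace, window: tuple[float, float], *, flank_frac: float = 0.25
) -> GlassTransitionEvent | None:
    """Baseline-construction analysis of the ΔCp step at Tg.

    Linear baselines are fitted to the leading and trailing
    ``flank_frac`` of the window; Tg_mid is where the trace crosses the
    midline between them, Tg_onset the intersection of the
    low-temperature baseline with the steepest tangent, and ΔCp the
    baseline separation at Tg_mid divided by the heating rate (K/s).
    Returns None (with a warning) if the step is below the noise floor.
    """
    T, y = trace.window(*window)
    n = T.size
    k = max(int(n * flank_frac), 3)
    c_lo, noise_lo = _linfit(T[:k], y[:k])
    c_hi, noise_hi = _linfit(T[-k:], y[-k:])
    noise = max(noise_lo, noise_hi)

    mid_T = 0.5 * (T[0] + T[-1])
    sep_mid = np.polyval(c_lo, mid_T) - np.polyval(c_hi, mid_T)
    if abs(sep_mid) < max(4.0 * noise, 1e-12):
        warnings.warn("no resolvable glass-transition step in window", stacklevel=2)
        return None

    midline = 0.5 * (np.polyval(c_lo, T) + np.polyval(c_hi, T))
    s = y - midline
    # root of a local linear fit through the central part of the step:
    # unbiased under noise, exact for a clean sigmoid
    central = np.abs(s) <= 0.25 * abs(sep_mid)
    Tg_mid = None
    if central.sum() >= 5:
        c = np.polyfit(T[central], s[central], 1)
        if c[0] != 0:
            root = -c[1] / c[0]
            if T[0] <= root <= T[-1]:
                Tg_mid = float(root)
    if Tg_mid is None:
        sign0 = np.sign(s[0])
        idx = None
        for i in range(1, n):
            if np.sign(s[i]) != sign0 and np.sign(s[i]) != 0:
                idx = i
                break
        if idx is None:
            warnings.warn("trace never crosses the baseline midline", stacklevel=2)
            return None
        t = s[idx - 1] / (s[idx - 1] - s[idx])
        Tg_mid = float(T[idx - 1] + t * (T[idx] - T[idx - 1]))

    grad = np.gradient(_smooth_for_gradient(T, y), T)
    inner = slice(k, n - k)
    j = k + int(np.argmax(np.abs(grad[inner])))
    g = grad[j]
    # tangent y(Tj) + g (T - Tj) meets the low-T baseline c_lo
    denom = g - c_lo[0]
    if abs(denom) < 1e-15:
        Tg_onset = Tg_mid
    else:
        Tg_onset = float((np.polyval(c_lo, T[j]) - y[j] + g * T[j]) / denom)
    Tg_onset = min(Tg_onset, Tg_mid)

    delta_cp = abs(sep_mid := np.polyval(c_lo, Tg_mid) - np.polyval(c_hi, Tg_mid)) / trace.rate_K_per_s
    return GlassTransitionEvent(Tg_onset=Tg_onset, Tg_mid=Tg_mid, delta_cp=float(delta_cp))


def detect_exotherm_onset(
    trace: DSCTrace, window: tuple[float, float], *, flank_frac: float = 0.15
) -> ThermalEvent | None:
    """Tangent-construction onset of a crystallization exotherm.

    A single linear baseline is fitted through both flanks of the
    window; the onset is where the steepest leading-edge tangent meets
    that baseline, the peak is refined parabolically, and the area is
    the baseline-corrected trapezoidal integral converted to J/g.
    Returns None if no peak rises above the noise.
    """
    T, y = trace.window(*window)
    n = T.size
    k = max(int(n * flank_frac), 3)
    flank_T = np.concatenate([T[:k], T[-k:]])
    flank_y = np.concatenate([y[:k], y[-k:]])
    c_base, noise = _linfit(flank_T, flank_y)
    r = _smooth_for_gradient(T, y - np.polyval(c_base, T))

    ipk = int(np.argmax(r))
    if r[ipk] < max(5.0 * noise, 1e-12) or ipk in (0, n - 1):
        warnings.warn("no exothermic peak above noise in window", stacklevel=2)
        return None

    # parabolic refinement of the peak position
    if 0 < ipk < n - 1:
        sl = slice(max(ipk - 2, 0), min(ipk + 3, n))
        c = np.polyfit(T[sl], r[sl], 2)
        T_peak = float(-c[1] / (2 * c[0])) if c[0] < 0 else float(T[ipk])
    else:
        T_peak = float(T[ipk])

    grad = np.gradient(r, T)
    j = int(np.argmax(grad[: ipk + 1]))
    g = grad[j]
    if g <= 0:
        warnings.warn("leading edge has no rising tangent", stacklevel=2)
        return None
    onset = float(T[j] - r[j] / g)

    area = float(np.trapezoid(r, T) / trace.rate_K_per_s)
    return ThermalEvent(kind="exotherm", onset=onset, peak=T_peak, area=area)


def tangent_onset(component: GaussianComponent) -> float:
    """Closed-form tangent onset of a Gaussian peak: center − 2σ."""
    return component.center - 2.0 * component.sigma


def deconvolve_melting(
    trace: DSCTrace,
    n_components: int,
    window: tuple[float, float],
    init_centers: Sequence[float] | None = None,
) -> list[GaussianComponent]:
    """Multi-peak Gaussian deconvolution of overlapping melting endotherms.

    Fits a sum of ``n_components`` Gaussians plus a linear baseline by
    least squares.  Initial centres are user-supplied or equally spaced
    over the window (deterministic).  Components are returned sorted by
    centre; with exactly four components the polymorph labels IV, III,
    II, I are assigned in ascending-centre order, otherwise labels are
    left empty (see :func:`glasspharm.stability_analysis.assign_polymorphs`
    for window-based labelling).  Non-convergence or a collapsing width
    raises — in manual practice such a fit would be re-run with
    different settings rather than silently accepted.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    T, y = trace.window(*window)
    span = T[-1] - T[0]

    Tm = 0.5 * (T[0] + T[-1])
    c_base = np.polyfit(
        np.concatenate([T[:3], T[-3:]]) - Tm, np.concatenate([y[:3], y[-3:]]), 1
    )
    r0 = y - np.polyval(c_base, T - Tm)
    # melting components share a sign (endothermic); fit in that orientation
    sign = -1.0 if abs(np.min(r0)) > abs(np.max(r0)) else 1.0
    amp_scale = float(np.max(np.abs(r0)))
    if amp_scale <= 0:
        raise ValueError("window contains no signal above the baseline")

    if init_centers is None:
        # deterministic data-driven starts: the n most prominent extrema
        # of the baseline-corrected signal, padded equally spaced
        from scipy.signal import find_peaks

        idx, props = find_peaks(sign * r0, prominence=0.02 * amp_scale)
        order = np.argsort(props["prominences"])[::-1][:n_components]
        peak_centers = list(T[idx[order]])
        if not peak_centers:
            peak_centers = [float(T[np.argmax(sign * r0)])]
        centers = list(peak_centers)
        # overlapping components merge into one discrete maximum: seed the
        # missing starts next to the most prominent peaks
        sigma_seed = max(span / (8.0 * n_components), 0.3)
        j = 0
        while len(centers) < n_components:
            base = peak_centers[j % len(peak_centers)]
            centers.append(base + 2.0 * sigma_seed * (1 + j // len(peak_centers)))
            j += 1
        init_centers = np.asarray(sorted(centers))
    else:
        init_centers = np.asarray(init_centers, dtype=float)
        if init_centers.size != n_components:
            raise ValueError("init_centers length must equal n_components")

    sigma0 = max(span / (8.0 * n_components), 0.3)
    amp0 = [
        sign * max(abs(r0[np.argmin(np.abs(T - c))]), 0.05 * amp_scale)
        for c in init_centers
    ]

    # parameter vector: per component (amp, center, log_sigma), then baseline (b0, b1)
    x0, lo, hi = [], [], []
    for a, c in zip(amp0, init_centers):
        x0 += [a, c, np.log(sigma0)]
        lo += [-100.0 * amp_scale if sign < 0 else 0.0, T[0], np.log(1e-3 * span)]
        hi += [0.0 if sign < 0 else 100.0 * amp_scale, T[-1], np.log(span)]
    x0 += [c_base[1], c_base[0]]
    lo += [-np.inf, -np.inf]
    hi += [np.inf, np.inf]

    def model(x: np.ndarray) -> np.ndarray:
        out = x[-2] + x[-1] * (T - Tm)
        for i in range(n_components):
            a, c, ls = x[3 * i : 3 * i + 3]
            s = np.exp(ls)
            out = out + a * np.exp(-0.5 * ((T - c) / s) ** 2)
        return out

    x_scale = []
    for _ in range(n_components):
        x_scale += [amp_scale, 1.0, 0.3]
    x_scale += [amp_scale, amp_scale / span]
    result = least_squares(
        lambda x: model(x) - y, np.asarray(x0), bounds=(np.asarray(lo), np.asarray(hi)),
        x_scale=np.asarray(x_scale), xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=10000,
    )
    if not result.success:
        raise RuntimeError(f"melting deconvolution did not converge (status {result.status})")

    comps = []
    for i in range(n_components):
        a, c, ls = result.x[3 * i : 3 * i + 3]
        s = float(np.exp(ls))
        if s < 5e-3 * span:
            raise RuntimeError(f"component {i} collapsed (sigma = {s:.3g} K)")
        area = float(a * s * np.sqrt(2.0 * np.pi) / trace.rate_K_per_s)
        comps.append(GaussianComponent(center=float(c), sigma=s, area=area))
    comps.sort(key=lambda comp: comp.center)
    if n_components == len(FOUR_FORM_ORDER):
        comps = [replace(comp, label=lab) for comp, lab in zip(comps, FOUR_FORM_ORDER)]
    return comps
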