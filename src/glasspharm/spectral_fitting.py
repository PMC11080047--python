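"""Deconvolution of dielectric loss spectra into relaxation processes.

Each measured ε″(f) isotherm is fitted, in log10 ε″, with a composite of
HN/CC relaxation functions plus an optional DC-conductivity term.  The
fitted components feed the relaxation map (T, τ_max per process), the
temperature evolution of the dielectric strength Δε(T), its
normalisation Δε_N(T) = Δε(T)/Δε(T_ref) with T_ref = 312 K by default,
and the detection of recrystallization onsets as a drop of Δε_N below
its low-temperature plateau.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .dielectric_models import (
    EPS0,
    PROCESS_LABELS,
    ConductivityTerm,
    LossSpectrum,
    RelaxationProcess,
    composite_loss,
    tau_max,
)

__all__ = [
    "ProcessPlan",
    "FitPlan",
    "SpectrumFit",
    "DeltaEpsSeries",
    "fit_loss_spectrum",
    "extract_relaxation_points",
    "normalize_delta_eps",
    "detect_recrystallization_onset",
]

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-12
# process rank used to pair detected peaks (ascending frequency) with
# processes (slow to fast)
_RANK = {label: i for i, label in enumerate(PROCESS_LABELS)}

_PARAM_NAMES = ("delta_eps", "tau_hn", "a", "b")
_DEFAULT_BOUNDS = {
    "delta_eps": (1e-6, 1e6),
    "tau_hn": (1e-14, 1e8),
    "a": (0.05, 1.0),
    "b": (0.05, 1.0),
}


@dataclass
class ProcessPlan:
    """Configuration for one relaxation process in a fit.

    ``init`` and ``fix`` map parameter names (``delta_eps``, ``tau_hn``,
    ``a``, ``b``) to values; fixed parameters are excluded from the
    optimisation (used e.g. to pin the β-process shape above Tg to its
    glassy-state Arrhenius extrapolation, or to reuse the last
    pre-crystallization α shape for the residual α′ process).
    """

    label: str
    model: str = "HN"
    init: dict | None = None
    fix: dict | None = None
    bounds: dict | None = None


@dataclass
class FitPlan:
    """Which processes (and whether a conductivity term) to fit."""

    processes: list[ProcessPlan]
    fit_conductivity: bool = False
    s_exp: float = 1.0
    sigma_init: float | None = None


@dataclass
class SpectrumFit:
    """Result of deconvolving one loss spectrum."""

    temperature: float
    components: list[RelaxationProcess]
    conductivity: ConductivityTerm
    residual_rms: float
    converged: bool
    eps_inf: float | None = None
    sample_id: str = ""
    silica_wt_pct: float = 0.0

    def component(self, label: str) -> RelaxationProcess:
        for proc in self.components:
            if proc.label == label:
                return proc
        raise KeyError(label)


@dataclass
class DeltaEpsSeries:
    """Temperature evolution of the dielectric strength of one process."""

    label: str
    temperatures: np.ndarray
    delta_eps: np.ndarray
    T_ref: float = 312.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.delta_eps = np.asarray(self.delta_eps, dtype=float)
        if self.temperatures.shape != self.delta_eps.shape:
            raise ValueError("temperature and delta_eps lengths differ")
        order = np.argsort(self.temperatures)
        self.temperatures = self.temperatures[order]
        self.delta_eps = self.delta_eps[order]
        if np.any(self.delta_eps <= 0):
            raise ValueError("delta_eps values must be > 0")


def _smooth(y: np.ndarray, width: int = 5) -> np.ndarray:
    if y.size < width:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _initial_guesses(spectrum: LossSpectrum, plan: FitPlan) -> list[dict]:
    """Deterministic data-driven starts: peak positions of the smoothed
    log-spectrum assigned to the planned processes slow-to-fast."""
    mask = spectrum.loss > 0
    f = spectrum.frequencies[mask]
    logy = np.log10(spectrum.loss[mask])
    sm = _smooth(logy)
    peaks, _ = find_peaks(sm)
    peak_freqs = list(f[peaks])
    peak_heights = [10.0 ** sm[p] for p in peaks]
    if not peak_freqs:  # monotone spectrum: fall back to global max
        i = int(np.argmax(sm))
        peak_freqs, peak_heights = [f[i]], [10.0 ** sm[i]]

    plans = sorted(plan.processes, key=lambda p: _RANK[p.label])
    guesses: list[dict] = []
    for k, pp in enumerate(plans):
        if k < len(peak_freqs):
            f_pk, h_pk = peak_freqs[k], peak_heights[k]
        else:
            # no detected peak left: place 2 decades above the last one
            f_pk = peak_freqs[-1] * 100.0 ** (k - len(peak_freqs) + 1)
            h_pk = peak_heights[-1] * 0.3
        g = {
            "delta_eps": 2.0 * h_pk,
            "tau_hn": 1.0 / (2.0 * np.pi * f_pk),
            "a": 0.8,
            "b": 1.0 if pp.model == "CC" else 0.8,
        }
        if pp.init:
            g.update(pp.init)
        guesses.append(g)
    # restore the caller's process order (guesses are aligned with `plans`)
    return [guesses[plans.index(pp)] for pp in plan.processes]


def fit_loss_spectrum(spectrum: LossSpectrum, plan: FitPlan) -> SpectrumFit:
    """Least-squares deconvolution of one loss spectrum.

    The objective is uniform-weight least squares on log10 ε″ (points
    with ε″ ≤ 0 are masked as noise).  Δε, τ and σ_dc are optimised in
    log10; a and b linearly within (0, 1].  Non-convergence is flagged
    on the returned :class:`SpectrumFit`, never silent.
    """
    if not plan.processes and not plan.fit_conductivity:
        raise ValueError("fit plan must name at least one process")
    mask = spectrum.loss > 0
    f = spectrum.frequencies[mask]
    y = spectrum.loss[mask]
    if f.size < 8:
        raise ValueError(f"need >= 8 usable frequency points, got {f.size}")

    guesses = _initial_guesses(spectrum, plan)

    # --- assemble the free-parameter vector -------------------------------
    names: list[tuple[int, str]] = []      # (process index, parameter)
    x0: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    for i, (pp, g) in enumerate(zip(plan.processes, guesses)):
        fixed = pp.fix or {}
        for pname in _PARAM_NAMES:
            if pname in fixed:
                continue
            if pname == "b" and pp.model == "CC":
                continue
            b_lo, b_hi = (pp.bounds or {}).get(pname, _DEFAULT_BOUNDS[pname])
            val = np.clip(g[pname], b_lo, b_hi)
            if pname in ("delta_eps", "tau_hn"):
                x0.append(np.log10(val))
                lo.append(np.log10(b_lo))
                hi.append(np.log10(b_hi))
            else:
                x0.append(val)
                lo.append(b_lo)
                hi.append(b_hi)
            names.append((i, pname))
    if plan.fit_conductivity:
        sig0 = plan.sigma_init
        if sig0 is None:
            # a rising low-frequency edge pins sigma; otherwise start tiny
            w0 = 2.0 * np.pi * f[0]
            sig0 = max(y[0] * EPS0 * w0**plan.s_exp * 0.5, 1e-18)
        names.append((-1, "sigma_dc"))
        x0.append(np.log10(sig0))
        lo.append(-20.0)
        hi.append(2.0)

    n_free = len(x0)
    if f.size < n_free:
        raise ValueError(f"{f.size} points cannot constrain {n_free} parameters")

    def build(x: np.ndarray) -> tuple[list[RelaxationProcess], ConductivityTerm]:
        params = [dict(g) for g in guesses]
        sigma = 0.0
        for (i, pname), val in zip(names, x):
            if i < 0:
                sigma = 10.0**val
            elif pname in ("delta_eps", "tau_hn"):
                params[i][pname] = 10.0**val
            else:
                params[i][pname] = val
        for i, pp in enumerate(plan.processes):
            for pname, val in (pp.fix or {}).items():
                params[i][pname] = val
            if pp.model == "CC":
                params[i]["b"] = 1.0
        procs = [
            RelaxationProcess(pp.label, pp.model, p["delta_eps"], p["tau_hn"], p["a"], p["b"])
            for pp, p in zip(plan.processes, params)
        ]
        cond = ConductivityTerm(sigma_dc=sigma, s_exp=plan.s_exp)
        return procs, cond

    logy = np.log10(y)

    def resid(x: np.ndarray) -> np.ndarray:
        procs, cond = build(x)
        model = composite_loss(procs, cond, f)
        return np.log10(np.maximum(model, _LOG_FLOOR)) - logy

    result = least_squares(
        resid, np.asarray(x0), bounds=(np.asarray(lo), np.asarray(hi)),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
    )
    procs, cond = build(result.x)
    rms = float(np.sqrt(np.mean(result.fun**2)))
    converged = bool(result.success)
    if not converged:
        logger.warning(
            "fit at T=%.1f K did not converge (status %d)", spectrum.temperature, result.status
        )
    return SpectrumFit(
        temperature=spectrum.temperature,
        components=procs,
        conductivity=cond,
        residual_rms=rms,
        converged=converged,
        sample_id=spectrum.sample_id,
        silica_wt_pct=spectrum.silica_wt_pct,
    )


def extract_relaxation_points(fits: Sequence[SpectrumFit]) -> pd.DataFrame:
    """Per-process (T, τ_max, Δε) table from a sequence of spectrum fits.

    τ_max is the HN peak-time conversion applied to each fitted
    component.  Unconverged fits are excluded with a warning.  Columns:
    ``label, T_K, tau_s, delta_eps, a, b, residual_rms``; sorted by
    label then temperature.  α and α′ are kept distinct.
    """
    rows = []
    for fit in fits:
        if not fit.converged:
            warnings.warn(
                f"excluding unconverged fit at T={fit.temperature:.1f} K", stacklevel=2
            )
            continue
        for proc in fit.components:
            rows.append(
                {
                    "label": proc.label,
                    "T_K": fit.temperature,
                    "tau_s": tau_max(proc),
                    "delta_eps": proc.delta_eps,
                    "a": proc.a,
                    "b": proc.b,
                    "residual_rms": fit.residual_rms,
                }
            )
    df = pd.DataFrame(rows, columns=["label", "T_K", "tau_s", "delta_eps", "a", "b", "residual_rms"])
    return df.sort_values(["label", "T_K"], kind="stable").reset_index(drop=True)


def delta_eps_series(points: pd.DataFrame, label: str, T_ref: float = 312.0) -> DeltaEpsSeries:
    """Extract the Δε(T) series for one process from a relaxation-point table."""
    sub = points[points["label"] == label]
    if sub.empty:
        raise ValueError(f"no points for process {label!r}")
    return DeltaEpsSeries(label, sub["T_K"].to_numpy(), sub["delta_eps"].to_numpy(), T_ref=T_ref)


def normalize_delta_eps(series: DeltaEpsSeries, T_ref: float | None = None) -> DeltaEpsSeries:
    """Normalise Δε by its value at the reference temperature.

    Δε_N(T) = Δε(T) / Δε(T_ref); the reference value is interpolated
    linearly if T_ref is not a grid point.  Idempotent: normalising a
    normalised series changes nothing.
    """
    T_ref = series.T_ref if T_ref is None else T_ref
    T, v = series.temperatures, series.delta_eps
    if not (T[0] <= T_ref <= T[-1]):
        raise ValueError(f"T_ref={T_ref} K outside series range [{T[0]}, {T[-1]}] K")
    ref = float(np.interp(T_ref, T, v))
    return DeltaEpsSeries(series.label, T.copy(), v / ref, T_ref=T_ref, normalized=True)


def detect_recrystallization_onset(
    series: DeltaEpsSeries, drop_threshold: float = 0.05
) -> float | None:
    """Onset temperature of the drop in dielectric strength, or None.

    Recrystallization removes reorienting dipoles, so Δε (or Δε_N)
    falls sharply above an onset.  The low-temperature plateau is the
    median of the points before the drop; the onset is the first
    temperature where the series falls below (1 − drop_threshold) ×
    plateau (and stays below at the next point, to reject single noise
    dips), refined by linear interpolation.  Scale-invariant.
    """
    if not 0 < drop_threshold < 1:
        raise ValueError("drop_threshold must be in (0, 1)")
    T, v = series.temperatures, series.delta_eps
    if T.size < 5:
        raise ValueError("need at least 5 points for onset detection")

    def first_persistent_below(level: float) -> int | None:
        below = v < level
        for i in range(T.size):
            if below[i] and (i == T.size - 1 or below[i + 1]):
                return i
        return None

    plateau = float(np.median(v[: min(5, T.size)]))
    i = first_persistent_below((1.0 - drop_threshold) * plateau)
    if i is None:
        if np.std(v) / np.mean(v) > drop_threshold:
            warnings.warn("series is noisy but shows no persistent drop", stacklevel=2)
        return None
    if i == 0:
        warnings.warn("series starts below threshold; no plateau to reference", stacklevel=2)
        return None
    # re-reference the plateau to everything before the detected drop
    plateau = float(np.median(v[:i]))
    level = (1.0 - drop_threshold) * plateau
    j = first_persistent_below(level)
    if j is None or j == 0:
        return None
    # linear interpolation of the crossing
    t = (v[j - 1] - level) / (v[j - 1] - v[j])
    return float(T[j - 1] + t * (T[j] - T[j - 1]))
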