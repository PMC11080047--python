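"""Time–temperature superposition of structural-relaxation peaks.

If the shape of the α-peak is temperature-invariant, loss spectra taken
at different temperatures collapse onto the spectrum at a reference
temperature after purely horizontal shifts on the log-frequency axis.
The merged master curve is then described by the frequency-domain KWW
shape, whose stretching exponent β_KWW quantifies the peak breadth
(β = 1: narrow symmetric Debye peak; smaller β: broader, more
asymmetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .dielectric_models import KWWShape, LossSpectrum, kww_loss

__all__ = ["MasterCurve", "KWWFitResult", "build_masterplot", "fit_kww", "fit_kww_spectrum"]


@dataclass
class MasterCurve:
    """Superposed α-peak spectra, peak-normalised, on a reduced log-f axis."""

    T_ref: float
    shifts: dict[float, float]          # temperature -> log10 frequency shift
    log10_f_reduced: np.ndarray
    eps_norm: np.ndarray

    def span_decades(self) -> float:
        return float(self.log10_f_reduced[-1] - self.log10_f_reduced[0])


@dataclass
class KWWFitResult:
    beta_kww: float
    tau_reduced: float
    residual_rms: float
    converged: bool = True


def _parabolic_peak(logf: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """(log10 f_max, height) from a parabola through the 5 points around
    the discrete maximum; None if the maximum sits at the window edge."""
    i = int(np.argmax(y))
    if i < 2 or i > y.size - 3:
        return None
    sl = slice(i - 2, i + 3)
    c = np.polyfit(logf[sl], y[sl], 2)
    if c[0] >= 0:
        return float(logf[i]), float(y[i])
    x0 = -c[1] / (2.0 * c[0])
    return float(x0), float(np.polyval(c, x0))


def build_masterplot(spectra: Sequence[LossSpectrum], T_ref: float) -> MasterCurve:
    """Horizontal superposition of α-peaks onto the reference spectrum.

    Each spectrum's peak position is located by a parabolic fit through
    the 5 points around its discrete maximum (in log10 f); the spectrum
    is shifted so this maximum aligns with the reference peak and its
    amplitude normalised to unit peak height.  Only horizontal shifts
    are applied, so peak-normalised shapes are preserved.  Spectra whose
    maximum sits at the frequency-window edge are excluded with a
    warning.
    """
    ref = None
    for s in spectra:
        if np.isclose(s.temperature, T_ref):
            ref = s
            break
    if ref is None:
        raise ValueError(f"no spectrum at the reference temperature {T_ref} K")
    ref_peak = _parabolic_peak(np.log10(ref.frequencies), ref.loss)
    if ref_peak is None:
        raise ValueError("reference spectrum has its maximum at the window edge")
    ref_pos, _ = ref_peak

    shifts: dict[float, float] = {}
    chunks_x, chunks_y = [], []
    for s in spectra:
        logf = np.log10(s.frequencies)
        pk = _parabolic_peak(logf, s.loss)
        if pk is None:
            warnings.warn(
                f"spectrum at {s.temperature:.1f} K: peak at window edge, excluded",
                stacklevel=2,
            )
            continue
        pos, height = pk
        shift = ref_pos - pos
        shifts[float(s.temperature)] = float(shift)
        chunks_x.append(logf + shift)
        chunks_y.append(s.loss / height)
    x = np.concatenate(chunks_x)
    y = np.concatenate(chunks_y)
    order = np.argsort(x)
    return MasterCurve(T_ref=T_ref, shifts=shifts, log10_f_reduced=x[order], eps_norm=y[order])


def _kww_norm_on(
    logf: np.ndarray, beta: float, tau: float, pts_per_decade: int = 10
) -> np.ndarray:
    """Peak-normalised KWW loss evaluated at ``logf`` via a spline over a
    coarse quadrature grid (the shape is smooth in log f)."""
    f_pk_guess = 1.0 / (2.0 * np.pi * tau)
    lo = min(logf.min(), np.log10(f_pk_guess) - 1.5) - 0.3
    hi = max(logf.max(), np.log10(f_pk_guess) + 1.5) + 0.3
    n = max(int((hi - lo) * pts_per_decade) + 1, 25)
    grid = np.linspace(lo, hi, n)
    vals = kww_loss(KWWShape(beta, tau), 10.0**grid)
    spline = CubicSpline(grid, vals)
    # refine the peak of the spline for exact unit normalisation
    i = int(np.argmax(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n - 1)]
    xs = np.linspace(a, b, 201)
    peak = float(np.max(spline(xs)))
    return spline(logf) / peak


def fit_kww(
    curve: MasterCurve,
    *,
    downweight_decades: float = 2.0,
    downweight: float = 0.25,
) -> KWWFitResult:
    """Fit the peak-normalised KWW loss shape to a master curve.

    β and the reduced relaxation time are free.  Points more than
    ``downweight_decades`` above the peak get weight ``downweight``,
    since the high-frequency flank is typically contaminated by the
    faster secondary β-process.
    """
    x, y = curve.log10_f_reduced, curve.eps_norm
    if curve.span_decades() < 2.0:
        raise ValueError("master curve must span at least 2 decades")
    x_pk = x[int(np.argmax(y))]
    w = np.where(x > x_pk + downweight_decades, np.sqrt(downweight), 1.0)

    def resid(p: np.ndarray) -> np.ndarray:
        beta = p[0]
        tau = 10.0 ** p[1]
        return w * (_kww_norm_on(x, beta, tau) - y)

    p0 = np.array([0.6, np.log10(1.0 / (2.0 * np.pi * 10.0**x_pk))])
    result = least_squares(
        resid, p0, bounds=([0.1, p0[1] - 4.0], [1.0, p0[1] + 4.0]),
        xtol=1e-10, ftol=1e-10, max_nfev=200,
    )
    rms = float(np.sqrt(np.mean((result.fun / w) ** 2)))
    return KWWFitResult(
        beta_kww=float(result.x[0]),
        tau_reduced=float(10.0 ** result.x[1]),
        residual_rms=rms,
        converged=bool(result.success),
    )


def fit_kww_spectrum(spectrum: LossSpectrum, **kwargs) -> KWWFitResult:
    """KWW fit to a single spectrum (peak-normalised), for per-isotherm
    shape analysis without building a master curve."""
    logf = np.log10(spectrum.frequencies)
    pk = _parabolic_peak(logf, spectrum.loss)
    if pk is None:
        raise ValueError("spectrum peak at window edge")
    _, height = pk
    curve = MasterCurve(
        T_ref=spectrum.temperature,
        shifts={float(spectrum.temperature): 0.0},
        log10_f_reduced=logf,
        eps_norm=spectrum.loss / height,
    )
    return fit_kww(curve, **kwargs)
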