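"""Composition-series stability analyses for drug/silica composites.

ΔCp at the glass transition is extensive and additive: drug molecules
immobilised on the silica surface contribute nothing, so ΔCp per total
sample mass falls linearly with silica loading and extrapolates to zero
at the monomolecular loading capacity (MLC) — the composition where the
drug exactly covers the silica surface as an adsorbed monolayer.

The crystallization onset Tc(w) is V-shaped in silica loading: a small
amount of silica promotes nucleation (Tc falls), past a critical
concentration the stabilising effect wins (Tc rises).  The vertex is
located with a continuous two-segment piecewise-linear fit.

Melting deconvolution areas, normalised to the drug mass, give the
relative abundance of the polymorphic forms crystallising from the
composite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .dsc_analysis import DSCTrace, GaussianComponent, tangent_onset

__all__ = [
    "MLCFit",
    "CrystallizationTrend",
    "DEFAULT_FORM_WINDOWS",
    "fit_mlc",
    "fit_crystallization_trend",
    "normalize_to_drug",
    "polymorph_fractions",
    "assign_polymorphs",
]

#: Reference tangent-onset windows (K) for the known polymorphic forms;
#: components falling outside all windows are labelled "X".
DEFAULT_FORM_WINDOWS: dict[str, tuple[float, float]] = {
    "IV": (406.0, 409.0),
    "III": (410.0, 414.0),
    "II": (414.0, 417.0),
    "I": (420.0, 423.0),
}


@dataclass(frozen=True)
class MLCFit:
    """Linear ΔCp(w) fit and its zero-crossing (the MLC composition)."""

    slope: float       # J/(g K %)
    intercept: float   # J/(g K)
    w_mlc: float | None  # wt % silica at delta_cp = 0; None when flagged
    slope_se: float
    intercept_se: float
    w_mlc_se: float | None
    flagged: bool = False


@dataclass(frozen=True)
class CrystallizationTrend:
    """Two-segment continuous piecewise-linear fit of Tc versus loading."""

    w_critical: float
    slopes: tuple[float, float]
    Tc_at_break: float
    sse: float
    boundary_flag: bool = False


def fit_mlc(series: Sequence[tuple[float, float]] | np.ndarray) -> MLCFit:
    """Ordinary least-squares line through (silica wt %, ΔCp) points.

    w_mlc = −intercept/slope, with its standard error from first-order
    error propagation including the slope–intercept covariance.  A
    non-negative slope is physically meaningless here and returns a
    flagged result with ``w_mlc = None``.
    """
    pts = np.asarray(series, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 (wt %, delta_cp) points")
    w, dcp = pts[:, 0], pts[:, 1]
    (slope, intercept), cov = np.polyfit(w, dcp, 1, cov=True)
    se_s, se_i = np.sqrt(np.diag(cov))
    cov_si = cov[0, 1]
    if slope >= 0:
        return MLCFit(float(slope), float(intercept), None, float(se_s), float(se_i), None,
                      flagged=True)
    w_mlc = -intercept / slope
    # var(-i/s) = (se_i/s)^2 + (i se_s/s^2)^2 - 2 (i/s^3) cov_si
    var = (se_i / slope) ** 2 + (intercept * se_s / slope**2) ** 2 \
        - 2.0 * intercept * cov_si / slope**3
    w_se = float(np.sqrt(max(var, 0.0)))
    return MLCFit(float(slope), float(intercept), float(w_mlc), float(se_s), float(se_i), w_se)


def fit_crystallization_trend(
    series: Sequence[tuple[float, float]] | np.ndarray, grid_step: float = 0.1
) -> CrystallizationTrend:
    """Best continuous two-segment linear fit of Tc(w) over a breakpoint grid.

    The model is Tc(w) = c + m1·min(w − b, 0) + m2·max(w − b, 0); the
    breakpoint b is scanned over the interior data range at
    ``grid_step`` wt % resolution and the segment parameters solved
    linearly at each candidate.  Monotone data put the vertex at a data
    boundary and are flagged (``boundary_flag``) as showing no interior
    minimum.
    """
    pts = np.asarray(series, dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 (wt %, Tc) points")
    order = np.argsort(pts[:, 0])
    w, tc = pts[order, 0], pts[order, 1]

    best = None
    for b in np.arange(w[0], w[-1] + 0.5 * grid_step, grid_step):
        A = np.column_stack([np.ones_like(w), np.minimum(w - b, 0.0), np.maximum(w - b, 0.0)])
        coef, *_ = np.linalg.lstsq(A, tc, rcond=None)
        sse = float(np.sum((A @ coef - tc) ** 2))
        if best is None or sse < best[0]:
            best = (sse, float(b), coef)
    sse, b, (c, m1, m2) = best
    at_boundary = b <= w[0] + grid_step or b >= w[-1] - grid_step
    no_vertex = not (m1 < 0 < m2)
    return CrystallizationTrend(
        w_critical=b,
        slopes=(float(m1), float(m2)),
        Tc_at_break=float(c),
        sse=sse,
        boundary_flag=bool(at_boundary or no_vertex),
    )


def normalize_to_drug(trace: DSCTrace) -> DSCTrace:
    """Divide the heat flow by the drug mass fraction.

    Silica contributes no thermal events, so traces normalised this way
    are directly comparable per gram of drug.
    """
    if trace.normalized_to_drug:
        return trace
    return DSCTrace(
        temperatures=trace.temperatures.copy(),
        heat_flow=trace.heat_flow / trace.drug_mass_fraction,
        heating_rate=trace.heating_rate,
        sample_id=trace.sample_id,
        silica_wt_pct=trace.silica_wt_pct,
        drug_mass_fraction=trace.drug_mass_fraction,
        normalized_to_drug=True,
    )


def assign_polymorphs(
    components: Sequence[GaussianComponent],
    windows: Mapping[str, tuple[float, float]] = DEFAULT_FORM_WINDOWS,
    tolerance: float = 0.7,
) -> list[GaussianComponent]:
    """Label components by matching their tangent onsets to form windows.

    A component whose onset falls inside (or within ``tolerance`` K of)
    a reference window gets that form's label; among eligible windows
    the one with the nearest midpoint wins, so onsets on a shared
    boundary resolve to the closer form.  Anything else is the
    undefined polymorph "X".
    """
    out = []
    for comp in components:
        onset = tangent_onset(comp)
        best_label, best_key = "X", None
        for label, (lo, hi) in windows.items():
            dist = 0.0 if lo <= onset <= hi else min(abs(onset - lo), abs(onset - hi))
            if dist > tolerance:
                continue
            key = abs(onset - 0.5 * (lo + hi))
            if best_key is None or key < best_key:
                best_label, best_key = label, key
        out.append(replace(comp, label=best_label))
    return out


def polymorph_fractions(components: Sequence[GaussianComponent]) -> dict[str, float]:
    """Area fraction of each polymorph form among the melting components.

    Fractions are |area|-weighted and sum to exactly 1.
    """
    if not components:
        raise ValueError("need at least one melting component")
    areas = {}
    for comp in components:
        label = comp.label or "?"
        areas[label] = areas.get(label, 0.0) + abs(comp.area)
    total = sum(areas.values())
    if total == 0:
        raise ValueError("total melting area is zero")
    return {label: a / total for label, a in areas.items()}
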