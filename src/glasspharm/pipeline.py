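"""End-to-end orchestration of the dielectric and calorimetric analyses.

These functions tie the per-spectrum and per-trace operations into the
reproducible runs the command-line interface exposes: deconvolve a whole
temperature series of loss spectra, build the relaxation map with its
derived glass metrics, and assemble DSC event and stability reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import masterplot as mp
from .dielectric_models import LossSpectrum
from .dielectric_models import tau_max as tau_max_of
from .relaxation_map import (
    ArrheniusParams,
    arrhenius_tau,
    classify_secondary,
    fit_arrhenius,
    fit_vft,
    fragility,
    tg_from_tau,
)
from .spectral_fitting import (
    FitPlan,
    ProcessPlan,
    SpectrumFit,
    delta_eps_series,
    detect_recrystallization_onset,
    extract_relaxation_points,
    fit_loss_spectrum,
    normalize_delta_eps,
)

__all__ = ["BDSRunConfig", "fit_bds_series", "build_relaxation_report", "analyze_bds"]

logger = logging.getLogger(__name__)


@dataclass
class BDSRunConfig:
    """Knobs of a dielectric analysis run (defaults follow the study
    conventions: Δε and masterplot reference 312 K, Tg at τ = 100 s,
    t_c = 2 ps)."""

    tg_boundary: float = 309.0       # K: spectra above are "liquid", below "glassy"
    T_ref: float = 312.0             # masterplot / delta-eps normalisation reference
    tau_g: float = 100.0             # s, kinetic Tg convention
    t_c: float = 2e-12               # s, coupling-model crossover time
    drop_threshold: float = 0.05
    tolerance_decades: float = 1.0
    fit_conductivity: bool = True
    fix_beta_above_tg: bool = True


def _cluster_secondary_branches(T: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Assign glassy-state relaxation points to the β or γ Arrhenius branch.

    With a fixed frequency window, usually only one secondary peak is in
    view per isotherm: the faster γ at low temperature, the slower β
    once its peak enters the window at higher temperature.  Points are
    sorted by temperature and split at the index minimising the total
    two-line least-squares error of log10 τ versus 1/T; the branch with
    the steeper slope (higher activation energy) is β.  Returns an array
    of labels aligned with the inputs.
    """
    order = np.argsort(T)
    x = 1.0 / T[order]
    y = np.log10(tau[order])
    n = T.size
    labels = np.empty(n, dtype=object)
    if n < 6:
        slope = np.polyfit(x, y, 1)[0] if n >= 2 else 0.0
        Ea = slope * np.log(10.0) * 8.314 / 1e3
        labels[:] = "beta" if Ea >= 40.0 else "gamma"
        return labels
    best = None
    for k in range(3, n - 2):
        sse = 0.0
        for sl in (slice(0, k), slice(k, n)):
            c = np.polyfit(x[sl], y[sl], 1)
            sse += float(np.sum((np.polyval(c, x[sl]) - y[sl]) ** 2))
        if best is None or sse < best[0]:
            best = (sse, k)
    # compare against a single-line fit: if two lines barely help, keep one branch
    c1 = np.polyfit(x, y, 1)
    sse1 = float(np.sum((np.polyval(c1, x) - y) ** 2))
    k = best[1]
    if best[0] > 0.25 * sse1:
        Ea = c1[0] * np.log(10.0) * 8.314 / 1e3
        labels[:] = "beta" if Ea >= 40.0 else "gamma"
        return labels
    slope_lo = np.polyfit(x[:k], y[:k], 1)[0]
    slope_hi = np.polyfit(x[k:], y[k:], 1)[0]
    lab_sorted = np.empty(n, dtype=object)
    # segments are in ascending temperature; the branch with the steeper
    # Arrhenius slope (d log10 tau / d(1/T)) is beta
    if slope_hi >= slope_lo:
        lab_sorted[:k], lab_sorted[k:] = "gamma", "beta"
    else:
        lab_sorted[:k], lab_sorted[k:] = "beta", "gamma"
    labels[order] = lab_sorted
    return labels


def fit_bds_series(
    spectra: Sequence[LossSpectrum], config: BDSRunConfig | None = None
) -> list[SpectrumFit]:
    """Deconvolve a temperature series of loss spectra for one sample.

    Glassy isotherms are fitted with two CC processes; fitted components
    whose peak falls outside the frequency window (or whose strength is
    negligible) are discarded, and the surviving points are assigned to
    the β/γ Arrhenius branches by two-line clustering of log10 τ versus
    1/T.  Liquid isotherms get a free HN α-process plus a conductivity
    term, with the β (and γ) contributions pinned to their glassy-state
    Arrhenius extrapolations, only Δε free — the secondary processes are
    barely seen above Tg and would otherwise destabilise the α shape.
    An α component whose peak sits within half a decade of the window
    edge is dropped as unresolvable.
    """
    import dataclasses

    config = config or BDSRunConfig()
    glassy = [s for s in spectra if s.temperature <= config.tg_boundary]
    liquid = [s for s in spectra if s.temperature > config.tg_boundary]

    fits: list[SpectrumFit] = []
    kept: list[tuple[SpectrumFit, list]] = []
    for s in glassy:
        plan = FitPlan([ProcessPlan("beta", "CC"), ProcessPlan("gamma", "CC")])
        try:
            fit = fit_loss_spectrum(s, plan)
        except ValueError as exc:
            logger.info("glassy isotherm at %.0f K skipped: %s", s.temperature, exc)
            continue
        if not fit.converged:
            fits.append(fit)
            continue
        strongest = max(c.delta_eps for c in fit.components)
        f_lo, f_hi = s.frequencies[0], s.frequencies[-1]
        margin = 10.0**0.5
        comps = []
        for c in fit.components:
            f_peak = 1.0 / (2.0 * np.pi * tau_max_of(c))
            # a peak far outside the window (or a negligible strength) is
            # not constrained by the data; discard the component
            if f_lo / margin <= f_peak <= f_hi * margin and c.delta_eps >= 0.05 * strongest:
                comps.append(c)
        if len(comps) == 2 and max(comps[0].tau_hn, comps[1].tau_hn) / min(
            comps[0].tau_hn, comps[1].tau_hn
        ) < 100.0:
            comps = [max(comps, key=lambda c: c.delta_eps)]
        if comps:
            kept.append((fit, comps))
        else:
            logger.info(
                "glassy isotherm at %.0f K dropped (no resolvable peak in window)",
                s.temperature,
            )

    arrhenius: dict[str, ArrheniusParams] = {}
    shape_a: dict[str, float] = {}
    if kept:
        # isotherms where both secondary peaks survive fix the branch
        # identities by rank (beta is the slower process); isotherms with a
        # single surviving peak are assigned to the nearer Arrhenius line
        pair_pts: dict[str, list] = {"beta": [], "gamma": []}
        labelled: dict[int, list] = {}
        singles: list[tuple[SpectrumFit, object]] = []
        for fit, comps in kept:
            if len(comps) == 2:
                slow, fast = sorted(comps, key=lambda c: -c.tau_hn)
                labelled.setdefault(id(fit), []).extend(
                    [("beta", slow, fit), ("gamma", fast, fit)]
                )
                pair_pts["beta"].append((fit.temperature, tau_max_of(slow), slow))
                pair_pts["gamma"].append((fit.temperature, tau_max_of(fast), fast))
            else:
                singles.append((fit, comps[0]))

        lines: dict[str, np.ndarray] = {}
        for label in ("beta", "gamma"):
            if len(pair_pts[label]) >= 4:
                T = np.array([p[0] for p in pair_pts[label]])
                tau = np.array([p[1] for p in pair_pts[label]])
                lines[label] = np.polyfit(1.0 / T, np.log10(tau), 1)
        if lines:
            for fit, comp in singles:
                x = 1.0 / fit.temperature
                y = np.log10(tau_max_of(comp))
                label = min(
                    lines, key=lambda lab: abs(np.polyval(lines[lab], x) - y)
                )
                labelled.setdefault(id(fit), []).append((label, comp, fit))
                pair_pts[label].append((fit.temperature, tau_max_of(comp), comp))
        elif singles:
            # no isotherm shows both peaks: fall back to two-line clustering
            T_arr = np.array([fit.temperature for fit, _ in singles])
            tau_arr = np.array([tau_max_of(c) for _, c in singles])
            for (fit, comp), label in zip(
                singles, _cluster_secondary_branches(T_arr, tau_arr)
            ):
                labelled.setdefault(id(fit), []).append((str(label), comp, fit))
                pair_pts[str(label)].append((fit.temperature, tau_max_of(comp), comp))

        for fit, _ in kept:
            fit.components = [
                dataclasses.replace(comp, label=label)
                for label, comp, _ in labelled.get(id(fit), [])
            ]
            fits.append(fit)
        for label in ("beta", "gamma"):
            pts = pair_pts[label]
            if len(pts) >= 3:
                arr = np.array([(T, tau) for T, tau, _ in pts])
                try:
                    arrhenius[label] = fit_arrhenius(arr)
                except ValueError as exc:
                    logger.warning("%s-branch Arrhenius fit skipped: %s", label, exc)
                    continue
                shape_a[label] = float(np.mean([c.a for _, _, c in pts]))

    for s in sorted(liquid, key=lambda s: s.temperature):
        procs = [ProcessPlan("alpha", "HN")]
        if config.fix_beta_above_tg:
            for label in ("beta", "gamma"):
                if label in arrhenius:
                    procs.append(
                        ProcessPlan(
                            label, "CC",
                            fix={
                                "tau_hn": float(arrhenius_tau(arrhenius[label], s.temperature)),
                                "a": shape_a[label],
                            },
                        )
                    )
        plan = FitPlan(procs, fit_conductivity=config.fit_conductivity)
        fit = fit_loss_spectrum(s, plan)
        alpha = fit.component("alpha")
        f_peak = 1.0 / (2.0 * np.pi * tau_max_of(alpha))
        f_lo, f_hi = s.frequencies[0], s.frequencies[-1]
        if not (f_lo * 10**0.5 <= f_peak <= f_hi / 10**0.5):
            logger.info(
                "alpha peak at %.0f K too close to the window edge; component dropped",
                s.temperature,
            )
            fit.components = [c for c in fit.components if c.label != "alpha"]
        fits.append(fit)
    return fits


def build_relaxation_report(
    points: pd.DataFrame,
    beta_kww: float,
    config: BDSRunConfig | None = None,
) -> dict:
    """Relaxation map: VFT fit of α, Tg, fragility, Arrhenius fits of
    β/γ, and coupling-model classification of each secondary process."""
    config = config or BDSRunConfig()
    report: dict = {"beta_kww": beta_kww}

    alpha = points[points["label"] == "alpha"]
    if len(alpha) >= 3:
        vft = fit_vft(np.column_stack([alpha["T_K"], alpha["tau_s"]]))
        Tg = tg_from_tau(vft, config.tau_g)
        frag = fragility(vft, Tg)
        report["vft"] = {
            "log10_tau_inf": vft.log10_tau_inf, "T0": vft.T0, "D": vft.D,
            "stderr": vft.stderr,
        }
        report["Tg_K"] = Tg
        report["m_p"] = frag.m_p
        alpha_pts = np.column_stack([alpha["T_K"], alpha["tau_s"]])
    else:
        alpha_pts = None

    for label in ("beta", "gamma"):
        sub = points[points["label"] == label]
        if len(sub) < 3:
            continue
        try:
            arr = fit_arrhenius(np.column_stack([sub["T_K"], sub["tau_s"]]))
        except ValueError as exc:
            logger.warning("%s-process Arrhenius fit skipped: %s", label, exc)
            continue
        entry = {"log10_tau_inf": arr.log10_tau_inf, "Ea_kJ_per_mol": arr.Ea,
                 "stderr": arr.stderr}
        if alpha_pts is not None:
            coupling = classify_secondary(
                arr, alpha_pts, beta_kww,
                tolerance_decades=config.tolerance_decades, t_c=config.t_c,
            )
            entry["coupling_classification"] = coupling.classification
            entry["mean_offset_decades"] = coupling.mean_offset_decades
        report[label] = entry
    return report


def analyze_bds(
    spectra: Sequence[LossSpectrum],
    config: BDSRunConfig | None = None,
    fits: list[SpectrumFit] | None = None,
) -> dict:
    """Full dielectric pipeline for one sample: deconvolution,
    masterplot + KWW shape, relaxation map, Δε normalisation and
    recrystallization onset.  Precomputed ``fits`` (from
    :func:`fit_bds_series` on the same spectra) may be passed to avoid
    refitting."""
    config = config or BDSRunConfig()
    if fits is None:
        fits = fit_bds_series(spectra, config)
    points = extract_relaxation_points([f for f in fits if f.converged])

    liquid = sorted(
        (s for s in spectra if s.temperature > config.tg_boundary),
        key=lambda s: s.temperature,
    )
    beta_kww = np.nan
    try:
        curve = mp.build_masterplot(liquid, config.T_ref)
        kww = mp.fit_kww(curve)
        beta_kww = kww.beta_kww
    except ValueError as exc:
        logger.warning("masterplot skipped: %s", exc)

    report = build_relaxation_report(points, beta_kww, config)

    onset = None
    try:
        series = delta_eps_series(points, "alpha", T_ref=config.T_ref)
        if series.temperatures.size >= 5:
            norm = normalize_delta_eps(series)
            onset = detect_recrystallization_onset(norm, config.drop_threshold)
    except ValueError as exc:
        logger.warning("delta-eps analysis skipped: %s", exc)
    report["recrystallization_onset_K"] = onset
    report["n_spectra"] = len(spectra)
    report["n_converged"] = int(sum(f.converged for f in fits))
    return report
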