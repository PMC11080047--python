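"""Text-format readers and writers for spectra, traces and reports.

Formats
-------
Loss table (CSV, header required)
    ``sample_id, silica_wt_pct, temperature_K, frequency_Hz, eps_loss``;
    one row per (spectrum, frequency) point.

DSC table (CSV, header required)
    ``sample_id, silica_wt_pct, temperature_K, heat_flow_W_per_g`` with
    ``# key: value`` metadata lines before the header
    (``heating_rate_K_per_min``, ``exo_up``, ``drug_mass_fraction``).
    Heat flow is stored in the file's declared convention and
    normalised to exothermic-positive on read.

Temperatures are always kelvin; the composition coordinate is the
silica weight percent.  JSON reports keep full double precision; TSV
outputs are rounded to 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .dielectric_models import LossSpectrum
from .dsc_analysis import DSCTrace

__all__ = [
    "read_loss_table",
    "write_loss_table",
    "read_dsc_table",
    "write_dsc_table",
    "write_json_report",
    "write_tsv",
    "config_hash",
]

_LOSS_COLUMNS = ["sample_id", "silica_wt_pct", "temperature_K", "frequency_Hz", "eps_loss"]
_DSC_COLUMNS = ["sample_id", "silica_wt_pct", "temperature_K", "heat_flow_W_per_g"]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _read_csv_with_meta(path: str | Path, required: list[str]) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            stripped = line.strip()
            if stripped.startswith("#"):
                if ":" in stripped:
                    key, _, val = stripped.lstrip("# ").partition(":")
                    meta[key.strip()] = val.strip()
                header_line = i + 1
            elif stripped:
                break
            else:
                header_line = i + 1
    try:
        df = pd.read_csv(path, skiprows=header_line)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}, line {header_line + 1}: missing required column(s) {missing}"
        )
    for col in required:
        if col == "sample_id":
            continue
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}, line {header_line + 2 + row}: non-numeric value in column {col!r}"
            )
        df[col] = pd.to_numeric(df[col])
    return df, meta


def read_loss_table(path: str | Path) -> list[LossSpectrum]:
    """Read a loss table into one :class:`LossSpectrum` per isotherm."""
    df, _ = _read_csv_with_meta(path, _LOSS_COLUMNS)
    spectra = []
    for (sample, w, T), grp in df.groupby(
        ["sample_id", "silica_wt_pct", "temperature_K"], sort=True
    ):
        grp = grp.sort_values("frequency_Hz")
        spectra.append(
            LossSpectrum(
                temperature=float(T),
                frequencies=grp["frequency_Hz"].to_numpy(),
                loss=grp["eps_loss"].to_numpy(),
                sample_id=str(sample),
                silica_wt_pct=float(w),
            )
        )
    return spectra


def write_loss_table(spectra: Sequence[LossSpectrum], path: str | Path) -> None:
    rows = []
    for s in spectra:
        for f, y in zip(s.frequencies, s.loss):
            rows.append((s.sample_id, s.silica_wt_pct, s.temperature, f, y))
    pd.DataFrame(rows, columns=_LOSS_COLUMNS).to_csv(path, index=False)


def read_dsc_table(path: str | Path, exo_up: bool | None = None) -> list[DSCTrace]:
    """Read DSC traces; heat flow is flipped to exothermic-positive if the
    file metadata (or the ``exo_up`` override) declares endo-up data."""
    df, meta = _read_csv_with_meta(path, _DSC_COLUMNS)
    if exo_up is None:
        exo_up = meta.get("exo_up", "true").lower() in ("true", "1", "yes")
    rate = float(meta.get("heating_rate_K_per_min", 10.0))
    drug_frac = float(meta.get("drug_mass_fraction", 0.0)) or None
    sign = 1.0 if exo_up else -1.0
    traces = []
    for (sample, w), grp in df.groupby(["sample_id", "silica_wt_pct"], sort=True):
        grp = grp.sort_values("temperature_K")
        traces.append(
            DSCTrace(
                temperatures=grp["temperature_K"].to_numpy(),
                heat_flow=sign * grp["heat_flow_W_per_g"].to_numpy(),
                heating_rate=rate,
                sample_id=str(sample),
                silica_wt_pct=float(w),
                drug_mass_fraction=drug_frac if drug_frac else max(1.0 - float(w) / 100.0, 1e-6),
            )
        )
    return traces


def write_dsc_table(traces: Sequence[DSCTrace], path: str | Path) -> None:
    """Write traces exothermic-positive with metadata comment lines."""
    path = Path(path)
    first = traces[0]
    with open(path, "w") as fh:
        fh.write(f"# heating_rate_K_per_min: {first.heating_rate:g}\n")
        fh.write("# exo_up: true\n")
        fh.write(f"# drug_mass_fraction: {first.drug_mass_fraction:g}\n")
        fh.write(",".join(_DSC_COLUMNS) + "\n")
        for t in traces:
            for T, y in zip(t.temperatures, t.heat_flow):
                fh.write(f"{t.sample_id},{t.silica_wt_pct:g},{float(T)!r},{float(y)!r}\n")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    return obj


def write_json_report(obj: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """TSV output rounded to 6 significant digits."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: float(f"{v:.6g}") if np.isfinite(v) else v)
    out.to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for run logs."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
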