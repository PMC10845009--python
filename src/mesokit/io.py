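"""Reading and writing the plain-text formats used across the pipeline.

Patterns and spectra travel as two/three-column delimited text with
``#``-comment headers carrying the state point, e.g.::

    # temperature_C: 30
    # water_wt: 30
    0.300  1.234
    ...

A manifest is a CSV with columns ``file, temperature_C, water_wt``
listing the members of a temperature/composition series.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .dielectric import DielectricSpectrum, RelaxationMap
from .ftir import FTIRSpectrum
from .saxs import PhaseDiagram, SAXSPattern

__all__ = [
    "read_columns", "read_saxs_pattern", "read_dielectric_spectrum",
    "read_ftir_spectrum", "read_manifest", "load_series",
    "write_saxs_pattern", "write_dielectric_spectrum", "write_ftir_spectrum",
    "write_series", "phase_diagram_to_json", "relaxation_map_to_json",
]

_META_RE = re.compile(r"^#\s*(\w+)\s*[:=]\s*(.+?)\s*$")


def read_columns(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a delimited numeric table with ``#`` metadata comments.

    Accepts whitespace- or comma-delimited columns.  Returns the data as
    a 2-D array plus the parsed metadata dict (values cast to float where
    possible).
    """
    meta: dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        m = _META_RE.match(line)
        if m:
            key, val = m.group(1), m.group(2)
            try:
                meta[key] = float(val)
            except ValueError:
                meta[key] = val
            continue
        if line.startswith("#"):
            continue
        parts = re.split(r"[,\s]+", line)
        try:
            rows.append([float(p) for p in parts if p])
        except ValueError:
            continue  # non-numeric header line
    if not rows:
        raise ValueError(f"no numeric data found in {path}")
    return np.asarray(rows, dtype=float), meta


def _state_point(meta: dict, temperature, water_wt) -> tuple[float, float]:
    T = temperature if temperature is not None else meta.get("temperature_C", np.nan)
    wt = water_wt if water_wt is not None else meta.get("water_wt", np.nan)
    return float(T), float(wt)


def read_saxs_pattern(path: str | Path, temperature: float | None = None,
                      water_wt: float | None = None,
                      q_unit: str = "nm") -> SAXSPattern:
    """Two-column (q, intensity) text; ``q_unit='angstrom'`` multiplies q by 10."""
    data, meta = read_columns(path)
    q, i = data[:, 0], data[:, 1]
    if q_unit in ("angstrom", "A", "A^-1"):
        q = q * 10.0
    elif q_unit not in ("nm", "nm^-1"):
        raise ValueError(f"unknown q unit {q_unit!r}")
    T, wt = _state_point(meta, temperature, water_wt)
    return SAXSPattern(q, i, T, wt if np.isfinite(wt) else 0.0)


def read_dielectric_spectrum(path: str | Path, temperature: float | None = None,
                             water_wt: float | None = None) -> DielectricSpectrum:
    """Three-column (frequency_Hz, eps_real, eps_imag) text."""
    data, meta = read_columns(path)
    T, wt = _state_point(meta, temperature, water_wt)
    return DielectricSpectrum(data[:, 0], data[:, 1], data[:, 2], T, wt)


def read_ftir_spectrum(path: str | Path, temperature: float | None = None,
                       water_wt: float | None = None) -> FTIRSpectrum:
    """Two-column (wavenumber_cm-1, absorbance) text."""
    data, meta = read_columns(path)
    T, wt = _state_point(meta, temperature, water_wt)
    return FTIRSpectrum(data[:, 0], data[:, 1], T, wt)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV: columns file, temperature_C, water_wt."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    missing = {"file", "temperature_C", "water_wt"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


_READERS = {"saxs": read_saxs_pattern, "bds": read_dielectric_spectrum,
            "ftir": read_ftir_spectrum}


def load_series(manifest_path: str | Path, kind: str) -> list:
    """Load every member of a manifest with the reader for ``kind``."""
    reader = _READERS[kind]
    mdir = Path(manifest_path).parent
    df = read_manifest(manifest_path)
    out = []
    for _, row in df.iterrows():
        p = Path(row["file"])
        if not p.is_absolute():
            p = mdir / p
        out.append(reader(p, temperature=float(row["temperature_C"]),
                          water_wt=float(row["water_wt"])))
    return out


# ---------------------------------------------------------------------------
# writers


def _write_table(path: Path, header: dict, cols: list[np.ndarray],
                 fmt: str = "%.8g") -> None:
    lines = [f"# {k}: {v}" for k, v in header.items()]
    data = np.column_stack(cols)
    lines += ["  ".join(fmt % v for v in row) for row in data]
    path.write_text("\n".join(lines) + "\n")


def write_saxs_pattern(path: str | Path, pattern: SAXSPattern) -> None:
    _write_table(Path(path),
                 {"temperature_C": pattern.temperature, "water_wt": pattern.water_wt,
                  "columns": "q_nm-1 intensity"},
                 [pattern.q, pattern.intensity])


def write_dielectric_spectrum(path: str | Path, spectrum: DielectricSpectrum) -> None:
    _write_table(Path(path),
                 {"temperature_C": spectrum.temperature, "water_wt": spectrum.water_wt,
                  "columns": "frequency_Hz eps_real eps_imag"},
                 [spectrum.frequency, spectrum.eps_real, spectrum.eps_imag])


def write_ftir_spectrum(path: str | Path, spectrum: FTIRSpectrum) -> None:
    _write_table(Path(path),
                 {"temperature_C": spectrum.temperature, "water_wt": spectrum.water_wt,
                  "columns": "wavenumber_cm-1 absorbance"},
                 [spectrum.wavenumber, spectrum.absorbance])


_WRITERS = {"saxs": write_saxs_pattern, "bds": write_dielectric_spectrum,
            "ftir": write_ftir_spectrum}


def write_series(outdir: str | Path, kind: str, series: list,
                 prefix: str | None = None) -> Path:
    """Write a series plus its manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or kind
    writer = _WRITERS[kind]
    rows = []
    for item in series:
        name = f"{prefix}_T{item.temperature:g}C.dat"
        writer(outdir / name, item)
        rows.append({"file": name, "temperature_C": item.temperature,
                     "water_wt": item.water_wt})
    manifest = outdir / f"{prefix}_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def phase_diagram_to_json(diagram: PhaseDiagram) -> str:
    payload = {
        "grid": json.loads(diagram.to_frame().to_json(orient="records")),
        "excess_boundary": {str(k): v for k, v in diagram.excess_boundary.items()},
    }
    return json.dumps(payload, indent=2)


def relaxation_map_to_json(rmap: RelaxationMap) -> str:
    payload = {
        "processes": {str(k): v for k, v in rmap.processes.items()},
        "kink_temperature": rmap.kink_temperature,
        "flags": rmap.flags,
    }
    return json.dumps(payload, indent=2)
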