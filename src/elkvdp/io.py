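"""Delimited-text file formats for traces, titrations and spectra.

One canonical dialect is used everywhere: UTF-8, tab-separated columns,
'#'-prefixed comment/metadata header.  Trace metadata round-trips through a
single JSON header line so write -> read is the identity to full float
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .gating import CurrentTrace
from .tmfret import EmissionSpectrum, QuenchingMeasurement, QuenchingTitration

__all__ = [
    "write_trace",
    "read_trace",
    "write_titrations",
    "read_titrations",
    "read_spectrum",
]

_TRACE_MAGIC = "# elkvdp-trace v1"


def write_trace(trace: CurrentTrace, path, include_occupancy=None) -> None:
    """Write a current trace as tab-separated text with a JSON metadata header."""
    path = Path(path)
    cols = {"time_s": trace.time, "voltage_mV": trace.voltage, "current": trace.current}
    if include_occupancy is not None:
        occ, names = include_occupancy
        for j, name in enumerate(names):
            cols[f"p_{name}"] = occ[:, j]
    with path.open("w") as fh:
        fh.write(_TRACE_MAGIC + "\n")
        fh.write("# " + json.dumps(trace.meta, sort_keys=True, default=float) + "\n")
        fh.write("\t".join(cols) + "\n")
        arr = np.column_stack(list(cols.values()))
        for row in arr:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def read_trace(path) -> CurrentTrace:
    """Read a trace file written by :func:`write_trace` (errors name the line)."""
    path = Path(path)
    meta: dict = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("{"):
                    try:
                        meta = json.loads(body)
                    except json.JSONDecodeError as exc:
                        raise ParseError(f"bad metadata JSON: {exc}", lineno) from exc
                continue
            if header is None:
                header = line.split("\t")
                if "time_s" not in header:
                    raise ParseError("missing time_s column in header", lineno)
                if "current" not in header:
                    raise ParseError("missing current column in header", lineno)
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, found {len(parts)}", lineno
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"non-numeric value: {exc}", lineno) from exc
    if header is None or not rows:
        raise ParseError("file contains no data rows (empty trace)")
    arr = np.asarray(rows)
    t = arr[:, header.index("time_s")]
    if np.any(np.diff(t) <= 0):
        raise ParseError("time column is not strictly increasing")
    i = arr[:, header.index("current")]
    v = (
        arr[:, header.index("voltage_mV")]
        if "voltage_mV" in header
        else np.full_like(t, np.nan)
    )
    return CurrentTrace(time=t, current=i, voltage=v, meta=meta)


def write_titrations(titrations: list[QuenchingTitration], path) -> None:
    """Write quenching titrations as a long-format TSV."""
    recs = [
        {
            "condition": t.label,
            "conc_uM": m.conc_uM,
            "fl_metal": m.fl_metal,
            "fl_no_metal": m.fl_no_metal,
        }
        for t in titrations
        for m in t.measurements
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def read_titrations(path) -> dict[str, QuenchingTitration]:
    """Read a titration TSV into one titration per condition label."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read titration table: {exc}") from exc
    required = {"condition", "conc_uM", "fl_metal", "fl_no_metal"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"titration table missing columns: {sorted(missing)}")
    out = {}
    for label, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("conc_uM")
        ms = [
            QuenchingMeasurement(r.conc_uM, r.fl_metal, r.fl_no_metal)
            for r in grp.itertuples()
        ]
        out[str(label)] = QuenchingTitration(str(label), ms)
    return out


def read_spectrum(path, background_region=None) -> EmissionSpectrum:
    """Read a two-column (wavelength_nm, intensity) TSV spectrum."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"cannot read spectrum: {exc}") from exc
    if not {"wavelength_nm", "intensity"} <= set(df.columns):
        raise ParseError("spectrum needs wavelength_nm and intensity columns")
    return EmissionSpectrum(
        df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy(),
        background_region=background_region,
    )
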