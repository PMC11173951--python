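"""Delimited-text readers/writers for curves, spectra and system configs.

Formats are deliberately minimal and locale-fixed: comma-separated, dot
decimal, UTF-8, one header line.  Titration curves use the header
``volume_mL,pH`` or ``volume_mL,emf_mV``; spectrophotometric series use
``pH,absorbance`` with an optional third ``dilution_factor`` column.
Numbers are written with 12 significant digits so a write→read round trip
is lossless at that precision.  Malformed rows are reported with their
1-based line number.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .equilibria import AcidSystem, TitrationCurve
from .synthetic_data import SpectroSeries

__all__ = [
    "read_curve",
    "write_curve",
    "read_spectro",
    "write_spectro",
    "read_system_config",
    "write_system_config",
    "FormatError",
]

_CURVE_HEADERS = {"volume_mL,pH": "pH", "volume_mL,emf_mV": "emf"}
_FLOAT = "%.12g"


class FormatError(ValueError):
    """A file does not conform to the expected delimited format."""


def _parse_cell(cell: str, lineno: int, path) -> float:
    cell = cell.strip()
    if re.fullmatch(r"-?\d+,\d+", cell):
        raise FormatError(
            f"{path}:{lineno}: comma decimal {cell!r} — use dot-decimal notation"
        )
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric cell {cell!r}") from None


def _read_rows(path, expected_headers) -> tuple[str, list]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}:1: empty file, expected a header line")
    header = lines[0].strip()
    if header not in expected_headers:
        raise FormatError(
            f"{path}:1: unrecognized header {header!r}; "
            f"expected one of {sorted(expected_headers)}"
        )
    n_cols = len(header.split(","))
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        if len(cells) != n_cols:
            # a comma-decimal row doubles the cell count; give the clearer hint
            if len(cells) > n_cols and re.search(r"\d,\d", line):
                raise FormatError(
                    f"{path}:{lineno}: too many cells — looks like comma "
                    "decimals; use dot-decimal notation"
                )
            raise FormatError(
                f"{path}:{lineno}: expected {n_cols} cells, got {len(cells)}"
            )
        rows.append((lineno, [_parse_cell(c, lineno, path) for c in cells]))
    if not rows:
        raise FormatError(f"{path}:2: no data rows after the header")
    return header, rows


def read_curve(path) -> TitrationCurve:
    """Read a titration curve; header decides pH vs EMF readings."""
    header, rows = _read_rows(path, _CURVE_HEADERS)
    vols = np.array([r[1][0] for r in rows])
    readings = np.array([r[1][1] for r in rows])
    bad = np.flatnonzero(np.diff(vols) <= 0)
    if bad.size:
        lineno = rows[bad[0] + 1][0]
        raise FormatError(f"{path}:{lineno}: volumes must be strictly increasing")
    return TitrationCurve(vols, readings, reading_kind=_CURVE_HEADERS[header])


def write_curve(curve: TitrationCurve, path) -> None:
    header = "volume_mL,pH" if curve.reading_kind == "pH" else "volume_mL,emf_mV"
    lines = [header] + [
        f"{_FLOAT % v},{_FLOAT % r}" for v, r in zip(curve.volumes, curve.readings)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_SPECTRO_HEADERS = {"pH,absorbance": 2, "pH,absorbance,dilution_factor": 3}


def read_spectro(path, **beer_lambert) -> SpectroSeries:
    """Read an absorbance-vs-pH series.

    Optical parameters (eps_acid, eps_base, c_total, pathlength) are not in
    the file; pass them as keyword arguments if downstream code needs them.
    """
    header, rows = _read_rows(path, _SPECTRO_HEADERS)
    ph = np.array([r[1][0] for r in rows])
    a = np.array([r[1][1] for r in rows])
    dil = None
    if _SPECTRO_HEADERS[header] == 3:
        dil = np.array([r[1][2] for r in rows])
    return SpectroSeries(ph_values=ph, absorbance=a, dilution_factors=dil,
                         **beer_lambert)


def write_spectro(series: SpectroSeries, path) -> None:
    if series.dilution_factors is not None:
        lines = ["pH,absorbance,dilution_factor"] + [
            f"{_FLOAT % p},{_FLOAT % a},{_FLOAT % d}"
            for p, a, d in zip(series.ph_values, series.absorbance,
                               series.dilution_factors)
        ]
    else:
        lines = ["pH,absorbance"] + [
            f"{_FLOAT % p},{_FLOAT % a}"
            for p, a in zip(series.ph_values, series.absorbance)
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_SYSTEM_FIELDS = {
    "pka": float, "c_acid": float, "v0": float, "c_base": float,
    "pkw": float, "ionic_background": float, "temperature": float,
    "acid_kind": str,
}


def read_system_config(path) -> AcidSystem:
    """Read an AcidSystem from a flat ``key = value`` text file."""
    values = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in _SYSTEM_FIELDS:
            raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
        conv = _SYSTEM_FIELDS[key]
        try:
            values[key] = conv(raw.strip())
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: bad value {raw.strip()!r} for {key}"
            ) from None
    missing = {"pka", "c_acid", "v0", "c_base"} - values.keys()
    if missing:
        raise FormatError(f"{path}: missing required keys {sorted(missing)}")
    return AcidSystem(**values)


def write_system_config(system: AcidSystem, path) -> None:
    lines = [
        f"{key} = {getattr(system, key)}" for key in _SYSTEM_FIELDS
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
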