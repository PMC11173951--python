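"""Packaged reference tables of literature and measured pKa values.

Three tables ship with the package as delimited text:

``table1``
    Literature aqueous pKa values of monosubstituted benzoic and
    phenylboronic acids, one row per reported value (a cell with several
    reported values becomes several rows), with the bibliographic source
    number and an ``approximate`` flag for "ca." entries.  The companion
    ``table1_sigma`` table holds the Hammett σ constants printed with it.
``table2``
    pKa of fluoro-substituted phenylboronic acids in water (by
    spectrophotometric and potentiometric titration, 25 °C) and in
    water/dioxane 1:1 at 70 °C; missing determinations are empty cells.
``table3``
    New measurements for F/Cl/Br/I/CN-substituted phenylboronic acids by
    the three methods (S, P1, P2) with their stated uncertainties and the
    Hammett σ of the meta/para entries.

Values are stored exactly as printed, with one transcription note: the
I/meta P2 uncertainty appears in the source as "003" and is stored as
0.03 (see the table's ``notes``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .hammett import HammettRecord, LiteratureEntry

__all__ = [
    "FixtureTable",
    "load_fixture",
    "literature_entries",
    "table1_hammett_records",
    "table3_hammett_records",
    "table3_method_pairs",
    "table2_method_pairs",
]

_NOTES = {
    "table3": (
        "uncertainty of (I, meta, P2) printed as '003'; stored as 0.03 "
        "(obvious typo)",
    ),
}


@dataclass
class FixtureTable:
    """A packaged reference table and its transcription notes."""

    name: str
    data: pd.DataFrame
    notes: tuple = field(default_factory=tuple)


def _read(name: str) -> pd.DataFrame:
    with resources.files("boronpka.data").joinpath(f"{name}.csv").open("r") as fh:
        return pd.read_csv(fh)


def load_fixture(name: str) -> FixtureTable:
    """Load one of the packaged tables: table1, table1_sigma, table2, table3."""
    known = ("table1", "table1_sigma", "table2", "table3")
    if name not in known:
        raise KeyError(f"unknown fixture {name!r}; known: {known}")
    return FixtureTable(name=name, data=_read(name), notes=_NOTES.get(name, ()))


def literature_entries(
    family: str = "boronic",
    sources: set[str] | None = None,
) -> list[LiteratureEntry]:
    """Literature table rows as LiteratureEntry objects, one per (cell, source).

    ``sources`` restricts to values from the given bibliography numbers
    (as strings), e.g. {"52"}.
    """
    df = load_fixture("table1").data
    df = df[df["family"] == family]
    if sources is not None:
        df = df[df["source"].astype(str).isin({str(s) for s in sources})]
    out = []
    grouped = df.groupby(
        ["substituent", "position", "source", "approximate"], sort=False
    )
    for (sub, pos, src, approx), g in grouped:
        out.append(
            LiteratureEntry(
                substituent=sub,
                position=pos,
                acid_family=family,
                pka_values=tuple(g["pka"].astype(float)),
                approximate=bool(approx),
                source=str(src),
            )
        )
    return out


def _sigma_map() -> dict:
    s = load_fixture("table1_sigma").data
    return {(r.substituent, r.position): float(r.sigma) for r in s.itertuples()}


def table1_hammett_records(family: str = "boronic") -> list[HammettRecord]:
    """Meta/para Hammett records from aggregated literature means.

    Aggregates the literature values to unweighted means per substituent and
    position (excluding approximate entries) and attaches the tabulated σ.
    """
    from .hammett import aggregate_literature

    agg = aggregate_literature(literature_entries(family))
    sig = _sigma_map()
    records = []
    for row in agg.itertuples():
        key = (row.substituent, row.position)
        if row.position not in ("meta", "para") or key not in sig:
            continue
        records.append(
            HammettRecord(
                substituent=row.substituent,
                position=row.position,
                sigma=sig[key],
                pka=float(row.mean_pka),
                source="table1-mean",
            )
        )
    return records


def table3_hammett_records() -> list[HammettRecord]:
    """Meta/para records from the measured table: pKa = mean(S, P1)."""
    df = load_fixture("table3").data
    records = []
    for row in df.itertuples():
        if row.position not in ("meta", "para"):
            continue
        records.append(
            HammettRecord(
                substituent=row.substituent,
                position=row.position,
                sigma=float(row.sigma),
                pka=float((row.pka_s + row.pka_p1) / 2.0),
                source="table3-mean(S,P1)",
            )
        )
    return records


def table3_method_pairs(
    method_a: str = "pka_s",
    method_b: str = "pka_p1",
    substituents: set[str] | None = None,
    exclude: set[tuple] | None = None,
) -> list[tuple]:
    """(label, a, b) pairs from the measured table for compare_methods.

    ``exclude`` removes specific (substituent, position) rows, e.g.
    {("I", "ortho")} for the sterically anomalous ortho-iodo compound.
    """
    df = load_fixture("table3").data
    pairs = []
    for row in df.itertuples():
        if substituents is not None and row.substituent not in substituents:
            continue
        if exclude and (row.substituent, row.position) in exclude:
            continue
        a = getattr(row, method_a)
        b = getattr(row, method_b)
        label = f"{row.position}-{row.substituent}"
        pairs.append((label, None if pd.isna(a) else float(a),
                      None if pd.isna(b) else float(b)))
    return pairs


def table2_method_pairs(
    col_a: str = "pka_water_spectro", col_b: str = "pka_water_pot"
) -> list[tuple]:
    """(substituent, a, b) pairs from the fluoro-series solvent table."""
    df = load_fixture("table2").data
    return [
        (
            row.substituent,
            None if pd.isna(getattr(row, col_a)) else float(getattr(row, col_a)),
            None if pd.isna(getattr(row, col_b)) else float(getattr(row, col_b)),
        )
        for row in df.itertuples()
    ]
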