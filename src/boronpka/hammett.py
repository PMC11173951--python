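"""Hammett linear free-energy analysis of substituted aryl acids.

The Hammett equation log(K_X/K_0) = ρσ relates a substituent's electronic
constant σ (meta/para only — ortho substituents add steric and H-bonding
effects the basic equation does not describe) to the shift it causes in an
acid's dissociation constant.  On the pKa scale it reads

    pK_X = pK_0 - ρ σ_X

and we store ρ as the positive reaction constant (σ > 0, electron
withdrawal, strengthens the acid and lowers pKa).  For benzoic acid in
water at 25 °C ρ = 1.00 by definition of the σ scale; phenylboronic acids
respond to substitution roughly twice as strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HammettRecord",
    "HammettFit",
    "LiteratureEntry",
    "aggregate_literature",
    "fit_hammett",
    "predict_pka",
    "correlate",
    "LITERATURE_WATER_FIT",
    "HALOGEN_CN_FIT",
]

POSITIONS = ("ortho", "meta", "para", "parent")


@dataclass(frozen=True)
class HammettRecord:
    """One (substituent, σ, pKa) point for a Hammett regression."""

    substituent: str
    position: str
    sigma: float | None
    pka: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.position == "ortho" and self.sigma is not None:
            raise ValueError("sigma is undefined for ortho substituents")


@dataclass(frozen=True)
class HammettFit:
    """A fitted (or frozen) Hammett line pK_X = pk0 - rho*sigma."""

    rho: float
    pk0: float
    r_squared: float = float("nan")
    n: int = 0
    residuals: tuple = ()
    fixed_intercept: bool = False
    label: str = ""


@dataclass(frozen=True)
class LiteratureEntry:
    """A literature pKa cell: possibly several reported values, one source."""

    substituent: str
    position: str
    acid_family: str  # 'boronic' | 'benzoic'
    pka_values: tuple
    approximate: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pka_values:
            raise ValueError("pka_values must be non-empty")
        if self.position not in POSITIONS:
            raise ValueError(f"unknown position {self.position!r}")
        if self.acid_family not in ("boronic", "benzoic"):
            raise ValueError(f"unknown acid_family {self.acid_family!r}")


#: Frozen published lines.  LITERATURE_WATER_FIT aggregates the collected
#: aqueous literature values for meta/para phenylboronic acids;
#: HALOGEN_CN_FIT is the line measured on the halogen/CN series (mean of
#: the spectrophotometric and full-model potentiometric determinations).
LITERATURE_WATER_FIT = HammettFit(rho=2.06, pk0=8.76, label="literature-water")
HALOGEN_CN_FIT = HammettFit(rho=2.52, pk0=8.92, label="halogen-cn-measured")


def aggregate_literature(
    entries: Iterable[LiteratureEntry],
    include_approximate: bool = False,
) -> pd.DataFrame:
    """Unweighted mean pKa per (substituent, position, acid_family).

    Entries flagged approximate ("ca." values) are excluded unless
    ``include_approximate``.  Returns a DataFrame with columns
    substituent, position, acid_family, mean_pka, n_values.
    """
    rows = []
    for e in entries:
        if e.approximate and not include_approximate:
            continue
        for v in e.pka_values:
            rows.append((e.substituent, e.position, e.acid_family, float(v)))
    if not rows:
        return pd.DataFrame(
            columns=["substituent", "position", "acid_family", "mean_pka", "n_values"]
        )
    df = pd.DataFrame(rows, columns=["substituent", "position", "acid_family", "pka"])
    out = (
        df.groupby(["substituent", "position", "acid_family"], sort=False)["pka"]
        .agg(mean_pka="mean", n_values="size")
        .reset_index()
    )
    out["n_values"] = out["n_values"].astype(int)
    return out


def fit_hammett(
    records: Sequence[HammettRecord],
    fixed_pk0: float | None = None,
) -> HammettFit:
    """Fit pK_X = pk0 - rho*sigma over meta/para records.

    Default: ordinary least squares of pKa on σ (free intercept); rho is
    the negated slope.  With ``fixed_pk0`` the intercept is pinned and
    (pk0 - pKa) is regressed on σ through the origin, the form closest to
    the equation's log(K_X/K_0) = ρσ statement when pK_0 is known.

    Requires at least 4 records; any ortho record is an error (σ does not
    describe ortho effects) as is a missing σ.
    """
    records = list(records)
    for r in records:
        if r.position == "ortho":
            raise ValueError(f"ortho record {r.substituent!r} not allowed in a Hammett fit")
        if r.sigma is None:
            raise ValueError(f"record {r.substituent!r} has no sigma")
    if len(records) < 4:
        raise ValueError("need at least 4 well-spaced (sigma, pKa) records")
    sigma = np.array([r.sigma for r in records])
    pka = np.array([r.pka for r in records])

    if fixed_pk0 is None:
        res = stats.linregress(sigma, pka)
        rho = -float(res.slope)
        pk0 = float(res.intercept)
        fixed = False
    else:
        pk0 = float(fixed_pk0)
        rho = float(np.sum(sigma * (pk0 - pka)) / np.sum(sigma**2))
        fixed = True
    fitted = pk0 - rho * sigma
    resid = pka - fitted
    sst = float(np.sum((pka - pka.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return HammettFit(
        rho=rho,
        pk0=pk0,
        r_squared=r2,
        n=len(records),
        residuals=tuple(resid),
        fixed_intercept=fixed,
    )


def predict_pka(fit: HammettFit, sigma: float) -> float:
    """Predicted pKa of the substituted acid: pk0 - rho*sigma."""
    return fit.pk0 - fit.rho * sigma


def correlate(
    x: Sequence[tuple], y: Sequence[tuple]
) -> tuple[float, float, float, int]:
    """OLS of y-pKa on x-pKa over the label intersection.

    ``x`` and ``y`` are sequences of (label, pka).  Returns
    (slope, intercept, r_squared, n); needs at least 3 matched labels.
    """
    xd = {label: float(v) for label, v in x}
    yd = {label: float(v) for label, v in y}
    labels = [l for l in xd if l in yd]
    if len(labels) < 3:
        raise ValueError(f"need >= 3 matched labels, found {len(labels)}")
    xa = np.array([xd[l] for l in labels])
    ya = np.array([yd[l] for l in labels])
    res = stats.linregress(xa, ya)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), len(labels)
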