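"""Forward model of a strong-base titration of a monoprotic acid.

Phenylboronic acids ionize as Lewis acids — they bind hydroxide to give the
tetrahedral boronate anion RB(OH)3- rather than losing a proton — but the
resulting equilibrium

    RB(OH)2 + 2 H2O  <=>  RB(OH)3- + H3O+,   Ka = [RB(OH)3-][H3O+]/[RB(OH)2]

has exactly the algebraic form of a monoprotic Bronsted acid, so one model
serves boronic and carboxylic acids alike.  All constants here are
concentration constants: at a fixed ionic background (0.1 M KCl swamps the
reacting species) activity coefficients are constant and can be folded into
the constants.  An optional Davies activity correction is provided for users
who want conditional constants computed from a thermodynamic Ka/Kw instead.

The speciation solver finds [H3O+] from the charge balance

    [Na+] + [K+] + [H+] = [A-] + [Cl-] + [OH-]

where Na+ comes from the titrant, K+/Cl- from the inert background (they
cancel but are carried for the ionic-strength bookkeeping), [A-] follows from
Ka and the diluted analytical concentration, and [OH-] = Kw/[H+].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AcidSystem",
    "ActivityModel",
    "TitrationCurve",
    "ionized_fraction",
    "davies_log_gamma",
    "solve_proton_concentration",
    "ph_at_volume",
    "titration_curve",
    "equivalence_volume",
]

#: Water autoionization exponent on the concentration scale at 25 °C.
DEFAULT_PKW = 13.997


@dataclass(frozen=True)
class AcidSystem:
    """A monoprotic acid + strong-base titration system.

    Parameters
    ----------
    pka : float
        -log10 of the (concentration-based) acid dissociation constant.
    c_acid : float
        Analytical acid concentration in the initial analyte, mol/L.
    v0 : float
        Initial analyte volume, mL.
    c_base : float
        Titrant (NaOH) concentration, mol/L.
    pkw : float
        -log10 of the water ion product, concentration scale.
    ionic_background : float
        Inert 1:1 electrolyte (KCl) concentration, mol/L.
    temperature : float
        Celsius; metadata only, no constant is temperature-corrected.
    acid_kind : str
        'lewis' (boronic) or 'bronsted' (carboxylic); metadata only — the
        mathematical form is identical.
    """

    pka: float
    c_acid: float
    v0: float
    c_base: float
    pkw: float = DEFAULT_PKW
    ionic_background: float = 0.1
    temperature: float = 25.0
    acid_kind: str = "lewis"

    def __post_init__(self) -> None:
        if self.c_acid < 0:
            raise ValueError(f"c_acid must be >= 0, got {self.c_acid}")
        if self.c_base <= 0:
            raise ValueError(f"c_base must be > 0, got {self.c_base}")
        if self.v0 <= 0:
            raise ValueError(f"v0 must be > 0, got {self.v0}")
        if self.ionic_background < 0:
            raise ValueError("ionic_background must be >= 0")
        if self.c_acid > 0 and not (0.0 < self.pka < self.pkw):
            raise ValueError(
                f"pKa must lie in (0, pKw)=(0, {self.pkw}), got {self.pka}"
            )

    def with_(self, **changes) -> "AcidSystem":
        return replace(self, **changes)


@dataclass(frozen=True)
class ActivityModel:
    """Activity-coefficient treatment.

    mode='concentration' (default) takes every γ ≡ 1, i.e. the system's
    constants are already concentration constants at the working ionic
    strength.  mode='davies' treats pka/pkw as thermodynamic constants and
    computes conditional constants with the Davies equation at the actual
    ionic strength of the solution.
    """

    mode: Literal["concentration", "davies"] = "concentration"
    debye_a: float = 0.509  # Debye–Hückel A at 25 °C, (L/mol)^0.5

    def log_gamma(self, charge: int, ionic_strength: float) -> float:
        if self.mode == "concentration":
            return 0.0
        return davies_log_gamma(charge, ionic_strength, self.debye_a)


CONCENTRATION = ActivityModel()


@dataclass
class TitrationCurve:
    """A (titrant volume, reading) series; measured or simulated."""

    volumes: np.ndarray
    readings: np.ndarray
    reading_kind: Literal["pH", "emf"] = "pH"
    system: AcidSystem | None = None
    noise_meta: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.volumes.shape != self.readings.shape:
            raise ValueError("volumes and readings must have equal length")
        if self.volumes.size and self.volumes[0] < 0:
            raise ValueError("volumes must be >= 0")
        if np.any(np.diff(self.volumes) <= 0):
            raise ValueError("volumes must be strictly increasing")
        if self.reading_kind not in ("pH", "emf"):
            raise ValueError(f"unknown reading_kind {self.reading_kind!r}")

    def __len__(self) -> int:
        return int(self.volumes.size)


def ionized_fraction(pka: float, ph) -> float | np.ndarray:
    """Fraction of the acid present as the anion at a given pH.

    Closed form 1/(1 + 10**(pKa - pH)); equals 0.5 at pH = pKa and is
    strictly increasing in pH.
    """
    return 1.0 / (1.0 + 10.0 ** (np.asarray(pka) - np.asarray(ph)))


def davies_log_gamma(charge: int, ionic_strength: float, debye_a: float = 0.509) -> float:
    """log10 activity coefficient of an ion by the Davies equation.

    log10 γ = -A z² (√I/(1+√I) - 0.3 I).  Empirical, serviceable to
    I ≈ 0.5 mol/L; exactly 0 at infinite dilution.
    """
    if ionic_strength < 0:
        raise ValueError("ionic_strength must be >= 0")
    s = np.sqrt(ionic_strength)
    return -debye_a * charge**2 * (s / (1.0 + s) - 0.3 * ionic_strength)


def _conditional_constants(
    system: AcidSystem, activity: ActivityModel, ionic_strength: float
) -> tuple[float, float]:
    """(Ka, Kw) on the concentration scale at the given ionic strength."""
    ka = 10.0 ** (-system.pka)
    kw = 10.0 ** (-system.pkw)
    if activity.mode == "davies":
        # HA neutral (γ=1); Ka_c = Ka_th / (γ+ γ-), likewise Kw.
        lg = activity.log_gamma(1, ionic_strength)
        ka /= 10.0 ** (2 * lg)
        kw /= 10.0 ** (2 * lg)
    return ka, kw


def _charge_balance(h: float, na: float, ca: float, ka: float, kw: float) -> float:
    """Excess positive charge at proton concentration h (K+/Cl- cancel)."""
    return na + h - ca * ka / (ka + h) - kw / h


def solve_proton_concentration(
    system: AcidSystem,
    v_added: float,
    activity: ActivityModel = CONCENTRATION,
) -> float:
    """[H3O+] (mol/L) at a point of the titration.

    Dilution by the total volume v0 + v is always applied.  The root of the
    monotone charge balance is bracketed on [1e-14, 1] mol/L and solved by
    Brent's method in log10[H+]; the returned root satisfies the charge
    balance to well under 1e-12 mol/L.

    Raises
    ------
    ValueError
        If v_added < 0 or the charge balance cannot be bracketed (malformed
        system, e.g. pKa at or beyond pKw).
    """
    if v_added < 0:
        raise ValueError("v_added must be >= 0")
    vtot = system.v0 + v_added
    dil = system.v0 / vtot
    ca = system.c_acid * dil
    na = system.c_base * v_added / vtot

    ionic = system.ionic_background * dil + na
    for _ in range(8 if activity.mode == "davies" else 1):
        ka, kw = _conditional_constants(system, activity, ionic)

        def g(x: float) -> float:
            return _charge_balance(10.0**x, na, ca, ka, kw)

        lo, hi = -14.0, 0.0
        if g(lo) > 0 or g(hi) < 0:
            raise ValueError(
                "charge balance has no root in [1e-14, 1] M; check the system"
            )
        x = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
        h = 10.0**x
        if activity.mode != "davies":
            break
        # all ions are 1:1 here, and by electroneutrality the anion sum
        # equals the cation sum, so I = background + Σ cations beyond KCl
        ionic_new = system.ionic_background * dil + na + h
        if abs(ionic_new - ionic) < 1e-10:
            ionic = ionic_new
            break
        ionic = ionic_new
    return h


def ph_at_volume(
    system: AcidSystem, v_added: float, activity: ActivityModel = CONCENTRATION
) -> float:
    """pH = -log10 [H3O+] (concentration scale) at a titration point."""
    return -np.log10(solve_proton_concentration(system, v_added, activity))


def titration_curve(
    system: AcidSystem,
    volumes: Sequence[float],
    activity: ActivityModel = CONCENTRATION,
) -> TitrationCurve:
    """Ideal (noise-free) pH titration curve over a volume schedule."""
    vols = np.asarray(volumes, dtype=float)
    ph = np.array([ph_at_volume(system, v, activity) for v in vols])
    return TitrationCurve(vols, ph, reading_kind="pH", system=system)


def equivalence_volume(system: AcidSystem) -> float:
    """Titrant volume (mL) at which added base equals the acid's moles."""
    return system.c_acid * system.v0 / system.c_base
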