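"""pKa estimation from titration data, and method-agreement statistics.

Three inverse procedures:

P1  full equilibrium-model fit — Levenberg–Marquardt least squares of the
    observed readings (pH or EMF) against the speciation forward model,
    refining pKa and optionally the analyte concentration and the electrode
    calibration (e0, slope);
P2  half-neutralization read-off — locate the equivalence point as the
    maximum of the finite-difference derivative dpH/dV, then read the pH at
    half that volume (for a buffered monoprotic acid, pH(Veq/2) ≈ pKa);
S   spectrophotometric Henderson–Hasselbalch — fit the sigmoidal
    A(pH) = (A_HA + A_A·10^(pH-pKa)) / (1 + 10^(pH-pKa))
    to a dilution-corrected absorbance series.

P1 and S are exact on noise-free data; P2 trades a small, systematic bias
(the hydroxide term shifts pH(Veq/2) slightly below pKa for weakly buffered
systems) for not needing any model fit — it is the quick bench method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

from .equilibria import AcidSystem, ActivityModel, CONCENTRATION, TitrationCurve, ph_at_volume
from .synthetic_data import ElectrodeCal, SpectroSeries, emf_to_ph

__all__ = [
    "FitResult",
    "MethodComparison",
    "calibrate_electrode",
    "fit_potentiometric_full",
    "locate_equivalence",
    "fit_half_neutralization",
    "fit_spectrophotometric_hh",
    "compare_methods",
]

_MIN_POINTS = {"P1": 4, "P2": 5, "S": 4}


@dataclass
class FitResult:
    """An estimated pKa with its provenance and diagnostics."""

    pka: float
    stderr: float | None
    method: str  # 'P1', 'P2' or 'S'
    n_points: int
    residual_rms: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _MIN_POINTS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.converged and not np.isfinite(self.pka):
            raise ValueError("converged result must have finite pKa")

    def __str__(self) -> str:  # Table-style "7.93 ± 0.02 (P1)"
        if self.stderr is not None and np.isfinite(self.stderr):
            return f"{self.pka:.2f} ± {self.stderr:.2f} ({self.method})"
        return f"{self.pka:.2f} ({self.method})"


@dataclass
class MethodComparison:
    """Paired-difference agreement statistics between two pKa methods."""

    pairs: list
    rms: float
    max_abs: float
    mean_abs: float
    n: int
    n_missing: int = 0


def calibrate_electrode(buffer_ph: Sequence[float], buffer_emf: Sequence[float]) -> ElectrodeCal:
    """Least-squares linear calibration of electrode EMF on buffer pH.

    Exact through two points; with more buffers, ordinary least squares.
    Returns the calibration with slope stored as a positive magnitude.
    """
    ph = np.asarray(buffer_ph, dtype=float)
    emf = np.asarray(buffer_emf, dtype=float)
    if ph.size != emf.size:
        raise ValueError("buffer_ph and buffer_emf must have equal length")
    if np.unique(ph).size < 2:
        raise ValueError("need at least 2 distinct buffer pH values")
    slope, intercept = np.polyfit(ph, emf, 1)
    return ElectrodeCal(e0=float(intercept), slope=float(-slope))


def _model_readings(
    curve: TitrationCurve,
    pka: float,
    c_acid: float,
    e0: float,
    slope: float,
    base_system: AcidSystem,
    activity: ActivityModel,
) -> np.ndarray:
    system = base_system.with_(pka=pka, c_acid=c_acid)
    ph = np.array([ph_at_volume(system, v, activity) for v in curve.volumes])
    if curve.reading_kind == "emf":
        return e0 - slope * ph
    return ph


def fit_potentiometric_full(
    curve: TitrationCurve,
    init: AcidSystem,
    cal: ElectrodeCal | None = None,
    fit_c_acid: bool = False,
    fit_electrode: bool = False,
    activity: ActivityModel = CONCENTRATION,
    max_iter: int = 200,
) -> FitResult:
    """Full-model potentiometric fit (method P1).

    Refines pKa (always) and optionally c_acid and/or the electrode pair
    (e0, slope) by Levenberg–Marquardt minimization of the sum of squared
    reading residuals; all other parameters stay at their given values.
    Standard errors come from the curvature (covariance) at the optimum.
    The default refines pKa only — on a single curve the other parameters
    are weakly identifiable and are better fixed at their known values.
    """
    if len(curve) < _MIN_POINTS["P1"]:
        raise ValueError("P1 needs at least 4 points")
    if np.ptp(curve.readings) == 0:
        raise ValueError("degenerate curve: all readings equal")
    if curve.reading_kind == "emf" and cal is None:
        raise ValueError("an ElectrodeCal is required to fit an EMF curve")

    params = lmfit.Parameters()
    params.add("pka", value=init.pka, min=0.05, max=init.pkw - 0.05)
    params.add("c_acid", value=init.c_acid, min=0.0, vary=fit_c_acid)
    params.add("e0", value=cal.e0 if cal else 0.0, vary=fit_electrode and cal is not None)
    params.add(
        "slope",
        value=cal.slope if cal else 1.0,
        min=1.0,
        vary=fit_electrode and cal is not None,
    )

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = _model_readings(
            curve, p["pka"].value, p["c_acid"].value, p["e0"].value,
            p["slope"].value, init, activity,
        )
        return model - curve.readings

    out = lmfit.minimize(residual, params, method="leastsq",
                         max_nfev=max_iter * (1 + len(params)), xtol=1e-12, ftol=1e-12)
    res = out.residual
    rms = float(np.sqrt(np.mean(res**2)))
    p = out.params
    stderr = p["pka"].stderr
    return FitResult(
        pka=float(p["pka"].value),
        stderr=None if stderr is None else float(stderr),
        method="P1",
        n_points=len(curve),
        residual_rms=rms,
        converged=bool(out.success),
        diagnostics={
            "nfev": out.nfev,
            "redchi": out.redchi,
            "c_acid": float(p["c_acid"].value),
            "e0": float(p["e0"].value),
            "slope": float(p["slope"].value),
            "message": out.message,
        },
    )


def locate_equivalence(curve: TitrationCurve, smooth: bool = False) -> float:
    """Equivalence volume from the maximum of the dpH/dV derivative plot.

    Central finite differences at interior points; with ``smooth`` a 3-point
    moving average is applied to the pH first (useful on noisy data).  The
    equivalence is the highest *interior peak* of the derivative — a run of
    equal values strictly above both neighbours, resolved to the midpoint of
    the run.  Runs touching the boundary of the derivative grid are not
    peaks: a dilute weak acid's curve is steepest right at the start (the
    jump out of the unbuffered region), and a derivative still rising at
    the last sample signals a titration truncated before equivalence.  A
    curve with no interior peak (flat ramp, truncated run) raises.
    """
    if len(curve) < _MIN_POINTS["P2"]:
        raise ValueError("need at least 5 points to locate the equivalence")
    if curve.reading_kind != "pH":
        raise ValueError("locate_equivalence expects pH readings")
    v = curve.volumes
    ph = curve.readings
    if smooth:
        kernel = np.ones(3) / 3.0
        inner = np.convolve(ph, kernel, mode="valid")
        ph = np.concatenate([[ph[0]], inner, [ph[-1]]])
    deriv = (ph[2:] - ph[:-2]) / (v[2:] - v[:-2])
    vmid = v[1:-1]

    # equality up to roundoff, so a numerically flat ramp forms one run
    tol = 1e-9 * max(float(np.max(np.abs(deriv))), 1e-300)
    best = None  # (value, run_start, run_end)
    i, m = 0, deriv.size
    while i < m:
        j = i
        while j + 1 < m and abs(deriv[j + 1] - deriv[i]) <= tol:
            j += 1
        if (
            0 < i
            and j < m - 1
            and deriv[i - 1] < deriv[i] - tol
            and deriv[j + 1] < deriv[i] - tol
        ):
            if best is None or deriv[i] > best[0]:
                best = (float(deriv[i]), i, j)
        i = j + 1
    if best is None:
        raise ValueError(
            "no interior maximum in the dpH/dV plot: flat ramp or titration "
            "truncated before the equivalence point"
        )
    _, i, j = best
    return float(0.5 * (vmid[i] + vmid[j]))


def fit_half_neutralization(curve: TitrationCurve, smooth: bool = False) -> FitResult:
    """Half-neutralization pKa read-off (method P2).

    pKa = pH at half the equivalence volume, linearly interpolated between
    the bracketing samples.
    """
    veq = locate_equivalence(curve, smooth=smooth)
    vhalf = veq / 2.0
    v = curve.volumes
    if not (v[0] <= vhalf <= v[-1]):
        raise ValueError("half-equivalence volume outside the sampled range")
    pka = float(np.interp(vhalf, v, curve.readings))
    return FitResult(
        pka=pka,
        stderr=None,
        method="P2",
        n_points=len(curve),
        residual_rms=0.0,
        converged=True,
        diagnostics={"v_eq": veq, "v_half": vhalf, "smoothed": smooth},
    )


def fit_spectrophotometric_hh(series: SpectroSeries, max_iter: int = 200) -> FitResult:
    """Henderson–Hasselbalch fit to an absorbance-vs-pH series (method S).

    Dilution-corrects the absorbances (multiplying by the stored factors)
    and fits A(pH) = (A_HA + A_A·10^(pH-pKa))/(1+10^(pH-pKa)) for the
    limiting absorbances and pKa by Levenberg–Marquardt.
    """
    if len(series) < _MIN_POINTS["S"]:
        raise ValueError("S needs at least 4 points")
    ph = series.ph_values
    a = series.absorbance.copy()
    if series.dilution_factors is not None:
        a = a * series.dilution_factors
    if np.ptp(a) == 0:
        raise ValueError("flat absorbance series")

    warn = None
    pka0 = float(ph[np.argmin(np.abs(a - 0.5 * (a.min() + a.max())))])
    if not (ph.min() < pka0 < ph.max()):
        warn = "pH range may not bracket the transition"

    params = lmfit.Parameters()
    params.add("a_acid", value=float(a[np.argmin(ph)]))
    params.add("a_base", value=float(a[np.argmax(ph)]))
    params.add("pka", value=pka0, min=0.0, max=14.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        r = 10.0 ** (ph - p["pka"].value)
        model = (p["a_acid"].value + p["a_base"].value * r) / (1.0 + r)
        return model - a

    out = lmfit.minimize(residual, params, method="leastsq",
                         max_nfev=max_iter * 4, xtol=1e-12, ftol=1e-12)
    p = out.params
    stderr = p["pka"].stderr
    diagnostics = {
        "nfev": out.nfev,
        "a_acid": float(p["a_acid"].value),
        "a_base": float(p["a_base"].value),
        "message": out.message,
    }
    if warn:
        diagnostics["warning"] = warn
    return FitResult(
        pka=float(p["pka"].value),
        stderr=None if stderr is None else float(stderr),
        method="S",
        n_points=len(series),
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
        converged=bool(out.success),
        diagnostics=diagnostics,
    )


def compare_methods(pairs: Sequence[tuple]) -> MethodComparison:
    """Agreement statistics over paired pKa determinations.

    ``pairs`` is a sequence of (label, value_a, value_b); pairs where either
    side is missing (None or NaN) are dropped (pairwise deletion) and
    counted in ``n_missing``.  rms = sqrt(mean of squared differences).
    """
    complete, missing = [], 0
    for label, a, b in pairs:
        if a is None or b is None or not np.isfinite(a) or not np.isfinite(b):
            missing += 1
            continue
        complete.append((label, float(a), float(b)))
    if not complete:
        raise ValueError("no complete pairs to compare")
    d = np.array([a - b for _, a, b in complete])
    return MethodComparison(
        pairs=complete,
        rms=float(np.sqrt(np.mean(d**2))),
        max_abs=float(np.max(np.abs(d))),
        mean_abs=float(np.mean(np.abs(d))),
        n=len(complete),
        n_missing=missing,
    )
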