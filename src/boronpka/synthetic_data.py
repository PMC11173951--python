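"""Synthetic potentiometric and spectrophotometric titration data.

Emulates the bench setup behind the fitters: a weak (boronic) acid at
8e-4–2e-3 mol/L in 0.1 M KCl, titrated with ~0.05 M aqueous NaOH at 25 °C,
read out either by a glass electrode (pH directly, or EMF through a linear
Nernst calibration) or by UV absorbance of the neutral/anionic forms.
Noise is independent Gaussian on the reading and on each dispensed volume;
a seeded generator makes every dataset reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import (
    CONCENTRATION,
    AcidSystem,
    ActivityModel,
    TitrationCurve,
    equivalence_volume,
    ionized_fraction,
    ph_at_volume,
    titration_curve,
)

__all__ = [
    "ElectrodeCal",
    "SpectroSeries",
    "NoiseSpec",
    "nernst_emf",
    "emf_to_ph",
    "default_schedule",
    "generate_potentiometric",
    "generate_spectrophotometric",
    "NERNST_SLOPE_25C",
    "P1_CAL_BUFFERS",
    "P2_CAL_BUFFERS",
]

#: Ideal Nernstian glass-electrode response magnitude at 25 °C, mV per pH.
NERNST_SLOPE_25C = 59.16

#: Calibration buffer pH sets: four buffers for the full-model workflow,
#: two (pH 4 and 7) for the quick half-neutralization workflow.
P1_CAL_BUFFERS = (2.0, 4.0, 7.0, 9.0)
P2_CAL_BUFFERS = (4.0, 7.0)


@dataclass(frozen=True)
class ElectrodeCal:
    """Linear glass-electrode calibration E = e0 - slope*pH.

    slope is stored as the magnitude of the (negative) Nernst response,
    so it is positive for a healthy electrode.
    """

    e0: float
    slope: float = NERNST_SLOPE_25C

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be > 0 (stored as a magnitude)")


@dataclass
class SpectroSeries:
    """An absorbance-vs-pH series with its Beer–Lambert parameters.

    eps_acid / eps_base are molar absorptivities (L mol^-1 cm^-1) of the
    neutral and anionic forms at the monitored wavelength; dilution_factors,
    when present, are the cumulative analyte dilution at each point (the
    stored absorbance is the as-measured, diluted one).
    """

    ph_values: np.ndarray
    absorbance: np.ndarray
    eps_acid: float = 0.0
    eps_base: float = 0.0
    c_total: float = 0.0
    pathlength: float = 1.0
    dilution_factors: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.ph_values.shape != self.absorbance.shape:
            raise ValueError("ph_values and absorbance must have equal length")
        if self.pathlength <= 0:
            raise ValueError("pathlength must be > 0")
        if self.dilution_factors is not None:
            self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
            if self.dilution_factors.shape != self.ph_values.shape:
                raise ValueError("dilution_factors must match ph_values length")
            if np.any(self.dilution_factors < 1):
                raise ValueError("dilution_factors must be >= 1")

    def __len__(self) -> int:
        return int(self.ph_values.size)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian instrument noise: reading sigma (pH or mV), volume sigma (mL).

    Defaults model a well-behaved autotitrator: 0.005 pH on the reading and
    1 µL on each dispensed volume. The same seed always reproduces the same
    dataset.
    """

    sigma_reading: float = 0.005
    sigma_volume: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_reading < 0 or self.sigma_volume < 0:
            raise ValueError("noise sigmas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseSpec(0.0, 0.0, 0)

#: Default EMF-reading noise (mV) when a calibration converts pH to EMF.
SIGMA_EMF_DEFAULT = 0.3


def nernst_emf(cal: ElectrodeCal, ph):
    """Electrode EMF (mV) at a given pH: E = e0 - slope*pH."""
    return cal.e0 - cal.slope * np.asarray(ph)


def emf_to_ph(cal: ElectrodeCal, emf):
    """Invert the calibration: pH = (e0 - E)/slope."""
    return (cal.e0 - np.asarray(emf)) / cal.slope


def default_schedule(system: AcidSystem, n_points: int = 100) -> np.ndarray:
    """Dosing schedule 0 → 2×equivalence volume in equal steps.

    A constant-rate pump recording at fixed intervals traverses volume
    uniformly, so equal volume steps are the natural idealization.
    """
    veq = equivalence_volume(system)
    return np.linspace(0.0, 2.0 * veq, n_points)


def generate_potentiometric(
    system: AcidSystem,
    schedule=None,
    cal: ElectrodeCal | None = None,
    noise: NoiseSpec = NOISELESS,
    activity: ActivityModel = CONCENTRATION,
) -> TitrationCurve:
    """Simulate a potentiometric titration.

    The ideal curve comes from the speciation solver; the *dispensed*
    volumes are then perturbed by N(0, sigma_volume²) — the recorded volume
    stays at the nominal schedule, which is exactly how an autotitrator's
    dosing error enters real data — and readings by N(0, sigma_reading²).
    With a calibration the reading is EMF in mV, otherwise pH.  All sigmas
    zero reproduces the ideal curve exactly.
    """
    if schedule is None:
        schedule = default_schedule(system)
    schedule = np.asarray(schedule, dtype=float)
    rng = noise.rng()

    if noise.sigma_volume > 0:
        # dosing error: the pump delivers `actual`, the log records `schedule`
        actual = schedule + rng.normal(0.0, noise.sigma_volume, schedule.size)
        actual = np.maximum(actual, 0.0)
        ph = np.array([ph_at_volume(system, v, activity) for v in actual])
    else:
        ph = titration_curve(system, schedule, activity).readings

    if cal is not None:
        readings = nernst_emf(cal, ph)
        kind = "emf"
    else:
        readings = ph
        kind = "pH"
    if noise.sigma_reading > 0:
        readings = readings + rng.normal(0.0, noise.sigma_reading, readings.size)

    return TitrationCurve(
        schedule,
        readings,
        reading_kind=kind,
        system=system,
        noise_meta={
            "sigma_reading": noise.sigma_reading,
            "sigma_volume": noise.sigma_volume,
            "seed": noise.seed,
            "cal": None if cal is None else (cal.e0, cal.slope),
        },
    )


def generate_spectrophotometric(
    pka: float,
    template: SpectroSeries,
    noise: NoiseSpec = NOISELESS,
) -> SpectroSeries:
    """Simulate an absorbance-vs-pH series by Beer–Lambert mixing.

    A(pH) = l·c·(eps_acid·(1-f) + eps_base·f) with f the ionized fraction,
    divided by the template's dilution factors when present, plus Gaussian
    reading noise (sigma_reading is in absorbance units here).
    """
    ph = np.asarray(template.ph_values, dtype=float)
    f = ionized_fraction(pka, ph)
    a = template.pathlength * template.c_total * (
        template.eps_acid * (1.0 - f) + template.eps_base * f
    )
    if template.dilution_factors is not None:
        a = a / template.dilution_factors
    if noise.sigma_reading > 0:
        a = a + noise.rng().normal(0.0, noise.sigma_reading, a.size)
    return SpectroSeries(
        ph_values=ph,
        absorbance=a,
        eps_acid=template.eps_acid,
        eps_base=template.eps_base,
        c_total=template.c_total,
        pathlength=template.pathlength,
        dilution_factors=template.dilution_factors,
        meta={"pka_true": pka, "seed": noise.seed,
              "sigma_reading": noise.sigma_reading},
    )
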