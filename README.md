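# boronpka

Titration modelling, pKa estimation and Hammett analysis for phenylboronic
acids (and, with the same mathematics, their Brønsted analogues such as
benzoic acids).

Boronic acids are Lewis acids: in water they ionize by binding hydroxide,

    RB(OH)2 + 2 H2O  <=>  RB(OH)3^- + H3O+ ,

an equilibrium whose constant Ka = [RB(OH)3⁻][H3O⁺]/[RB(OH)2] has exactly
the monoprotic form, so the familiar acid–base machinery applies. Their
acidity (pKa) governs diol ester formation, anion sensing and catalysis,
which makes fast, reliable pKa determination a routine need in boron
chemistry and medicinal chemistry labs. This package implements the
complete desk workflow around that need:

- **forward model** (`equilibria`): charge-/mass-balance speciation solver
  for a strong-base titration of a monoprotic acid at fixed ionic
  background (0.1 M KCl; concentration constants, optional Davies
  activity correction), producing ideal titration curves;
- **synthetic data** (`synthetic_data`): seeded, noise-parameterized
  potentiometric (pH or glass-electrode EMF) and spectrophotometric
  datasets emulating the bench protocol;
- **three inverse estimators** (`pka_fitters`):
  P1 — full equilibrium-model Levenberg–Marquardt fit;
  P2 — quick half-neutralization read-off (pH at half the equivalence
  volume located from the ΔpH/ΔV derivative plot);
  S — spectrophotometric Henderson–Hasselbalch fit of
  A(pH) = (A_HA + A_A·10^(pH−pKa))/(1+10^(pH−pKa));
  plus electrode calibration and paired method-agreement statistics;
- **Hammett analysis** (`hammett`): pK_X = pK₀ − ρσ fitting (free or
  fixed intercept), prediction, literature aggregation and cross-series
  correlation, with the published lines pK = 8.76 − 2.06σ and
  pK = 8.92 − 2.52σ shipped as frozen fits;
- **reference tables and I/O** (`tables`, `io`, `cli`): the literature
  and measured pKa tables packaged as text fixtures, delimited
  readers/writers, and a `boronpka` command-line tool.

## Worked example

Simulate a noisy titration of a pKa 7.95 acid (1 mM in 50 mL, 0.05 M
NaOH, default instrument noise), then recover the pKa three ways:

```python
import numpy as np
from boronpka import (AcidSystem, NoiseSpec, SpectroSeries,
                      generate_potentiometric, generate_spectrophotometric,
                      fit_potentiometric_full, fit_half_neutralization,
                      fit_spectrophotometric_hh)

system = AcidSystem(pka=7.95, c_acid=1e-3, v0=50.0, c_base=0.05)
curve = generate_potentiometric(system, noise=NoiseSpec(seed=1))
print(fit_potentiometric_full(curve, system.with_(pka=8.5)))
print(fit_half_neutralization(curve, smooth=True))

template = SpectroSeries(ph_values=np.linspace(5, 11, 25),
                         absorbance=np.zeros(25),
                         eps_acid=500.0, eps_base=1800.0, c_total=1e-3)
series = generate_spectrophotometric(7.95, template, NoiseSpec(0.003, 0.0, 1))
print(fit_spectrophotometric_hh(series))
```

prints

```
7.95 ± 0.00 (P1)
7.94 (P2)
7.95 ± 0.00 (S)
```

— the full-model (P1) and spectrophotometric (S) fits recover the true
pKa with sub-0.01 standard errors (shown at the 2-decimal reporting
precision); the quick P2 read-off lands slightly low, as it
systematically does for weak acids (the hydroxide term shifts the
half-neutralization pH below pKa).

Fitting the Hammett line to the packaged halogen/CN measurement table
(mean of the S and P1 determinations, ten meta/para compounds):

```python
from boronpka import fit_hammett, predict_pka, LITERATURE_WATER_FIT
from boronpka.tables import table3_hammett_records

fit = fit_hammett(table3_hammett_records())
print(f"rho={fit.rho:.4f}  pk0={fit.pk0:.4f}  R2={fit.r_squared:.4f}  n={fit.n}")
print(f"{predict_pka(LITERATURE_WATER_FIT, 0.78):.2f}")   # para-NO2
```

prints

```
rho=2.5236  pk0=8.9175  R2=0.9764  n=10
7.15
```

i.e. the measured series gives pK_X = 8.92 − 2.52 σ_X: phenylboronic
acids respond to ring substitution about 2.5× more strongly than benzoic
acids (for which ρ = 1 by definition of the σ scale), and the literature
line predicts pKa 7.15 for the para-nitro compound.

The same workflows are available from the shell:

```
boronpka simulate-titration --pka 8.2 --sigma-ph 0.005 --out curve.csv
boronpka fit --method p1 --data curve.csv --pka0 8.5
boronpka hammett fit --source table3
boronpka compare --table table3 --columns pka_s pka_p1
```

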