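# Methods

## The model

Phenylboronic acids are Lewis acids: in water they do not donate a proton but
bind hydroxide, forming the tetrahedral boronate anion,

    RB(OH)2 + 2 H2O  <=>  RB(OH)3^- + H3O+ ,
    Ka = [RB(OH)3^-][H3O+] / [RB(OH)2] .

This equilibrium has exactly the algebraic form of a monoprotic Brønsted
acid (for which benzoic acids are the comparison series), so a single
forward model serves both families; `AcidSystem.acid_kind` is metadata only.

All constants are **concentration constants**. The experimental design this
package emulates holds the ionic medium at 0.1 M KCl, which swamps the
reacting species, keeps activity coefficients constant over a titration,
and lets them be folded into the constants. An optional Davies-equation
mode (`ActivityModel(mode="davies")`) instead treats pKa/pKw as
thermodynamic constants and converts them to conditional constants at the
actual ionic strength, iterating the ionic-strength estimate to a fixed
point (at most 8 rounds; it converges in 2–3 because the background
dominates). pH throughout is −log10 [H3O+] on the concentration scale.

### Speciation solver

At titrant volume v the solver finds [H+] from the charge balance

    [Na+] + [K+] + [H+] = [A-] + [Cl-] + [OH-] ,

with Na+ = c_base·v/(v0+v), every analytical concentration diluted by
v0/(v0+v) (dilution is always applied), [A-] from Ka, and [OH-] = Kw/[H+].
K+ and Cl− cancel but are carried for the Davies ionic-strength
bookkeeping. The balance is strictly monotone in [H+], so the root is
bracketed on [1e-14, 1] mol/L and solved by Brent's method in log10[H+]
(xtol 1e-15, ≤200 iterations); the residual at the root is far below
1e-12 mol/L, which the tests assert against an independent bisection
oracle. A system with pKa ≥ pKw cannot bracket and raises.

Defaults: pKw = 13.997 (25 °C, concentration scale), Debye–Hückel A =
0.509 (mol/L)^-1/2. No constant is temperature-corrected; temperature is
metadata.

## Synthetic data

The generator emulates the bench protocol the fitters were designed for:
acid at 8e-4–2e-3 mol/L in 50 mL of 0.1 M KCl, titrated with 0.05 M NaOH
at 25 °C; readout either as pH or as EMF through a linear glass-electrode
calibration E = E0 − S·pH (Nernstian S ≈ 59.16 mV/pH at 25 °C; calibration
against 4 buffers {2,4,7,9} for the full-model workflow, 2 buffers {4,7}
for the quick one). The default dosing schedule is 0 → 2×equivalence
volume in 100 equal steps — a constant-rate pump sampled at fixed
intervals traverses volume uniformly.

Noise is independent Gaussian: sigma_reading = 0.005 pH (0.3 mV on EMF)
and sigma_volume = 0.001 mL per dose, chosen as a realistic autotitrator
budget; the volume error perturbs the *delivered* volume while the log
records the nominal schedule, which is how dosing error enters real data.
A `NoiseSpec` seed makes every dataset reproducible; all sigmas zero
reproduces the ideal curve bit-for-bit.

Spectrophotometric series follow Beer–Lambert mixing of the neutral and
anionic chromophores, A(pH) = l·c·(ε_HA·(1−f) + ε_A·f) with f the ionized
fraction, optionally divided by per-point analyte dilution factors.
Defaults ε_HA = 500, ε_A = 1800 L mol⁻¹ cm⁻¹ at c = 1e-3 M in a 1 cm
cuvette give absorbances in the 0.5–1.8 AU range typical of these
titrations.

What the generator does **not** emulate: electrode drift and junction
potentials, carbonate contamination of the titrant, protodeboronation of
the analyte during slow titrations, temperature excursions, and boroxine
or diol side-equilibria. Passing round-trip tests therefore shows the
estimators are correct and calibrated under the stated noise model, not
that they are robust to every systematic error of real glassware.

## The three estimators

**P1 — full equilibrium-model fit.** Levenberg–Marquardt least squares of
the observed readings against the forward model, refining pKa always and,
optionally, c_acid and the electrode pair (E0, S); everything else stays
fixed. Standard errors come from the Jacobian-based covariance at the
optimum (scaled by the reduced chi-square, so they adapt to the actual
noise level). Convergence: relative step below 1e-12 or 200 iterations.
On a single curve the non-pKa parameters are weakly identifiable, so the
default refines pKa only. Exhaustive grid search at 1e-4 resolution (run
in two stages because the sum of squares is unimodal in pKa) agrees with
the optimizer to the grid resolution.

**P2 — half-neutralization read-off.** The equivalence point is the
highest *interior peak* of the finite-difference ΔpH/ΔV plot (central
differences; optional 3-point pre-smoothing for noisy data; a run of
tied maxima resolves to its midpoint). Runs touching the grid boundary
are not peaks: a dilute weak acid's curve is steepest right at the start
(the jump out of the unbuffered region), and a derivative still rising at
the last point means the titration was truncated — both raise. The pKa is
then the pH linearly interpolated at half the equivalence volume.

P2 is deliberately the quick, cruder method. Its estimand pH(Veq/2)
differs from pKa by the water terms in the charge balance: about −0.01
(hydroxide) for the headline weak system (pKa 8.76, 1e-3 M), and +0.12
(free proton) for a dilute stronger acid (pKa 4, 1e-3 M). On top of that,
for weakly buffered systems the true inflection sits slightly before the
stoichiometric equivalence, adding roughly −0.02 here. Both effects are
reproduced exactly by an independent bisection oracle in the tests; they
are why the full-model and spectrophotometric methods are preferred when
accuracy matters.

**S — spectrophotometric Henderson–Hasselbalch.** After multiplying the
absorbances by their dilution factors, least squares of

    A(pH) = (A_HA + A_A·10^(pH−pKa)) / (1 + 10^(pH−pKa))

over (A_HA, A_A, pKa). The fit warns (in diagnostics) when the pH range
does not bracket the transition. Initial values: the absorbances at the
pH extremes and the pH nearest the half-range absorbance.

**Agreement statistics.** `compare_methods` uses pairwise deletion
(missing sides dropped and counted) and reports rms, max and mean
absolute difference; rms reproduces the published 0.14 (spectro vs
full-model) and 0.18 (full vs quick potentiometric, ortho-iodo excluded
as the sterically anomalous outlier).

## Hammett analysis

The Hammett equation log(K_X/K_0) = ρσ becomes pK_X = pK_0 − ρσ on the
pKa scale; ρ is stored positive (electron-withdrawing σ > 0 strengthens
the acid). Ortho records are rejected — σ does not describe ortho
steric/H-bond effects, and the literature comparison shows no ortho
correlation — and at least 4 points are required.

Two regression modes: free intercept (OLS of pKa on σ; the default and
what the headline ρ = 2.52, pK0 = 8.92 line uses) and fixed intercept
(pK0 pinned, (pK0 − pKa) regressed on σ through the origin — the form
closest to the defining equation when the parent pKa is known). On the
aggregated literature data the two bracket the published ρ = 2.06
(2.093 free, 2.033 fixed); the inclusion choices behind the published
aggregation are not fully specified, which is why both modes ship.

Literature aggregation is the unweighted mean per (substituent, position,
family); approximate ("ca.") entries are excluded by default. Note the
tabulated parent (unsubstituted) boronic values average to 8.77, while
the published parent constant is 8.76; the frozen published lines
(`LITERATURE_WATER_FIT`, `HALOGEN_CN_FIT`) store the printed coefficients
verbatim.

As a scale sanity check, refitting the benzoic-acid literature means
gives ρ = 0.97, consistent with the definitional ρ = 1.00 for benzoic
acid ionization in water at 25 °C.

## Numerical choices and limitations

- Brent root-finding in log10[H+]; residuals < 1e-12 mol/L asserted.
- Half-volume pH by linear interpolation (monotone data), not splines.
- Derivative ties broken at the run midpoint; roundoff-flat ramps are
  detected with a relative tolerance of 1e-9 on the derivative.
- Table values are stored as printed; one transcription fix (an
  uncertainty printed "003" stored as 0.03) is flagged in the fixture
  notes. Missing cells are genuine missing markers, never zero.
- Monte-Carlo checks use 100 replicates at the default noise; problem
  sizes (100-point schedules, 25-point spectral series) match the
  default generator conditions.
- Out of scope: polyprotic refinement, boroxine/amine and diol
  side-equilibria, temperature dependence of constants, σ⁺/σ⁻/Taft
  extensions, and any quantum-chemical pKa prediction.
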