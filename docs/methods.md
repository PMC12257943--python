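# Methods

This note records the models, conventions and numerical choices behind
`irapkit`, and what the synthetic-trial tests do and do not demonstrate
about real data.

## Physical conversions

Oxygen is carried internally as % air saturation. Conversion to partial
pressure uses PO₂ = (sat/100) · 0.2095 · (P_bar − p_H₂O(T)), with water
vapour pressure from the Arden Buck (1981) fit
p_H₂O = 0.61121·exp((18.678 − T/234.5)·(T/(257.14 + T))) kPa. Freshwater O₂
solubility at 100% air saturation uses the Benson–Krause empirical fit (the
USGS form, mg O₂ L⁻¹ at 101.325 kPa, valid 0–40 °C), reproducing the
published saturation table to three significant figures (e.g. 9.09 mg L⁻¹ at
20 °C). Barometric pressure defaults to 101.325 kPa and is overridable per
trial; solubility scales proportionally with pressure, and salinity is fixed
at zero (freshwater trials only). These conventions matter because hypoxia
endpoints are reported in kPa while ramps are controlled in % air
saturation; the conversion constants are documented here precisely so that
kPa values are attributable.

## Oxygen uptake extraction

The uptake equation ṀO₂ = |dPO₂/dt| · (V_r − V_f) · S_O · 3600 / (100 · M_f)
treats the slope in % air saturation s⁻¹: the /100 maps the slope to a
fraction of the chamber's oxygen capacity S_O·(V_r − V_f), and the 3600
expresses the rate per hour. "Sequential" windows are contiguous and
non-overlapping — each starts one sample after the previous window ends —
which is the native resolution of an intermittent-flow protocol; a rolling
stride (a window at every sample) is available for sensitivity analysis, and
the sequential estimates are a strict subset of the rolling ones. The window
length defaults to the full measurement phase. Windows failing the linearity
requirement (R² > 0.95) are retained with an `excluded` flag so that counts
of usable values remain auditable; a perfectly flat window is assigned
R² = 0 (linearity undemonstrable) with slope 0.

Background correction subtracts the nearest-in-time blank-chamber value.
The blank series is fitted with the same chamber geometry and normalised to
the same body mass as the fish, so values subtract directly; a warning is
raised whenever background exceeds 5% of the fish's contemporaneous ṀO₂.

## Metabolic summary

SMR is the 20% quantile of non-excluded ṀO₂ values recorded after a 12-h
recovery exclusion, using the linear-interpolation quantile convention (the
mean-of-lowest-normal alternative from the SMR literature is out of scope).
A warning fires below 200 contributing values. MMR is the peak non-excluded
window within a 1-h post-chase horizon, ties broken toward earlier time.
Note that a windowed estimator necessarily reads slightly below the
instantaneous peak of a decaying recovery curve — the within-window mean of
the excess — which is a property of the measurement protocol, not a bug.

EPOC integrates (ṀO₂ − SMR) from sealing until the first window at or below
1.1·SMR (that window excluded). Each window is weighted by the cycle period
it represents, computed from midpoint boundaries between consecutive
windows, so excluded windows hand their time to retained neighbours rather
than deflating the integral; unit weighting is available as an option.

Mass-centred group means fit log₁₀(value) on log₁₀(mass) plus group
indicators with a common allometric slope (ordinary least squares via
statsmodels), reporting each group's back-transformed prediction at a common
mass (default: the geometric mean of all masses) with standard errors on the
log scale. When masses carry no variation the slope is dropped with a
warning and the result reduces to group geometric means.

## P_crit

The default `smr_intersection` method anchors P_crit to SMR directly:
oxyconforming points are selected by scanning upward from the lowest PO₂
while ṀO₂ < SMR (requiring ≥ 3 points), a line is fitted to them, and
P_crit is the PO₂ at which that line reaches SMR. The alternative
`broken_stick` method fits two least-squares segments over all hypoxia
windows at every candidate split (each segment ≥ 2 points) and reports the
intersection of the two fitted lines at the RSS-optimal split — the
conventional broken-stick output, which coincides with a data point placed
exactly at the breakpoint. Results carry the method label, the conformity
and regulation fits, the count of ṀO₂ points recorded before ṀO₂ first fell
below SMR, and a validity flag requiring that count to be ≥ 10.

## Tolerance ramps and plasticity metrics

Ramp endpoints are the driver value at the loss-of-equilibrium time,
linearly interpolated between samples (ramps are linear by protocol).
ARR is computed from group-mean endpoints — a single fish experiences one
acclimation temperature, so per-fish ARR is undefined — and reported at two
decimals. TSM is exact arithmetic. The identity
ARR = 1 + ΔTSM/Δaccl-temperature is asserted for every computed pair.

## Cardiac analysis

ƒ_Hmax per step is 60 / mean(RR) over the RR intervals falling wholly inside
the final 1-min window of each 6-min step; steps with fewer than five window
beats are flagged missing rather than fabricated. Arrhythmia detection is an
operational decision (ECG studies rely on inspection): a step is arrhythmic
when its window contains an RR gap exceeding 1.8× the window median RR or
when the RR coefficient of variation exceeds 0.15; both thresholds are
parameters. The curve summary searches the peak over pre-arrhythmic steps
only (ties toward the lower temperature), and the fold increase is the ratio
peak/initial — "relative increase" read as a ratio rather than 1 + Δ/initial
(identical when the 12 °C step is the minimum). Group-mean curves should
average only non-arrhythmic fish per step.

## The synthetic-trial generator

The generator exists to close the loop: every estimator is exercised against
trials whose true parameters are known, with all randomness flowing from a
single explicit seed.

**Respirometry trial.** The fish's true uptake is
ṀO₂(t) = SMR·(1 + a·(1 + sin(2πt/24 h − π/2))/2) + (MMR − SMR)·e^(−kt),
i.e. an exponential post-exhaustion recovery on top of a diel cycle modelled
as a *non-negative* sinusoidal elevation (amplitude a = 10% of SMR, trough
at trial start). SMR is deliberately the floor of the diel cycle: a
zero-mean sinusoid would place the q0.2 quantile ≈ 0.8·a below the nominal
SMR (the arcsine-distribution quantile), contradicting both the estimator's
premise and the physiological reading that routine activity elevates
metabolism above the standard rate. The default recovery rate is 0.8 h⁻¹,
placing the repayment horizon near 5 h as typical for salmonids; the true
EPOC is the closed-form excess integral ((MMR − SMR) − 0.1·SMR)/k. Chamber
PO₂ follows the uptake ODE exactly within closed phases and relaxes
first-order toward bath saturation during flushes (≥ 99% equilibration
within the flush). Cycle timing defaults to 20/40/120 s
(flush/stabilization/measurement) for the first 3 h of recovery, then
90/95/360 s routine cycles out to 48 h; the 48-h record yields ~239
SMR-eligible windows after the 12-h exclusion, exceeding the ≥ 200 values a
reliable q0.2 needs. (The longer 75/120/780 s routine cycle used for larger
fish is supported but yields ~130 windows in the same span, which is why the
shorter cycle is the default study condition.) Optode noise is Gaussian,
SD 0.05% air saturation, chosen so routine windows pass the R² filter while
the q0.2 remains noise-limited rather than trivially exact. The fish chamber
carries the same microbial background uptake (4% of SMR) as the blank
chamber — background correction assumes precisely this.

**Hypoxia phase.** The bath is drawn down over 45 min to twice the true
P_crit, then at 0.15% air saturation min⁻¹ until the true LOE_hyp. Above
P_crit the fish oxyregulates at its *routine* rate, 1.1×SMR by default;
below P_crit it suppresses to the standard rate and conforms along the line
through the origin that reaches SMR at P_crit. The routine elevation is
essential, not cosmetic: a plateau exactly at SMR would put roughly half of
the first windows below SMR by noise alone, making the "≥ 10 points before
ṀO₂ fell below SMR" protocol requirement unsatisfiable and degenerating the
conforming-point scan whenever the estimated SMR exceeds the plateau.

**Tolerance ramps.** Warming at 0.1 °C min⁻¹ from 18 °C (thermal) and
deoxygenation at ~1.5% air saturation min⁻¹ to 20% then 0.1% min⁻¹
(hypoxia), with the LOE flag raised at the first sample crossing the true
endpoint; the endpoint is therefore exact up to one sample interval.

**Cardiac trial.** Beats are an inhomogeneous point process with rate
ƒ(T) = ƒ₁₂·Q10^((T−12)/10) up to T_peak (defaults ƒ₁₂ = 60 bpm, Q10 = 1.8),
declining 8 bpm °C⁻¹ beyond, under the 1 °C/6-min schedule from 12 °C.
RR intervals carry 3% lognormal jitter; from the true T_arr onward every
8th beat is dropped (RR × 2.2), which the gap detector flags in the first
affected step.

**What passing tests do not show.** The simulator emulates clean,
well-behaved trials: no optode drift, no digestion (SDA), no within-trial
temperature fluctuation, no activity bursts beyond the smooth diel cycle,
instant temperature steps in the cardiac trial, and an idealized sharp
P_crit transition. Parameter recovery under these conditions validates the
estimators' correctness, not their robustness to every pathology of real
recordings.

## Problem sizes and tolerances

End-to-end recovery is checked over 20 seeded trials at default noise
against these bounds: SMR and MMR within 5%, EPOC within 10% of the analytic
integral, P_crit within 1% air saturation, CT_max within one ramp sample,
T_arr within one 1 °C step. The acceptance script runs the same 20-trial
design. The noiseless uptake-equation oracle is held to 1e-9 relative;
unit-conversion invertibility to 1e-9; the broken-stick estimator must equal
an exhaustive brute-force search exactly.

## Known limitations

- Phase labels must be present in traces; automatic phase detection from
  unlabeled records is not implemented.
- The conformity model below P_crit is linear through the origin; oxygen
  supply capacity (α) methods and regulation-index metrics are out of scope.
- Arrhythmia detection sees only beat timestamps; waveform-level ECG
  artifacts are invisible to it.
- Routine statistical testing (ANOVA/ANCOVA p-values, post hoc comparisons,
  Box-Cox transforms) is intentionally out of scope; the package produces
  the adjusted means and derived metrics used for presentation.
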