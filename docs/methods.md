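# Methods

`pbpkdd` is a whole-body physiologically-based pharmacokinetic (PBPK)
simulator with in vitro-in vivo extrapolation (IVIVE) of metabolism, built
to run virtual clinical trials of enzyme-induction drug-drug interactions.
It ships calibrated parameter sets for efavirenz (a CYP3A4/CYP2B6 inducer)
and artemether (a high-first-pass CYP3A4/CYP2B6 substrate used in
artemisinin combination therapy), and a trial runner for the standard
interaction design: efavirenz 600 mg once daily for 14 days, then six
artemether doses over three days, in 50 virtual adults run as paired arms
(the same subjects with and without the inducer).

## Virtual population

Subjects are drawn as sex ~ Bernoulli(proportion female), age ~
Uniform(20-50 y), height ~ Normal per sex (male 176 ± 7 cm, female 163 ±
6 cm), BMI log-normal (median 24 kg/m², GSD 1.15); weight = BMI·(H/100)².
Organ masses follow log-linear allometry on height with published slopes,
anchored so a 176-cm male carries standard reference masses (liver 1.80
kg, brain 1.45 kg, bones 10.5 kg, ...); blood and skin scale with DuBois
body surface area, brain with the saturating-growth/slow-atrophy age
curve, adipose with a body-fat-percent equation on BMI/age/sex.  Random
variation is multiplicative, 10^ε with ε ~ N(0, SD) per organ (SDs
sex-specific where reported).  Skeletal muscle is the remainder against
body weight, so mass closure is exact by construction; a draw leaving
< 5 kg of muscle is rejected and resampled (at most 100 times).

Cardiac output is CO = QCC·BW^0.75 with QCC = 15 L/h/kg^0.75.  Regional
flows are fixed fractions of CO (adipose 0.052, bone 0.042, brain 0.114,
kidney 0.175, liver total 0.227 of which portal 0.181, muscle 0.191, skin
0.058, heart 0.040); the splanchnic organs (stomach : intestine : spleen :
pancreas = 1 : 15 : 3 : 1) jointly carry the portal fraction and drain into
the liver; the residual 10.1% goes to the "remaining" compartment.  The
arterial allocation sums exactly to CO and the lungs sit in series.

## Oral absorption (CAT model)

A stomach (transit time 0.5 h) feeds seven serial small-intestine segments
(total transit 3.3 h, so k_t = 7/3.3 h⁻¹).  Solid drug dissolves with a
first-order constant k_d (optionally capped by luminal solubility, and
optionally restricted to a "dissolvable fraction" of the dose — the
limiting behaviour of a solubility/release cap); dissolved drug in the
segments is absorbed with k_a = 2·P_eff/r.  P_eff comes from a log-log
Caco-2 correlation (slope 0.4926, intercept -0.1454) or a PSA/HBD
regression (log P_eff = 0.4926 - 0.0087·PSA - 0.43·HBD, P_eff in 10⁻⁴
cm/s).  The effective absorptive radius is r = 1.25 cm, a calibrated
constant: with the regression-predicted P_eff it yields k_a ≈ 0.7 h⁻¹ and
a permeability ceiling F_a,max = 0.868, inside which the artemether
dissolution constant (k_d = 4.50 h⁻¹, calibrated) gives F_a = 0.86.
Efavirenz absorption is solubility-limited: 54.3% of the dose is
dissolvable (calibrated), giving F_a = 0.45 at 600 mg.  Drug exiting the
last segment counts as unabsorbed; with no dissolution limit the model
reproduces the analytic transit-chain result F_a = 1 - (1 + k_a/k_t)⁻⁷,
which is a hard test oracle.

## Distribution

Tissue:plasma partition coefficients use the tissue-composition
(lipid/water) model: Kp = mixture(tissue)/mixture(plasma) · fu_p/fu_t with
mixture(x) = P·(V_nl + 0.3·V_ph) + (V_w + 0.7·V_ph); P = 10^logP except
adipose, which uses the vegetable-oil partition 10^(1.115·logP - 1.35) and
fu_t = 1.  Non-adipose tissues assume half the plasma binding-protein
concentration (fu_t = 1/(1 + 0.5·(1-fu_p)/fu_p)).  Both compounds are
treated as neutral at physiological pH (no pKa correction).  Each drug may
carry an empirical Kp scalar — the standard device for reconciling a
composition-based Kp set with an observed volume of distribution.
Efavirenz uses 0.151 (matching its ~150 L apparent volume; unscaled the
model overpredicts ~6-fold for this very lipophilic, highly bound
compound).  Artemether keeps the unscaled set: its observed apparent
volume is too uncertain (report range spans 100-4700 L/F) to justify a
scalar, and the unscaled set places the steady-state peak and trough in
the observed range.  Known limitation: the simulated artemether V/F
(~2000-4000 L by terminal-slope estimation) sits above the ~1600 L point
estimate reported clinically.

## Metabolism and IVIVE scaling

Recombinant-isoform intrinsic clearances (uL/min/pmol) scale to whole-organ
values by isoform abundance (pmol/mg microsomal protein) × MPPGL (40 mg/g)
× liver mass, divided by the predicted fraction unbound in the incubation
(log K = 0.072·logP² + 0.067·logP - 1.126 at 0.5 mg/mL protein).  The
hepatic abundances (CYP3A4 64, CYP2B6 9.9, CYP1A2 52, CYP2A6 42, CYP3A5 10
pmol/mg) are within published ranges and jointly calibrated — together
with the enterocyte blood flow Q_g = 2.15 L/h and the efavirenz UGT2B7
glucuronidation term (216.5 L/h unbound at the reference liver) — so that
the reference-chain availabilities and clearances of both compounds land
on their observed values.  Gut-wall metabolism uses the total intestinal
CYP3A4 content (70.5 nmol) and only CYP3A4.

Availability and clearance follow the well-stirred model with total
hepatic blood flow Q_h (portal + arterial — the flow actually perfusing
the organ, keeping CL_h = Q_h·(1 - F_h) self-consistent):

    F_g  = Q_g/(Q_g + fu_gut·CLint_g),   fu_gut = 1
    F_h  = Q_h/(Q_h + fu_b·CLint_h)
    CL_h = Q_h·fu_b·CLint_h/(Q_h + fu_b·CLint_h)

Blood and plasma are treated as equivalent matrices for the shipped
compounds (B:P = 1; the observed clearance/exposure chain is only mutually
consistent under that convention), so fu_b = fu_plasma.  For the reference
adult this gives artemether F_a·F_g·F_h = 0.86·0.195·0.60 ≈ 0.10 and
efavirenz 0.45·0.954·0.954 ≈ 0.41.

## Enzyme induction

An inducer raises hepatic expression of each targeted isoform by
E = 1 + Emax·I/(EC50 + I) (efavirenz: Emax 5.7/EC50 0.8 uM for CYP2B6,
6.5/3.9 uM for CYP3A4).  The driver concentration I is, by default, the
drug concentration in blood leaving the liver (uM); total-tissue and
unbound-tissue modes are selectable.  The liver-blood default is the
deliberate design choice: induction EC50s are measured in aqueous culture
medium, and driving the Emax model with the Kp-amplified total tissue
concentration of a lipophilic inducer (~8-fold plasma) double-counts
partitioning and saturates the response.  The effect ramps linearly from
the first inducer dose to 100% at 14 days and multiplies the victim's
per-isoform hepatic CLint inside the ODE system; gut-wall expression is
deliberately not induced (the observed gut availability is unchanged by
the inducer), and auto-induction of the inducer's own clearance is off by
default (a flag enables it).

## Whole-body ODE system and integration

Sixteen compartments per drug (arterial and venous blood, lungs in series,
thirteen flow-limited tissues) with V_T·dC_T/dt = Q_T·(C_art -
C_T·B:P/Kp_T); the liver additionally receives splanchnic outflow and
F_g × the gut absorption flux, and eliminates fu_b·CLint_h(t)·C_out,liver
(equivalent to the well-stirred form at steady state — a tested
equivalence).  Oral doses enter the stomach solid pool; an IV route exists
for verification oracles.  The full system is linear in the state, so the
integrator (LSODA with events handled by restart at each dose) is fed an
analytically assembled coefficient matrix and exact Jacobian; only the
victim's hepatic elimination coefficients vary in time, through the
inducer's liver concentration and the onset ramp.  The matrix path is
checked against an independent hand-written derivative function in the
suite.  Default contract tolerances are rtol 1e-6 / atol 1e-9 ng; the
trial runner uses atol 1e-6 ng (amounts are of order 1e7 ng), which holds
the global mass-balance defect below 0.1% — a hard test bound.  During
the 14-day inducer lead-in the victim's state block is identically zero,
so the runner integrates the inducer alone and co-integrates both drugs
from day 14; the handover is exact and is itself tested.

## Trial design and PK metrics

The standard design doses efavirenz at 0, 24, ..., 384 h and artemether at
336 + {0, 8, 20, 32, 44, 56} h; the alone arm shifts the artemether
schedule to t = 0.  Metrics are taken over the final 12-h artemether
interval on a ≤ 0.1 h grid: Cmax/Tmax, Ctrough, trapezoidal AUC_tau, and a
second AUC truncated 8 h post-dose.  The 8-h window is the reported
exposure metric: it matches the sampling scheme of the clinical comparator
studies, and the source report's exposure and clearance figures are only
simultaneously reproducible with a truncated window (its printed AUC and
CL/F are mutually inconsistent under AUC = dose/CL).  CL/F = dose/AUC_tau
over the full interval; V/F = CL/F·t_half/ln 2 with the terminal slope
fitted over the last quartile of the post-final-dose curve (flagged
missing if the slope is non-negative).  Population summaries are
median/range and mean ± SD on raw values; interaction ratios are computed
subject-wise in the paired design before summarising.  The dose scan
reruns the combination arm with all six artemether doses scaled (80, 160,
240 mg) in the same subjects and reports the smallest dose whose median
windowed AUC reaches a configurable fraction (default 2/3) of the
inducer-free median.

## What the generator does and does not emulate

Inter-individual variability enters only through anthropometry and organ
physiology (heights, BMI, organ-mass variability, allometric flows); the
drug-specific parameters (CLint, binding, permeability) are fixed
population values.  Real cohorts add large metabolic variability (e.g.
CYP2B6 polymorphism), so the simulated population ranges are narrower than
clinical ones — medians are the meaningful comparison, and passing tests
say nothing about extreme-subject behaviour.  Food effects, regional pH,
colonic absorption, transporters, metabolite (dihydroartemisinin)
kinetics and pharmacodynamics are all out of scope.

## Numerical and design notes

- Problem sizes: the shipped trial uses 50 subjects; the suite runs the
  full paired trial once (about half a minute) plus three seeds of the
  single-drug artemether arm.  These sizes are the study design, chosen to
  match the simulated cohort.
- Dose events are state discontinuities; the solver is restarted at each
  event, and output grids are assembled per inter-dose segment.
- Ties/degenerate inputs: a regimen with no doses yields an all-zero
  profile; a non-positive terminal slope leaves V/F missing rather than
  failing the run; a subject violating physiological invariants is
  resampled, and a run aborts if more than 10% of subjects fail to
  integrate.
- One reported quantity is knowingly not reproduced: the ~60% population
  median Cmax reduction quoted for the interaction.  The same source's
  summary table implies 70% (30 → 9 ng/mL), and a ~6-fold clearance
  increase with an ~80% AUC reduction cannot leave the peak only 60%
  lower in any first-order disposition model; this simulator yields ~77%
  at the matching AUC reduction and clearance fold, robustly across
  absorption-rate and volume assumptions.
- The efavirenz trough under the calibrated ~150 L apparent volume
  (~1200-1400 ng/mL mean) runs below the ~2300 ng/mL reported mean; the
  volume, clearance and trough figures cannot all hold at once with a
  24-h dosing interval.  Clearance and volume (the quantities the
  interaction mechanism depends on) were preferred.
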