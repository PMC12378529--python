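# Methods

## Model

The package computes a proxy for in-situ cardiovascular tissue glycation
from four blood analytes drawn at the same visit. The modelling assumptions
are:

1. glycation is non-enzymatic, irreversible, and proceeds with the same
   reaction dynamics in blood proteins and myocardial/vascular proteins at
   physiological pH (7.35–7.45) and temperature (37 °C), both treated as
   constant;
2. kinetics are linear over the modelled range (the full reaction is
   plausibly nonlinear; linearity is a first-order modelling choice);
3. each protein is characterised by a fixed half-life: A1c 28.7 d,
   fructosamine 16.5 d, LDL 3 d, cTnI 1 d. The cTnI literature spans ~2 h
   to 3.2 d and LDL 2–4 d; the defaults fix one value in each range and are
   overridable configuration;
4. glycation has a physiological optimum, anchored at A1c 31 mmol/mol
   (5.0%) with the glycemia-equivalent fructosamine 200 µmol/L; an
   individual's state is expressed as ratios rA, rF to these optima.

The two ratios are plotted against their substrates' half-lives and joined
by a straight line, `m = (rF − rA)/(16.5 − 28.7)`, `b = rA − 28.7·m`; the
glycation rate of a target protein is the line's value at the target's
half-life (TGR at 1 d, LGR at 3 d). Closed form:
`rate(h) = rF + (rA − rF)(h − 16.5)/12.2`, equivalently the affine
combination `((28.7 − h)/12.2)·rF − ((16.5 − h)/12.2)·rA`, whose
coefficients sum to 1. Because both targets lie below both anchors, the
rate increases in rF and decreases in rA; a panel exactly at the optima
gives rates of 1.0. Indices are TGI = TGR × cTnI and LGI = LGR × LDL.

## Units and rounding protocol

A1c carries an explicit unit tag (NGSP % or IFCC mmol/mol), converted by the
master equation `IFCC = 10.93 × NGSP − 23.50` with the IFCC value reported
at integer precision. Ratios are always formed on the IFCC scale: the
reference ratio 39/31 = 1.26 is only consistent in mmol/mol (the %-scale
quotient 5.7/5.0 = 1.14 does not reproduce any downstream value).

All displayed quantities round half-up (ties away from zero), implemented
in decimal arithmetic on the float's shortest representation so that e.g.
142.5 → 143 and 1.335 → 1.34 exactly. The protocol, load-bearing for
reproducing the reference report tables, is: ratios to 2 dp **before** the
slope-intercept step; rates to 2 dp; TGI to 1 dp; LGI to integer. The
reference tables contain two cells (the earlier report rows' rates, and one
LGR cell printed from unrounded ratios) that differ from this protocol by
one unit in the last place; the tests treat those as print-precision
discrepancies (±0.01 on rates) rather than adopting a second protocol,
because no single convention reproduces every printed cell and this one
reproduces the worked example and the latest report row exactly.

## Classification and screening

Quartile bands are fixed (not population-derived), closed on both printed
endpoints; a value in the gap between consecutive bands (printed bounds sit
at measurement precision) is assigned to the lower band, making
classification total on the modelled range. Band edges derive from the
constants: cTnI spans the 1.6 ng/L detection limit to the sex-specific
exclusion ceiling, rates span 1.0–1.5, TGI band 3 tops at 1.5 × the cTnI
ceiling (6.75 women / 7.5 men), LGI spans 60–270. The LGI range starts at
60 (= 1.0 × 60 mg/dL), the value consistent with its own derivation.
Raising the male cTnI ceiling within the supported 5–7 ng/L window moves
only the male cTnI/TGI band-3/4 edges and male screening.

Screening flags analytes **strictly above** A1c 46 mmol/mol, LDL 180 mg/dL,
cTnI 4.5 (women) / 5.0 (men) ng/L. Screening never errors and never blocks
computation; eligibility is the conjunction of the per-analyte checks.

## Tracking and forecasting

Series are keyed by calendar year (annual cadence; duplicate years are
rejected, longer gaps logged as warnings). Next-year forecasts fit ordinary
least squares per raw biomarker column on the 0-based year index —
calendar-day spacing within years is ignored — and evaluate one step ahead.
Predictions are rounded at the column's reporting precision first (A1c
1 dp %, fructosamine/LDL integer, cTnI 1 dp) and the metrics then
recomputed from the rounded forecasts, so a predicted row obeys the same
internal identities as an observed one. An alternative `column-ols` mode
extrapolates the metric columns directly; neither mode is privileged by the
reference material, and recomputation was chosen for internal consistency.
The horizon is fixed at one year: individual biomarker drift under ageing,
health changes and medication makes longer extrapolation unreliable. A1c is
regressed on the % scale (at annual increments the two scales give
consistent rounded predictions).

Diagnostics: the glycation gap rA − rF is flagged when |gap| > 0.15 by
default — the threshold is a configurable placeholder, not an empirically
derived constant — and year-over-year divergence notes annotate cTnI rising
without a TGR rise (non-glycation factor suspected) and cTnI+LDL falling
together (consistent with LDL-lowering intervention).

## Burden simulation

Cumulative excess glycation over a span is the trapezoidal AUC of the index
trajectory **above its baseline** (raw-index AUC would be dominated by the
baseline rectangle and does not measure excess exposure). The default path
is linear in index space from the baseline to the endpoint index, where the
endpoint is the rate × concentration product rounded at the index's display
precision before integration; for such a path the AUC is exactly
`span × (endpoint − baseline)/2` on any grid with ≥ 2 points (the default
grid is 301 points over 30 years). The built-in 30-year archetypes start at
the optimum (TGI 1.6, LGI 60 at age 25) and end at: normal TGR 1.11 / cTnI
2.6 / LGR 1.11 / LDL 100; prediabetic TGR 1.24 / cTnI 3.4 / LGR 1.25 /
LDL 140 — giving excess burdens of 19.5 vs 39 TGI-years (2.0-fold) and 765
vs 1725 LGI-years (2.3-fold). A `component-linear` mode interpolates rate
and concentration separately (a quadratic index path, e.g. ≈18.7 instead of
19.5 for the normal TGI drift); it is offered for sensitivity analysis.

## Synthetic cohorts

The generator emulates the two archetypes as linear biomarker drift plus
independent per-draw Gaussian noise (defaults: 0.1 %-units A1c — scaled by
10.93 to the internal IFCC scale — 5 µmol/L fructosamine, 0.2 ng/L cTnI,
5 mg/dL LDL; all configurable, chosen as plausible assay-scale noise for
fixtures). The archetype biomarker endpoints are a package design choice —
the reference material prints only rate/concentration endpoints — selected
so the noise-free year-30 panel reproduces the archetype rates exactly
under the rounding protocol: normal A1c 31→34.4 mmol/mol and fructosamine
200→222 µmol/L (rA = rF = 1.11 ⇒ TGR = LGR = 1.11); prediabetic A1c
31→42.8 and fructosamine 200→264 (rA 1.38, rF 1.32 ⇒ TGR 1.24, LGR 1.25).
Draws are annual (sub-annual intervals are rejected because series are
year-keyed), values are truncated at 10% of the start value so panels
always validate, and a fixed seed yields bit-identical cohorts.

What the generator does **not** emulate: within-person autocorrelation,
assay drift and inter-assay variability, intercurrent illness, smoking or
anemia effects, medication changes, or nonlinear ageing trends. Tests
passing on these cohorts therefore demonstrate pipeline correctness under
the stated drift-plus-noise model, not clinical validity on real series.

## Numerical choices

* Half-up rounding throughout via `decimal` on `repr(float)` — binary-safe
  and deterministic.
* OLS via `numpy.polyfit` (degree 1); cross-checked in tests against the
  normal-equations closed form and statsmodels.
* Trapezoidal integration via `numpy.trapezoid`.
* Degenerate geometry (equal anchor half-lives) is rejected at constant
  construction and again at the slope computation.
* Negative-slope panels (rF > rA, rates above both anchors) compute
  normally; the glycation-gap flag is the intended detector for the large
  discrepancies that produce them.
* A strict half-life ordering A1c > fructosamine > LDL > cTnI is enforced
  on configuration so the extrapolation geometry is always downward.

## Limitations

The model is theoretical: linear kinetics, fixed half-lives, constant
pH/temperature, and no adjustment for smoking, anemia, illness or assay
variability (handled clinically, not algorithmically). Single panels carry
little information by design; the tool's outputs are monitoring aids, not
diagnostic or treatment recommendations. Forecasts are one-year only.
Multi-year extrapolation, AGE-concentration estimation and missing-analyte
imputation are out of scope.
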