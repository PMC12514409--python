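# Methods

## Model structure

The engine is a deterministic expected-value cohort recursion: fractions of
a closed cohort ("masses", not individuals) move between health states in
one-year cycles from age 50 to age 100.  Health states are *susceptible*
(never diagnosed, subdivided by screening sub-state), *diagnosed* with CRC
by stage 1–4 and years since diagnosis (a five-year tunnel), *cured*, and
three absorbing death states (other-cause, CRC, colonoscopy perforation).
A seeded individual-level microsimulation (`colocea.microsim`) implements
the identical transition kernel and serves as a statistical oracle in the
test suite; it is never the primary computation path.

Within each cycle events are applied in a fixed order — (1) other-cause
death from the life table, (2) screening events and their complications,
(3) CRC incidence with stage assignment, (4) stage-specific CRC death and
cure-clock advance, (5) accruals.  The order matters at the third
significant figure and is part of the model definition.  Deaths are
end-of-year events; no half-cycle correction is applied, mirroring a simple
annual-cycle spreadsheet cohort model.

## Screening pathways

FIT arms offer an annual FIT to everyone in the testing pool (uptake 60%
per offer, independently each year).  Positivity is the sum of true and
false positives, `sens·prev + (1−spec)·(1−prev)`; the point prevalence a
FIT can detect is proxied by the age-specific annual incidence rate, which
keeps the recursion linear (the false-positive term dominates: 8.1% versus
≲0.3%).  Positives proceed to colonoscopy (uptake 100% at base case).
Therapeutic colonoscopies (polyps removed, probability 73%) trigger
3-yearly surveillance until a polyp-free visit; polyp-free participants
pause for 10 years before resuming annual FIT.  Direct arms offer a primary
colonoscopy (uptake 98.9%), repeat it after 10 years when clean, and use
the same surveillance loop.  The per-visit polyp-finding probability at
surveillance reuses the 73% polypectomy rate (no separate recurrence
estimate exists); both are overridable.

Protection against incidence is attached to the last procedure a mass
actually received:

* the FIT-level reduction (21%) applies in the year a FIT is taken;
* the colonoscopy-level reduction (44.2% conventional, 48.9% AI-assisted)
  applies while a mass is in a post-colonoscopy state (hiatus,
  surveillance, or the 10-year repeat track).

This state-dependent rule is what makes FIT followed by AI-assisted
colonoscopy strictly more effective than FIT followed by conventional
colonoscopy, as the source analysis found.  The headline programme-level
quantity `effective_incidence_reduction` remains the simple product of
modality efficacy and primary-test uptake.  Participants who miss a
scheduled surveillance or repeat colonoscopy drop back to the unprotected
pool (FIT arms re-engage them through annual FIT): protection is
conditional on staying on schedule, since the efficacy estimates come from
adherent screening programmes.  Diagnosed patients are not screened; cured
patients are neither re-screened nor at further CRC risk (recurrence
management is out of scope).

Complications apply per colonoscopy (bleeding 0.98%, perforation 0.08%);
perforation mortality (0.0029%) is interpreted per perforation event, with
a per-colonoscopy basis switchable.  Perforation deaths are
procedure-related: they accrue life years lost into a ledger separate from
the cancer-related total.

## Incidence conventions

Age-specific annual incidence is piecewise constant on quinquennial bands
(55.9, 89.8, 137, 200, 253.2 per 100,000 for ages 50–74, half-open bands;
330.5 for 75+).  By default new cases arise only during the follow-up
window, ages [50, 75), with other-cause attrition; under this convention
the unscreened cohort accrues ≈3,232 cases per 100,000, matching the
published base-case count to 0.02%.  The `incidence_stop_age` switch
extends case accrual beyond 75 (activating the sixth band) for
residual-lifetime analyses.

## Life table and life years lost

The published analysis used the Hong Kong standard life table, which is not
reproduced in print.  The bundled stand-in is a synthetic Gompertz–Makeham
table, `qx(age) = 1 − exp(−(c + a·e^{b·age}))` with a = 2×10⁻⁵ /yr,
b = 0.095 /yr, c = 5×10⁻⁴ /yr, closed at age 100.  Its residual life
expectancy at 50 is 33.6 years — chosen once to emulate a high-longevity
East-Asian population — so all absolute life-year magnitudes are stand-in
dependent and tolerance-based, while within-model comparisons (orderings,
dominance) are not.  Expectations are curtate (survival-product sums);
each CRC death at age *a* in cycle *t* forfeits `ex(a)` undiscounted years
and a discounted amount whose clock is anchored at model start (first lost
year discounted by `(1+r)^−(t+1)`), keeping life-year and cost discounting
on one timeline.  Discounting from the year of death instead is available
via the `years_from_model_start` offset.

## Costs

Money is discounted at 3%/year to model start; event counts are reported
undiscounted.  Cancer care is charged as a single stage-specific lump sum
($17,071 / $19,755 / $26,883 / $45,115 for stages 1–4) in the diagnosis
year — the published stage totals already bundle diagnosis, treatment, and
a 9-day admission, and no spreading rule is specified.  A consultation fee
($96) is charged once per colonoscopy attendance and histopathology ($142)
once per therapeutic colonoscopy; both attachments are toggles because the
source tables do not pin them down (their implied per-procedure costs
suggest the original analysis charged neither).  AI-assisted and
conventional colonoscopy share the $1,259 unit cost; the one-time AI device
cost is excluded.  Indirect costs are out of scope.

## Parameters

All rates are fractions; the complete base case is in
`colocea.config.basecase()` and exportable as a flat manifest.  Notable
interpretation choices: the printed stage distribution sums to 100.1% and
is renormalized preserving ratios; the stage-mortality table's row labelled
"5" is read as stage 4; the narrative's 51.5% colonoscopy efficacy is
shipped as a named alternative scenario (`colonoscopy_reduction_51.5`)
while the tabulated 44.2%/48.9% are the base case.

## Sensitivity analysis

One- and two-way deterministic sweeps re-run the full comparison on a
parameter grid; `compliance.all` moves FIT, primary, and follow-up uptake
together (the convention for programme-uptake analyses).  Default grids:
compliance 0.10–1.00 in steps of 0.10, FIT specificity 0.20–0.919 in 8
steps, FIT sensitivity 0.40–1.00 in 7 steps, colonoscopy cost 0.5×–2×
base.  Threshold detection reports sign changes of any criterion curve by
linear interpolation between adjacent grid points.  No probabilistic
sensitivity analysis is included by design.

## What the synthetic data do and do not show

The synthetic life table reproduces smoothly increasing adult mortality and
high longevity but not sex structure, cohort (period) effects, or the exact
Hong Kong schedule; absolute life-year and cost totals therefore
demonstrate internal consistency, not calibration to registry data.
Passing tests show the recursion, pathways, accounting, and comparison
arithmetic are correct and mutually consistent (cohort engine versus
independent microsimulation, closed forms, conservation laws) — they do not
validate the clinical parameter estimates themselves.

## Numerical choices

Masses are float64; total mass (occupancy plus cumulative deaths) is
conserved to ≲10⁻¹⁰ of a 100,000-person cohort over the full horizon.
Currency is float64 internally; file exports use fixed decimal formatting
so repeated runs are byte-identical.  Presentation rounding (integer
counts, whole dollars, one-decimal percents) is half-up and applied only at
rendering; all comparisons use unrounded internals.  Pairwise ICERs with
equal effectiveness return an explicit `undefined` flag instead of
dividing.  Note that the ICER is invariant under swapping the two
strategies (both differences negate); only the dominance orientation flips.

## Known limitations

* No adenoma→carcinoma natural-history sub-model: prevention enters only
  through the modality-level incidence-reduction fractions.
* No stage shift under screening: one stage-at-diagnosis distribution
  serves all arms (a `screened_stage_distribution` hook ships disabled).
* FIT-arm procedure volumes follow mechanically from annual re-offer at 60%
  uptake and 8.4% positivity, giving far more FITs and follow-up
  colonoscopies (and correspondingly more prevented cases) than the
  published counts, whose re-offer mechanics are not recoverable from the
  printed figures; FIT-arm absolute counts should be read as
  model-internal, not calibrated.  A consequence is that annual FIT is this
  model's cheapest effect generator, so the ICER *rises* with programme
  compliance in the FIT arms, the direct arms being nearly flat — the
  opposite direction to the published compliance analysis, which is
  consistent only with FIT mechanics that make the FIT component the least
  efficient one.
* The published bleeding counts (≈0.2% of colonoscopies) are inconsistent
  with the stated 0.98% bleeding rate under any per-procedure basis; the
  stated rate is implemented unmodified.
* QALYs, willingness-to-pay acceptability, recurrence surveillance after
  cure, and population-level extrapolation are out of scope.
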