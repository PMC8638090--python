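# Methods

`akicea` implements a decision-analytic cost-effectiveness and
value-of-information model for biomarker-guided detection of acute kidney
injury (AKI) in hospitalised adults: a 90-day diagnostic decision tree
linked to a lifetime six-state chronic kidney disease (CKD) Markov cohort
model, analysed probabilistically with cost-effectiveness acceptability
curves (CEACs), an ICER dominance frontier, and expected value of
(partial) perfect information (EVPI/EVPPI).

## Decision problem

Five strategies are compared for a UK hospital cohort (entry age 63,
54.3% female) at risk of AKI: standard care (serum-creatinine and
urine-output monitoring) and four biomarker tests used alongside it —
NephroCheck (urinary TIMP-2·IGFBP-7) and three NGAL assays (plasma
BioPorto, urine BioPorto, urine ARCHITECT).  Test positives receive a
three-day preventative KDIGO care bundle (£106.36).  Only true positives
realise treatment benefits.  NephroCheck is assumed able to *avert* AKI
(it detects kidney stress before damage); the NGAL tests may reduce
severity but not prevent AKI.

## 90-day decision tree

Each tested cohort splits into TP/FN/FP/TN branches from the prevalence
and a per-draw (sensitivity, specificity) pair.  Within the TP branch the
care bundle:

- averts AKI with absolute risk reduction ARR = 16.6% (95% CI 5.5–27.99%)
  applied to the TP-branch prevalence (the AKI risk among test positives,
  i.e. the positive predictive value), capped at that prevalence.  The
  bundle trial population was test-positive, which is why the absolute
  effect attaches to this branch;
- shifts the conditional KDIGO stage distribution downward through a
  lower-triangular severity operator (default: a configurable fraction of
  each stage moves one stage milder — the source trial supports severity
  reduction but prints no matrix).

Averting or mitigating AKI does not automatically confer the full
observed outcome gap between AKI and non-AKI patients, because those
observational associations are partly confounded.  Attenuation fractions
interpolate each outcome between the would-be and the target stage:
full effect on CKD risk (f_ckd = 1), half on ICU need and length of stay
(f_icu = f_los = 0.5), none on 90-day mortality (f_mort = 0).  RRT
probability is attenuated with f_icu: ICU admission and kidney support
are grouped as critical-care outcomes and no separate fraction is
published.  False negatives follow standard care (AKI is eventually
caught by creatinine monitoring); false positives incur bundle costs
only in the base case, with a mortality relative risk (1.5) available in
scenario analysis for the harm of unnecessary nephrotoxic-treatment
withdrawal.

90-day QALYs value in-hospital days at the acute in-hospital utility and
the remaining days at the post-discharge utility; decedents are credited
half the interval (timing of death within the window is not published).
Expected in-hospital days are capped at 90.

Day-90 survivors are handed to the Markov model split over {No CKD,
CKD 1–4}.  The CKD share combines the background CKD prevalence (11.05%)
with stage-specific hazard ratios for incident CKD, attenuated by f_ckd
for averted/mitigated cases.

## Lifetime Markov model

Six states: No CKD, CKD 1–4, ESRD, dialysis, post-transplant, death, in
annual cycles from age 63 to an age cap of 100 (the published horizon is
"lifetime" without a stated cap).  Reversion to milder states is
structurally impossible; the only two-way traffic is dialysis ↔
post-transplant (graft failure returns to dialysis, after which a further
transplant is permitted, without limit).  CKD 1–4 is a single averaged
state: stage-by-stage progression and CKD regression are deliberately out
of scope, in line with conventional kidney-disease models.

Mortality composes state-specific relative risks with age/sex-mixed
general-population annual death probabilities multiplicatively on the
survival scale, q = 1 − (1 − qx)^RR; base transitions are renormalised
over survivors.  A max(disease-specific, general) composition would be an
alternative; the multiplicative form is used throughout and is the main
structural assumption a user might wish to vary.

Rewards use the trapezoidal (life-table) half-cycle correction — the mean
of cycle-start and cycle-end occupancy — applied to both costs and QALYs.
Utilities are adjusted multiplicatively by population norms,
base · norm(age)/norm(63), so quality of life declines naturally with
age.  Costs and QALYs beyond the first model year are discounted at 3.5%
per annum (cycle 1 undiscounted).  The decision tree covers days 0–90
undiscounted and Markov cycle 1 is treated as the first model year, so no
additional lag discounting is applied at the handoff.

Sex is handled as a cohort mix (female-fraction weighting of lifetable
and norms), not as two separate cohorts, consistent with a cohort model
of a 54.3%-female population.

Because lifetime outcomes are linear in the day-90 start split, each PSA
draw needs only two Markov unit runs (pure No CKD and pure CKD starts);
arm-level results are mixtures.  Scenario variants that stratify the
continuation (by ICU exposure or AKI exposure) add further unit runs.

## Parameter uncertainty and sampling

Distribution families follow the standard health-economics convention
(none are stated in the source): beta for probabilities and utilities,
gamma for costs and lengths of stay, lognormal for hazard/risk ratios,
and a bivariate logit-normal for joint (sensitivity, specificity) with
the published between-measure correlation.  Perfect correlation
(rho = −1, the plasma NGAL row) uses an explicit rank-1 construction
(z_sp = −z_se) rather than a generic covariance factorisation, which
rejects singular matrices.  Structural constants (discount rate, horizon,
attenuation fractions) are fixed in the PSA.

One global seed expands into independent per-parameter substreams keyed
on a stable hash of the parameter name, so adding or removing a parameter
never perturbs the other parameters' draws, and identical (parameters,
n, seed) give bit-identical draw matrices.

Beta distributions are constructed from published (mean, 95% CI) triples
by a concentration search holding the mean exact; when the printed CI is
a normal-approximation interval that no beta with that exact mean can
carry (the care-bundle ARR is such a case), both shapes are freed and
the interval is matched instead — for the PSA it is the propagated
uncertainty that must reproduce the evidence, while the point estimate
is carried separately for deterministic runs.  Gamma parameters are
moment-matched (shape = mean²/SE², scale = SE²/mean); SE = 0 degenerates
to a fixed value.

## CEA aggregation

ICERs are computed on unrounded means.  The frontier excludes strictly
dominated strategies (weakly more costly and weakly less effective, at
least one strict) and then extendedly dominated ones (incremental ICERs
along the frontier must strictly increase).  Extended dominance is
implemented even though the published base case needs only strict
dominance, because arbitrary inputs require it.  CEAC probabilities are
per-draw argmax-NMB frequencies over a £0–£50,000 grid (£500 steps,
always containing £20,000); NMB ties break to the lower-cost strategy
and then to registration order, so curves are deterministic.

## Value of information

EVPI per patient is mean(max_s NMB) − max_s(mean NMB) at £20,000/QALY
for the NephroCheck versus standard-care comparison.  Population scaling
multiplies by the annual caseload (564,738 AKI episodes) and the
ten-year decision horizon, undiscounted by default — this convention
reproduces the published population figure, whereas a 3.5% annuity does
not; a discounted annuity-due factor is available as an option.

EVPPI uses the single-loop regression estimator (the method class of the
SAVI tool): each strategy's mean-centred NMB is regressed on the
parameter subset with an additive cubic B-spline basis (quantile interior
knots, one basis column dropped per block for identifiability next to
the intercept, ~n/20 basis functions shared across the subset so large
groups do not overfit), and the EVPI formula is applied to the fitted
conditional expectations, clipped at zero.  Rank-deficient designs halve
the basis dimension with a warning.  Group EVPPI (baseline
probabilities, costs, utilities, relative effects) runs the same
estimator on the multivariate subset with the same additive basis.

## Synthetic fixture

The published analysis prints its pooled accuracy table, the bundle
effect, the decision context and the attenuation fractions, but keeps
per-stage acute outcomes, unit costs, utilities, Markov transitions and
demographic tables in unpublished supplementary material.  The fixture
embeds every printed value verbatim and flags everything else
``placeholder=True`` so tests asserting published numbers can never
touch a stand-in.  Placeholders were chosen once as clinically plausible
UK NHS magnitudes: AKI prevalence 15% in a monitored at-risk inpatient
cohort; KDIGO stage mix (0.55, 0.25, 0.20); ICU need, RRT need, length
of stay and 90-day mortality all worsening with stage; CKD hazard ratios
1.9/2.5/3.8 by stage; ward day £346 versus ICU day £1,306; utilities
ordered No CKD > CKD 1–4 > post-transplant > ESRD ≈ dialysis; a Gompertz
lifetable (a = 2.27e-5, b = 0.095, female hazard scale 0.75) giving
UK-like annual death probabilities; linearly declining population
utility norms.

What the fixture does and does not show: it exercises every structural
mechanism (classification branches, bundle effects, attenuation,
handoff, Markov progression, discounting, dominance, CEAC, VOI) with
valid, realistically scaled inputs, so passing tests demonstrate the
machinery, not the published conclusions.  Under these placeholder
magnitudes the care-bundle effect is strong relative to test and bundle
costs, so NephroCheck dominates in essentially every draw and the
fixture's own EVPI is ~£0 — unlike the published analysis, whose
parameter tables imply far smaller, highly uncertain incremental
effects.  The published base-case strategy means are therefore carried
as an explicit fixture input for frontier tests rather than recomputed.

## Numerical choices and degenerate inputs

- 95% intervals use the exact normal quantile 1.959964…, required to
  round-trip the published 2-dp accuracy intervals.
- Branch weights are validated to sum to 1 (1e-9); Markov rows to 1e-12;
  occupancy conservation to 1e-10 per cycle.
- ARR above the branch prevalence is capped with a logged warning;
  day-90 CKD shares outside [0, 1] are clamped with a warning; acute
  outcome tables that are not monotone in KDIGO stage warn but do not
  error (sampled draws may legitimately cross).
- Problem sizes: 1,000 PSA draws for headline runs (the published draw
  count), 10⁵ draws for sampling-moment checks, 10⁴ draws for VOI toy
  validations.

## Known limitations

- Patient-level heterogeneity, time-varying within-90-day hazards and
  biomarker threshold (ROC) modelling are out of scope.
- Correlations are modelled only between sensitivity and specificity;
  other parameters are sampled independently (no published correlations).
- The ICU-dependent long-term scenario assumes CKD share and ICU
  exposure are independent within an arm when mixing Markov runs.
- Expected value of sample information (EVSI) and bootstrap CIs on EVPPI
  are not implemented.
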