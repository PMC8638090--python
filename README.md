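# akicea

Decision-analytic cost-effectiveness and value-of-information model for
biomarker-guided detection of acute kidney injury (AKI) in hospitalised
adults, from a UK NHS perspective.

Early AKI detection with urinary/plasma biomarkers (NephroCheck, NGAL
assays) may allow a preventative KDIGO care bundle to avert or mitigate
kidney damage, reducing ICU admission, renal replacement therapy,
length of stay, chronic kidney disease (CKD) and mortality.  Whether
that is worth the testing cost is a classic linked-evidence problem:
diagnostic accuracy comes from a meta-analysis, treatment effect from a
care-bundle trial, and outcome links from observational cohorts.  This
package implements the full machinery for that question, aimed at health
economists and methodologists who need a tested, scriptable
re-implementation rather than a spreadsheet or TreeAge model:

- a **90-day decision tree** over TP/FN/FP/TN classification branches,
  with care-bundle AKI aversion (absolute risk reduction 16.6%, 95% CI
  5.5–27.99%), KDIGO severity down-shifting, and attenuated outcome
  effects (full on CKD risk, half on ICU/LOS, none on 90-day mortality);
- a **lifetime six-state Markov cohort model** (No CKD, CKD 1–4, ESRD,
  dialysis, post-transplant, death) in annual cycles with half-cycle
  correction, age/sex-adjusted mortality and utilities, 3.5% discounting;
- **probabilistic sensitivity analysis** (beta/gamma/lognormal families,
  bivariate logit-normal accuracy with the published correlations,
  reproducible per-parameter random substreams);
- **CEA aggregation**: net monetary benefit, strict and extended
  dominance, incremental ICERs, cost-effectiveness acceptability curves;
- **value of information**: EVPI and regression-based EVPPI
  (additive B-spline estimator, SAVI method class), with population
  scaling (564,738 AKI episodes/year over a 10-year horizon);
- a **synthetic fixture** embedding every published constant verbatim and
  flagged, clinically plausible placeholders for the unpublished
  supplementary parameter tables, so everything runs and tests offline.

Core quantities, in the field's usual notation: classification
probabilities (p·Se, p·(1−Se), (1−p)·(1−Sp), (1−p)·Sp); NMB = λ·QALY −
cost at willingness-to-pay λ = £20,000/QALY; state mortality
q = 1 − (1 − qx)^RR; EVPI = E[max_s NMB_s] − max_s E[NMB_s].

## Worked example

```python
from akicea import default_config, run_psa, basecase_table, ceac, run_voi

config = default_config(seed=0)            # synthetic base-case fixture
results = run_psa(config, n_draws=1000, seed=42)
print(basecase_table(results).to_string(index=False))
```

prints (fixture values — the unpublished supplementary tables are
replaced by flagged placeholders, so these are *not* the published
results):

```
            strategy         cost incremental_cost      qaly incremental_qaly icer_incremental  icer_vs_reference      status  p_ce  p_ce_vs_reference
         nephrocheck  9840.268535      -217.948316 11.027263         0.019513             None      -11169.576772 on_frontier   1.0              1.000
 ngal_urine_bioporto 10057.736054        Dominated 11.010225        Dominated        Dominated        -194.281495   dominated   0.0              0.949
       standard_care 10058.216852        Dominated 11.007750        Dominated        Dominated                NaN   dominated   0.0                NaN
ngal_urine_architect 10067.196811        Dominated 11.010028        Dominated        Dominated        3941.292779   dominated   0.0              0.898
ngal_plasma_bioporto 10070.626888        Dominated 11.010286        Dominated        Dominated        4892.466928   dominated   0.0              0.890
```

Each row is one strategy's mean discounted lifetime cost and QALYs per
patient across 1,000 draws; `status` is the dominance classification,
`p_ce` the probability of being the most cost-effective strategy at
£20,000/QALY, and `p_ce_vs_reference` the pairwise probability of beating
standard care.  Under the fixture's placeholder magnitudes the
care-bundle effect is strong relative to test costs, so NephroCheck
dominates; with the published (unpublished-supplement) inputs the tests
were instead slightly costlier with tiny QALY gains.  Feeding the
published strategy means to the same frontier code reproduces the
published structure — the three NGAL strategies dominated, standard care
and NephroCheck on the frontier:

```python
from akicea import REFERENCE_BASECASE_MEANS, StrategyOutcome, frontier
outcomes = [StrategyOutcome.from_means(s, c, q)
            for s, (c, q) in REFERENCE_BASECASE_MEANS.items()]
for e in frontier(outcomes, reference="standard_care"):
    print(e.strategy_id, e.status)
```

## Analysis scripts and CLI

The `analysis/` drivers run the study end to end, writing tables under
`results/`:

```bash
python analysis/01_build_fixture.py      # emit the synthetic fixture
python analysis/02_basecase_frontier.py  # point estimates + published-means frontier
python analysis/03_psa_ceac.py           # 1000-draw PSA, base-case table, CEAC
python analysis/04_voi.py                # EVPI / EVPPI ranking
python analysis/05_scenarios.py          # structural scenarios 1-12
```

The same operations are available as a CLI:

```bash
akicea fixtures -o fixtures
akicea psa --config fixtures/fixture.yaml --draws 1000 --seed 42 -o results
akicea voi --draws 1000 -o results
akicea scenario 12 -o results            # FP mortality RR = 1.5
```

Every run logs the resolved configuration, seed and a content hash to
`run_log.json`; identical seeds give byte-identical outputs.

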