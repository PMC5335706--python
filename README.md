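# pres — personalized regimen selection for neoadjuvant breast-cancer chemotherapy

`pres` implements PRES (Personalized REgimen Selection), a pipeline for
choosing among three neoadjuvant chemotherapy regimens — anthracycline
alone (**A**), paclitaxel plus anthracycline (**TA**), and docetaxel plus
anthracycline (**TxA**) — from bulk gene-expression profiles and clinical
covariates, using pathological complete response (pCR) versus residual
disease (RD) as the outcome. It is aimed at biostatisticians and
computational biologists working on individualized treatment rules for
multi-cohort microarray data.

The method, per treatment arm:

1. **Screening.** A Welch two-sample t-test per probe between pCR and RD
   patients at significance level α = 0.05, followed by random sampling
   screening (RSS): repeated response-stratified patient subsamples and
   random probe subsets, a random forest per draw, and ranking by how often
   a probe lands in the top *q* of a draw's importance ranking.
2. **Response model.** A random-forest classifier over the clinical
   encoding (age plus indicator-coded ER/PR/HER2 status) and the top-*k*
   ranked probes, with *k* chosen by stratified 5-fold cross-validation
   maximizing the F₀.₅ score,
   F_β = (1+β²)·P·R / (β²·P + R) with β = 0.5,
   which weights precision over recall — appropriate under low pCR
   prevalence. *k* = 0 is the clinical-only model.
3. **Calibration.** Out-of-fold predicted probabilities (10-fold; the
   whole pipeline refit inside each fold) are partitioned into five
   equal-width probability intervals (PIs) on [0, 1]; each interval's
   **pCR score** is its observed pCR fraction, the MLE of the expected pCR
   rate for patients mapped to that interval.
4. **Assignment.** Each patient's three predicted probabilities map
   through the three PI tables; the regimen with the highest pCR score is
   assigned, except that A is preferred when its score is within ±0.01 of
   the best taxane score (toxicity rule). The expected number of pCR cases
   is the sum of assigned scores; its 95% CI comes from 1000 redraws of
   the bin scores from truncated Gaussians with binomial standard errors.
5. **Validation.** Leave-one-study-out (LOSO) across cohorts,
   receptor-status strata (HER2−, and HER2−/ER− restricted to TA/TxA), and
   a one-sided Welch test that drug-resistant cell lines receive lower
   predicted pCR probabilities than sensitive ones.

Because the original patient-level cohorts are external, the package ships
a first-class synthetic generator (`pres.simulate`) that emulates their
structure — seven cohorts, arm totals 139/730/210, arm prevalences
8.6/19.7/30.5%, sparse per-regimen signatures, cohort batch shifts — with
full ground truth, so every stage is testable against known answers.

## Worked example

```python
from pres import (PipelineConfig, SimulationConfig, simulate, small_design,
                  fit_pres, assign_patients, oracle_policy_value,
                  single_regimen_values)

config = SimulationConfig(seed=3, n_probes=1000,
    cohort_design=small_design({"A": 600, "TA": 600, "TxA": 600}, n_cohorts=3))
dataset, truth = simulate(config)

profile = PipelineConfig.desk_scale()
fit = fit_pres(dataset, profile, seed=11)
for regimen, model in fit.models.items():
    print(regimen, "k* =", model.k_star_)

result = assign_patients(dataset, fit, profile, mode="toxicity")
print("expected pCR rate:", round(result.expected_pcr_rate, 3))
print("oracle value:", round(oracle_policy_value(truth, result.patients["assigned_regimen"]), 3))
print("single-regimen oracle values:",
      {r: round(v, 3) for r, v in single_regimen_values(truth).items()})
```

Output from this exact run:

```
A k* = 4
TA k* = 13
TxA k* = 30
expected pCR rate: 0.342
oracle value: 0.329
single-regimen oracle values: {'A': 0.082, 'TA': 0.186, 'TxA': 0.294}
```

The probe-count selection recovers the planted signature sizes (4/13/30);
assigning every patient the regimen with the highest calibrated pCR score
yields a true (oracle) response rate of 32.9%, versus 29.4% for giving
everyone the best single regimen — the gain personalization buys on this
dataset.

A CLI mirrors the library: `pres simulate`, `pres screen`, `pres run-all`,
`pres assign`, `pres validate-loso`, `pres stratify`.

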