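# psdoc

Performance status (PS) — the ECOG/WHO/Zubrod grade (0 fully active … 4
completely disabled) or the Karnofsky score (100 perfect health … 10
moribund) — drives treatment decisions and trial eligibility in oncology,
yet it is rarely recorded as structured data.  `psdoc` measures how often
PS is actually written down in cancer patients' electronic health records,
and what predicts its documentation, using only claims codes and free-text
reports:

* **Rule-based extraction** of PS mentions from (French) clinical text:
  a single pattern over the keyword aliases (ECOG, PS, OMS, WHO, Zubrod,
  Karnofsky, IK, performance status), with negation scoping ("PS is not
  0", "le PS n'est pas à 2") and family-context scoping ("mère : PS 3"),
  and hard guards against decoy tokens (PSA values, IPS indices, phone
  numbers, vitals).
* **Incident-cancer cohort construction** from dated ICD-10 claims: first
  cancer code with a 24-month washout, cancer-site grouping and hospital
  assignment from that first code, an explicit exclusion cascade (adults,
  hospital share ≥ 1% of diagnoses, sex/site consistency, at least one
  report), document windowing to −90/+365 days of diagnosis, and
  metastatic-at-diagnosis (C77–C79 within +90 days) and one-year-mortality
  outcomes.
* **Prevalence statistics**: patient- and document-level documentation
  proportions with stratified cross-tabs, Spearman's ρ between hospital
  volume and documentation, and mortality split by documentation status.
* **Logistic modelling** of P(PS documented) with sex, age as a restricted
  cubic spline (3 knots at the 0.10/0.50/0.90 quantiles), cancer group,
  hospital, and per-type report counts — fitted with and without
  metastatic status — reporting odds ratios with Wald 95% CIs.
* **A synthetic-data generator** that emulates all three input tables
  (patients, claims events, annotated documents) with known ground truth,
  so the whole pipeline is testable end to end without access to any real
  clinical data warehouse.

The core model is a binomial GLM with logit link,

    logit P(has_ps_i = 1) = β₀ + β_sex·male_i + f_rcs(age_i) + β_group(g_i)
                           + β_hosp(h_i) + β_mdt·n_mdt,i + β_cons·n_cons,i
                           + β_hosp_doc·n_hosp,i [+ β_met·met_i]

where `f_rcs` is the natural cubic spline (linear beyond its boundary
knots) and `has_ps` means at least one clean (non-negated, non-family) PS
mention in any in-window report.

## Worked example

Run the whole pipeline on a simulated 500-patient world:

```
psdoc run-all --seed 7 --out demo
cat demo/summary.txt
```

prints

```
PS documentation pipeline summary
=================================
patients in cohort:            468
patient-level PS prevalence:   0.470
1-year mortality, with PS:     0.214
1-year mortality, without PS:  0.137
document-level PS prevalence:  0.249
  consultation                 0.215
  hospitalization              0.335
  mdt                          0.196
extractor accuracy (overall):  1.000
extractor macro F1 (overall):  1.000
```

Reading this: of the 500 simulated patients, 468 survive the exclusion
cascade (the step-by-step counts are in `demo/exclusions.log`); 47% of
them have a PS documented within −90/+365 days of their first cancer
code; patients *with* a documented PS die more often within a year (21%
vs 14%) — the informative-presence pattern in which clinicians write the
score down more readily for sicker patients; about a quarter of in-window
reports contain a score, most often hospitalization reports.  The run
directory also contains `cohort.csv`, per-hospital and per-cancer-group
prevalence tables, `coefficients.csv` with ORs and 95% CIs for both model
variants, and `mentions.jsonl` with every extracted mention and its
offsets.  Each stage is also available as its own verb (`simulate`,
`extract`, `cohort`, `stats`, `fit`) and as library functions.

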