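# Methods

## The measurement problem

A performance status is only usable as real-world evidence if it was
written down.  `psdoc` treats documentation itself as the outcome: a
patient "has a PS" when at least one clinical report dated within −90 to
+365 days of their first cancer ICD-10 code contains a clean score
mention.  Everything below serves that definition: the extractor decides
"clean mention", the cohort builder decides "first cancer code" and "in
window", and the statistics and models describe who gets documented.

## Rule-based extraction

One compiled pattern captures a keyword alias (ECOG, PS, OMS, WHO,
Zubrod, performance status, Karnofsky, IK, indice de Karnofsky; matched
case-insensitively at word boundaries, longest alternative first)
followed by a value, optionally through a short closed-lexicon infix of
connectors/copulas/negation words (`:`, `=`, à, de, is, was, est, était,
not, non, pas, n'est, coté, évalué, score).  The infix is what lets the
canonical negated form "PS is not 0" surface as a mention at all, so that
negation scoping — not the matcher — rejects it.  Value semantics:

* ECOG-family keywords accept 0–4 (optionally `/4`); a bare ECOG-family
  keyword with a value in {10, 20, …, 100} (e.g. "PS 80") is read as a
  Karnofsky score, the value range being the safest arbiter of mixed
  conventions.
* Karnofsky-family keywords accept 10–100 in steps of 10, optionally
  with `%` or `/100`.
* Ranges ("PS 1-2") yield one mention with `value` and `value_upper`;
  presence, not the exact value, is the analysis outcome.
* Word-boundary guards make embedded tokens (PSA, IPS, psychologique)
  unmatchable, and a trailing-digit guard kills dates and lab values.

Qualification is sentence-scoped (periods and newlines):

* **Negation** — a cue (not, no, pas, non, sans, aucun(e), ni, jamais)
  within the 5 tokens preceding the mention or inside it.  The window
  default mirrors common clinical-NLP negation-scope settings and is
  configurable.
* **Family context** — a kinship cue (mère, père, frère, sœur, fils,
  fille, famille, antécédents [familiaux], mother, father, …) strictly
  before the mention in the same sentence.  Cues after the mention do not
  flag ("PS 2 ; famille informée" stays the patient's score).

`karnofsky_to_ecog` applies the standard correspondence (100–90 → 0,
80–70 → 1, 60–50 → 2, 40–30 → 3, 20–10 → 4), i.e. `(100 − k) // 20`.

Evaluation is binary document classification (PS present/absent) with
per-class precision/recall/F1, accuracy, macro-averaged (unweighted mean)
and support-weighted F1, computed per report type and overall.

## Cohort construction

* **Incidence**: a patient is incident when their earliest cancer code
  (C00–C97; D00–D09/D37–D48 optionally) inside the study window
  (2019-01-01 to 2021-06-01 by default) has no cancer code in the open
  interval (index − 730 d, index).  A code exactly 730 days earlier does
  not block.  Patients failing washout are dropped entirely, not shifted
  to a later code.
* **Grouping**: cancer group and hospital come from the first code;
  same-day ties break on lexicographic code then event order; later codes
  are never re-checked.  Ranges: Breast C50; Colorectal C18–C21; Lung
  C33–C34; Prostate C61; Gynaecological C51–C58; Genitourinary C60,
  C62–C68; Skin C43–C44; Haematological C81–C96; other-GI C15–C17,
  C22–C26; everything else Other.
* **Exclusion order** (each step logged with removed/remaining counts):
  age < 18 at index; hospital with < 1% of incident diagnoses (share
  computed once, on the pre-exclusion denominator, which is the natural
  reading of "share of diagnoses") or flagged paediatric; male
  gynaecological / female prostate (male breast retained); no in-window
  report of the three types.
* **Windows**, all inclusive: documents in [index − 90 d, index + 365 d];
  metastatic if any C77–C79 in [index, index + 90 d]; died within one
  year if death ≤ index + 365 d.  A death date before the index is a data
  inconsistency: warned, and counted as a one-year death.

## Statistics

Cross-tabs carry exact proportions; table-facing percentages round
half-up at the printed precision so published cells are reproduced
exactly from their counts.  Spearman's ρ uses average ranks for ties with
the two-sided t-approximation p-value, t = ρ√((n−2)/(1−ρ²)) on n − 2
degrees of freedom — what standard software reports at the study's scale
of 15 hospitals.  An exact permutation p-value is available behind
`method="exact"`; it enumerates all n! pairings and is therefore limited
to n ≤ 8 (beyond that the enumeration buys nothing over the
approximation and costs minutes).

## Regression

Binomial GLM with logit link, fitted by iteratively reweighted least
squares (tolerance 1e-8, 100 iterations max), standard errors from the
observed information, Wald 95% CIs.  Age enters through a restricted
cubic spline with 3 knots at the 0.10/0.50/0.90 quantiles (the
convention of the `rms` ecosystem); the basis is the truncated-power
natural-spline construction, scaled by (t_k − t_1)², and is tested
against a constraint-projection oracle for span equality.  Report counts
enter untransformed and linear.  Reference levels are explicit
configuration — sex F, cancer group Breast, hospital the largest in the
data — because ORs are only interpretable against a stated reference.
Terms with |log-odds| > 15 are flagged as probable separation (their CIs
degenerate towards (0, ∞) rather than raising).  Two variants are fitted,
without and with metastatic status, and a per-term OR-ratio table lets
the user inspect adjustment stability.

Wald rather than profile-likelihood intervals, and maximum likelihood
rather than penalised fits, match how ORs with 95% CIs are conventionally
reported in clinical epidemiology at cohort sizes in the tens of
thousands, where the two coincide to well under printed precision.

## Synthetic-data generator

The generator emulates the study's data structure, not its narrative
prose.  Defaults (all configurable):

* 15 hospitals with a realistic size spread (weights shaped like a large
  multisite system, largest ≈ 16% of patients) and 10 primary-site groups
  with weights matching a mixed incident-cancer case mix (haematological
  16%, other 17%, other-GI 15%, skin 10%, …).
* Ages N(66, 14²) truncated to [18, 95]; 53% male overall, with prostate
  male-only, gynaecological female-only, breast 99% female.
* Metastatic probability per group (5% haematological … 40% lung; ≈ 21%
  overall); metastatic patients receive a C77–C79 code within 0–90 days
  of index.
* Report counts per type Poisson with means MDT 1.5, consultation 2.5,
  hospitalization 2.0 — chosen to put the median documents per patient
  near six.  15% of documents are dated outside the −90/+365 window so
  window filtering is genuinely exercised.
* 5% washout violators: an extra cancer code 30–729 days before the
  index, placed before the study window start so the violator label is
  exact (an in-window earlier code would itself become the index).
* A latent true ECOG grade per patient (distribution shifted towards
  poorer grades when metastatic) drives both the surface values of
  generated mentions and one-year mortality: baseline death probability
  0.10, log-odds +1.2 when the true grade is ≥ 2.  This builds the
  informative-presence pattern — documented patients die more — through
  plausible causal channels rather than by construction.
* **Documentation propensity** is patient-level logistic: baseline −0.9,
  male log(1.08), +0.12 per decade of age over 60, group effects spanning
  0 to −1.54 (reference Breast), hospital effects spanning −1.1 to +0.95,
  metastatic log(3.3), and per-report increments (MDT 0.25, consultation
  0.12, hospitalization 0.18) for in-window counts.  Positive patients
  have clean mentions distributed over their in-window reports (carrier
  rates per type shaped to land per-type document prevalence in the
  15–30% band, highest for cancer-coded hospitalization stays).  Because
  the generating process is exactly the model family the regression
  module fits, parameter recovery is a sharp correctness check, and
  `generate_regression_cohort` exposes the covariates-plus-outcome path
  directly (no text) for large-n recovery experiments.
* **Text** is assembled from French template sentences (a smaller English
  set is available): positive ECOG-style and Karnofsky-style mentions,
  negated forms (valued and valueless), family-attributed forms, decoys
  (PSA, IPS, phone numbers, vitals) and neutral filler, in random order.
  Gold labels and character spans are computed from template identity
  alone — never by running the extractor — so extractor evaluation is not
  circular (a test breaks the extractor and checks the gold labels do not
  move).
* The `mention_mix` proportions control the surface-form composition:
  the positive mass splits ECOG- vs Karnofsky-style mentions, the
  remaining mass sets the per-document rate of negated / family / decoy
  distractors.

### What passing tests do and do not show

The templates are unambiguous by design: every generated sentence is
clearly positive, negated, family-attributed or a decoy under the stated
rules.  Extractor metrics of 1.0 on this corpus therefore demonstrate
that the rules and the generator agree perfectly on the grammar they
share — i.e. internal consistency and the absence of decoy leakage — not
that the extractor would score 1.0 on real clinical notes, which contain
typos, layout artefacts, rarer aliases and genuinely ambiguous scope.
The published validation on real annotated reports puts the achievable
level above 0.95; the synthetic corpus bounds are set at that level.

## Problem sizes

The shipped experiments use: 50-patient worlds for oracle equivalence,
400-patient worlds (~2,400 annotated documents, ≥ 500 per type) for
extractor performance, 20,000 patients for model smoke checks, and 20
seeds × 50,000 patients for parameter recovery — sizes at which every
check is sharp (binomial/Wald error well inside the asserted margins)
while the full suite stays in the minutes range on one core.

## Known limitations

* The synthetic text is template French; no misspellings, OCR noise,
  section headers or table layouts.  Real-corpus performance must be
  established on real annotations.
* Negation/family scoping is lexicon- and window-based; it does not parse
  syntax and will mis-scope sufficiently convoluted sentences (the
  hand-labelled corpora deliberately stay within the rules' contract).
* One cancer group per patient, fixed at the first code; no
  multiple-primary handling, no staging beyond the binary metastatic
  proxy (C77–C79 claims codes), no hospital-transfer modelling.
* Patient-level published percentages are reproduced from published
  counts; published regression ORs are not reproducible without the
  original (access-restricted) data, so model correctness is established
  by parameter recovery on synthetic cohorts instead.  Note that the
  source report's abstract quotes a 35% patient-level prevalence while
  its characteristics table yields 41%; the arithmetic here follows the
  table's counts.
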