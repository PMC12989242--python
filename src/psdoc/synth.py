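"""Synthetic EHR generator for the PS-documentation analysis.

Emulates the three tables the pipeline consumes — patients, dated ICD-10
claims events, and typed clinical documents (MDT / consultation /
hospitalization reports) — with the statistical structure the analysis
assumes:

* an incident-cancer population spread over 15 hospitals and 10 primary-site
  groups, with a configurable fraction of washout violators (an extra cancer
  code placed before the study window so the incident filter must drop them);
* metastatic patients carrying a secondary-neoplasm code (C77-C79) within
  90 days of their index code;
* a latent true ECOG grade per patient that drives both the surface value of
  generated mentions and one-year mortality (informative presence: poor PS
  shifts the death log-odds);
* a patient-level logistic documentation propensity — baseline log-odds plus
  additive effects of sex, age per decade, cancer group, hospital,
  metastatic status, and per-document increments for each report type —
  which decides whether the patient's record carries a PS score; positive
  mentions are then distributed over the in-window documents;
* French template sentences for positive mentions (ECOG-style and
  Karnofsky-style), negated mentions, family-attributed mentions, decoy
  tokens (PSA, IPS, blood pressure, phone numbers) and neutral filler, with
  gold labels and character spans computed from the template identity —
  never by running the extractor.

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "PsPropensity",
    "MortalityParams",
    "GoldSpan",
    "GoldDocument",
    "GeneratorConfigError",
    "generate_cohort",
    "generate_documents",
    "generate_regression_cohort",
    "documents_to_frame",
    "DOC_TYPES",
    "CANCER_GROUPS",
]

MDT = "MDT"
CONSULTATION = "CONSULTATION"
HOSPITALIZATION = "HOSPITALIZATION"
DOC_TYPES = (MDT, CONSULTATION, HOSPITALIZATION)

CANCER_GROUPS = (
    "Breast", "Colorectal", "Genitourinary", "Gynaecological", "Haematological",
    "Lung", "Other", "OtherGI", "Prostate", "Skin",
)

# Representative primary-site ICD-10 codes per group.
_GROUP_CODES = {
    "Breast": ["C50.1", "C50.4", "C50.9"],
    "Colorectal": ["C18.0", "C18.7", "C19", "C20"],
    "Genitourinary": ["C64", "C67.2", "C62.9"],
    "Gynaecological": ["C53.9", "C54.1", "C56"],
    "Haematological": ["C81.9", "C83.3", "C90.0", "C91.1"],
    "Lung": ["C33", "C34.1", "C34.9"],
    "Other": ["C32.9", "C49.9", "C71.9", "C73"],
    "OtherGI": ["C15.3", "C16.0", "C22.0", "C25.9"],
    "Prostate": ["C61"],
    "Skin": ["C43.5", "C44.3"],
}

_METASTASIS_CODES = ["C77.0", "C78.0", "C78.7", "C79.3", "C79.5"]

_HOSPITALS = tuple(f"H{i:02d}" for i in range(1, 16))

# Hospital sampling weights shaped like a large multisite system: a few
# big centres, several mid-sized, a couple of small ones.
_HOSPITAL_COUNTS = np.array(
    [11195, 3358, 3221, 3387, 3515, 2991, 9537, 6734, 834, 1412, 1743, 1074, 3819, 10086, 5573],
    dtype=float,
)

_DEFAULT_HOSPITAL_WEIGHTS = dict(zip(_HOSPITALS, _HOSPITAL_COUNTS / _HOSPITAL_COUNTS.sum()))

_DEFAULT_GROUP_WEIGHTS = {
    "Breast": 0.079, "Colorectal": 0.086, "Genitourinary": 0.078,
    "Gynaecological": 0.040, "Haematological": 0.159, "Lung": 0.087,
    "Other": 0.166, "OtherGI": 0.148, "Prostate": 0.056, "Skin": 0.101,
}

_DEFAULT_P_METASTATIC = {
    "Breast": 0.15, "Colorectal": 0.25, "Genitourinary": 0.15,
    "Gynaecological": 0.15, "Haematological": 0.05, "Lung": 0.40,
    "Other": 0.30, "OtherGI": 0.30, "Prostate": 0.20, "Skin": 0.10,
}

# Latent true-ECOG distributions (grades 0..4).
_TRUE_PS_NONMET = np.array([0.35, 0.35, 0.15, 0.10, 0.05])
_TRUE_PS_MET = np.array([0.10, 0.25, 0.30, 0.20, 0.15])

_MENTION_FAMILIES = (
    "ecog_style", "karnofsky_style", "negated", "family_attributed", "decoy_only",
)


class GeneratorConfigError(ValueError):
    """Raised when a GeneratorConfig field fails validation."""


def _default_group_effects() -> dict[str, float]:
    # Reference Breast; spread mirrors the wide between-site variation of
    # documentation prevalence across primary-site groups.
    return {
        "Breast": 0.0, "Lung": 0.05, "OtherGI": -0.28, "Haematological": -0.36,
        "Gynaecological": -0.60, "Colorectal": -0.77, "Prostate": -0.94,
        "Other": -1.08, "Genitourinary": -1.27, "Skin": -1.54,
    }


def _default_hospital_effects() -> dict[str, float]:
    spread = [0.0, -1.0, 0.0, -0.05, -1.1, -0.1, -0.55, 0.35, -0.45,
              -0.2, 0.45, -1.05, 0.05, 0.95, 0.2]
    return dict(zip(_HOSPITALS, spread))


@dataclass
class PsPropensity:
    """Additive log-odds model for patient-level PS documentation."""

    baseline: float = -0.9
    male: float = math.log(1.08)
    age_per_decade: float = 0.12  # centred at age 60
    metastatic: float = math.log(3.3)
    group: dict[str, float] = field(default_factory=_default_group_effects)
    hospital: dict[str, float] = field(default_factory=_default_hospital_effects)
    per_mdt: float = 0.25
    per_consultation: float = 0.12
    per_hospitalization: float = 0.18


@dataclass
class MortalityParams:
    """One-year mortality model: baseline probability, shifted when the
    latent true PS is poor (ECOG >= 2)."""

    p_death_1y: float = 0.10
    poor_ps_log_odds: float = 1.2


@dataclass
class GeneratorConfig:
    n_patients: int = 500
    seed: int = 0
    hospital_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HOSPITAL_WEIGHTS))
    cancer_group_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_WEIGHTS))
    p_metastatic_by_group: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_P_METASTATIC))
    doc_rate_params: dict[str, float] = field(
        default_factory=lambda: {MDT: 1.5, CONSULTATION: 2.5, HOSPITALIZATION: 2.0})
    ps_propensity: PsPropensity = field(default_factory=PsPropensity)
    mention_mix: dict[str, float] = field(
        default_factory=lambda: {
            "ecog_style": 0.55, "karnofsky_style": 0.15, "negated": 0.12,
            "family_attributed": 0.08, "decoy_only": 0.10,
        })
    mortality_params: MortalityParams = field(default_factory=MortalityParams)
    washout_violator_frac: float = 0.05
    study_start: dt.date = dt.date(2019, 1, 1)
    study_end: dt.date = dt.date(2021, 6, 1)
    #: fraction of documents dated outside the -90/+365 diagnostic window
    out_of_window_frac: float = 0.15
    #: probability that a hospitalization report is linked to a cancer-coded stay
    p_cancer_coded_stay: float = 0.6
    language: str = "fr"  # "fr" or "en" template set

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise GeneratorConfigError("n_patients must be a non-negative integer")
        if not isinstance(self.seed, (int, np.integer)):
            raise GeneratorConfigError("seed must be an integer")
        for name, probmap in [
            ("hospital_weights", self.hospital_weights),
            ("cancer_group_weights", self.cancer_group_weights),
            ("mention_mix", self.mention_mix),
        ]:
            if not probmap:
                raise GeneratorConfigError(f"{name} must be non-empty")
            vals = list(probmap.values())
            if any(v < 0 or v > 1 for v in vals):
                raise GeneratorConfigError(f"{name} probabilities must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise GeneratorConfigError(f"{name} must sum to 1 (got {sum(vals)!r})")
        if set(self.mention_mix) - set(_MENTION_FAMILIES):
            raise GeneratorConfigError(
                f"mention_mix keys must be among {_MENTION_FAMILIES}")
        for g, p in self.p_metastatic_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise GeneratorConfigError(
                    f"p_metastatic_by_group[{g!r}] must lie in [0, 1]")
        for t, rate in self.doc_rate_params.items():
            if t not in DOC_TYPES:
                raise GeneratorConfigError(f"doc_rate_params has unknown type {t!r}")
            if rate < 0:
                raise GeneratorConfigError(f"doc_rate_params[{t!r}] must be >= 0")
        for name, frac in [
            ("washout_violator_frac", self.washout_violator_frac),
            ("out_of_window_frac", self.out_of_window_frac),
            ("p_cancer_coded_stay", self.p_cancer_coded_stay),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise GeneratorConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.mortality_params.p_death_1y <= 1.0:
            raise GeneratorConfigError("mortality_params.p_death_1y must lie in [0, 1]")
        if self.study_end <= self.study_start:
            raise GeneratorConfigError("study_end must be after study_start")
        if self.language not in ("fr", "en"):
            raise GeneratorConfigError("language must be 'fr' or 'en'")


@dataclass(frozen=True)
class GoldSpan:
    """A gold mention span: 0-based half-open offsets plus qualification."""

    start: int
    end: int
    scale: str
    value: int
    negated: bool = False
    family: bool = False


@dataclass
class GoldDocument:
    doc_id: str
    patient_id: str
    doc_type: str
    date: dt.date
    text: str
    cancer_coded_stay: bool
    gold_has_ps: bool
    gold_spans: list[GoldSpan]


def _choice(rng: np.random.Generator, items: list, p=None):
    return items[int(rng.choice(len(items), p=p))]


def _sample_categorical(rng: np.random.Generator, weights: dict[str, float], n: int) -> np.ndarray:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return np.array(keys, dtype=object)[idx]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the patient and claims-event tables.

    Patient columns beyond the core schema (``true_*``) expose the
    generator's ground truth for oracle tests and for document generation.
    Deterministic given the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    patient_ids = [f"P{i:06d}" for i in range(n)]
    hospital = _sample_categorical(rng, config.hospital_weights, n)
    group = _sample_categorical(rng, config.cancer_group_weights, n)

    # sex respects group anatomy: prostate male, gynaecological female,
    # breast overwhelmingly female, 53% male elsewhere
    u = rng.random(n)
    sex = np.where(u < 0.53, "M", "F").astype(object)
    sex[group == "Prostate"] = "M"
    sex[group == "Gynaecological"] = "F"
    breast = group == "Breast"
    sex[breast] = np.where(rng.random(int(breast.sum())) < 0.99, "F", "M")

    age = np.clip(rng.normal(66.0, 14.0, n), 18.0, 95.0)

    span_days = (config.study_end - config.study_start).days
    violator = rng.random(n) < config.washout_violator_frac

    index_offset = rng.integers(0, span_days, n)
    prior_offset = np.full(n, -1)
    if violator.any():
        nv = int(violator.sum())
        # earlier code strictly before study start, gap < 730 d to the index
        before = rng.integers(10, 350, nv)          # days before study start
        into = rng.integers(0, 720 - 350, nv)       # index position into the window
        prior_offset[violator] = -before
        index_offset[violator] = into

    index_date = np.array(
        [config.study_start + dt.timedelta(days=int(d)) for d in index_offset],
        dtype=object,
    )

    metastatic_p = np.array(
        [config.p_metastatic_by_group.get(g, 0.0) for g in group], dtype=float)
    metastatic = rng.random(n) < metastatic_p

    true_ps = np.empty(n, dtype=int)
    for is_met, probs in ((False, _TRUE_PS_NONMET), (True, _TRUE_PS_MET)):
        mask = metastatic == is_met
        true_ps[mask] = rng.choice(5, size=int(mask.sum()), p=probs)

    mp = config.mortality_params
    base = np.clip(mp.p_death_1y, 1e-9, 1 - 1e-9)
    eta = math.log(base / (1 - base)) + mp.poor_ps_log_odds * (true_ps >= 2)
    died_1y = rng.random(n) < _sigmoid(eta)
    death_offset = np.where(
        died_1y,
        rng.integers(0, 365, n),
        np.where(rng.random(n) < 0.2, rng.integers(366, 900, n), -1),
    )

    birth_date, death_date = [], []
    for i in range(n):
        idx = index_date[i]
        birth_date.append(idx - dt.timedelta(days=int(round(age[i] * 365.25))))
        if death_offset[i] >= 0:
            death_date.append(idx + dt.timedelta(days=int(death_offset[i])))
        else:
            death_date.append(None)

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": sex,
            "birth_date": birth_date,
            "death_date": death_date,
            "true_index_date": list(index_date),
            "true_cancer_group": group,
            "true_hospital": hospital,
            "true_age_at_dx": np.round(age, 2),
            "true_metastatic": metastatic,
            "true_ps": true_ps,
            "true_washout_violator": violator,
            "true_died_within_1y": died_1y,
        }
    )

    rows = []
    for i in range(n):
        pid, g, h = patient_ids[i], group[i], hospital[i]
        idx = index_date[i]
        code = _choice(rng, _GROUP_CODES[g])
        if violator[i]:
            prior = config.study_start + dt.timedelta(days=int(prior_offset[i]))
            rows.append((pid, code, prior, h))
        rows.append((pid, code, idx, h))
        if metastatic[i]:
            met_code = _choice(rng, _METASTASIS_CODES)
            rows.append((pid, met_code,
                         idx + dt.timedelta(days=int(rng.integers(0, 91))), h))
        if rng.random() < 0.5:  # billing repeats of the primary after index
            rows.append((pid, code,
                         idx + dt.timedelta(days=int(rng.integers(30, 300))), h))
    events = pd.DataFrame(rows, columns=["patient_id", "code", "date", "hospital_id"])
    return patients, events


# ---------------------------------------------------------------------------
# document text templates: (prefix, core_format, suffix); the gold span covers
# the core.  Values: v = ECOG grade, lo/hi = ECOG range, k = Karnofsky score.

_ECOG_TEMPLATES_FR = [
    ("", "OMS {v}", "."),
    ("Le patient a un ", "PS à {v}", "."),
    ("", "ECOG : {v}", "."),
    ("", "Zubrod {v}", "."),
    ("État général conservé, ", "performance status {v}", "."),
    ("", "ECOG {v}/4", "."),
]
_ECOG_RANGE_TEMPLATE_FR = ("", "PS {lo}-{hi}", ".")

_KARNOFSKY_TEMPLATES_FR = [
    ("", "Karnofsky {k}%", "."),
    ("", "IK {k}", "."),
    ("Score : ", "indice de Karnofsky à {k}", "."),
    ("", "Karnofsky : {k}/100", "."),
]

# negated: (prefix, core or None, suffix); core=None means no extractable span
_NEGATED_TEMPLATES_FR = [
    ("", None, "PS non évaluable ce jour."),
    ("Pas de ", None, "PS coté dans le dossier."),
    ("Le ", "PS n'est pas à {v}", " aujourd'hui."),
]

_FAMILY_TEMPLATES_FR = [
    ("Mère : ", "PS {v}", "."),
    ("Antécédents familiaux : père avec ", "ECOG {v}", "."),
    ("Sa fille a eu un ", "Karnofsky {k}%", "."),
]

_DECOY_TEMPLATES_FR = [
    "PSA {x} ng/mL.",
    "IPS 0.{d2} au doppler.",
    "Rappeler au 01 42 {d2} {d2b}.",
    "TA 1{d1}0/{d1b}0 mmHg.",
    "Température 37.{d1}°C.",
]

_FILLER_FR = [
    "Patient vu ce jour en consultation.",
    "Bilan biologique sans anomalie notable.",
    "Poursuite du traitement en cours.",
    "Bonne tolérance de la chimiothérapie.",
    "Examen clinique sans particularité.",
    "Dossier discuté avec l'équipe.",
    "Prochaine évaluation dans trois semaines.",
]

_ECOG_TEMPLATES_EN = [
    ("", "ECOG PS {v}", "."),
    ("", "WHO {v}", "."),
    ("Patient with ", "performance status {v}", "."),
]
_ECOG_RANGE_TEMPLATE_EN = ("", "PS {lo}-{hi}", ".")
_KARNOFSKY_TEMPLATES_EN = [("", "Karnofsky {k}%", "."), ("", "Karnofsky score of {k}", ".")]
_NEGATED_TEMPLATES_EN = [("", "PS is not {v}", " today."), ("No ", None, "PS recorded.")]
_FAMILY_TEMPLATES_EN = [("Mother had ", "PS = {v}", "."), ("Her father had ", "ECOG {v}", ".")]
_DECOY_TEMPLATES_EN = ["PSA {x} ng/mL.", "BP 1{d1}0/{d1b}0 mmHg."]
_FILLER_EN = [
    "Seen in clinic today.",
    "Routine bloods unremarkable.",
    "Treatment continued as planned.",
]


def _template_sets(language: str):
    if language == "en":
        return (_ECOG_TEMPLATES_EN, _ECOG_RANGE_TEMPLATE_EN, _KARNOFSKY_TEMPLATES_EN,
                _NEGATED_TEMPLATES_EN, _FAMILY_TEMPLATES_EN, _DECOY_TEMPLATES_EN,
                _FILLER_EN)
    return (_ECOG_TEMPLATES_FR, _ECOG_RANGE_TEMPLATE_FR, _KARNOFSKY_TEMPLATES_FR,
            _NEGATED_TEMPLATES_FR, _FAMILY_TEMPLATES_FR, _DECOY_TEMPLATES_FR,
            _FILLER_FR)


def _jitter_ecog(rng: np.random.Generator, v: int) -> int:
    return int(np.clip(v + rng.integers(-1, 2), 0, 4))


def _karnofsky_for(rng: np.random.Generator, ecog: int) -> int:
    hi = 100 - 20 * ecog
    return int(_choice(rng, [hi, hi - 10]))


def _positive_sentence(rng, templates, range_tpl, karn_templates, true_ps, family_weights):
    """One clean mention sentence; returns (text, [GoldSpan])."""
    p_ecog, p_karn = family_weights
    if rng.random() < p_ecog / (p_ecog + p_karn):
        v = _jitter_ecog(rng, true_ps)
        if rng.random() < 0.12 and v < 4:  # occasional range mention "PS 1-2"
            prefix, core, suffix = range_tpl
            core = core.format(lo=v, hi=v + 1)
            scale, value = "ECOG_FAMILY", v
        else:
            prefix, core, suffix = templates[int(rng.integers(len(templates)))]
            core = core.format(v=v)
            scale, value = "ECOG_FAMILY", v
    else:
        k = _karnofsky_for(rng, true_ps)
        prefix, core, suffix = karn_templates[int(rng.integers(len(karn_templates)))]
        core = core.format(k=k)
        scale, value = "KARNOFSKY", k
    text = prefix + core + suffix
    span = GoldSpan(len(prefix), len(prefix) + len(core), scale, value)
    return text, [span]


def _negated_sentence(rng, templates, true_ps):
    prefix, core, suffix = templates[int(rng.integers(len(templates)))]
    if core is None:
        return prefix + suffix, []
    v = _jitter_ecog(rng, true_ps)
    core = core.format(v=v)
    text = prefix + core + suffix
    return text, [GoldSpan(len(prefix), len(prefix) + len(core), "ECOG_FAMILY", v,
                           negated=True)]


def _family_sentence(rng, templates):
    prefix, core, suffix = templates[int(rng.integers(len(templates)))]
    v = int(rng.integers(0, 5))
    k = _karnofsky_for(rng, v)
    filled = core.format(v=v, k=k)
    scale = "KARNOFSKY" if "{k}" in core else "ECOG_FAMILY"
    value = k if scale == "KARNOFSKY" else v
    text = prefix + filled + suffix
    return text, [GoldSpan(len(prefix), len(prefix) + len(filled), scale, value,
                           family=True)]


def _decoy_sentence(rng, templates):
    tpl = templates[int(rng.integers(len(templates)))]
    return tpl.format(
        x=f"{rng.integers(1, 30)}.{rng.integers(0, 10)}",
        d1=int(rng.integers(1, 9)), d1b=int(rng.integers(5, 10)),
        d2=f"{rng.integers(10, 99)}", d2b=f"{rng.integers(10, 99)}",
    ), []


def _assemble(rng, sentences):
    """Join sentence (text, spans) pairs in random order, offsetting spans."""
    order = rng.permutation(len(sentences))
    parts, spans, cursor = [], [], 0
    for j in order:
        text, rel = sentences[int(j)]
        for s in rel:
            spans.append(GoldSpan(s.start + cursor, s.end + cursor, s.scale,
                                  s.value, s.negated, s.family))
        parts.append(text)
        cursor += len(text) + 1  # single-space joiner
    return " ".join(parts), spans


def generate_documents(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    config: GeneratorConfig,
) -> list[GoldDocument]:
    """Draw typed, dated, annotated documents for a generated cohort.

    Whether a patient's in-window record documents a PS is drawn from the
    patient-level logistic propensity; if positive, at least one in-window
    document carries a clean mention.  Documents dated outside the window
    (and documents of PS-negative patients) may still carry clean mentions
    outside the window, plus negated / family / decoy distractors anywhere,
    so window filtering and qualification are genuinely exercised.  Gold
    labels derive from template identity alone.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    (ecog_tpl, range_tpl, karn_tpl, neg_tpl, fam_tpl, decoy_tpl, filler) = (
        _template_sets(config.language))

    mix = {f: config.mention_mix.get(f, 0.0) for f in _MENTION_FAMILIES}
    pos_mass = mix["ecog_style"] + mix["karnofsky_style"]
    distract_mass = mix["negated"] + mix["family_attributed"] + mix["decoy_only"]
    prop = config.ps_propensity

    docs: list[GoldDocument] = []
    for row in patients.itertuples(index=False):
        pid = row.patient_id
        idx: dt.date = row.true_index_date
        true_ps = int(row.true_ps)

        per_doc = []  # (type, date, in_window, coded_stay)
        for t in DOC_TYPES:
            for _ in range(int(rng.poisson(config.doc_rate_params.get(t, 0.0)))):
                if rng.random() < config.out_of_window_frac:
                    if rng.random() < 0.5:
                        date = idx - dt.timedelta(days=int(rng.integers(91, 400)))
                    else:
                        date = idx + dt.timedelta(days=int(rng.integers(366, 520)))
                    in_window = False
                else:
                    date = idx + dt.timedelta(days=int(rng.integers(-90, 366)))
                    in_window = True
                coded = bool(
                    t == HOSPITALIZATION and rng.random() < config.p_cancer_coded_stay)
                per_doc.append([t, date, in_window, coded])

        n_in = {t: sum(1 for d in per_doc if d[0] == t and d[2]) for t in DOC_TYPES}
        eta = (
            prop.baseline
            + prop.male * (row.sex == "M")
            + prop.age_per_decade * (float(row.true_age_at_dx) - 60.0) / 10.0
            + prop.group.get(row.true_cancer_group, 0.0)
            + prop.hospital.get(row.true_hospital, 0.0)
            + prop.metastatic * bool(row.true_metastatic)
            + prop.per_mdt * n_in[MDT]
            + prop.per_consultation * n_in[CONSULTATION]
            + prop.per_hospitalization * n_in[HOSPITALIZATION]
        )
        any_in = sum(n_in.values()) > 0
        has_ps = bool(any_in and pos_mass > 0 and rng.random() < _sigmoid(eta))

        # choose which in-window documents carry a clean mention
        carrier = np.zeros(len(per_doc), dtype=bool)
        if has_ps:
            in_idx = [i for i, d in enumerate(per_doc) if d[2]]
            # carrier rates shaped so per-type document prevalence lands in
            # the ~0.15-0.30 band typical of oncology reports, highest for
            # cancer-coded hospitalization stays
            base_p = {MDT: 0.40, CONSULTATION: 0.42, HOSPITALIZATION: 0.55}
            for i in in_idx:
                p = base_p[per_doc[i][0]] * (1.3 if per_doc[i][3] else 1.0)
                carrier[i] = rng.random() < min(p, 0.95)
            if not carrier[[*in_idx]].any():
                carrier[int(_choice(rng, in_idx))] = True

        for j, (t, date, in_window, coded) in enumerate(per_doc):
            sentences = [(filler[int(rng.integers(len(filler)))], [])
                         for _ in range(int(rng.integers(1, 4)))]
            if carrier[j]:
                sentences.append(_positive_sentence(
                    rng, ecog_tpl, range_tpl, karn_tpl, true_ps,
                    (mix["ecog_style"], mix["karnofsky_style"])))
            elif not in_window and pos_mass > 0 and rng.random() < 0.15:
                # out-of-window clean mentions: present in text, outside window
                sentences.append(_positive_sentence(
                    rng, ecog_tpl, range_tpl, karn_tpl, true_ps,
                    (mix["ecog_style"], mix["karnofsky_style"])))
            if distract_mass > 0 and rng.random() < distract_mass:
                r = rng.random() * distract_mass
                if r < mix["negated"]:
                    sentences.append(_negated_sentence(rng, neg_tpl, true_ps))
                elif r < mix["negated"] + mix["family_attributed"]:
                    sentences.append(_family_sentence(rng, fam_tpl))
                else:
                    sentences.append(_decoy_sentence(rng, decoy_tpl))
            text, spans = _assemble(rng, sentences)
            gold_has = any(not s.negated and not s.family for s in spans)
            docs.append(GoldDocument(
                doc_id=f"{pid}-D{len(docs):06d}",
                patient_id=pid,
                doc_type=t,
                date=date,
                text=text,
                cancer_coded_stay=coded,
                gold_has_ps=gold_has,
                gold_spans=spans,
            ))
    return docs


def documents_to_frame(docs: Iterable[GoldDocument]) -> pd.DataFrame:
    """Tabular view of a document list (gold spans serialised to dicts)."""
    return pd.DataFrame(
        [
            {
                "doc_id": d.doc_id,
                "patient_id": d.patient_id,
                "doc_type": d.doc_type,
                "date": d.date,
                "text": d.text,
                "cancer_coded_stay": d.cancer_coded_stay,
                "gold_has_ps": d.gold_has_ps,
                "gold_spans": [asdict(s) for s in d.gold_spans],
            }
            for d in docs
        ]
    )


def generate_regression_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw an analysis-ready cohort straight from the patient-level model.

    Covariates (sex, age, cancer group, hospital, in-window document counts,
    metastatic status) are sampled as in :func:`generate_cohort`, and the
    ``has_ps`` outcome is drawn from the logistic documentation propensity —
    no document text involved.  This is the harness for parameter-recovery
    experiments at large n, where the text layer would only add runtime, not
    information: the fitted model is exactly the generating family.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    n = config.n_patients
    prop = config.ps_propensity

    hospital = _sample_categorical(rng, config.hospital_weights, n)
    group = _sample_categorical(rng, config.cancer_group_weights, n)
    u = rng.random(n)
    sex = np.where(u < 0.53, "M", "F").astype(object)
    sex[group == "Prostate"] = "M"
    sex[group == "Gynaecological"] = "F"
    breast = group == "Breast"
    sex[breast] = np.where(rng.random(int(breast.sum())) < 0.99, "F", "M")
    age = np.clip(rng.normal(66.0, 14.0, n), 18.0, 95.0)

    counts = {t: rng.poisson(config.doc_rate_params.get(t, 0.0), size=n)
              for t in DOC_TYPES}
    total = sum(counts.values())
    while (total == 0).any():  # cohort rows must carry >= 1 document
        zero = total == 0
        for t in DOC_TYPES:
            counts[t][zero] = rng.poisson(
                config.doc_rate_params.get(t, 0.0), size=int(zero.sum()))
        total = sum(counts.values())

    p_met = np.array([config.p_metastatic_by_group.get(g, 0.0) for g in group])
    metastatic = rng.random(n) < p_met

    group_eff = np.array([prop.group.get(g, 0.0) for g in group])
    hosp_eff = np.array([prop.hospital.get(h, 0.0) for h in hospital])
    eta = (
        prop.baseline
        + prop.male * (sex == "M")
        + prop.age_per_decade * (age - 60.0) / 10.0
        + group_eff
        + hosp_eff
        + prop.metastatic * metastatic
        + prop.per_mdt * counts[MDT]
        + prop.per_consultation * counts[CONSULTATION]
        + prop.per_hospitalization * counts[HOSPITALIZATION]
    )
    has_ps = rng.random(n) < _sigmoid(eta)

    true_ps = np.empty(n, dtype=int)
    for is_met, probs in ((False, _TRUE_PS_NONMET), (True, _TRUE_PS_MET)):
        mask = metastatic == is_met
        true_ps[mask] = rng.choice(5, size=int(mask.sum()), p=probs)
    mp = config.mortality_params
    base = np.clip(mp.p_death_1y, 1e-9, 1 - 1e-9)
    death_eta = math.log(base / (1 - base)) + mp.poor_ps_log_odds * (true_ps >= 2)
    died = rng.random(n) < _sigmoid(death_eta)

    span_days = (config.study_end - config.study_start).days
    index_date = [config.study_start + dt.timedelta(days=int(d))
                  for d in rng.integers(0, span_days, n)]

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "index_date": index_date,
            "sex": sex,
            "age_at_dx": np.round(age, 3),
            "cancer_group": group,
            "hospital_id": hospital,
            "n_mdt": counts[MDT],
            "n_consult": counts[CONSULTATION],
            "n_hosp": counts[HOSPITALIZATION],
            "metastatic_at_dx": metastatic,
            "has_ps": has_ps,
            "died_within_1y": died,
        }
    )
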