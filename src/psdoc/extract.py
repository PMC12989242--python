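"""Rule-based extraction of performance-status (PS) scores from clinical text.

Oncologists record a patient's functional ability either on the
ECOG/WHO/Zubrod scale (0 = fully active .. 4 = completely disabled) or on
the Karnofsky scale (100 = perfect health down to 10 = moribund, in steps
of 10).  In French clinical notes the score surfaces under many aliases —
"OMS 2", "PS = 1", "ECOG : 3", "Karnofsky 80%", "IK 70", "Zubrod 0" — often
next to decoy tokens that must never match (PSA values, IPS indices, blood
pressures, phone numbers).

The extraction pipeline is a single compiled pattern that captures a PS
keyword followed (possibly through a short connector/copula/negation infix)
by a value on a valid scale, plus two qualification passes that decide
whether a mention is negated ("PS is not 0", "le PS n'est pas à 2") or
attributed to a relative ("mère : PS 3").  Document-level presence is then
the existence of at least one clean (non-negated, non-family) mention, and
patient-level presence the existence of at least one positive document in
the diagnostic window.

Offsets are 0-based half-open character offsets into the source text
throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

__all__ = [
    "PSMention",
    "ExtractionMetrics",
    "find_mentions",
    "qualify_negation",
    "qualify_family",
    "qualify_mentions",
    "extract_document",
    "karnofsky_to_ecog",
    "document_has_ps",
    "patient_has_ps",
    "evaluate",
    "DEFAULT_NEGATION_CUES",
    "DEFAULT_FAMILY_CUES",
]

ECOG_FAMILY = "ECOG_FAMILY"
KARNOFSKY = "KARNOFSKY"

ECOG_VALUES = frozenset(range(0, 5))
KARNOFSKY_VALUES = frozenset(range(10, 101, 10))

#: keywords whose scale is Karnofsky a priori; every other keyword is
#: ECOG-family, with a value-range fallback to Karnofsky (a bare "PS 80").
_KARNOFSKY_KEYWORDS = frozenset({"karnofsky", "indice de karnofsky", "ik"})

_LETTER = "A-Za-zÀ-ÖØ-öø-ÿœŒ"

# Longest alternatives first so the scanner is longest-match-first.
_KEYWORD_ALT = (
    r"indice\s+de\s+karnofsky|performance\s+status|karnofsky|zubrod|ecog|oms|who|ik|ps"
)

# Short closed-lexicon infix between keyword and value: connectors, copulas,
# and negation words that routinely sit inside the mention ("PS is not 0",
# "PS n'est pas à 2", "PS évalué à 3", "Karnofsky : 80").
_GAP = (
    r"(?:\s*[:=]|\s+(?:n['’]est|is|was|est|était|etait|not|non|pas|"
    r"coté|cotée|cote|évalué|évaluée|evalue|score|à|a|de))*"
)

_MENTION_RE = re.compile(
    rf"(?<![0-9{_LETTER}])(?P<kw>{_KEYWORD_ALT})(?![{_LETTER}])"
    rf"(?P<gap>{_GAP})"
    rf"\s*(?P<val>\d{{1,3}})"
    rf"(?:\s*[-–]\s*(?P<upper>\d{{1,3}}))?"
    rf"(?:\s*(?P<pct>%)|\s*/\s*(?P<den>100|4))?"
    rf"(?!\.?\d)",
    re.IGNORECASE,
)

_SENTENCE_BOUNDARY = ("\n", ".")

_TOKEN_RE = re.compile(rf"[0-9{_LETTER}]+(?:['’][0-9{_LETTER}]+)?")

DEFAULT_NEGATION_CUES = frozenset(
    {"not", "no", "pas", "non", "sans", "aucun", "aucune", "ni", "jamais"}
)

DEFAULT_FAMILY_CUES = frozenset(
    {
        "mother", "father", "brother", "sister", "son", "daughter",
        "mère", "mere", "père", "pere", "frère", "frere", "sœur", "soeur",
        "fils", "fille", "famille", "familial", "familiale", "familiaux",
        "parents", "oncle", "tante", "cousin", "cousine",
        "antécédents",  # "antécédents familiaux" headers
    }
)

#: number of tokens preceding the mention scanned for a negation cue
DEFAULT_NEGATION_WINDOW = 5


@dataclass(frozen=True)
class PSMention:
    """One candidate performance-status score found in a document.

    ``start``/``end`` are 0-based half-open offsets; ``matched_text`` always
    equals ``text[start:end]`` of the source document.  ``value_upper`` is
    set for range mentions such as "PS 1-2".
    """

    doc_id: str
    start: int
    end: int
    matched_text: str
    scale: str  # ECOG_FAMILY or KARNOFSKY
    value: int
    value_upper: int | None = None
    negated: bool = False
    family: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid span ({self.start}, {self.end})")
        valid = ECOG_VALUES if self.scale == ECOG_FAMILY else KARNOFSKY_VALUES
        if self.value not in valid:
            raise ValueError(f"value {self.value} invalid for scale {self.scale}")
        if self.value_upper is not None:
            if self.value_upper not in valid or self.value_upper < self.value:
                raise ValueError(
                    f"value_upper {self.value_upper} invalid for {self.scale} "
                    f"range starting at {self.value}"
                )


def _normalise_keyword(raw: str) -> str:
    return " ".join(raw.lower().split())


def _mention_from_match(doc_id: str, text: str, m: re.Match) -> PSMention | None:
    """Validate a raw regex match and build a mention, or reject it."""
    kw = _normalise_keyword(m.group("kw"))
    is_karnofsky_kw = kw in _KARNOFSKY_KEYWORDS
    value = int(m.group("val"))
    pct = m.group("pct") is not None
    den = m.group("den")
    end = m.end()

    if den == "4":
        # explicit /4 denominator forces the ECOG scale
        if is_karnofsky_kw or value not in ECOG_VALUES:
            return None
        scale = ECOG_FAMILY
    elif pct or den == "100":
        if value not in KARNOFSKY_VALUES:
            return None
        scale = KARNOFSKY
    elif is_karnofsky_kw:
        if value not in KARNOFSKY_VALUES:
            return None
        scale = KARNOFSKY
    elif value in ECOG_VALUES:
        scale = ECOG_FAMILY
    elif value in KARNOFSKY_VALUES:
        # bare ECOG-family keyword with a Karnofsky-range value ("PS 80"):
        # the value range is the safest arbiter of the intended scale
        scale = KARNOFSKY
    else:
        return None

    upper_raw = m.group("upper")
    upper: int | None = None
    if upper_raw is not None:
        candidate = int(upper_raw)
        valid = ECOG_VALUES if scale == ECOG_FAMILY else KARNOFSKY_VALUES
        if candidate in valid and candidate >= value:
            upper = candidate
        else:
            # drop an implausible range tail ("PS 3-80"), keep the value
            end = m.end("val")
    start = m.start()
    return PSMention(
        doc_id=doc_id,
        start=start,
        end=end,
        matched_text=text[start:end],
        scale=scale,
        value=value,
        value_upper=upper,
    )


def find_mentions(doc_id: str, text: str) -> list[PSMention]:
    """Scan ``text`` left-to-right for unqualified PS mentions.

    Keywords are matched case-insensitively at word boundaries, longest
    alternative first; matches never overlap.  Decoy tokens embedding a
    keyword ("PSA", "IPS") cannot match because of the boundary guards.
    Qualification (negation / family) is handled downstream.
    """
    mentions: list[PSMention] = []
    pos = 0
    while pos <= len(text):
        m = _MENTION_RE.search(text, pos)
        if m is None:
            break
        mention = _mention_from_match(doc_id, text, m)
        if mention is None:
            pos = m.end("kw")
            continue
        mentions.append(mention)
        pos = mention.end
    return mentions


def _sentence_bounds(text: str, start: int, end: int) -> tuple[int, int]:
    """Bounds of the sentence containing [start, end); period/newline split."""
    s = 0
    for ch in _SENTENCE_BOUNDARY:
        cut = text.rfind(ch, 0, start)
        if cut + 1 > s:
            s = cut + 1
    e = len(text)
    for ch in _SENTENCE_BOUNDARY:
        cut = text.find(ch, end)
        if cut != -1 and cut < e:
            e = cut
    return s, e


def _sentence_tokens(text: str, start: int, end: int) -> list[tuple[str, int, int]]:
    s, e = _sentence_bounds(text, start, end)
    return [
        (m.group(0).lower(), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text, s, e)
    ]


def qualify_negation(
    text: str,
    mention: PSMention,
    cues: frozenset[str] | set[str] = DEFAULT_NEGATION_CUES,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> PSMention:
    """Flag the mention as negated when a negation cue is in scope.

    Scope is the mention's sentence (period/newline boundaries), restricted
    to the ``window`` tokens immediately preceding the mention plus the
    tokens inside the mention span itself.
    """
    tokens = _sentence_tokens(text, mention.start, mention.end)
    inside = [
        i for i, (_, a, b) in enumerate(tokens)
        if a < mention.end and b > mention.start
    ]
    if inside:
        lo = max(0, inside[0] - window)
        scope = tokens[lo : inside[-1] + 1]
    else:  # defensive: mention with no tokens cannot be qualified
        scope = []
    negated = any(tok in cues for tok, _, _ in scope)
    return replace(mention, negated=negated)


def qualify_family(
    text: str,
    mention: PSMention,
    cues: frozenset[str] | set[str] = DEFAULT_FAMILY_CUES,
) -> PSMention:
    """Flag the mention as family-attributed.

    Conservative scope: a kinship cue must occur in the same sentence and
    strictly before the mention ("mère : PS 3" flags, "PS 2 ; famille
    informée" does not).
    """
    tokens = _sentence_tokens(text, mention.start, mention.end)
    before = [tok for tok, a, _ in tokens if a < mention.start]
    return replace(mention, family=any(tok in cues for tok in before))


def qualify_mentions(
    text: str,
    mentions: Iterable[PSMention],
    negation_cues: frozenset[str] | set[str] = DEFAULT_NEGATION_CUES,
    family_cues: frozenset[str] | set[str] = DEFAULT_FAMILY_CUES,
    negation_window: int = DEFAULT_NEGATION_WINDOW,
) -> list[PSMention]:
    """Apply both qualification passes to every mention of a document."""
    out = []
    for m in mentions:
        m = qualify_negation(text, m, negation_cues, negation_window)
        m = qualify_family(text, m, family_cues)
        out.append(m)
    return out


def extract_document(doc_id: str, text: str, **kwargs) -> list[PSMention]:
    """Find and qualify every PS mention of one document."""
    return qualify_mentions(text, find_mentions(doc_id, text), **kwargs)


def karnofsky_to_ecog(k: int) -> int:
    """Map a Karnofsky score to the corresponding ECOG grade.

    Standard correspondence: 100-90 -> 0, 80-70 -> 1, 60-50 -> 2,
    40-30 -> 3, 20-10 -> 4 (monotone non-increasing in k).
    """
    if k not in KARNOFSKY_VALUES:
        raise ValueError(f"Karnofsky score must be in 10..100 step 10, got {k}")
    return (100 - k) // 20


def document_has_ps(mentions: Sequence[PSMention]) -> bool:
    """True iff the document carries at least one clean PS mention."""
    return any(not m.negated and not m.family for m in mentions)


def patient_has_ps(document_mentions: Iterable[Sequence[PSMention]]) -> bool:
    """True iff any (already window-filtered) document is PS-positive."""
    return any(document_has_ps(ms) for ms in document_mentions)


@dataclass(frozen=True)
class ExtractionMetrics:
    """Binary document-classification metrics for PS presence.

    Per-class dictionaries are keyed ``"present"`` / ``"absent"``;
    ``macro_f1`` is the unweighted mean of the two class F1 values and
    ``weighted_f1`` their support-weighted mean.
    """

    n_docs: int
    accuracy: float
    precision: Mapping[str, float]
    recall: Mapping[str, float]
    f1: Mapping[str, float]
    support: Mapping[str, int]
    weighted_f1: float
    macro_f1: float


def _score(gold: np.ndarray, pred: np.ndarray) -> ExtractionMetrics:
    prec, rec, f1, support = precision_recall_fscore_support(
        gold, pred, labels=[True, False], zero_division=0
    )
    classes = ("present", "absent")
    n = len(gold)
    weighted = float(np.average(f1, weights=support)) if support.sum() else 0.0
    return ExtractionMetrics(
        n_docs=n,
        accuracy=float(np.mean(gold == pred)) if n else 0.0,
        precision=dict(zip(classes, map(float, prec))),
        recall=dict(zip(classes, map(float, rec))),
        f1=dict(zip(classes, map(float, f1))),
        support=dict(zip(classes, map(int, support))),
        weighted_f1=weighted,
        macro_f1=float(np.mean(f1)),
    )


def evaluate(
    gold: Mapping[str, bool],
    predicted: Mapping[str, bool],
    doc_types: Mapping[str, str] | None = None,
) -> dict[str, ExtractionMetrics]:
    """Score predicted document-level PS presence against gold labels.

    Returns metrics under key ``"overall"`` and, when ``doc_types`` is
    given, one entry per document type.  Raises when the two label sets
    are not aligned on the same document ids.
    """
    if set(gold) != set(predicted):
        missing = set(gold) ^ set(predicted)
        raise ValueError(f"gold/predicted doc_id sets differ, e.g. {sorted(missing)[:5]}")
    ids = sorted(gold)
    g = np.array([gold[i] for i in ids], dtype=bool)
    p = np.array([predicted[i] for i in ids], dtype=bool)
    out = {"overall": _score(g, p)}
    if doc_types is not None:
        types = np.array([doc_types[i] for i in ids])
        for t in sorted(set(types)):
            mask = types == t
            out[t] = _score(g[mask], p[mask])
    return out
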