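"""Independent brute-force oracles and hand-labelled fixture corpora.

Everything here is deliberately written as plain loops over rows, separate
from the package's vectorised implementations, so tests compare two
independent derivations of the same rules.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd


# ---------------------------------------------------------------------------
# brute-force cohort re-derivation (loops, no pandas groupby)

def _is_cancer(code: str) -> bool:
    code = code.strip().upper()
    return len(code) >= 3 and code[0] == "C" and code[1:3].isdigit() and int(code[1:3]) <= 97


def _group(code: str) -> str:
    num = int(code[1:3])
    if num == 50:
        return "Breast"
    if 18 <= num <= 21:
        return "Colorectal"
    if 33 <= num <= 34:
        return "Lung"
    if num == 61:
        return "Prostate"
    if 51 <= num <= 58:
        return "Gynaecological"
    if num == 60 or 62 <= num <= 68:
        return "Genitourinary"
    if 43 <= num <= 44:
        return "Skin"
    if 81 <= num <= 96:
        return "Haematological"
    if 15 <= num <= 17 or 22 <= num <= 26:
        return "OtherGI"
    return "Other"


def brute_force_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    documents: pd.DataFrame,
    doc_has_ps: dict,
    study_start=dt.date(2019, 1, 1),
    study_end=dt.date(2021, 6, 1),
) -> pd.DataFrame:
    """Re-derive the full cohort table by exhaustive scanning."""
    ev = []
    for i, row in events.reset_index(drop=True).iterrows():
        d = row["date"]
        if not isinstance(d, dt.date):
            d = pd.Timestamp(d).date()
        ev.append((str(row["patient_id"]), str(row["code"]).upper(), d,
                   str(row["hospital_id"]), i))

    # incident index per patient, 730-day open-interval washout
    incident = {}
    pids = sorted({e[0] for e in ev})
    for pid in pids:
        cancer_dates = sorted(d for p, c, d, h, i in ev if p == pid and _is_cancer(c))
        in_win = [d for d in cancer_dates if study_start <= d <= study_end]
        if not in_win:
            continue
        index = in_win[0]
        if any(0 < (index - d).days < 730 for d in cancer_dates):
            continue
        incident[pid] = index

    # first code on the index day: lexicographic code, then event order
    assigned = {}
    for pid, index in incident.items():
        day = sorted(
            (c, i, h) for p, c, d, h, i in ev
            if p == pid and d == index and _is_cancer(c)
        )
        code, _, hosp = day[0]
        assigned[pid] = (code, _group(code), hosp)

    pat = {str(r["patient_id"]): r for _, r in patients.iterrows()}

    rows = []
    for pid, index in incident.items():
        code, group, hosp = assigned[pid]
        birth = pat[pid]["birth_date"]
        if not isinstance(birth, dt.date):
            birth = pd.Timestamp(birth).date()
        rows.append({
            "patient_id": pid, "index_date": index, "index_code": code,
            "sex": pat[pid]["sex"], "age_at_dx": (index - birth).days / 365.25,
            "cancer_group": group, "hospital_id": hosp,
        })

    # hospital shares before any exclusion
    n_all = len(rows)
    share = {}
    for r in rows:
        share[r["hospital_id"]] = share.get(r["hospital_id"], 0) + 1

    kept = [r for r in rows if r["age_at_dx"] >= 18.0]
    kept = [r for r in kept if share[r["hospital_id"]] / n_all >= 0.01]
    kept = [r for r in kept
            if not ((r["sex"] == "M" and r["cancer_group"] == "Gynaecological")
                    or (r["sex"] == "F" and r["cancer_group"] == "Prostate"))]

    out = []
    for r in kept:
        pid, index = r["patient_id"], r["index_date"]
        n = {"MDT": 0, "CONSULTATION": 0, "HOSPITALIZATION": 0}
        has_ps = False
        for _, doc in documents.iterrows():
            if str(doc["patient_id"]) != pid:
                continue
            if doc["doc_type"] not in n:
                continue
            d = doc["date"]
            if not isinstance(d, dt.date):
                d = pd.Timestamp(d).date()
            if -90 <= (d - index).days <= 365:
                n[doc["doc_type"]] += 1
                if doc_has_ps.get(doc["doc_id"], False):
                    has_ps = True
        if sum(n.values()) < 1:
            continue
        metastatic = any(
            c[:3] in ("C77", "C78", "C79") and 0 <= (d - index).days <= 90
            for p, c, d, h, i in ev if p == pid
        )
        death = pat[pid]["death_date"]
        died = False
        if death is not None and not pd.isna(death):
            if not isinstance(death, dt.date):
                death = pd.Timestamp(death).date()
            died = (death - index).days <= 365
        r2 = dict(r)
        r2.update(n_mdt=n["MDT"], n_consult=n["CONSULTATION"],
                  n_hosp=n["HOSPITALIZATION"], metastatic_at_dx=metastatic,
                  has_ps=has_ps, died_within_1y=died)
        out.append(r2)
    cols = ["patient_id", "index_date", "index_code", "sex", "age_at_dx",
            "cancer_group", "hospital_id", "n_mdt", "n_consult", "n_hosp",
            "metastatic_at_dx", "has_ps", "died_within_1y"]
    return pd.DataFrame(out, columns=cols).sort_values("patient_id").reset_index(drop=True)


def naive_spearman(x, y):
    """Rank (average ties, by sorting) then Pearson — the textbook route."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


# ---------------------------------------------------------------------------
# hand-labelled qualification corpora (text, expected flag); each sentence
# contains exactly one findable mention and is unambiguous under the rules

NEGATION_CORPUS = [
    # negated: cue within the same sentence, inside or up to 5 tokens before
    ("PS is not 0", True),
    ("Le PS n'est pas à 2.", True),
    ("OMS is not 2", True),
    ("ECOG non à 3", True),
    ("pas de PS 1 documenté", True),
    ("aucun ECOG 2 retrouvé", True),
    ("sans PS 3 mentionné ce jour", True),
    ("no Karnofsky 80% recorded", True),
    ("IK n'est pas à 70.", True),
    ("le score n'est pas un OMS 0", True),
    ("non retenu : ECOG 1", True),
    ("résultat négatif, pas un PS 4", True),
    ("jamais de Zubrod 3 documenté", True),
    ("aucune trace d'un IK 60", True),
    ("sans évaluation, pas de ECOG 0 noté", True),
    ("WHO is not 1", True),
    ("état non compatible avec un PS 0", True),
    ("ni OMS 1 ni autre score", True),
    ("pas formellement un Karnofsky 90%", True),
    ("le PS n'est pas 3", True),
    # clean: no cue, cue after the mention, cue out of window, or cue in a
    # previous sentence
    ("ECOG 1, bon état général", False),
    ("OMS 1", False),
    ("PS = 2 ce jour", False),
    ("Karnofsky 80%", False),
    ("Zubrod 0 confirmé", False),
    ("Pas d'anomalie. PS 1", False),
    ("douleur non contrôlée. ECOG 2", False),
    ("IK 70 sans autre précision", False),
    ("score ECOG : 3 non confirmé par la suite", False),
    ("PS 2, pas de complication", False),
    ("Aucune plainte. OMS 0 ce jour", False),
    ("la douleur n'est pas contrôlée par le traitement actuel, OMS 1", False),
    ("bilan normal, ECOG 0", False),
    ("patient stable avec un PS à 1", False),
    ("Karnofsky : 90/100 ce jour", False),
    ("amélioration nette, OMS 2", False),
    ("WHO 1 noté en consultation", False),
    ("évaluation faite : PS 0", False),
    ("indice de Karnofsky à 60 mesuré", False),
    ("PS 1-2 selon l'infirmière", False),
]

FAMILY_CORPUS = [
    # family-attributed: kinship cue in the same sentence, before the mention
    ("mother had PS = 3", True),
    ("Mère : PS 3.", True),
    ("antécédents familiaux : père avec ECOG 2", True),
    ("sa sœur avait un IK 60", True),
    ("le père du patient avait un OMS 2", True),
    ("fille : Karnofsky 70%", True),
    ("son frère a un PS 1", True),
    ("famille : la mère garde un ECOG 1", True),
    ("father had ECOG 3", True),
    ("oncle avec PS 2 connu", True),
    # patient's own score: no cue, cue after the mention, or cue in a
    # previous sentence
    ("PS = 3", False),
    ("ECOG 2, famille informée", False),
    ("Mère décédée. PS 1", False),
    ("OMS 1 ; la famille est présente", False),
    ("PS 2 expliqué à la fille du patient", False),
    ("Karnofsky 80% ce jour", False),
    ("Antécédents familiaux sans particularité. ECOG 0", False),
    ("IK 70, discussion avec le père ensuite", False),
    ("Zubrod 1 chez le patient", False),
    ("PS à 2, sœur prévenue", False),
]

# unambiguous document-level fixture corpus, stratified by report type
# like a small annotated validation set; label = document has a clean PS
FIXTURE_CORPUS = [
    ("MDT", "Dossier discuté en RCP. OMS 1. Décision de chimiothérapie.", True),
    ("MDT", "RCP du jour. Pas de PS coté dans le dossier. À réévaluer.", False),
    ("MDT", "Mère : PS 3. Patient lui-même non évalué ce jour.", False),
    ("MDT", "Présentation du dossier. ECOG : 2. Traitement validé.", True),
    ("MDT", "PSA 12.4 ng/mL. Décision de surveillance.", False),
    ("MDT", "Karnofsky 80%. Inclusion essai discutée.", True),
    ("MDT", "Le PS n'est pas à 0 selon l'équipe.", False),
    ("MDT", "Performance status 3, soins de support.", True),
    ("MDT", "Bilan présenté. Décision collégiale. Pas d'autre examen.", False),
    ("MDT", "PS 1-2, chimiothérapie retenue.", True),
    ("CONSULTATION", "Patient vu ce jour. ECOG 1, bon état général.", True),
    ("CONSULTATION", "Consultation de suivi. Bilan biologique normal.", False),
    ("CONSULTATION", "IK 70. Poursuite du traitement.", True),
    ("CONSULTATION", "IPS 0.92 au doppler. Pas de sténose.", False),
    ("CONSULTATION", "PS non évaluable ce jour, patient alité à l'extérieur.", False),
    ("CONSULTATION", "antécédents familiaux : père avec ECOG 2.", False),
    ("CONSULTATION", "OMS 0, reprise du travail envisagée.", True),
    ("CONSULTATION", "Tension artérielle 130/80 mmHg. RAS.", False),
    ("CONSULTATION", "Zubrod 2 ce jour, adaptation des doses.", True),
    ("CONSULTATION", "Appeler au 01 42 34 56 78 pour le prochain rendez-vous.", False),
    ("HOSPITALIZATION", "Entrée pour cure. PS = 2. Tolérance correcte.", True),
    ("HOSPITALIZATION", "Hospitalisation programmée. Sortie à J3.", False),
    ("HOSPITALIZATION", "Karnofsky : 60/100 à l'entrée.", True),
    ("HOSPITALIZATION", "PSA 4.5 ng/mL, bilan par ailleurs normal.", False),
    ("HOSPITALIZATION", "sans PS 3 mentionné dans le compte rendu initial.", False),
    ("HOSPITALIZATION", "ECOG 2/4 à l'admission.", True),
    ("HOSPITALIZATION", "Sa fille a eu un Karnofsky 70% l'an dernier.", False),
    ("HOSPITALIZATION", "État général conservé, performance status 1.", True),
    ("HOSPITALIZATION", "Température 38.2°C à J1, apyrexie ensuite.", False),
    ("HOSPITALIZATION", "indice de Karnofsky à 50, soins de support.", True),
]

# decoy sentences that must never produce a mention
DECOY_CORPUS = [
    "PSA 4.5 ng/mL, bilan normal",
    "PSA 0.8 ng/mL en surveillance",
    "IPS 0.92 au doppler",
    "IPS 1.1 à droite",
    "Appeler le 01 42 16 10 00",
    "TA 120/80 mmHg",
    "TA 135/85 mmHg ce jour",
    "Température 37.2°C",
    "Glycémie 1.05 g/L",
    "Poids 72 kg, taille 1.75 m",
    "Hémoglobine 11.2 g/dL",
    "Créatinine 85 µmol/L",
    "Saturation 97% en air ambiant",
    "EVA 3/10 ce jour",
    "Date de naissance 12/04/1957",
]
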