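"""File formats of the pipeline: CSV tables and JSONL documents.

patients.csv / events.csv / cohort.csv are UTF-8 CSV with a header row and
ISO-8601 dates; documents.jsonl and mentions.jsonl carry one JSON object
per line, documents with their gold annotations under a ``"gold"`` key.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .extract import PSMention
from .synth import GoldDocument, GoldSpan

__all__ = [
    "write_patients", "read_patients",
    "write_events", "read_events",
    "write_documents", "read_documents",
    "write_mentions", "read_mentions",
]


def _date_str(d) -> str | None:
    if d is None or (isinstance(d, float) and pd.isna(d)) or pd.isna(d):
        return None
    if isinstance(d, dt.date):
        return d.isoformat()
    return pd.Timestamp(d).date().isoformat()


def write_patients(patients: pd.DataFrame, path) -> None:
    df = patients.copy()
    for c in df.columns:
        if "date" in c:
            df[c] = df[c].map(_date_str)
    df.to_csv(path, index=False)


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for c in df.columns:
        if "date" in c:
            df[c] = pd.to_datetime(df[c]).dt.date
    return df


def write_events(events: pd.DataFrame, path) -> None:
    df = events.copy()
    df["date"] = df["date"].map(_date_str)
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "hospital_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_documents(docs: Iterable[GoldDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {
                "doc_id": d.doc_id,
                "patient_id": d.patient_id,
                "doc_type": d.doc_type,
                "date": d.date.isoformat(),
                "text": d.text,
                "cancer_coded_stay": d.cancer_coded_stay,
                "gold": {
                    "has_ps": d.gold_has_ps,
                    "spans": [
                        {
                            "start": s.start, "end": s.end, "scale": s.scale,
                            "value": s.value, "negated": s.negated,
                            "family": s.family,
                        }
                        for s in d.gold_spans
                    ],
                },
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_documents(path) -> list[GoldDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            docs.append(
                GoldDocument(
                    doc_id=rec["doc_id"],
                    patient_id=rec["patient_id"],
                    doc_type=rec["doc_type"],
                    date=dt.date.fromisoformat(rec["date"]),
                    text=rec["text"],
                    cancer_coded_stay=bool(rec.get("cancer_coded_stay", False)),
                    gold_has_ps=bool(rec["gold"]["has_ps"]),
                    gold_spans=[GoldSpan(**s) for s in rec["gold"]["spans"]],
                )
            )
    return docs


def write_mentions(mentions: Iterable[PSMention], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(json.dumps(m.__dict__, ensure_ascii=False) + "\n")


def read_mentions(path) -> list[PSMention]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(PSMention(**json.loads(line)))
    return out
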