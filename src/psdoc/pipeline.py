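"""Pipeline orchestration: simulate → extract → cohort → stats → fit.

Stages communicate only through files with documented schemas, so each is
independently testable and replaceable.  Every stochastic stage consumes a
seed derived deterministically from the global seed and the stage name;
outputs are reproducible byte-for-byte for identical inputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import extract as extract_mod
from . import io as io_mod
from . import prevalence as prev_mod
from . import regression as reg_mod
from . import synth as synth_mod

__all__ = ["PipelineConfig", "run_simulate", "run_extract", "run_cohort",
           "run_stats", "run_fit", "run_full", "stage_seed"]

log = logging.getLogger("psdoc")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    out_dir: Path = Path("psdoc_run")
    seed: int = 0
    simulate: bool = True
    generator: synth_mod.GeneratorConfig = field(
        default_factory=synth_mod.GeneratorConfig)
    cohort_params: cohort_mod.CohortParams = field(
        default_factory=cohort_mod.CohortParams)
    model_spec: reg_mod.ModelSpec = field(default_factory=reg_mod.ModelSpec)
    # when not simulating, paths to pre-existing inputs
    patients_path: Path | None = None
    events_path: Path | None = None
    documents_path: Path | None = None

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, out_dir=None) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if seed is not None:
            cfg.seed = int(seed)
        if out_dir is not None:
            cfg.out_dir = Path(out_dir)
        elif "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        cfg.simulate = bool(raw.get("simulate", True))
        gen = raw.get("generator", {})
        for k, v in gen.items():
            if k in ("study_start", "study_end"):
                v = dt.date.fromisoformat(v)
            if k == "ps_propensity":
                v = synth_mod.PsPropensity(**v)
            if k == "mortality_params":
                v = synth_mod.MortalityParams(**v)
            setattr(cfg.generator, k, v)
        for k, v in raw.get("cohort", {}).items():
            if k in ("study_start", "study_end") and v is not None:
                v = dt.date.fromisoformat(v)
            setattr(cfg.cohort_params, k, v)
        for k, v in raw.get("model", {}).items():
            setattr(cfg.model_spec, k, v)
        for k in ("patients_path", "events_path", "documents_path"):
            if raw.get(k):
                setattr(cfg, k, Path(raw[k]))
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (dt.date, Path)):
                return str(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d.pop("out_dir")  # the experiment, not its output location
        blob = json.dumps(d, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate and write patients.csv, events.csv, documents.jsonl."""
    out = _outdir(config)
    gen = dataclasses.replace(
        config.generator, seed=stage_seed(config.seed, "simulate"))
    patients, events = synth_mod.generate_cohort(gen)
    docs = synth_mod.generate_documents(patients, events, gen)
    paths = {
        "patients": out / "patients.csv",
        "events": out / "events.csv",
        "documents": out / "documents.jsonl",
    }
    io_mod.write_patients(patients, paths["patients"])
    io_mod.write_events(events, paths["events"])
    io_mod.write_documents(docs, paths["documents"])
    manifest = {
        "seed": config.seed,
        "generator_seed": gen.seed,
        "n_patients": gen.n_patients,
        "config_hash": config.config_hash(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("simulated %d patients, %d events, %d documents",
             len(patients), len(events), len(docs))
    return paths


def _load_inputs(config: PipelineConfig):
    out = _outdir(config)
    ppath = config.patients_path or out / "patients.csv"
    epath = config.events_path or out / "events.csv"
    dpath = config.documents_path or out / "documents.jsonl"
    for p in (ppath, epath, dpath):
        if not Path(p).exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
    return (io_mod.read_patients(ppath), io_mod.read_events(epath),
            io_mod.read_documents(dpath))


def run_extract(config: PipelineConfig) -> Path:
    """Run the extractor over documents.jsonl, write mentions.jsonl and
    per-document labels doc_labels.csv."""
    out = _outdir(config)
    _, _, docs = _load_inputs(config)
    mentions, labels = [], []
    for d in docs:
        ms = extract_mod.extract_document(d.doc_id, d.text)
        mentions.extend(ms)
        labels.append({"doc_id": d.doc_id, "has_ps": extract_mod.document_has_ps(ms)})
    io_mod.write_mentions(mentions, out / "mentions.jsonl")
    pd.DataFrame(labels).to_csv(out / "doc_labels.csv", index=False)
    log.info("extracted %d mentions over %d documents", len(mentions), len(docs))
    return out / "doc_labels.csv"


def run_cohort(config: PipelineConfig) -> Path:
    """Build cohort.csv and exclusions.log from the extracted labels."""
    out = _outdir(config)
    patients, events, docs = _load_inputs(config)
    labels = pd.read_csv(out / "doc_labels.csv", dtype={"doc_id": str})
    doc_has_ps = dict(zip(labels["doc_id"], labels["has_ps"].astype(bool)))
    doc_frame = synth_mod.documents_to_frame(docs)
    cohort, excl = cohort_mod.build_cohort(
        patients, events, doc_frame, doc_has_ps, config.cohort_params)
    cohort.to_csv(out / "cohort.csv", index=False)
    excl.to_tsv(out / "exclusions.log")
    for step, removed, remaining in excl.steps:
        log.info("exclusion %-45s removed %5d remaining %6d",
                 step, removed, remaining)
    return out / "cohort.csv"


def run_stats(config: PipelineConfig) -> Path:
    """Prevalence cross-tabs, extraction metrics vs gold, summary JSON."""
    out = _outdir(config)
    _, _, docs = _load_inputs(config)
    cohort = pd.read_csv(out / "cohort.csv", dtype={"patient_id": str,
                                                    "hospital_id": str})
    labels = pd.read_csv(out / "doc_labels.csv", dtype={"doc_id": str})
    doc_has_ps = dict(zip(labels["doc_id"], labels["has_ps"].astype(bool)))

    for by in (["hospital_id"], ["cancer_group"]):
        tab = prev_mod.patient_prevalence(cohort, by)
        tab.cells.to_csv(out / f"prevalence_patient_by_{by[0]}.csv", index=False)

    doc_frame = synth_mod.documents_to_frame(docs)
    index_dates = dict(zip(cohort["patient_id"],
                           pd.to_datetime(cohort["index_date"]).dt.date))
    in_window = cohort_mod.window_documents(
        doc_frame, index_dates, config.cohort_params)
    in_window = in_window.assign(
        has_ps=[doc_has_ps.get(d, False) for d in in_window["doc_id"]])
    if len(in_window):
        tab = prev_mod.document_prevalence(in_window, ["doc_type"])
        tab.cells.to_csv(out / "prevalence_document_by_type.csv", index=False)

    gold = {d.doc_id: d.gold_has_ps for d in docs}
    pred = {d: doc_has_ps.get(d, False) for d in gold}
    types = {d.doc_id: d.doc_type for d in docs}
    metrics = extract_mod.evaluate(gold, pred, types)
    (out / "extraction_metrics.json").write_text(json.dumps(
        {k: dataclasses.asdict(v) for k, v in metrics.items()},
        indent=2, sort_keys=True))

    summary = prev_mod.headline_summary(
        cohort, in_window if len(in_window) else None)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out / "summary.json"


def run_fit(config: PipelineConfig) -> Path:
    """Fit both model variants and write the coefficient tables."""
    out = _outdir(config)
    cohort = pd.read_csv(out / "cohort.csv", dtype={"patient_id": str,
                                                    "hospital_id": str})
    fit_a, fit_b, stability = reg_mod.compare_models(cohort, config.model_spec)
    table = pd.concat([
        reg_mod.coefficient_table(fit_a, "without_metastatic"),
        reg_mod.coefficient_table(fit_b, "with_metastatic"),
    ])
    table.to_csv(out / "coefficients.csv", index=False)
    stability.to_csv(out / "model_stability.csv", index=False)
    return out / "coefficients.csv"


def run_full(config: PipelineConfig) -> Path:
    """Run every stage and write a plain-text summary report."""
    out = _outdir(config)
    if config.simulate:
        run_simulate(config)
    run_extract(config)
    run_cohort(config)
    run_stats(config)
    run_fit(config)

    summary = json.loads((out / "summary.json").read_text())
    metrics = json.loads((out / "extraction_metrics.json").read_text())
    lines = [
        "PS documentation pipeline summary",
        "=================================",
        f"patients in cohort:            {summary['n_patients']}",
        f"patient-level PS prevalence:   {summary['patient_prevalence']:.3f}",
        f"1-year mortality, with PS:     {summary['mortality_1y_with_ps']:.3f}",
        f"1-year mortality, without PS:  {summary['mortality_1y_without_ps']:.3f}",
    ]
    if "document_prevalence" in summary:
        lines.append(
            f"document-level PS prevalence:  {summary['document_prevalence']:.3f}")
        for t, p in sorted(summary.get("document_prevalence_by_type", {}).items()):
            lines.append(f"  {t.lower():<28} {p:.3f}")
    lines.append(
        f"extractor accuracy (overall):  {metrics['overall']['accuracy']:.3f}")
    lines.append(
        f"extractor macro F1 (overall):  {metrics['overall']['macro_f1']:.3f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out / "summary.txt"
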