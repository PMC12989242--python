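"""Prevalence of performance-status documentation: descriptive statistics.

Patient- and document-level PS-documentation proportions, optionally
stratified (hospital, cancer group, document type), the Spearman
correlation between a hospital's document volume and its documentation
proportion, and one-year mortality split by documentation status.

Percentages destined for tables are rounded half-up to the printed
precision, so desk-scale recomputation from published counts reproduces
published cells exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrossTab",
    "patient_prevalence",
    "document_prevalence",
    "spearman_volume_correlation",
    "mortality_by_documentation",
    "percent",
]


def percent(n_with: float, n_total: float, decimals: int = 0) -> float:
    """Half-up-rounded percentage, as printed in summary tables.

    >>> percent(28105, 68479)
    41.0
    >>> percent(3221, 68479, 1)
    4.7
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(n_with) / Decimal(n_total) * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CrossTab:
    """Stratified counts of PS documentation.

    ``cells`` holds one row per stratum with n_with_ps, n_total and the
    exact proportion; strata with zero total are omitted.  ``overall`` is
    the unstratified (n_with_ps, n_total, proportion) triple.
    """

    by: tuple[str, ...]
    cells: pd.DataFrame
    overall: tuple[int, int, float]

    def proportions(self) -> dict:
        key = list(self.by)
        return {
            tuple(row[k] for k in key) if len(key) > 1 else row[key[0]]:
                row["proportion"]
            for _, row in self.cells.iterrows()
        }

    def check_marginals(self) -> bool:
        """Stratum counts must add up to the overall totals."""
        return (
            int(self.cells["n_with_ps"].sum()) == self.overall[0]
            and int(self.cells["n_total"].sum()) == self.overall[1]
        )


def _crosstab(df: pd.DataFrame, flag_col: str, by: Sequence[str]) -> CrossTab:
    if df.empty:
        raise ValueError("input table is empty")
    by = tuple(by)
    flags = df[flag_col].astype(bool)
    overall = (int(flags.sum()), len(df), float(flags.mean()))
    grouped = (
        df.assign(_flag=flags)
        .groupby(list(by), observed=True)["_flag"]
        .agg(n_with_ps="sum", n_total="count")
        .reset_index()
    )
    grouped = grouped[grouped["n_total"] > 0].copy()
    grouped["n_with_ps"] = grouped["n_with_ps"].astype(int)
    grouped["proportion"] = grouped["n_with_ps"] / grouped["n_total"]
    return CrossTab(by=by, cells=grouped, overall=overall)


def patient_prevalence(cohort: pd.DataFrame, by: Sequence[str]) -> CrossTab:
    """Proportion of patients with a documented PS, per stratum of ``by``
    (columns of the cohort table, e.g. hospital_id or cancer_group)."""
    return _crosstab(cohort, "has_ps", by)


def document_prevalence(
    documents: pd.DataFrame,
    by: Sequence[str],
    cancer_coded_only: bool = False,
) -> CrossTab:
    """Proportion of documents containing a PS, per stratum of ``by``.

    ``documents`` must carry a boolean ``has_ps`` column (the extractor's
    document-level decision) and be restricted to the cohort's in-window
    set.  With ``cancer_coded_only`` the table is first restricted to
    hospitalization reports linked to a cancer-coded stay.
    """
    df = documents
    if cancer_coded_only:
        df = df[(df["doc_type"] == "HOSPITALIZATION") & df["cancer_coded_stay"]]
    return _crosstab(df, "has_ps", by)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def spearman_volume_correlation(
    volumes: Sequence[float],
    proportions: Sequence[float],
    method: str = "t",
) -> tuple[float, float]:
    """Spearman's rho between per-hospital document volume and the
    per-hospital PS-documentation proportion, with a two-sided p-value.

    Average ranks for ties; p from the t-approximation
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom
    (``method="t"``), or exact permutation enumeration for n <= 8
    (``method="exact"``).
    """
    x = np.asarray(volumes, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if len(x) != len(y):
        raise ValueError("volumes and proportions must be aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 hospitals")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for an all-tied input")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if method == "t":
        p = float(res.pvalue)
    elif method == "exact":
        if len(x) > 8:
            raise ValueError("exact permutation p-value limited to n <= 8")
        p = _exact_spearman_p(x, y, rho)
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, p


def mortality_by_documentation(cohort: pd.DataFrame) -> tuple[float, float]:
    """One-year death proportions (with documented PS, without).

    Empty groups yield 0.0 for that arm.
    """
    has = cohort[cohort["has_ps"].astype(bool)]
    hasnt = cohort[~cohort["has_ps"].astype(bool)]
    p1 = float(has["died_within_1y"].mean()) if len(has) else 0.0
    p0 = float(hasnt["died_within_1y"].mean()) if len(hasnt) else 0.0
    return p1, p0


def headline_summary(
    cohort: pd.DataFrame, documents: pd.DataFrame | None = None
) -> dict:
    """Headline statistics bundle written by the pipeline's stats stage."""
    out: dict = {
        "n_patients": int(len(cohort)),
        "patient_prevalence": float(cohort["has_ps"].mean()),
    }
    p_with, p_without = mortality_by_documentation(cohort)
    out["mortality_1y_with_ps"] = p_with
    out["mortality_1y_without_ps"] = p_without
    if documents is not None and len(documents):
        out["n_documents"] = int(len(documents))
        out["document_prevalence"] = float(documents["has_ps"].mean())
        by_type = document_prevalence(documents, ["doc_type"])
        out["document_prevalence_by_type"] = {
            k: float(v) for k, v in by_type.proportions().items()
        }
    return out
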