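"""Cohort CSV reading/validation, scoring output and the evaluation report.

The cohort CSV schema (header names exact, order-insensitive):

    patient_id, ica_infraclinoid, ica_supraclinoid, m1_proximal, m1_distal,
    aca, m2_superior, m2_inferior (each 0/1), nihss (0-42), aspects (0-10),
    mrs0, mrs90 (0-6), treatment (optional: APT|TPA|EVT|empty)

plus optional repeated-rating columns cbs_rater1, cbs_rater2, mcbs_rater1,
mcbs_rater2 and any extra passthrough columns (age, sex, ...).

Validation is either strict (any bad row aborts) or lenient (bad rows are
quarantined with a reason and the analysis continues on the rest), mirroring
complete-case flow accounting in a clinical study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st
from .scoring import SEGMENTS, builtin_scheme, score_cohort

__all__ = [
    "CohortTable",
    "ValidationReport",
    "CohortValidationError",
    "REQUIRED_COLUMNS",
    "read_cohort",
    "write_cohort",
    "attach_scores",
    "run_evaluation",
    "write_report",
]

REQUIRED_COLUMNS: tuple[str, ...] = (
    "patient_id",
    *SEGMENTS,
    "nihss",
    "aspects",
    "mrs0",
    "mrs90",
)

RATER_COLUMNS: tuple[str, ...] = (
    "cbs_rater1",
    "cbs_rater2",
    "mcbs_rater1",
    "mcbs_rater2",
)

_TREATMENTS = {"APT", "TPA", "EVT"}


class CohortValidationError(ValueError):
    """A cohort file failed validation in strict mode."""


@dataclass
class ValidationReport:
    n_read: int = 0
    n_valid: int = 0
    quarantined: list = field(default_factory=list)  # (patient_id, reason)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantined)


@dataclass
class CohortTable:
    """Validated per-patient records plus provenance."""

    df: pd.DataFrame
    provenance: str = ""

    @property
    def n(self) -> int:
        return len(self.df)


def _row_problem(row: pd.Series) -> str | None:
    for s in SEGMENTS:
        v = row[s]
        if pd.isna(v) or v not in (0, 1, True, False):
            return f"segment flag {s!r} must be 0/1, got {v!r}"
    checks = (("nihss", 0, 42), ("aspects", 0, 10), ("mrs0", 0, 6), ("mrs90", 0, 6))
    for col, lo, hi in checks:
        v = row[col]
        if pd.isna(v):
            return f"{col} is missing"
        try:
            iv = int(v)
        except (TypeError, ValueError):
            return f"{col} must be an integer, got {v!r}"
        if iv != float(v) or not lo <= iv <= hi:
            return f"{col} must be an integer in {lo}..{hi}, got {v!r}"
    if "treatment" in row.index:
        t = row["treatment"]
        if not (pd.isna(t) or t == "" or t in _TREATMENTS):
            return f"treatment must be one of APT/TPA/EVT or empty, got {t!r}"
    return None


def read_cohort(path, strict: bool = False) -> tuple[CohortTable, ValidationReport]:
    """Read and validate a cohort CSV.

    Strict mode raises on the first invalid row; lenient mode quarantines
    invalid rows (with reasons) and returns the valid remainder.  Missing
    required columns and duplicate patient ids are errors in both modes.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "treatment": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required column(s): {', '.join(missing)}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dupes:
        raise CohortValidationError(f"duplicate patient_id(s): {sorted(set(dupes))}")

    report = ValidationReport(n_read=len(df))
    keep = []
    for idx, row in df.iterrows():
        problem = _row_problem(row)
        if problem is None:
            keep.append(idx)
        else:
            pid = str(row["patient_id"])
            if strict:
                raise CohortValidationError(f"row {pid}: {problem}")
            report.quarantined.append((pid, problem))
    valid = df.loc[keep].copy()
    for s in SEGMENTS:
        valid[s] = valid[s].astype(int)
    for col in ("nihss", "aspects", "mrs0", "mrs90"):
        valid[col] = valid[col].astype(int)
    report.n_valid = len(valid)
    return CohortTable(df=valid.reset_index(drop=True), provenance=str(path)), report


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table back to CSV (booleans serialized as 0/1)."""
    df = table.df.copy()
    for s in SEGMENTS:
        df[s] = df[s].astype(int)
    df.to_csv(path, index=False)


def attach_scores(table: CohortTable, schemes=("cbs", "mcbs")) -> pd.DataFrame:
    """Return the cohort frame with one integer score column per scheme."""
    df = table.df.copy()
    for name in schemes:
        report = score_cohort(df, builtin_scheme(name))
        if report.unscorable:
            bad = ", ".join(pid for pid, _ in report.unscorable)
            raise CohortValidationError(f"unscorable rows for {name}: {bad}")
        df[name] = report.scores()
    return df


# ---------------------------------------------------------------------------
# evaluation report


def _r4(x: float) -> float:
    return float(np.round(float(x), 4))


def _pct(x: float) -> float:
    return float(np.round(100.0 * float(x), 2))


def _corr_entry(res: st.CorrelationResult) -> dict:
    return {
        "rho": _r4(res.rho),
        "p_value": _r4(res.p_value),
        "n": res.n,
        "method": res.method,
    }


def _roc_entry(scores: np.ndarray, labels: st.OutcomeLabels) -> dict:
    roc_res = st.roc(scores, labels)
    yj = st.youden(roc_res)
    return {
        "auc": _r4(roc_res.auc),
        "auc_se": _r4(roc_res.auc_se),
        "ci95": [_r4(roc_res.ci95[0]), _r4(roc_res.ci95[1])],
        "n_pos": roc_res.n_pos,
        "n_neg": roc_res.n_neg,
        "youden_j": _r4(yj.j),
        "criterion": f"<={yj.criterion:g}",
        "sensitivity_pct": _pct(yj.sensitivity),
        "specificity_pct": _pct(yj.specificity),
    }


def run_evaluation(table: CohortTable, strata_col: str | None = None) -> dict:
    """Score both schemes and compute the full score-vs-outcome report.

    Sections: correlations (score vs NIHSS/ASPECTS/mRS90),
    outcome_correlations (score vs each dichotomized outcome), roc (per
    outcome per scheme, with Youden criteria), paired_tests (DeLong),
    stratified (optional, per treatment stratum), contingency (score x
    disability counts).  Deterministic and JSON-serializable with stable
    key order.
    """
    df = attach_scores(table)
    outcomes = {}
    triples = np.array([st.dichotomize(m, s) for m, s in zip(df["mrs90"], df["nihss"])])
    for j, name in enumerate(("mortality", "disability", "severity")):
        outcomes[name] = st.OutcomeLabels(triples[:, j], name)

    report: dict = {
        "meta": {
            "n": int(len(df)),
            "provenance": table.provenance,
            "schemes": ["cbs", "mcbs"],
            "positivity_rule": "score <= criterion predicts the adverse outcome",
        }
    }

    corr = {}
    for scheme in ("cbs", "mcbs"):
        corr[scheme] = {
            target: _corr_entry(st.spearman(df[scheme], df[target]))
            for target in ("nihss", "aspects", "mrs90")
        }
    report["correlations"] = corr

    oc = {}
    for scheme in ("cbs", "mcbs"):
        oc[scheme] = {}
        for name, labels in outcomes.items():
            try:
                oc[scheme][name] = _corr_entry(st.spearman(df[scheme], labels.labels))
            except st.ConstantInputError:
                oc[scheme][name] = {"note": "degenerate: single outcome class"}
    report["outcome_correlations"] = oc

    roc_section: dict = {}
    paired: dict = {}
    for name, labels in outcomes.items():
        if labels.n_pos == 0 or labels.n_neg == 0:
            roc_section[name] = {"note": "degenerate: single outcome class"}
            paired[name] = {"note": "degenerate: single outcome class"}
            continue
        roc_section[name] = {
            scheme: _roc_entry(df[scheme].to_numpy(), labels)
            for scheme in ("cbs", "mcbs")
        }
        cmp_res = st.delong_paired(
            df["mcbs"].to_numpy(), df["cbs"].to_numpy(), labels
        )
        paired[name] = {
            "auc_mcbs": _r4(cmp_res.auc_a),
            "auc_cbs": _r4(cmp_res.auc_b),
            "delta": _r4(cmp_res.delta),
            "z": _r4(cmp_res.z),
            "p_value": _r4(cmp_res.p_value),
        }
    report["roc"] = roc_section
    report["paired_tests"] = paired

    if strata_col is not None:
        strat = {}
        for scheme in ("cbs", "mcbs"):
            strat[scheme] = {}
            for name, labels in outcomes.items():
                tmp = df.assign(_outcome=labels.labels)
                recs = st.stratified_spearman(tmp, scheme, "_outcome", strata_col)
                strat[scheme][name] = {
                    str(r["group"]): (
                        _corr_entry(r["result"])
                        if r["result"] is not None
                        else {"skipped": r["skipped_reason"], "n": r["n"]}
                    )
                    for r in recs
                }
        report["stratified"] = strat

    contingency = {}
    for scheme in ("cbs", "mcbs"):
        tab = st.score_outcome_table(
            df[scheme].to_numpy(), outcomes["disability"]
        )
        contingency[scheme] = {
            str(int(score)): {"n_neg": int(r["n_neg"]), "n_pos": int(r["n_pos"])}
            for score, r in tab.iterrows()
        }
    report["contingency_disability"] = contingency
    return report


def write_report(report: dict, path) -> None:
    """Serialize a report with stable key order (byte-identical re-runs)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
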