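"""Cohort-level report: contingency, survival, and stratified-Cox summaries.

Takes a clinical table that already carries `tmb` and `min_phbr` columns and
produces the dichotomized comparisons the pipeline is built for: PHBR-class
demographics (risk ratio + Fisher), Kaplan-Meier medians with log-rank and
hazard ratios for each dichotomy and the four TMB × PHBR strata, and the
TMB-stratified Cox quantifying the PHBR effect on PFS.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .cohort import (
    BENEFIT,
    DEFAULT_PHBR_THRESHOLD,
    DEFAULT_TMB_THRESHOLD,
    NO_BENEFIT,
    NOT_EVALUABLE,
    assign_stratum,
    dichotomize_phbr,
    dichotomize_tmb,
    overall_benefit,
)
from .errors import EmptyInputError
from .stats import (
    ContingencyTable2x2,
    cox_ph,
    fisher_exact,
    km_fit,
    log_rank,
    risk_ratio,
)


def annotate_classes(
    clinical: pd.DataFrame,
    tmb_threshold: float = DEFAULT_TMB_THRESHOLD,
    phbr_threshold: float = DEFAULT_PHBR_THRESHOLD,
) -> pd.DataFrame:
    """Add tmb_class / phbr_class / stratum / benefit columns."""
    df = clinical.copy()
    df["tmb_class"] = [
        dichotomize_tmb(None if pd.isna(t) else float(t), tmb_threshold)
        for t in df["tmb"]
    ]
    df["phbr_class"] = [
        dichotomize_phbr(float(p), phbr_threshold) for p in df["min_phbr"]
    ]
    df["stratum"] = [
        assign_stratum(t, p).joint for t, p in zip(df["tmb_class"], df["phbr_class"])
    ]
    df["benefit"] = [
        overall_benefit(r, None if pd.isna(f) else float(f))
        for r, f in zip(df["response"], df.get("followup_months", [None] * len(df)))
    ]
    return df


def _phbr_rr_row(df: pd.DataFrame, mask: pd.Series, label: str) -> Optional[dict]:
    """One demographics row: group vs rest, outcome = PHBR-low membership."""
    a = int(((df["phbr_class"] == "low") & mask).sum())
    b = int(((df["phbr_class"] == "high") & mask).sum())
    c = int(((df["phbr_class"] == "low") & ~mask).sum())
    d = int(((df["phbr_class"] == "high") & ~mask).sum())
    table = ContingencyTable2x2(a, b, c, d)
    row = {"comparison": label, "a": a, "b": b, "c": c, "d": d,
           "p_fisher": fisher_exact(table)}
    try:
        rr = risk_ratio(table)
        row.update(rr=rr.rr, ci_low=rr.ci_low, ci_high=rr.ci_high)
    except EmptyInputError:
        pass
    except Exception:
        row.update(rr=np.nan, ci_low=np.nan, ci_high=np.nan)
    return row


def contingency_report(df: pd.DataFrame) -> pd.DataFrame:
    """Demographics-by-PHBR-class table (risk ratio for PHBR < threshold)."""
    rows = []
    if df["sex"].notna().any():
        rows.append(_phbr_rr_row(df, df["sex"] == "male", "male vs female"))
    if df["therapy"].notna().any():
        rows.append(
            _phbr_rr_row(df, df["therapy"] == "monotherapy", "monotherapy vs combination")
        )
    for threshold in (10.0, 20.0, 50.0):
        high = df["tmb"].notna() & (df["tmb"] >= threshold)
        rows.append(_phbr_rr_row(df, ~high, f"TMB<{threshold:g} vs >={threshold:g}"))
    evaluable = df["benefit"] != NOT_EVALUABLE
    rows.append(
        _phbr_rr_row(df[evaluable], df.loc[evaluable, "benefit"] == BENEFIT,
                     "benefit vs no benefit")
    )
    rows.append(_phbr_rr_row(df[evaluable], df.loc[evaluable, "response"] == "PD",
                             "PD vs others"))
    return pd.DataFrame([r for r in rows if r is not None])


def benefit_rate(df: pd.DataFrame) -> tuple[int, int]:
    """(benefit count, evaluable denominator); not-evaluable patients excluded."""
    evaluable = df["benefit"] != NOT_EVALUABLE
    return int((df["benefit"] == BENEFIT).sum()), int(evaluable.sum())


def _survival_comparison(
    df: pd.DataFrame, groups: dict[str, pd.Series], time_col: str, event_col: str
) -> dict:
    fits = {}
    samples = []
    for label, mask in groups.items():
        sub = df[mask & df[time_col].notna() & df[event_col].notna()]
        times = sub[time_col].astype(float).to_numpy()
        events = sub[event_col].astype(bool).to_numpy()
        fits[label] = km_fit(times, events)
        samples.append((times, events))
    lr = log_rank(samples)
    return {
        "medians": {
            label: (fit.median if fit.median_reached
                    else f"NR (median follow-up {fit.median_followup:.1f})")
            for label, fit in fits.items()
        },
        "n": {label: fit.n for label, fit in fits.items()},
        "log_rank_p": lr.p_value,
        "hazard_ratio": lr.hazard_ratio,
        "hr_ci": (lr.hr_ci_low, lr.hr_ci_high),
        "fits": fits,
    }


def survival_report(df: pd.DataFrame, time_col: str = "pfs_months",
                    event_col: str = "pfs_event") -> dict:
    """KM + log-rank for the PHBR dichotomy, the TMB dichotomy, and the 4 strata."""
    report = {
        "by_phbr": _survival_comparison(
            df,
            {"PHBR-low": df["phbr_class"] == "low",
             "PHBR-high": df["phbr_class"] == "high"},
            time_col, event_col,
        ),
        "by_tmb": _survival_comparison(
            df,
            {"TMB-high": df["tmb_class"] == "high",
             "TMB-low": df["tmb_class"] == "low"},
            time_col, event_col,
        ),
    }
    strata = {s: df["stratum"] == s for s in df["stratum"].unique()}
    if len(strata) >= 2:
        report["by_stratum"] = _survival_comparison(df, strata, time_col, event_col)
    return report


def stratified_phbr_cox(df: pd.DataFrame, time_col: str = "pfs_months",
                        event_col: str = "pfs_event"):
    """Cox PH of the PHBR-low indicator, stratified by TMB class.

    Each TMB stratum keeps its own baseline hazard, so the fit quantifies the
    within-stratum PHBR effect.
    """
    data = pd.DataFrame(
        {
            "time": df[time_col].astype(float),
            "event": df[event_col].astype(bool).astype(int),
            "phbr_low": (df["phbr_class"] == "low").astype(int),
            "tmb_class": df["tmb_class"],
        }
    )
    return cox_ph(data, "time", "event", ["phbr_low"], strata="tmb_class")


def analyze_cohort(
    clinical: pd.DataFrame,
    tmb_threshold: float = DEFAULT_TMB_THRESHOLD,
    phbr_threshold: float = DEFAULT_PHBR_THRESHOLD,
) -> dict:
    """Full report: contingency, benefit rates, PFS/OS survival, stratified Cox."""
    df = annotate_classes(clinical, tmb_threshold, phbr_threshold)
    out: dict = {"n_patients": int(len(df)), "annotated": df}
    out["contingency"] = contingency_report(df)
    n_benefit, n_evaluable = benefit_rate(df)
    out["benefit_rate"] = {"benefit": n_benefit, "evaluable": n_evaluable}
    out["stratum_counts"] = df["stratum"].value_counts().to_dict()
    out["pfs"] = survival_report(df, "pfs_months", "pfs_event")
    if df.get("os_months") is not None and df["os_months"].notna().any():
        out["os"] = survival_report(df, "os_months", "os_event")
    try:
        cox = stratified_phbr_cox(df)
        row = cox.summary.loc["phbr_low"]
        out["stratified_cox_phbr"] = {
            "hazard_ratio": float(row["hazard_ratio"]),
            "ci": (float(row["hr_ci_low"]), float(row["hr_ci_high"])),
            "p": float(row["p"]),
            "n": cox.n,
            "n_events": cox.n_events,
        }
    except Exception as exc:  # degenerate small cohorts
        out["stratified_cox_phbr"] = {"error": str(exc)}
    return out
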