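"""Outcome statistics: contingency, survival, and model-selection layer.

Implements the analyses used to relate presentation (min-PHBR) and mutational
burden (TMB) to checkpoint-blockade outcome: 2×2 risk ratios with Wald
log-scale confidence intervals, Fisher's exact test, Kaplan-Meier estimation
with log-rank comparison, Cox proportional-hazards regression (optionally
stratified so each TMB stratum keeps its own baseline hazard), backward
model selection on AIC for logistic regression with AUROC reporting, and the
rank-based auxiliaries (Spearman, Mann-Whitney).

Estimation is delegated to scipy / lifelines / statsmodels / scikit-learn;
this module owns the estimators' wiring, the risk-ratio formula, and the
backward-AIC loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import statsmodels.api as sm

from .errors import (
    ArityError,
    DegenerateModelError,
    DomainError,
    EmptyInputError,
    UndefinedEstimateError,
)

DEFAULT_ALPHA = 0.05
#: univariable p-value below which a covariate enters multivariable models
MULTIVARIABLE_INCLUSION_P = 0.10


# ---------------------------------------------------------------------------
# contingency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b | c, d): rows are comparison groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DomainError("contingency counts must be nonnegative")

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class RiskRatioResult:
    rr: float
    ci_low: float
    ci_high: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if not self.ci_low <= self.rr <= self.ci_high:
            raise DomainError("risk-ratio CI does not bracket the estimate")


def risk_ratio(table: ContingencyTable2x2, alpha: float = DEFAULT_ALPHA) -> RiskRatioResult:
    """Risk ratio (a/(a+b)) / (c/(c+d)) with a Wald CI on the log scale.

    CI = exp(ln RR ± z_{1-α/2} · sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))).
    No continuity correction; zero numerator cells make the estimate
    undefined and raise.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0 or c == 0:
        raise UndefinedEstimateError(
            "risk ratio and its Wald CI are undefined with a zero numerator cell"
        )
    if a + b == 0 or c + d == 0:
        raise UndefinedEstimateError("both comparison groups must be nonempty")
    rr = (a / (a + b)) / (c / (c + d))
    se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    z = sps.norm.ppf(1 - alpha / 2)
    return RiskRatioResult(
        rr=rr,
        ci_low=float(np.exp(np.log(rr) - z * se)),
        ci_high=float(np.exp(np.log(rr) + z * se)),
        alpha=alpha,
    )


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: hypergeometric tables as or less probable."""
    return float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Product-limit estimate for one group.

    `median` is the smallest time with S(t) ≤ 0.5, or None when not reached;
    a not-reached median is accompanied by the reverse-KM median follow-up.
    """

    survival: pd.DataFrame  # columns: time, survival, at_risk
    median: Optional[float]
    median_followup: Optional[float]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return self.median is not None


def km_fit(times: Sequence[float], events: Sequence[bool]) -> SurvivalFit:
    """Kaplan-Meier product-limit fit of one group, censoring at last visit."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise EmptyInputError("cannot fit a survival curve to an empty group")
    if (times < 0).any():
        raise DomainError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.values,
            "survival": kmf.survival_function_.iloc[:, 0].values,
            "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).values,
        }
    )
    median = kmf.median_survival_time_
    median = None if np.isinf(median) else float(median)
    median_followup = None
    if median is None:
        # reverse KM: flip event flags so censorings become "events"
        rkm = KaplanMeierFitter()
        rkm.fit(times, event_observed=~events)
        mfu = rkm.median_survival_time_
        median_followup = None if np.isinf(mfu) else float(mfu)
    return SurvivalFit(
        survival=curve,
        median=median,
        median_followup=median_followup,
        n=int(times.size),
        n_events=int(events.sum()),
    )


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    degrees_of_freedom: int
    hazard_ratio: Optional[float] = None  # 2-group comparisons only
    hr_ci_low: Optional[float] = None
    hr_ci_high: Optional[float] = None


def log_rank(
    groups: Sequence[tuple[Sequence[float], Sequence[bool]]],
    alpha: float = DEFAULT_ALPHA,
    with_hazard_ratio: bool = True,
) -> LogRankResult:
    """Log-rank test across ≥ 2 groups.

    For exactly two groups an unadjusted Cox fit supplies the accompanying
    hazard ratio (first group relative to the second); pass
    ``with_hazard_ratio=False`` to skip that fit when only the test is needed.
    """
    if len(groups) < 2:
        raise ArityError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for idx, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            raise EmptyInputError(f"log-rank group {idx} is empty")
        times.append(t)
        events.append(np.asarray(e, dtype=bool))
        labels.append(np.full(t.size, idx))
    result = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    out = LogRankResult(
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        degrees_of_freedom=len(groups) - 1,
    )
    if len(groups) == 2 and with_hazard_ratio:
        df = pd.DataFrame(
            {
                "time": np.concatenate(times),
                "event": np.concatenate(events).astype(int),
                "group0": (np.concatenate(labels) == 0).astype(int),
            }
        )
        if df["event"].sum() > 0 and df["group0"].nunique() == 2:
            cox = cox_ph(df, "time", "event", ["group0"], alpha=alpha)
            row = cox.summary.loc["group0"]
            out.hazard_ratio = float(row["hazard_ratio"])
            out.hr_ci_low = float(row["hr_ci_low"])
            out.hr_ci_high = float(row["hr_ci_high"])
    return out


@dataclass
class CoxResult:
    """Cox proportional-hazards fit (Efron tie handling).

    `summary` is indexed by covariate with columns coef, hazard_ratio,
    hr_ci_low, hr_ci_high, p.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    strata: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


def cox_ph(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str],
    strata: Optional[str] = None,
    alpha: float = DEFAULT_ALPHA,
) -> CoxResult:
    """Cox PH regression; `strata` gives each stratum its own baseline hazard.

    Ties are handled by Efron's method (lifelines' default).  Complete-case:
    rows with missing values in any used column are dropped.
    """
    cols = [duration_col, event_col, *covariates] + ([strata] if strata else [])
    df = data[cols].dropna().copy()
    if df.empty:
        raise EmptyInputError("no complete cases for Cox regression")
    if df[event_col].sum() == 0:
        raise DegenerateModelError("no events: Cox partial likelihood is degenerate")
    if strata is not None:
        if (df.groupby(strata)[event_col].sum() == 0).any():
            raise DegenerateModelError(f"a {strata!r} stratum has no events")
    fitter = CoxPHFitter(alpha=alpha)
    fit_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(
                df,
                duration_col=duration_col,
                event_col=event_col,
                strata=strata,
                show_progress=False,
            )
        except Exception as exc:
            raise DegenerateModelError(f"Cox fit did not converge: {exc}") from exc
        fit_warnings = [str(w.message) for w in caught if "convergence" in str(w.message).lower()]
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "hr_ci_low": np.exp(s[f"coef lower {100 * (1 - alpha):g}%"]),
            "hr_ci_high": np.exp(s[f"coef upper {100 * (1 - alpha):g}%"]),
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        n=int(df.shape[0]),
        n_events=int(df[event_col].sum()),
        strata=strata,
        warnings=fit_warnings,
    )


# ---------------------------------------------------------------------------
# logistic model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    """Backward-AIC logistic selection trace and final model."""

    retained: list[str]
    aic_trace: list[tuple[str, float]]  # (action, AIC after it)
    final_params: pd.Series
    final_pvalues: pd.Series
    auroc: float
    forced_aic: dict[str, float] = field(default_factory=dict)
    forced_auroc: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[sm.Logit, object, list[str]]:
    design = sm.add_constant(X, has_constant="add")
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, design)
        result = model.fit(disp=0, maxiter=200)
        for w in caught:
            msg = str(w.message)
            if "separat" in msg.lower() or "converge" in msg.lower():
                notes.append(msg)
    return model, result, notes


def backward_aic_logistic(
    outcome: Sequence[int],
    candidates: pd.DataFrame,
    forced_terms: Optional[pd.DataFrame] = None,
) -> ModelSelectionResult:
    """Backward elimination on AIC, then sequential addition of forced terms.

    Starting from the full candidate-covariate logistic model, single terms
    are removed one at a time; at each step the removal producing the lowest
    AIC is accepted iff it does not increase the AIC, until no acceptable
    removal remains.  Forced terms (e.g. TMB, then PHBR) are then added
    sequentially and the AIC after each addition is recorded, together with
    the in-sample AUROC of each model.  Separation or non-convergence is
    reported in `warnings`, never silently ignored.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("outcome must be binary 0/1")
    candidates = candidates.copy()
    notes: list[str] = []

    current = list(candidates.columns)
    _, result, w = _fit_logit(y, candidates[current])
    notes.extend(w)
    trace: list[tuple[str, float]] = [("full model", float(result.aic))]
    current_aic = float(result.aic)

    while current:
        best_term, best_aic = None, current_aic
        for term in current:
            reduced = [t for t in current if t != term]
            _, res, w2 = _fit_logit(y, candidates[reduced])
            if float(res.aic) <= best_aic:
                best_term, best_aic = term, float(res.aic)
        if best_term is None:
            break
        current.remove(best_term)
        current_aic = best_aic
        trace.append((f"removed {best_term}", best_aic))

    _, final_res, w3 = _fit_logit(y, candidates[current])
    notes.extend(w3)
    final_scores = np.asarray(final_res.predict())
    final_auroc = auroc(final_scores, y) if len(np.unique(y)) == 2 else float("nan")

    forced_aic: dict[str, float] = {}
    forced_auroc: dict[str, float] = {}
    params, pvalues = final_res.params, final_res.pvalues
    if forced_terms is not None and not forced_terms.empty:
        X = candidates[current].copy()
        for term in forced_terms.columns:
            X[term] = forced_terms[term].values
            _, res, w4 = _fit_logit(y, X)
            notes.extend(w4)
            forced_aic[term] = float(res.aic)
            forced_auroc[term] = auroc(np.asarray(res.predict()), y)
            params, pvalues = res.params, res.pvalues
            final_auroc = forced_auroc[term]

    return ModelSelectionResult(
        retained=current,
        aic_trace=trace,
        final_params=params,
        final_pvalues=pvalues,
        auroc=float(final_auroc),
        forced_aic=forced_aic,
        forced_auroc=forced_auroc,
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# rank-based auxiliaries
# ---------------------------------------------------------------------------

def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUROC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedEstimateError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ArityError("spearman needs equal-length vectors of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedEstimateError("spearman undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with tie correction, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("both samples must be nonempty")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(u), float(p)
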