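"""Prognostic analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

Reproduces the downstream analysis of a signature-classified cohort:

* Kaplan-Meier curves (with censor marks) per endpoint, optionally grouped;
* unweighted log-rank tests between groups;
* univariate and multivariate Cox models over the standard clinical
  covariates (Efron tie handling, Wald CIs and p-values);
* the two-step prognostic-factor report: every covariate univariately, then
  a multivariate model over those with univariate p <= the entry threshold;
* subgroup RFS analysis by hormone-receptor subtype and grade;
* a baseline-characteristics table with chi-squared / Kruskal-Wallis tests.

Estimation is delegated to lifelines; this module owns the covariate
codings, the variable-entry rule, the subgroup definitions, and degenerate
cases (zero events, single groups, missing strata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import COX_VARIABLES, ENDPOINTS, CohortRecord, records_to_frame
from .errors import (
    ConvergenceError,
    DegenerateGroupingError,
    InvalidInputError,
)

log = logging.getLogger(__name__)

GroupBy = Optional[str | Callable[[CohortRecord], object]]


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate for one group."""

    group: object
    times: np.ndarray          # distinct event times, increasing
    survival: np.ndarray       # S(t) at those times; non-increasing, starts <= 1
    at_risk: np.ndarray        # risk-set size just before each event time
    censor_marks: np.ndarray   # censoring times
    n: int
    n_events: int


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    group_sizes: dict = field(default_factory=dict)


@dataclass
class CoxRow:
    variable: str
    label: str
    reference: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class CoxFit:
    model_type: str            # "univariate" or "multivariate"
    endpoint: str
    rows: list[CoxRow]
    n_used: int
    n_excluded: int
    n_events: int

    def row(self, variable: str) -> CoxRow:
        for r in self.rows:
            if r.variable == variable:
                return r
        raise KeyError(variable)


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    if endpoint not in ENDPOINTS:
        raise InvalidInputError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    return f"{endpoint}_time", f"{endpoint}_event"


def _group_labels(records: Sequence[CohortRecord], group_by: GroupBy) -> list[object]:
    if group_by is None:
        return ["all"] * len(records)
    if callable(group_by):
        return [group_by(r) for r in records]
    return [getattr(r, group_by) for r in records]


def kaplan_meier(records: Sequence[CohortRecord], endpoint: str = "rfs",
                 group_by: GroupBy = None) -> dict[object, SurvivalCurve]:
    """Kaplan-Meier product-limit curves, one per group.

    Censored subjects leave the risk set without a survival drop; censoring
    times are returned for tick marks.
    """
    if not records:
        raise InvalidInputError("empty cohort")
    tcol, ecol = _endpoint_columns(endpoint)
    labels = _group_labels(records, group_by)
    curves: dict[object, SurvivalCurve] = {}
    for g in dict.fromkeys(labels):  # preserves first-seen order
        sub = [r for r, lab in zip(records, labels) if lab == g]
        t = np.array([getattr(r, tcol) for r in sub], dtype=float)
        e = np.array([getattr(r, ecol) for r in sub], dtype=int)
        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        event_times = np.sort(np.unique(t[e == 1]))
        surv = kmf.survival_function_at_times(event_times).to_numpy() if len(event_times) else np.array([])
        # risk-set size just before each event time
        at_risk = np.array([(t >= et).sum() for et in event_times], dtype=int)
        curves[g] = SurvivalCurve(
            group=g, times=event_times, survival=surv, at_risk=at_risk,
            censor_marks=np.sort(t[e == 0]), n=len(sub), n_events=int(e.sum()))
    return curves


def log_rank(records: Sequence[CohortRecord], endpoint: str = "rfs",
             group_by: GroupBy = "tp53_status") -> LogRankResult:
    """Unweighted log-rank test between groups (df = #groups - 1)."""
    tcol, ecol = _endpoint_columns(endpoint)
    labels = _group_labels(records, group_by)
    groups = sorted(set(labels), key=str)
    if len(groups) < 2:
        raise DegenerateGroupingError(
            f"log-rank needs >= 2 groups, got {len(groups)}")
    t = [getattr(r, tcol) for r in records]
    e = [getattr(r, ecol) for r in records]
    res = multivariate_logrank_test(t, labels, e)
    sizes = {g: labels.count(g) for g in groups}
    return LogRankResult(statistic=float(res.test_statistic),
                         df=len(groups) - 1,
                         p_value=float(res.p_value),
                         group_sizes=sizes)


def cox_fit(records: Sequence[CohortRecord], endpoint: str,
            variables: Sequence[str], model_type: str) -> CoxFit:
    """Cox proportional-hazards fit over the named binary covariates.

    Complete-case: records missing any requested covariate are excluded and
    the exclusion count logged.  Ties are handled with the Efron
    approximation; hazard ratios come with Wald 95% CIs and p-values.
    """
    unknown = [v for v in variables if v not in COX_VARIABLES]
    if unknown:
        raise InvalidInputError(f"unknown Cox variable(s): {unknown}; "
                                f"known: {sorted(COX_VARIABLES)}")
    if model_type not in ("univariate", "multivariate"):
        raise InvalidInputError(f"model_type must be univariate or multivariate")
    tcol, ecol = _endpoint_columns(endpoint)

    rows = []
    for r in records:
        row = {"_time": getattr(r, tcol), "_event": getattr(r, ecol)}
        for v in variables:
            row[v] = COX_VARIABLES[v].encode(r)
        rows.append(row)
    df = pd.DataFrame(rows)
    n_total = len(df)
    df = df.dropna()
    n_excluded = n_total - len(df)
    if n_excluded:
        log.info("cox_fit(%s, %s): excluded %d incomplete record(s)",
                 endpoint, model_type, n_excluded)
    if df.empty or df["_event"].sum() < 1:
        raise InvalidInputError(f"cox_fit needs at least one {endpoint} event")
    for v in variables:
        if df[v].nunique() < 2:
            raise DegenerateGroupingError(
                f"variable {v!r} has a single level among complete cases")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except (_LLConvergenceError, ValueError) as exc:
        raise ConvergenceError(f"Cox fit failed for {variables}: {exc}") from exc

    out: list[CoxRow] = []
    for v in variables:
        spec = COX_VARIABLES[v]
        out.append(CoxRow(
            variable=v, label=spec.label, reference=spec.reference,
            hazard_ratio=float(np.exp(cph.params_[v])),
            ci_low=float(np.exp(cph.confidence_intervals_.loc[v].iloc[0])),
            ci_high=float(np.exp(cph.confidence_intervals_.loc[v].iloc[1])),
            p_value=float(cph.summary.loc[v, "p"]),
        ))
    return CoxFit(model_type=model_type, endpoint=endpoint, rows=out,
                  n_used=len(df), n_excluded=n_excluded,
                  n_events=int(df["_event"].sum()))


def run_table3(records: Sequence[CohortRecord], endpoint: str = "rfs",
               entry_p: float = 0.05) -> dict:
    """Two-step prognostic-factor report for one endpoint.

    Every covariate is fitted univariately; covariates with univariate Wald
    p <= ``entry_p`` then enter one multivariate model together.  If the
    selection is empty the multivariate step is skipped with a notice.
    """
    if not (0 < entry_p <= 1):
        raise InvalidInputError("entry_p must be in (0, 1]")
    univariate: list[CoxFit] = []
    for v in COX_VARIABLES:
        univariate.append(cox_fit(records, endpoint, [v], "univariate"))
    selected = [f.rows[0].variable for f in univariate if f.rows[0].p_value <= entry_p]
    multivariate = None
    if selected:
        multivariate = cox_fit(records, endpoint, selected, "multivariate")
    else:
        log.info("run_table3: no covariate reached univariate p <= %.3g; "
                 "multivariate step skipped", entry_p)
    return {"endpoint": endpoint, "entry_p": entry_p,
            "univariate": univariate, "selected": selected,
            "multivariate": multivariate}


# ---------------------------------------------------------------------------
# subgroup analysis

def _tnbc(r: CohortRecord) -> bool:
    return r.er == "negative" and r.pgr == "negative" and r.her2 == "negative"


#: Subgroup -> membership predicate (None = excluded for missing data).
SUBGROUPS: dict[str, Callable[[CohortRecord], Optional[bool]]] = {
    "ER-positive": lambda r: r.er == "positive",
    "ER-negative": lambda r: r.er == "negative",
    "LuminalA-like": lambda r: None if (r.er == "positive" and r.ki67_high is None)
        else (r.er == "positive" and r.ki67_high is False),
    "LuminalB-like": lambda r: None if (r.er == "positive" and r.ki67_high is None)
        else (r.er == "positive" and r.ki67_high is True),
    "TNBC": _tnbc,
    "Grade1": lambda r: None if r.grade is None else r.grade == 1,
    "Grade2": lambda r: None if r.grade is None else r.grade == 2,
    "Grade3": lambda r: None if r.grade is None else r.grade == 3,
}


def subgroup_rfs(records: Sequence[CohortRecord],
                 endpoint: str = "rfs") -> dict[str, dict]:
    """RFS by TP53 signature status within each clinical subgroup.

    Luminal A-like is ER-positive with Ki-67 < 10%; luminal B-like is
    ER-positive with Ki-67 >= 10% (the boundary value 10 goes to the high
    stratum); TNBC is ER-, PgR- and HER2-negative.  Subgroups that are empty,
    have a single TP53 class, or have no events report the degenerate
    condition instead of a p-value.
    """
    report: dict[str, dict] = {}
    for name, pred in SUBGROUPS.items():
        flags = [pred(r) for r in records]
        n_missing = sum(f is None for f in flags)
        members = [r for r, f in zip(records, flags) if f]
        entry: dict = {"n": len(members), "n_excluded_missing": n_missing}
        if n_missing:
            log.info("subgroup %s: %d record(s) excluded for missing data",
                     name, n_missing)
        if not members:
            entry["skipped"] = "empty subgroup"
            log.info("subgroup %s skipped: no patients", name)
            report[name] = entry
            continue
        entry["curves"] = kaplan_meier(members, endpoint, "tp53_status")
        statuses = {r.tp53_status for r in members}
        n_events = sum(getattr(r, f"{endpoint}_event") for r in members)
        if len(statuses) < 2:
            entry["skipped"] = f"single TP53 class ({statuses.pop()})"
        elif n_events == 0:
            entry["skipped"] = "no events in subgroup"
        else:
            entry["log_rank"] = log_rank(members, endpoint, "tp53_status")
            entry["events_by_group"] = {
                g: c.n_events for g, c in entry["curves"].items()}
        report[name] = entry
    return report


# ---------------------------------------------------------------------------
# baseline characteristics

#: Categorical characteristics: display name -> per-record level function
#: (None = NA, excluded from the test but counted).
_CHARACTERISTICS: dict[str, Callable[[CohortRecord], Optional[str]]] = {
    "p_stage": lambda r: r.p_stage,
    "er": lambda r: r.er,
    "pgr": lambda r: r.pgr,
    "her2": lambda r: r.her2,
    "tumor_size": lambda r: "<=2" if r.tumor_size_cm <= 2
        else (">2,<=5" if r.tumor_size_cm <= 5 else ">5"),
    "p_ln": lambda r: r.p_ln,
    "grade": lambda r: None if r.grade is None else str(r.grade),
    "ki67": lambda r: None if r.ki67_high is None
        else (">=10" if r.ki67_high else "<10"),
    "adj_chemo": lambda r: r.adj_chemo,
    "adj_endocrine": lambda r: r.adj_endocrine,
}


def characteristics_table(records: Sequence[CohortRecord],
                          group_by: str = "tp53_status") -> dict[str, dict]:
    """Baseline-characteristics comparison between groups.

    Each categorical variable gets a chi-squared test (no continuity
    correction) on its contingency table over non-missing records; age gets a
    Kruskal-Wallis test.  NA levels are excluded from the tests but reported
    as counts.  Tests with a zero expected cell are skipped with a warning.
    """
    labels = _group_labels(records, group_by)
    groups = sorted(set(labels), key=str)
    if len(groups) < 2:
        raise DegenerateGroupingError("characteristics table needs >= 2 groups")

    out: dict[str, dict] = {}
    ages = {g: [r.age for r, lab in zip(records, labels) if lab == g] for g in groups}
    kw_stat, kw_p = stats.kruskal(*ages.values())
    out["age"] = {"test": "kruskal-wallis", "statistic": float(kw_stat),
                  "p_value": float(kw_p),
                  "median": {g: float(np.median(a)) for g, a in ages.items()}}

    for name, levelfun in _CHARACTERISTICS.items():
        levels = [levelfun(r) for r in records]
        n_na = {g: sum(1 for lv, lab in zip(levels, labels) if lv is None and lab == g)
                for g in groups}
        present = sorted({lv for lv in levels if lv is not None})
        counts = pd.DataFrame(0, index=present, columns=groups)
        for lv, lab in zip(levels, labels):
            if lv is not None:
                counts.loc[lv, lab] += 1
        entry: dict = {"test": "chi-squared", "counts": counts,
                       "n_missing": n_na}
        table = counts.to_numpy()
        if table.shape[0] < 2 or (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            entry["skipped"] = "degenerate contingency table"
            log.warning("characteristics %s: test skipped (%s)", name, entry["skipped"])
        else:
            chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
            if (expected == 0).any():
                entry["skipped"] = "zero expected cell count"
                log.warning("characteristics %s: test skipped (%s)", name, entry["skipped"])
            else:
                entry.update(statistic=float(chi2), df=int(dof), p_value=float(p))
        out[name] = entry
    return out
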