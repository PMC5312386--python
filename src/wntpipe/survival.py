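"""Survival stratification and correlation statistics.

Cohorts are split by gene expression (median split, or a best-cutoff
scan in the style of the R2 genomics platform, always reported with a
Bonferroni-adjusted p over the cutoffs tried) or by signature group;
outcome separation is quantified with Kaplan-Meier curves and the
log-rank test. Spearman's rho with the Student-t approximation for its
p-value is provided for the expression/viability correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import InputError, NoCutoffError

CLINICAL_COLUMNS = ["sample", "time_days", "event", "mycn_amp", "mycn_expr"]


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table: positive times, 0/1 events, unique samples."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise InputError(f"clinical table missing columns: {missing}")
    if clinical["sample"].duplicated().any():
        dup = clinical.loc[clinical["sample"].duplicated(), "sample"].iloc[0]
        raise InputError(f"duplicate sample id {dup!r}")
    if (clinical["time_days"] <= 0).any():
        raise InputError("survival times must be > 0")
    if not clinical["event"].isin([0, 1]).all():
        raise InputError("event flags must be 0 or 1")
    return clinical


@dataclass
class StratificationResult:
    """Expression-based survival split with its log-rank test."""

    labels: pd.Series
    curves: dict
    chi2: float
    df: int
    p: float
    cutoff: float | None = None
    method: str = "median"
    n_cutoffs_tried: int = 1
    p_adjusted: float | None = None
    extras: dict = field(default_factory=dict)


def km_estimate(times, events, groups) -> dict:
    """Product-limit survival curves per group.

    Returns ``{group: DataFrame(time, survival, at_risk)}``; an
    all-censored group yields a flat curve at 1 with a warning.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    if events.sum() < 1:
        warnings.warn("no events in the data; all curves are flat at 1",
                      UserWarning, stacklevel=2)
    out = {}
    for g in pd.unique(groups):
        m = groups == g
        if events[m].sum() == 0:
            warnings.warn(f"group {g!r} has no events; curve is flat at 1",
                          UserWarning, stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        tab = kmf.event_table
        surv = kmf.survival_function_
        out[g] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(float),
                "survival": surv.iloc[:, 0].to_numpy(float),
                "at_risk": tab["at_risk"].reindex(surv.index).to_numpy(float),
            }
        ).reset_index(drop=True)
    return out


def logrank_test(times, events, groups):
    """Log-rank chi-squared across groups (df = number of groups - 1).

    Ties are handled with the standard hypergeometric variance, pooled
    at each event time.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise InputError("log-rank test needs >= 2 non-empty groups")
    if events.sum() < 1:
        raise InputError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(len(uniq) - 1), float(res.p_value)


def stratify_by_expression(
    values: pd.Series,
    clinical: pd.DataFrame,
    method: str = "median",
    min_group_frac: float = 0.1,
) -> StratificationResult:
    """Split a cohort on an expression row (or score) and test survival.

    ``method="median"`` splits at the median; ``method="scan"``
    evaluates every cutoff leaving at least ``min_group_frac`` of the
    samples on each side, reports the minimal log-rank p and a
    Bonferroni-adjusted p over the number of cutoffs tried.
    """
    clinical = validate_clinical(clinical)
    clin = clinical.set_index("sample")
    common = [s for s in clin.index if s in values.index]
    if len(common) < 4:
        raise InputError(f"only {len(common)} samples shared between "
                         "expression and clinical table (need >= 4)")
    x = values.loc[common].to_numpy(float)
    times = clin.loc[common, "time_days"].to_numpy(float)
    events = clin.loc[common, "event"].to_numpy(int)
    if np.ptp(x) == 0:
        raise NoCutoffError("expression is constant; no cutoff exists")

    def split_at(c):
        return np.where(x > c, "high", "low")

    if method == "median":
        cutoff = float(np.median(x))
        labels = split_at(cutoff)
        if len(np.unique(labels)) < 2:
            # median equals the max: flip boundary samples to keep 2 groups
            cutoff = float(np.max(x[x < np.max(x)]))
            labels = split_at(cutoff)
        chi2, df, p = logrank_test(times, events, labels)
        result = StratificationResult(
            labels=pd.Series(labels, index=common, name="group"),
            curves=km_estimate(times, events, labels),
            chi2=chi2, df=df, p=p, cutoff=cutoff, method="median",
        )
        return result
    if method != "scan":
        raise InputError(f"unknown stratification method {method!r}")

    n = len(x)
    floor = max(2, int(np.ceil(min_group_frac * n)))
    order = np.sort(np.unique(x))
    cuts = [
        (lo + hi) / 2.0
        for lo, hi in zip(order[:-1], order[1:])
        if floor <= np.sum(x > (lo + hi) / 2.0) <= n - floor
    ]
    if not cuts:
        raise NoCutoffError(
            f"no cutoff leaves >= {floor} samples per side (n = {n})"
        )
    best = None
    for c in cuts:
        chi2, df, p = logrank_test(times, events, split_at(c))
        if best is None or p < best[2]:
            best = (c, chi2, p)
    cutoff, chi2, p = best
    labels = split_at(cutoff)
    return StratificationResult(
        labels=pd.Series(labels, index=common, name="group"),
        curves=km_estimate(times, events, labels),
        chi2=chi2, df=1, p=p, cutoff=cutoff, method="scan",
        n_cutoffs_tried=len(cuts),
        p_adjusted=min(1.0, p * len(cuts)),
    )


def spearman_rho_t_pvalue(x, y):
    """Spearman's rho with the Student-t approximation for its p-value.

    Midranks handle ties; rho is the Pearson correlation of the ranks
    and the two-sided p comes from t = rho*sqrt((n-2)/(1-rho^2)) on
    n - 2 degrees of freedom. For rho = +/-1 the limiting p = 0 is
    returned.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise InputError(f"need n >= 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(p)
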