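"""Prognostic statistics for CT-index cohorts.

The workflow mirrors the standard prognostic toolbox for interstitial lung
disease cohorts:

* cohort description (mean +/- SD, median + IQR, counts with percentages);
* univariate and multivariate Cox proportional-hazards regression, with
  Akaike's information criterion (AIC = 2k - 2 log PL) to rank competing
  single-index models;
* ROC analysis against the vital-status flag, with the operating cut-off
  chosen by the Youden index J = sensitivity + specificity - 1;
* Kaplan-Meier stratification at the derived cut-offs with a two-group
  log-rank test;
* baseline vs follow-up comparison by the rank-sum test with Holm
  correction over the compared family;
* Spearman rank correlations between indexes.

Cox models are fitted by lifelines with the Efron approximation for tied
event days.  Confidence intervals are Wald intervals on the log-hazard
scale, exponentiated for reporting.  All simulation helpers take explicit
seeds; nothing touches global random state.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .records import (
    INDEX_COLUMNS,
    VISIT_COMPARISON_FAMILY,
    FOLLOWUP_PREFIX,
    records_to_frame,
)

ALPHA = 0.05  # significance level used throughout the reports

#: cut-off direction conventions: low kurtosis/skewness predict death,
#: high MLD/HAA%/FA% predict death
DEFAULT_DIRECTIONS = {
    "kurtosis": "le",
    "skewness": "le",
    "mld": "ge",
    "haa_pct": "ge",
    "fa_pct": "ge",
}

_DIRECTION_LABELS = {"le": "<= threshold predicts death",
                     "ge": ">= threshold predicts death"}


def _frame(records) -> pd.DataFrame:
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("empty cohort")
    return df


def _cohort_key(df: pd.DataFrame, time_col: str, event_col: str) -> str:
    ids = df.get("patient_id", pd.Series(range(len(df)), dtype=object))
    payload = "|".join(
        f"{i}:{t}:{e}"
        for i, t, e in sorted(zip(ids.astype(str), df[time_col], df[event_col]))
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

_NUMERIC_SUMMARY = (
    "age_years", "followup_days", "fvc_pct_pred", "dlco_pct_pred", "gap_points",
) + INDEX_COLUMNS
_CATEGORICAL_SUMMARY = ("sex", "smoking_status", "deceased")


def summarize_cohort(records, *, numeric: Sequence[str] = _NUMERIC_SUMMARY,
                     categorical: Sequence[str] = _CATEGORICAL_SUMMARY) -> pd.DataFrame:
    """Descriptive table: mean +/- SD and median (IQR) for numeric
    variables, counts with percentages for categorical ones.

    Percentages use the non-missing count of each variable as denominator;
    SD is reported missing for a single observation.
    """
    df = _frame(records)
    rows = []
    for var in numeric:
        if var not in df.columns:
            continue
        x = pd.to_numeric(df[var], errors="coerce").dropna()
        if x.empty:
            continue
        rows.append({
            "variable": var, "level": "", "n": int(x.size),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
            "median": float(x.median()),
            "q1": float(x.quantile(0.25)), "q3": float(x.quantile(0.75)),
            "count": np.nan, "pct": np.nan,
        })
    for var in categorical:
        if var not in df.columns:
            continue
        x = df[var].dropna()
        if x.empty:
            continue
        denom = int(x.size)
        for level, count in x.value_counts().sort_index().items():
            rows.append({
                "variable": var, "level": str(level), "n": denom,
                "mean": np.nan, "sd": np.nan, "median": np.nan,
                "q1": np.nan, "q3": np.nan,
                "count": int(count), "pct": 100.0 * count / denom,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox model: per-covariate table plus model-level summaries.

    ``table`` is indexed by covariate with columns ``coefficient``,
    ``hazard_ratio``, ``standard_error``, ``p_value``, ``ci95_low``,
    ``ci95_high`` (the CI on the hazard-ratio scale).
    """

    table: pd.DataFrame
    log_partial_likelihood: float
    aic: float
    n_subjects: int
    n_events: int
    covariates: tuple[str, ...]
    cohort_key: str = ""

    @property
    def k(self) -> int:
        return len(self.covariates)


def fit_cox(
    records,
    covariates: Sequence[str],
    *,
    time_col: str = "followup_days",
    event_col: str = "deceased",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by partial likelihood.

    Ties are handled with the Efron approximation; 95% intervals are Wald
    intervals on the log-hazard scale.  Rows with missing values in any
    used column are dropped with a warning.

    Raises
    ------
    ValueError
        Zero events, a constant covariate (named), a non-numeric
        covariate, or fewer than 2 usable rows.
    """
    df = _frame(records)
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates given")
    missing_cols = [c for c in covariates + [time_col, event_col] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing column(s): {missing_cols}")
    sub = df[[time_col, event_col] + covariates].apply(pd.to_numeric, errors="coerce")
    n_before = len(sub)
    sub = sub.dropna()
    if len(sub) < n_before:
        warnings.warn(
            f"dropped {n_before - len(sub)} row(s) with missing values",
            RuntimeWarning, stacklevel=2,
        )
    if len(sub) < 2:
        raise ValueError("fewer than 2 usable rows")
    n_events = int(sub[event_col].sum())
    if n_events == 0:
        raise ValueError("zero events: the Cox partial likelihood is undefined")
    for c in covariates:
        if sub[c].nunique() <= 1:
            raise ValueError(f"constant covariate: {c!r}")

    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=time_col, event_col=event_col,
                fit_options={"precision": 1e-12, "r_precision": 1e-16,
                             "max_steps": 500})
    except Exception as exc:
        raise ValueError(f"Cox model did not converge: {exc}") from exc

    summ = cph.summary
    table = pd.DataFrame({
        "coefficient": summ["coef"],
        "hazard_ratio": summ["exp(coef)"],
        "standard_error": summ["se(coef)"],
        "p_value": summ["p"],
        "ci95_low": np.exp(summ["coef lower 95%"]),
        "ci95_high": np.exp(summ["coef upper 95%"]),
    })
    table.index.name = "covariate"
    ll = float(cph.log_likelihood_)
    k = len(covariates)
    return CoxFit(
        table=table,
        log_partial_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n_subjects=int(len(sub)),
        n_events=n_events,
        covariates=tuple(covariates),
        cohort_key=_cohort_key(df.loc[sub.index], time_col, event_col),
    )


def rank_by_aic(fits: Iterable[CoxFit]) -> pd.DataFrame:
    """Order fitted models by ascending AIC (ties broken by name).

    All fits must come from the same cohort/time/event data, otherwise
    their AICs are not comparable and a ValueError is raised.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    keys = {f.cohort_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were made on differing cohorts; AICs not comparable")
    rows = [{
        "model": "+".join(f.covariates),
        "k": f.k,
        "log_partial_likelihood": f.log_partial_likelihood,
        "aic": f.aic,
    } for f in fits]
    out = pd.DataFrame(rows).sort_values(["aic", "model"], kind="mergesort")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROC cut-offs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCCutoff:
    """An operating cut-off for one variable against the deceased flag."""

    variable: str
    direction: str  # "le" or "ge"
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    auc_p_value: float
    youden_j: float

    @property
    def direction_label(self) -> str:
        return _DIRECTION_LABELS[self.direction]

    def __post_init__(self) -> None:
        if self.direction not in ("le", "ge"):
            raise ValueError(f"direction must be 'le' or 'ge', got {self.direction!r}")
        if not (0 <= self.sensitivity <= 100 and 0 <= self.specificity <= 100):
            raise ValueError("sensitivity/specificity outside [0, 100]")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc={self.auc} outside [0, 1]")


def roc_cutoff(
    records,
    variable: str,
    *,
    direction: Optional[str] = None,
    event_col: str = "deceased",
) -> ROCCutoff:
    """Derive the Youden-optimal cut-off of ``variable`` for mortality.

    The AUC is the Mann-Whitney probability that a deceased subject's
    value is on the predicted-death side of a surviving subject's, and its
    p-value comes from the normal approximation to the rank-sum null.
    The threshold is the observed value maximizing J = sensitivity +
    specificity - 1; ties prefer higher sensitivity, then the smaller
    threshold.

    ``direction`` may be "le" ("<= predicts death"), "ge", or None: None
    uses the fixed convention for known index names and automatic
    orientation (AUC >= 0.5) otherwise.
    """
    df = _frame(records)
    sub = df[[variable, event_col]].apply(pd.to_numeric, errors="coerce").dropna()
    x = sub[variable].to_numpy(dtype=float)
    y = sub[event_col].to_numpy(dtype=int)
    dead, alive = x[y == 1], x[y == 0]
    if dead.size == 0 or alive.size == 0:
        raise ValueError(f"{variable}: need both outcome classes for an ROC analysis")

    u_high, p_value = stats.mannwhitneyu(dead, alive, alternative="two-sided",
                                         method="asymptotic")
    auc_high = float(u_high) / (dead.size * alive.size)  # P(dead value > alive value)
    if direction is None:
        direction = DEFAULT_DIRECTIONS.get(variable)
    if direction is None or direction == "auto":
        direction = "ge" if auc_high >= 0.5 else "le"
    auc = auc_high if direction == "ge" else 1.0 - auc_high

    best = None
    for t in np.unique(x):
        if direction == "le":
            sens = np.count_nonzero(dead <= t) / dead.size
            spec = np.count_nonzero(alive > t) / alive.size
        else:
            sens = np.count_nonzero(dead >= t) / dead.size
            spec = np.count_nonzero(alive < t) / alive.size
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, float(t), sens, spec, j)
    _, threshold, sens, spec, j = best
    return ROCCutoff(
        variable=variable,
        direction=direction,
        threshold=threshold,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        auc=auc,
        auc_p_value=float(p_value),
        youden_j=j,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier stratification
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve for one stratum."""

    label: str
    times: np.ndarray  # includes t=0
    survival: np.ndarray  # S(t), starts at 1, non-increasing
    n_at_risk: np.ndarray
    n_subjects: int
    n_events: int

    def __post_init__(self) -> None:
        if self.survival.size and (self.survival[0] > 1.0 + 1e-12
                                   or np.any(np.diff(self.survival) > 1e-12)):
            raise ValueError("survival probabilities must start at 1 and be non-increasing")


@dataclass
class KMStratification:
    """Two Kaplan-Meier curves split at a cut-off, with a log-rank test."""

    predicted_death: KMCurve  # the stratum the cut-off flags as high risk
    predicted_survival: KMCurve
    logrank_statistic: float
    logrank_p: float
    variable: str = ""
    threshold: float = float("nan")
    direction: str = ""


def _km_curve(durations, events, label) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events, label=label)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(
        label=label,
        times=sf.index.to_numpy(dtype=float),
        survival=sf[label].to_numpy(dtype=float),
        n_at_risk=at_risk,
        n_subjects=int(len(durations)),
        n_events=int(np.sum(events)),
    )


def km_by_cutoff(
    records,
    variable: str,
    threshold: float,
    direction: str,
    *,
    time_col: str = "followup_days",
    event_col: str = "deceased",
) -> KMStratification:
    """Kaplan-Meier curves for the two strata defined by a cut-off.

    ``direction="le"`` flags values <= threshold as predicted death,
    ``"ge"`` flags values >= threshold.  Raises when a stratum is empty
    (naming the side) or when no events occurred at all (log-rank
    undefined).
    """
    if direction not in ("le", "ge"):
        raise ValueError(f"direction must be 'le' or 'ge', got {direction!r}")
    df = _frame(records)
    sub = df[[variable, time_col, event_col]].apply(pd.to_numeric, errors="coerce").dropna()
    x = sub[variable].to_numpy(dtype=float)
    flag = x <= threshold if direction == "le" else x >= threshold
    if not flag.any():
        raise ValueError(
            f"{variable}: predicted-death stratum "
            f"({_DIRECTION_LABELS[direction]} at {threshold}) is empty"
        )
    if flag.all():
        raise ValueError(
            f"{variable}: predicted-survival stratum (other side of {threshold}) is empty"
        )
    t = sub[time_col].to_numpy(dtype=float)
    e = sub[event_col].to_numpy(dtype=int)
    if e.sum() == 0:
        raise ValueError("all subjects censored: log-rank test undefined")
    op = "<=" if direction == "le" else ">="
    curve_pos = _km_curve(t[flag], e[flag], f"{variable} {op} {threshold:g}")
    curve_neg = _km_curve(t[~flag], e[~flag], f"{variable} {'>' if direction == 'le' else '<'} {threshold:g}")
    lr = _lifelines_logrank(t[flag], t[~flag], event_observed_A=e[flag],
                            event_observed_B=e[~flag])
    return KMStratification(
        predicted_death=curve_pos,
        predicted_survival=curve_neg,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        variable=variable,
        threshold=float(threshold),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# baseline vs follow-up comparison
# ---------------------------------------------------------------------------

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment of a p-value family (monotonicity enforced)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # no rank information at all
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def compare_visits(
    records,
    variables: Sequence[str] = VISIT_COMPARISON_FAMILY,
    *,
    paired: bool = False,
) -> pd.DataFrame:
    """Compare baseline and 12 +/- 3 month visits variable by variable.

    For each variable the subjects with both visits contribute their
    baseline and follow-up values; the table reports median (IQR) per
    visit, the interval difference (follow-up median minus baseline
    median), the rank-sum p-value, and Holm-adjusted p over the compared
    family.  ``paired=True`` switches to the signed-rank (paired) test —
    a deliberate extension beyond the unpaired contrast used by default.

    Raises
    ------
    ValueError
        Fewer than 2 subjects with any follow-up visit.
    """
    df = _frame(records)
    fu_cols = [c for c in df.columns if c.startswith(FOLLOWUP_PREFIX)]
    has_fu = df[fu_cols].notna().any(axis=1) if fu_cols else pd.Series(False, index=df.index)
    if int(has_fu.sum()) < 2:
        raise ValueError("need >= 2 paired records with both visits")

    rows = []
    for var in variables:
        fu_col = FOLLOWUP_PREFIX + var
        if var not in df.columns or fu_col not in df.columns:
            continue
        pair = df[[var, fu_col]].apply(pd.to_numeric, errors="coerce").dropna()
        if len(pair) < 2:
            continue
        base = pair[var].to_numpy(dtype=float)
        follow = pair[fu_col].to_numpy(dtype=float)
        if paired:
            diffs = follow - base
            p = 1.0 if np.all(diffs == 0) else float(
                stats.wilcoxon(base, follow, zero_method="wilcox").pvalue
            )
        else:
            p = _ranksum_p(base, follow)
        rows.append({
            "variable": var,
            "n_pairs": int(len(pair)),
            "baseline_median": float(np.median(base)),
            "baseline_q1": float(np.quantile(base, 0.25)),
            "baseline_q3": float(np.quantile(base, 0.75)),
            "followup_median": float(np.median(follow)),
            "followup_q1": float(np.quantile(follow, 0.25)),
            "followup_q3": float(np.quantile(follow, 0.75)),
            "interval_difference": float(np.median(follow) - np.median(base)),
            "p_raw": p,
        })
    if not rows:
        raise ValueError("no variable has >= 2 complete pairs")
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class SpearmanMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame


def spearman_matrix(records, variables: Sequence[str] = INDEX_COLUMNS) -> SpearmanMatrix:
    """Pairwise Spearman rank correlations (midranks for ties).

    Uses pairwise-complete observations; a constant variable yields
    missing entries (with a warning) rather than a spurious coefficient.
    Requires >= 3 records.
    """
    df = _frame(records)
    if len(df) < 3:
        raise ValueError("need >= 3 records for rank correlations")
    variables = [v for v in variables if v in df.columns]
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        for j in range(i + 1, k):
            pair = df[[variables[i], variables[j]]].apply(
                pd.to_numeric, errors="coerce").dropna()
            a = pair.iloc[:, 0].to_numpy(dtype=float)
            b = pair.iloc[:, 1].to_numpy(dtype=float)
            if len(pair) < 3 or np.all(a == a[0]) or np.all(b == b[0]):
                warnings.warn(
                    f"spearman: {variables[i]}/{variables[j]} constant or too few "
                    "complete pairs; reported missing",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            res = stats.spearmanr(a, b)
            rho[i, j] = rho[j, i] = float(res.statistic)
            pmat[i, j] = pmat[j, i] = float(res.pvalue)
    return SpearmanMatrix(
        rho=pd.DataFrame(rho, index=variables, columns=variables),
        p=pd.DataFrame(pmat, index=variables, columns=variables),
    )
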