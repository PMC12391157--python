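"""Outcome association stages: adjusted linear regression with
Benjamini-Hochberg correction, Cox proportional hazards with per-SD
normalization and a Schoenfeld diagnostic, ROC-derived cutoffs, and
Kaplan-Meier stratification.

The primary stage regresses a follow-up right-ventricular metric on one
baseline hemodynamic predictor, adjusting for patient sex and the ages at
both scans. The secondary stage fits a Cox model of time to pulmonic
valve replacement on the predictor plus sex and age at the baseline
scan, checks proportional hazards on the Schoenfeld residuals, derives a
Youden-optimal cutoff from ROC analysis of event status over the median
event time, and stratifies survival by that cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test

LINEAR_COVARIATES = ("sex", "age_at_cmr1", "age_at_cmr2")
COX_COVARIATES = ("sex", "age_at_cmr")


@dataclass
class LinearFitResult:
    """Adjusted OLS effect of one predictor on one outcome."""

    outcome: str
    predictor: str
    effect_estimate: float
    std_error: float
    unadjusted_p: float
    adjusted_p: float | None = None
    n: int = 0


@dataclass
class CoxResult:
    """Cox proportional-hazards effect of one predictor on time to event."""

    predictor: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    coefficient: float
    std_error: float
    p: float
    schoenfeld_p: float
    schoenfeld_ok: bool
    normalized: bool
    predictor_sd: float
    n_events: int


def fit_linear_outcome(
    cohort: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = LINEAR_COVARIATES,
) -> LinearFitResult:
    """OLS of outcome on predictor adjusted for sex and both scan ages."""
    cols = [outcome, predictor, *covariates]
    data = cohort[cols].dropna()
    if len(data) <= len(cols):
        raise ValueError("not enough observations for the model")
    if data[predictor].nunique() <= 1:
        raise ValueError(f"predictor {predictor!r} is constant")
    X = sm.add_constant(data[[predictor, *covariates]])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax()
        raise ValueError(f"collinear design: columns {pair[0]!r} and {pair[1]!r}")
    fit = sm.OLS(data[outcome], X).fit()
    return LinearFitResult(
        outcome=outcome,
        predictor=predictor,
        effect_estimate=float(fit.params[predictor]),
        std_error=float(fit.bse[predictor]),
        unadjusted_p=float(fit.pvalues[predictor]),
        n=len(data),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted(i) = min over j >= i (in the sorted order) of p(j) * m / j,
    capped at 1; returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def fit_cox(
    records: pd.DataFrame,
    predictor: str,
    normalize: bool = False,
    covariates: tuple[str, ...] = COX_COVARIATES,
    alpha: float = 0.05,
    duration_col: str = "time_to_event",
    event_col: str = "event",
) -> CoxResult:
    """Cox PH fit of the predictor plus a-priori covariates.

    With ``normalize`` the predictor is divided by its sample standard
    deviation, so the hazard ratio reads per-SD. The proportional-hazards
    assumption is checked via the rank-transformed Schoenfeld residual
    test; a failing check is reported, never acted on.
    """
    cols = [duration_col, event_col, predictor, *covariates]
    data = records[cols].dropna().copy()
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise ValueError("no events observed; Cox model is unidentifiable")
    if data[predictor].nunique() <= 1:
        raise ValueError(f"predictor {predictor!r} is constant")
    sd = float(data[predictor].std(ddof=1))
    if normalize:
        data[predictor] = data[predictor] / sd

    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # monotone likelihood / separation surfaces loudly
        raise RuntimeError(f"Cox fit failed (possible separation): {exc}") from exc

    coef = float(cph.params_[predictor])
    se = float(cph.standard_errors_[predictor])
    z = norm.ppf(1 - alpha / 2)
    ph = proportional_hazard_test(cph, data, time_transform="rank")
    sch_p = float(ph.summary.loc[predictor, "p"])
    return CoxResult(
        predictor=predictor,
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        coefficient=coef,
        std_error=se,
        p=float(cph.summary.loc[predictor, "p"]),
        schoenfeld_p=sch_p,
        schoenfeld_ok=sch_p >= alpha,
        normalized=normalize,
        predictor_sd=sd,
        n_events=n_events,
    )


def dichotomize_by_median_time(
    records: pd.DataFrame,
    duration_col: str = "time_to_event",
    event_col: str = "event",
) -> pd.Series:
    """Event-by-median-time labels for ROC analysis.

    Label 1: event at or before the median event time. Label 0: followed
    beyond the median without an event by then. Subjects censored before
    the median carry unknown status and are excluded (NaN-free return
    indexed by the retained rows).
    """
    events = records.loc[records[event_col] == 1, duration_col]
    if events.empty:
        raise ValueError("no events; cannot locate the median event time")
    median_t = float(events.median())
    t = records[duration_col]
    e = records[event_col].astype(bool)
    label1 = e & (t <= median_t)
    label0 = t > median_t
    keep = label1 | label0
    if not (t > median_t).any():
        raise ValueError("no subject followed beyond the median event time")
    return pd.Series(
        np.where(label1[keep], 1, 0), index=records.index[keep], name="event_by_median"
    )


def roc_optimal_cutoff(scores, labels) -> tuple[float, float, float, str]:
    """Youden-optimal threshold: maximize sensitivity + specificity.

    Candidate cutoffs are midpoints between adjacent sorted unique
    scores (plus outer sentinels); both orientations (high score predicts
    the event, or low score does) are searched and the better one
    reported as ``">="`` or ``"<="``. Ties resolve to the smallest
    qualifying cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pos = labels == 1
    best = None
    for cut in candidates:
        for direction in (">=", "<="):
            pred = scores >= cut if direction == ">=" else scores <= cut
            sens = (pred & pos).sum() / pos.sum()
            spec = (~pred & ~pos).sum() / (~pos).sum()
            j = sens + spec
            key = (-j, cut, direction)
            if best is None or key < best[0]:
                best = (key, cut, sens, spec, direction)
    _, cut, sens, spec, direction = best
    return float(cut), float(sens), float(spec), direction


def km_curve(
    records: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    duration_col: str = "time_to_event",
    event_col: str = "event",
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival step functions per group.

    Returns ``{group: DataFrame(time, survival)}`` where survival is the
    product-limit estimate, right-continuous and starting at 1.
    """
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in np.unique(groups):
        mask = groups == g
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(records.loc[mask, duration_col], records.loc[mask, event_col])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def exclude_interscan_pvr(
    cohort: pd.DataFrame, pvr_between_scans_col: str = "pvr_between_scans"
) -> tuple[pd.DataFrame, dict]:
    """Drop patients who had valve replacement between the two scans.

    The linear-outcome stage models native remodeling between scans, so
    interval PVR invalidates the follow-up measurement. Returns the
    filtered table and an audit entry.
    """
    if pvr_between_scans_col not in cohort:
        return cohort, {"excluded": 0, "reason": "column absent; nothing to exclude"}
    mask = cohort[pvr_between_scans_col].astype(bool)
    audit = {
        "excluded": int(mask.sum()),
        "reason": "PVR between scans",
        "excluded_index": cohort.index[mask].tolist(),
    }
    return cohort.loc[~mask].copy(), audit
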