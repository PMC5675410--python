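"""Survival screening, duplicate detection, random-effects meta-analysis,
and the enrichment of prognostic genes among highly correlating ones.

Overall survival (OS) runs from diagnosis to death; living patients are
censored.  Screening tools: a two-year short/long dichotomization with AUC,
univariate and covariate-adjusted Cox proportional-hazards models (Efron tie
handling, per-cohort z-scored expression by default so hazard ratios pool
across cohorts), and Kaplan-Meier log-rank tests with percentile or
optimized cutoffs.  Cohort collections are screened for duplicate patients
(expression correlation >= 0.999) before pooling per-study log hazard ratios
with a DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "dichotomize_two_year",
    "auc",
    "cox_univariate",
    "cox_multivariate",
    "km_dichotomized",
    "detect_duplicates",
    "meta_random_effects",
    "meta_analyze_probesets",
    "enrichment_fisher",
]


@dataclass(frozen=True)
class CoxResult:
    probe_set: str
    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    estimable: bool = True


def dichotomize_two_year(clinical: pd.DataFrame) -> tuple[pd.Series, int]:
    """Short (death within 24 months) vs long (alive or dead after 24).

    Patients censored before 24 months have unknown class and are excluded;
    the exclusion count is returned alongside.
    """
    os_m = clinical["os_months"]
    event = clinical["event"].astype(bool)
    outcome = pd.Series(pd.NA, index=clinical.index, dtype="object")
    outcome[(os_m <= 24) & event] = "short"
    outcome[os_m > 24] = "long"
    n_excluded = int(((os_m <= 24) & ~event).sum())
    if n_excluded:
        logger.info("two-year dichotomization: %d early-censored excluded", n_excluded)
    return outcome, n_excluded


def auc(marker: np.ndarray, outcome: pd.Series | np.ndarray) -> float:
    """AUC = P(marker_short > marker_long) + 0.5 P(equal).

    Short-term survival is the positive class: AUC above 0.5 means higher
    marker values in patients who died within two years.  Computed by the
    rank-sum identity; NaN if a class is empty.
    """
    marker = np.asarray(marker, dtype=float)
    outcome = np.asarray(outcome, dtype=object)
    short = marker[outcome == "short"]
    long_ = marker[outcome == "long"]
    if len(short) == 0 or len(long_) == 0:
        return float("nan")
    u = stats.mannwhitneyu(short, long_, alternative="two-sided").statistic
    return float(u / (len(short) * len(long_)))


def _fit_cox(df: pd.DataFrame, covariate_cols: list[str], marker_col: str) -> tuple:
    cph = CoxPHFitter()
    cph.fit(df[["os_months", "event", marker_col] + covariate_cols],
            duration_col="os_months", event_col="event")
    return (
        float(cph.params_[marker_col]),
        float(cph.standard_errors_[marker_col]),
        float(cph.summary.loc[marker_col, "p"]),
    )


def cox_univariate(
    marker: np.ndarray | pd.Series,
    clinical: pd.DataFrame,
    standardize: bool = True,
    name: str = "marker",
) -> CoxResult:
    """Univariate Cox PH fit of one continuous marker (Efron ties, Wald p).

    With ``standardize`` the marker is z-scored within the cohort so log
    hazard ratios are per standard deviation and comparable across cohorts.
    """
    x = np.asarray(marker, dtype=float)
    n_events = int(clinical["event"].sum())
    if n_events < 2 or np.ptp(x) == 0 or not np.isfinite(x).all():
        return CoxResult(name, float("nan"), float("nan"), float("nan"),
                         len(x), n_events, estimable=False)
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
    df = pd.DataFrame(
        {"os_months": clinical["os_months"].to_numpy(),
         "event": clinical["event"].to_numpy(), "x": x}
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            log_hr, se, p = _fit_cox(df, [], "x")
    except (ConvergenceError, ValueError):
        return CoxResult(name, float("nan"), float("nan"), float("nan"),
                         len(x), n_events, estimable=False)
    return CoxResult(name, log_hr, se, p, len(x), n_events)


def cox_multivariate(
    marker: np.ndarray | pd.Series,
    clinical: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "stage", "histology"),
    standardize: bool = True,
    name: str = "marker",
) -> CoxResult:
    """Marker effect adjusted for clinical covariates.

    Categorical covariates are dummy-coded; rows with missing covariates are
    dropped (logged); collinear covariates are removed one at a time with a
    log message and the model refit.  An empty covariate set reduces to
    :func:`cox_univariate`.
    """
    if not covariates:
        return cox_univariate(marker, clinical, standardize=standardize, name=name)
    x = np.asarray(marker, dtype=float)
    df = clinical[["os_months", "event"]].copy()
    df["x"] = (x - x.mean()) / x.std(ddof=1) if standardize and np.ptp(x) else x
    cov_cols = []
    for cov in covariates:
        col = clinical[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            for c in dummies.columns:
                df[c] = dummies[c]
                cov_cols.append(c)
        else:
            df[cov] = col.astype(float)
            cov_cols.append(cov)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("cox_multivariate: dropped %d incomplete rows", n_before - len(df))
    n_events = int(df["event"].sum())
    if n_events < 2 or np.ptp(df["x"]) == 0:
        return CoxResult(name, float("nan"), float("nan"), float("nan"),
                         len(df), n_events, estimable=False)
    cols = list(cov_cols)
    while True:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                log_hr, se, p = _fit_cox(df, cols, "x")
            return CoxResult(name, log_hr, se, p, len(df), n_events)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            if not cols:
                return CoxResult(name, float("nan"), float("nan"), float("nan"),
                                 len(df), n_events, estimable=False)
            dropped = cols.pop()  # drop the most recently added offender
            logger.warning("cox_multivariate: dropping collinear covariate %s", dropped)


def km_dichotomized(
    marker: np.ndarray | pd.Series,
    clinical: pd.DataFrame,
    rule: str = "percentile",
    q: float = 0.75,
    min_arm_fraction: float = 0.10,
) -> dict:
    """Two-group log-rank test after dichotomizing a marker.

    ``rule='percentile'`` splits at the q-quantile (default 75%).
    ``rule='optimized'`` scans every cutpoint leaving at least
    ``min_arm_fraction`` of samples per arm and reports the minimum log-rank
    p — an unadjusted, exploratory quantity, labeled as such.
    """
    x = np.asarray(marker, dtype=float)
    t = clinical["os_months"].to_numpy()
    e = clinical["event"].to_numpy()

    def _test(cut: float) -> dict | None:
        high = x > cut
        if high.sum() == 0 or (~high).sum() == 0:
            return None
        res = logrank_test(t[high], t[~high], e[high], e[~high])
        return {
            "cutoff": float(cut),
            "p": float(res.p_value),
            "statistic": float(res.test_statistic),
            "n_high": int(high.sum()),
            "n_low": int((~high).sum()),
        }

    if rule == "percentile":
        out = _test(float(np.quantile(x, q)))
        if out is None:
            return {"estimable": False, "rule": rule}
        return {**out, "rule": rule, "estimable": True, "cutoff_prespecified": True}
    if rule != "optimized":
        raise ValueError("rule must be 'percentile' or 'optimized'")
    n = len(x)
    lo = int(np.ceil(min_arm_fraction * n))
    order = np.sort(np.unique(x))
    best = None
    for cut in order[:-1]:
        high_n = int((x > cut).sum())
        if high_n < lo or n - high_n < lo:
            continue
        res = _test(float(cut))
        if res and (best is None or res["p"] < best["p"]):
            best = res
    if best is None:
        return {"estimable": False, "rule": rule}
    return {**best, "rule": rule, "estimable": True, "cutoff_prespecified": False}


def detect_duplicates(
    expressions: dict[str, pd.DataFrame] | list[pd.DataFrame],
    threshold: float = 0.999,
) -> pd.DataFrame:
    """All sample pairs (within and across cohorts) with product-moment
    correlation of expression >= threshold.

    The returned table marks, per pair, which copy a configured priority
    order (the input cohort order) would remove: the copy in the later
    cohort.
    """
    if isinstance(expressions, list):
        expressions = {f"cohort_{i}": e for i, e in enumerate(expressions)}
    names = list(expressions)
    shared = None
    for e in expressions.values():
        shared = e.index if shared is None else shared.intersection(e.index)
    if shared is None or len(shared) == 0:
        raise ValueError("cohorts share no probe sets")
    cols = []
    labels = []
    for name in names:
        mat = expressions[name].loc[shared]
        cols.append(mat.to_numpy(dtype=float))
        labels += [(name, s) for s in mat.columns]
    big = np.concatenate(cols, axis=1)
    z = big - big.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z /= sd
    corr = (z.T @ z) / (len(shared) - 1)
    rows = []
    order = {name: i for i, name in enumerate(names)}
    n = corr.shape[0]
    for i, j in zip(*np.nonzero(np.triu(corr >= threshold, k=1))):
        (c1, s1), (c2, s2) = labels[i], labels[j]
        keep_first = order[c1] <= order[c2]
        rows.append(
            {
                "cohort_a": c1,
                "sample_a": s1,
                "cohort_b": c2,
                "sample_b": s2,
                "correlation": float(corr[i, j]),
                "remove_cohort": c2 if keep_first else c1,
                "remove_sample": s2 if keep_first else s1,
            }
        )
    if rows:
        logger.info("duplicate detection: %d pairs at r >= %g", len(rows), threshold)
    return pd.DataFrame(
        rows,
        columns=[
            "cohort_a", "sample_a", "cohort_b", "sample_b",
            "correlation", "remove_cohort", "remove_sample",
        ],
    )


def meta_random_effects(log_hrs: np.ndarray, ses: np.ndarray) -> dict:
    """DerSimonian-Laird random-effects pooling of per-study log hazard ratios.

    Fixed-effect weights w_i = 1/se_i^2 give Q = sum w_i (b_i - b_FE)^2 and
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights 1/(se_i^2 + tau^2) produce the pooled estimate, its SE, a 95% CI
    and a two-sided normal p.
    """
    b = np.asarray(log_hrs, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    b, s = b[ok], s[ok]
    k = b.size
    if k < 2:
        return {"estimable": False, "k": int(k)}
    w = 1.0 / s**2
    b_fe = float((w * b).sum() / w.sum())
    q = float((w * (b - b_fe) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    pooled = float((w_star * b).sum() / w_star.sum())
    pooled_se = float(w_star.sum() ** -0.5)
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (pooled - 1.959963984540054 * pooled_se, pooled + 1.959963984540054 * pooled_se)
    return {
        "estimable": True,
        "k": int(k),
        "Q": q,
        "tau2": float(tau2),
        "pooled_log_hr": pooled,
        "pooled_se": pooled_se,
        "ci95": (float(ci[0]), float(ci[1])),
        "p": p,
        "study_log_hr": b.tolist(),
        "study_se": s.tolist(),
        "study_weight": (w_star / w_star.sum()).tolist(),
    }


def meta_analyze_probesets(
    cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    probe_sets: list[str],
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-probe-set meta-analysis over cohorts of (expression, clinical).

    Fits a univariate Cox model per cohort and pools log hazard ratios with
    the DerSimonian-Laird estimator; BH-FDR across probe sets.  Forest-plot
    data (per-study estimates and weights) are kept in the output columns.
    """
    rows = []
    for ps in probe_sets:
        betas, ses, studies = [], [], []
        for name, (expr, clin) in cohorts.items():
            if ps not in expr.index:
                continue
            res = cox_univariate(
                expr.loc[ps, clin.index].to_numpy(), clin,
                standardize=standardize, name=ps,
            )
            if res.estimable:
                betas.append(res.log_hr)
                ses.append(res.se)
                studies.append(name)
        meta = meta_random_effects(np.array(betas), np.array(ses))
        row = {"probe_set": ps, "k": meta.get("k", 0), "studies": studies}
        if meta["estimable"]:
            row.update(
                Q=meta["Q"], tau2=meta["tau2"],
                pooled_log_hr=meta["pooled_log_hr"], pooled_se=meta["pooled_se"],
                ci_low=meta["ci95"][0], ci_high=meta["ci95"][1], p=meta["p"],
                study_log_hr=meta["study_log_hr"], study_se=meta["study_se"],
                study_weight=meta["study_weight"],
            )
        else:
            row.update(Q=np.nan, tau2=np.nan, pooled_log_hr=np.nan,
                       pooled_se=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                       study_log_hr=[], study_se=[], study_weight=[])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("probe_set")
    mask = out["p"].notna()
    out["fdr_q"] = np.nan
    if mask.any():
        out.loc[mask, "fdr_q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def enrichment_fisher(
    highly_correlating: pd.Series, prognostic: pd.Series
) -> dict:
    """One-sided Fisher exact test: are prognostic probe sets overrepresented
    among highly correlating ones?

    2x2 table over the shared probe-set universe: a = prognostic and highly
    correlating, b = highly correlating only, c = prognostic among the rest,
    d = neither.  p is the upper hypergeometric tail.
    """
    hc = highly_correlating.astype(bool)
    pr = prognostic.astype(bool)
    if not hc.index.equals(pr.index):
        raise ValueError("flags must align over the same probe-set universe")
    a = int((hc & pr).sum())
    b = int((hc & ~pr).sum())
    c = int((~hc & pr).sum())
    d = int((~hc & ~pr).sum())
    if hc.all() or not hc.any() or pr.all() or not pr.any():
        warnings.warn("degenerate margin in enrichment table; p set to 1")
        return {"a": a, "b": b, "c": c, "d": d, "odds_ratio": float("nan"), "p_one_sided": 1.0}
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": float(odds), "p_one_sided": float(p),
    }
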