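"""The externally centered correlation coefficient (ECCC) and its analyses.

For each probe set, deviations of copy number and expression are taken not
from the sample means but from external/cohort centers: copy number deviates
from the external-reference scale center (2.0, since CN values are defined as
twice the ratio to the reference median), expression from the cohort median
of that probe set.  With dx_i = CN_i - c_x and dy_i = GE_i - c_y,

    ECCC = sum dx_i dy_i / sqrt(sum dx_i^2 * sum dy_i^2)  in [-1, 1].

Values are linear (not log-transformed) by default; a log2 mode exists for
sensitivity analysis.  Significance of equally directed deviations is tested
per probe set with a one-sided Wilcoxon signed-rank test on the scores
d_i = sign(dx_i dy_i) * min(|dx_i|, |dy_i|) (zeros dropped), exact for up to
25 nonzero scores and normal-approximated with continuity correction above.
Multiple testing uses Benjamini-Hochberg FDR across all probe sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .integration import PairedData

__all__ = [
    "CenteringSpec",
    "eccc",
    "equally_directed_scores",
    "equally_directed_test",
    "eccc_table",
    "permutation_null",
    "flag_loss_candidates",
    "quantile_class_analysis",
    "compare_gene_set",
]

EXACT_MAX_N = 25  # exact signed-rank distribution up to this many nonzero scores


@dataclass(frozen=True)
class CenteringSpec:
    """Where deviations are measured from.

    ``cn_center`` defaults to 2.0, the external-reference median on the
    2-centered scale.  Expression is centered at the cohort median per probe
    set unless ``ge_center_rule='fixed_value'`` with ``ge_center_value``.
    ``log_scale`` applies log2 to both matrices (and to ``cn_center``) first.
    """

    cn_center: float = 2.0
    ge_center_rule: str = "cohort_median_per_probeset"
    ge_center_value: float | None = None
    log_scale: bool = False
    cn_zero_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.cn_center <= 0:
            raise ValueError("cn_center must be positive")
        if self.ge_center_rule not in ("cohort_median_per_probeset", "fixed_value"):
            raise ValueError(f"unknown ge_center_rule {self.ge_center_rule!r}")
        if self.ge_center_rule == "fixed_value" and self.ge_center_value is None:
            raise ValueError("fixed_value centering needs ge_center_value")
        if self.cn_zero_tolerance < 0:
            raise ValueError("cn_zero_tolerance must be >= 0")


def _centered(expression, cn, centering: CenteringSpec):
    """Deviation matrices (dy, dx) given the centering rule."""
    y = np.asarray(expression, dtype=float)
    x = np.asarray(cn, dtype=float)
    cx = centering.cn_center
    if centering.log_scale:
        y = np.log2(y)
        x = np.log2(np.maximum(x, 1e-12))
        cx = np.log2(cx)
    if centering.ge_center_rule == "cohort_median_per_probeset":
        cy = np.median(y, axis=-1, keepdims=True)
    else:
        cy = centering.ge_center_value
        if centering.log_scale:
            cy = np.log2(cy)
    return y - cy, x - cx


def eccc(
    expression: np.ndarray,
    cn: np.ndarray,
    centering: CenteringSpec | None = None,
) -> float:
    """ECCC of one probe set; NaN (flagged, not erroring) if a deviation sum
    of squares is zero."""
    expression = np.asarray(expression, dtype=float)
    cn = np.asarray(cn, dtype=float)
    if expression.shape != cn.shape:
        raise ValueError("expression and cn vectors differ in length")
    if expression.size < 3:
        raise ValueError("need at least 3 samples")
    dy, dx = _centered(expression, cn, centering or CenteringSpec())
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        return float("nan")
    return float((dx @ dy) / np.sqrt(ssx * ssy))


def equally_directed_scores(
    expression: np.ndarray, cn: np.ndarray, centering: CenteringSpec | None = None
) -> np.ndarray:
    """Per-sample scores d_i = sign(dx dy) * min(|dx|, |dy|).

    A sample with a zero deviation on either side scores 0; copy-number
    deviations within ``cn_zero_tolerance`` of the center count as zero (a
    segment mean that close to 2 reflects estimation noise, not an
    aberration).
    """
    centering = centering or CenteringSpec()
    dy, dx = _centered(
        np.asarray(expression, dtype=float),
        np.asarray(cn, dtype=float),
        centering,
    )
    dx = np.where(np.abs(dx) <= centering.cn_zero_tolerance, 0.0, dx)
    return np.sign(dx * dy) * np.minimum(np.abs(dx), np.abs(dy))


def _signed_rank_p(d: np.ndarray) -> float:
    """One-sided (greater) Wilcoxon signed-rank p on nonzero scores."""
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if n <= EXACT_MAX_N:
        try:
            return float(
                stats.wilcoxon(d, alternative="greater", method="exact").pvalue
            )
        except ValueError:
            pass  # ties/zeros: fall through to the approximation
    return float(
        stats.wilcoxon(
            d, alternative="greater", method="approx", correction=True
        ).pvalue
    )


def equally_directed_test(
    expression: np.ndarray,
    cn: np.ndarray,
    centering: CenteringSpec | None = None,
) -> float:
    """P-value for a positive location shift of the equally-directed scores."""
    expression = np.asarray(expression, dtype=float)
    cn = np.asarray(cn, dtype=float)
    if expression.shape != cn.shape:
        raise ValueError("expression and cn vectors differ in length")
    return _signed_rank_p(equally_directed_scores(expression, cn, centering))


def _eccc_matrix(dy: np.ndarray, dx: np.ndarray) -> np.ndarray:
    num = (dx * dy).sum(axis=1)
    den = np.sqrt((dx * dx).sum(axis=1) * (dy * dy).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def eccc_table(
    paired: PairedData,
    centering: CenteringSpec | None = None,
    high_threshold: float = 0.7,
    moderate_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-probe-set ECCC records with test p, BH-FDR q, summaries and flags.

    ``high_correlation`` requires ECCC above ``high_threshold`` (default 0.7)
    and FDR below ``fdr_threshold`` (default 0.05); ``moderate_correlation``
    requires ECCC above ``moderate_threshold`` (default 0.5).
    """
    centering = centering or CenteringSpec()
    expr = paired.expression.to_numpy(dtype=float)
    cn = paired.cn.to_numpy(dtype=float)
    dy, dx = _centered(expr, cn, centering)
    values = _eccc_matrix(dy, dx)
    dx_score = np.where(np.abs(dx) <= centering.cn_zero_tolerance, 0.0, dx)
    scores = np.sign(dx_score * dy) * np.minimum(np.abs(dx_score), np.abs(dy))
    pvals = np.array([_signed_rank_p(row) for row in scores])
    fdr_q = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene": paired.annotation["gene"],
            "chromosome": paired.annotation["chromosome"],
            "position": paired.annotation["position"],
            "eccc": values,
            "p_value": pvals,
            "fdr_q": fdr_q,
            "median_ge": np.median(expr, axis=1),
            "median_cn": np.median(cn, axis=1),
            "cn_q25": np.quantile(cn, 0.25, axis=1),
            "cn_p95": np.quantile(cn, 0.95, axis=1),
            "ge_p95": np.quantile(expr, 0.95, axis=1),
            "n_high_gain_samples": (paired.calls.to_numpy() == 2).sum(axis=1),
        },
        index=paired.expression.index,
    )
    table["high_correlation"] = (
        (table["eccc"] > high_threshold) & (table["fdr_q"] < fdr_threshold)
    ).fillna(False)
    table["moderate_correlation"] = (table["eccc"] > moderate_threshold).fillna(False)
    return flag_loss_candidates(table)


def permutation_null(
    paired: PairedData,
    n_perm: int = 20,
    seed: int = 0,
    centering: CenteringSpec | None = None,
) -> dict:
    """Null ECCC distribution by permuting CN/expression sample pairings.

    Each permutation shuffles the expression matrix's sample labels relative
    to the CN matrix and recomputes every probe set's ECCC.  Returns the
    pooled null values plus a density summary for plot overlays.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    centering = centering or CenteringSpec()
    rng = np.random.default_rng(seed)
    dy, dx = _centered(
        paired.expression.to_numpy(dtype=float),
        paired.cn.to_numpy(dtype=float),
        centering,
    )
    n = dy.shape[1]
    pooled = np.empty((n_perm, dy.shape[0]))
    for k in range(n_perm):
        perm = rng.permutation(n)
        pooled[k] = _eccc_matrix(dy[:, perm], dx)
    flat = pooled.ravel()
    flat = flat[np.isfinite(flat)]
    qs = np.quantile(flat, [0.001, 0.025, 0.5, 0.975, 0.999])
    return {
        "null_values": flat,
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)),
        "quantiles": {
            "q0.001": qs[0],
            "q0.025": qs[1],
            "median": qs[2],
            "q0.975": qs[3],
            "q0.999": qs[4],
        },
        "n_perm": n_perm,
    }


def flag_loss_candidates(
    table: pd.DataFrame, median_threshold: float = 1.9, q25_threshold: float = 1.5
) -> pd.DataFrame:
    """Mark probe sets whose CN distribution indicates copy-number loss.

    A loss candidate has median CN below 1.9 and CN 25%-quantile below 1.5;
    gain-side analyses exclude these, loss-side correlations are reported
    separately.
    """
    table = table.copy()
    table["loss_candidate"] = (table["median_cn"] < median_threshold) & (
        table["cn_q25"] < q25_threshold
    )
    return table


def quantile_class_analysis(
    table: pd.DataFrame, stratifier: str = "median_ge", n_classes: int = 7
) -> dict:
    """ECCC distribution across equal-frequency classes of a stratifier.

    Classes are formed on ``median_ge`` or ``median_cn`` (ties broken by
    stable probe-set order); adjacent classes are compared by the two-sided
    Wilcoxon rank-sum test on ECCC with BH-FDR over the comparisons.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if stratifier not in ("median_ge", "median_cn"):
        raise ValueError("stratifier must be 'median_ge' or 'median_cn'")
    sub = table.dropna(subset=["eccc"])
    if len(sub) < n_classes:
        raise ValueError("fewer probe sets than classes")
    order = np.argsort(sub[stratifier].to_numpy(), kind="stable")
    chunks = np.array_split(order, n_classes)
    classes = []
    eccc_by_class = []
    for c, chunk in enumerate(chunks):
        vals = sub["eccc"].to_numpy()[chunk]
        eccc_by_class.append(vals)
        classes.append(
            {
                "class": c,
                "n": len(chunk),
                "stratifier_min": float(sub[stratifier].to_numpy()[chunk].min()),
                "stratifier_max": float(sub[stratifier].to_numpy()[chunk].max()),
                "eccc_median": float(np.median(vals)),
                "eccc_q25": float(np.quantile(vals, 0.25)),
                "eccc_q75": float(np.quantile(vals, 0.75)),
            }
        )
    pvals = []
    for c in range(1, n_classes):
        p = stats.mannwhitneyu(
            eccc_by_class[c], eccc_by_class[c - 1], alternative="two-sided"
        ).pvalue
        pvals.append(float(p))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    comparisons = [
        {"classes": (c, c + 1), "p": pvals[c], "fdr_q": float(fdr[c])}
        for c in range(n_classes - 1)
    ]
    return {"stratifier": stratifier, "classes": classes, "comparisons": comparisons}


def compare_gene_set(
    table: pd.DataFrame,
    gene_set: set[str],
    covariates: tuple[str, ...] = ("cn_p95", "ge_p95"),
) -> dict:
    """ECCC of a gene set vs all other probe sets, raw and adjusted.

    Unadjusted: two-sided Wilcoxon rank-sum test.  Adjusted: a linear model
    ECCC ~ in_set + covariates (default: per-probe-set 95th percentiles of CN
    and expression), reporting the indicator coefficient and its p — this
    asks whether the set differs beyond what its CN/GE levels explain.
    """
    sub = table.dropna(subset=["eccc"])
    in_set = sub["gene"].isin(gene_set).to_numpy()
    if not in_set.any():
        raise ValueError("gene set does not intersect the table")
    if in_set.all():
        raise ValueError("gene set covers every probe set; nothing to compare")
    x_in = sub["eccc"].to_numpy()[in_set]
    x_out = sub["eccc"].to_numpy()[~in_set]
    p_unadj = float(
        stats.mannwhitneyu(x_in, x_out, alternative="two-sided").pvalue
    )
    X = sm.add_constant(
        np.column_stack(
            [in_set.astype(float)] + [sub[c].to_numpy() for c in covariates]
        )
    )
    fit = sm.OLS(sub["eccc"].to_numpy(), X).fit()
    return {
        "n_in_set": int(in_set.sum()),
        "n_out_set": int((~in_set).sum()),
        "median_in": float(np.median(x_in)),
        "median_out": float(np.median(x_out)),
        "p_unadjusted": p_unadj,
        "adjusted_coefficient": float(fit.params[1]),
        "adjusted_p": float(fit.pvalues[1]),
        "covariates": list(covariates),
    }
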