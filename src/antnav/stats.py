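"""Inference layer: per-nest Welch comparisons and the habituation design.

Two designs are supported. The paired-nest design compares control and
test (odour-added) samples of a metric with an unequal-variance t-test
(Welch-Satterthwaite fractional degrees of freedom), one test per nest
and metric, with no multiplicity adjustment by default. The habituation
design is a one-way within-subject (repeated-measures) ANOVA over the
four ordered conditions Control, Test-Day1, Test-Day2, Test-Day3, with
three a priori Helmert contrasts: (1) control vs all test days, (2) Day1
vs Days 2-3, (3) Day2 vs Day3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import DesignError, InsufficientDataError

# Helmert coefficient rows for 4 ordered conditions, before scaling.
HELMERT_RAW = np.array(
    [
        [3.0, -1.0, -1.0, -1.0],   # control vs all test days
        [0.0, 2.0, -1.0, -1.0],    # Test-Day1 vs Test-Days 2-3
        [0.0, 0.0, 1.0, -1.0],     # Test-Day2 vs Test-Day3
    ]
)
HELMERT_LABELS = (
    "control_vs_test_days",
    "day1_vs_days23",
    "day2_vs_day3",
)


def helmert_coefficients() -> np.ndarray:
    """The three contrast vectors, each scaled to unit sum of squares."""
    return HELMERT_RAW / np.sqrt((HELMERT_RAW**2).sum(axis=1, keepdims=True))


@dataclass
class ComparisonResult:
    metric: str
    t: float
    df: float
    p: float
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int
    flags: tuple[str, ...] = ()


@dataclass
class ContrastResult:
    label: str
    coefficients: np.ndarray
    estimate: float       # mean per-subject contrast score
    t: float
    df: float
    p: float              # exact one-sample t, two-sided
    z: float              # normal-approximation statistic
    p_z: float


@dataclass
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    p: float
    condition_means: np.ndarray
    contrasts: list[ContrastResult] = field(default_factory=list)
    gg_epsilon: float = 1.0
    p_gg: float = np.nan


def welch_t_test(x, y, metric: str = "", pooled: bool = False) -> ComparisonResult:
    """Two-sample t-test, unequal variances by default (Welch).

    ``pooled=True`` selects the classical equal-variance form. With zero
    variance in both samples and equal means the result is t = 0, p = 1,
    flagged ``"degenerate"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    flags: tuple[str, ...] = ()
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if x.mean() == y.mean():
            t, df, p = 0.0, float(x.size + y.size - 2), 1.0
            flags = ("degenerate",)
        else:
            raise InsufficientDataError("both samples have zero variance")
    else:
        res = sps.ttest_ind(x, y, equal_var=pooled)
        t, df, p = float(res.statistic), float(res.df), float(res.pvalue)
    return ComparisonResult(
        metric=metric, t=t, df=df, p=p,
        mean_1=float(x.mean()), mean_2=float(y.mean()),
        sd_1=float(x.std(ddof=1)), sd_2=float(y.std(ddof=1)),
        n_1=int(x.size), n_2=int(y.size), flags=flags,
    )


def _check_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise DesignError("data must be a subjects x conditions matrix")
    if np.isnan(data).any():
        raise InsufficientDataError("missing cells; the design must be complete")
    n, k = data.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 conditions")
    return data


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity estimate from the condition covariance."""
    cov = np.cov(data, rowvar=False, ddof=1)
    k = cov.shape[0]
    centred = cov - cov.mean(axis=0) - cov.mean(axis=1)[:, None] + cov.mean()
    num = np.trace(centred) ** 2
    den = (k - 1) * (centred**2).sum()
    return float(num / den) if den > 0 else 1.0


def rm_anova(data, conditions: list[str] | None = None) -> AnovaResult:
    """One-way within-subject ANOVA on a complete subjects x conditions matrix.

    F = MS_condition / MS_(condition x subject), with df (k-1) and
    (k-1)(n-1). The Greenhouse-Geisser epsilon and corrected p-value are
    reported alongside but the headline F and p are uncorrected.
    """
    data = _check_matrix(data)
    n, k = data.shape
    if conditions is not None and len(conditions) != k:
        raise DesignError("condition labels do not match the matrix width")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)
    p = float(sps.f.sf(F, df_num, df_den))
    eps = _gg_epsilon(data)
    p_gg = float(sps.f.sf(F, df_num * eps, df_den * eps))
    result = AnovaResult(
        F=float(F), df_num=float(df_num), df_den=float(df_den), p=p,
        condition_means=cond_means, gg_epsilon=eps, p_gg=p_gg,
    )
    if k == 4:
        result.contrasts = helmert_contrasts(data)
    return result


def helmert_contrasts(data) -> list[ContrastResult]:
    """The three a priori Helmert contrasts on a subjects x 4 matrix.

    Per-subject contrast scores are tested against zero with an exact
    one-sample t; a normal-approximation z statistic is reported as well.
    """
    data = _check_matrix(data)
    n, k = data.shape
    if k != 4:
        raise DesignError("Helmert contrasts are defined for 4 ordered conditions")
    coeffs = helmert_coefficients()
    out: list[ContrastResult] = []
    for label, cvec in zip(HELMERT_LABELS, coeffs):
        scores = data @ cvec
        res = sps.ttest_1samp(scores, 0.0)
        se = scores.std(ddof=1) / np.sqrt(n)
        z = float(scores.mean() / se) if se > 0 else 0.0
        out.append(
            ContrastResult(
                label=label,
                coefficients=cvec,
                estimate=float(scores.mean()),
                t=float(res.statistic),
                df=float(n - 1),
                p=float(res.pvalue),
                z=z,
                p_z=float(2.0 * sps.norm.sf(abs(z))),
            )
        )
    return out


def batch_compare(
    metrics_control: pd.DataFrame,
    metrics_test: pd.DataFrame,
    metric_list: list[str],
    holm: bool = False,
) -> pd.DataFrame:
    """One Welch comparison per metric between two per-ant tables.

    No multiplicity adjustment by default; ``holm=True`` adds
    Holm-corrected p-values in a ``p_holm`` column.
    """
    for m in metric_list:
        if m not in metrics_control.columns or m not in metrics_test.columns:
            raise DesignError(f"unknown metric column: {m!r}")
    rows = []
    for m in metric_list:
        r = welch_t_test(
            metrics_control[m].to_numpy(), metrics_test[m].to_numpy(), metric=m
        )
        rows.append(
            {
                "metric": m, "t": r.t, "df": r.df, "p": r.p,
                "mean_control": r.mean_1, "mean_test": r.mean_2,
                "sd_control": r.sd_1, "sd_test": r.sd_2,
                "n_control": r.n_1, "n_test": r.n_2,
            }
        )
    table = pd.DataFrame(rows)
    if holm:
        table["p_holm"] = multipletests(table["p"], method="holm")[1]
    return table
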