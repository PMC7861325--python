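"""Per-index class statistics: Welch's t-test and Fisher score.

Each of the 25 eye/face indices is compared between the normal and
impaired classes with Welch's unequal-variances t-test (sign convention:
normal minus impaired, so indices that are larger under impairment get a
negative t) and scored for discernibility with the Fisher score (ratio of
between-class to within-class scatter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: variance floor in the Fisher-score denominator, guarding degenerate channels
VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class IndexStats:
    index_name: str
    t: float
    df: float  # Welch-Satterthwaite (report rounds to integer)
    p: float
    fisher: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def welch_t(x_normal: np.ndarray, x_impaired: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test, (t, df, p), normal minus impaired.

    Both samples need at least two values and the pair must carry some
    variance.
    """
    x0 = np.asarray(x_normal, dtype=float)
    x1 = np.asarray(x_impaired, dtype=float)
    if x0.size < 2 or x1.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if np.var(x0, ddof=1) == 0 and np.var(x1, ddof=1) == 0:
        if np.mean(x0) == np.mean(x1):
            # identical degenerate samples: no evidence of difference
            return 0.0, float(x0.size + x1.size - 2), 1.0
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(x0, x1, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fisher_score(
    x: np.ndarray, labels: np.ndarray, form: str = "grand_mean"
) -> float:
    """Single-feature Fisher score: between-class over within-class scatter.

    ``form="grand_mean"`` (default):
        F = [n0 (mu0-mu)^2 + n1 (mu1-mu)^2] / [n0 s0^2 + n1 s1^2]
    with class means mu_c, grand mean mu and (population) class variances
    s_c^2.  ``form="two_class"`` uses (mu0-mu1)^2 / (s0^2 + s1^2).
    Denominators are floored at a tiny constant so degenerate channels
    give a large finite score rather than dividing by zero.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    x0, x1 = x[labels == classes[0]], x[labels == classes[1]]
    mu0, mu1, mu = x0.mean(), x1.mean(), x.mean()
    v0, v1 = x0.var(), x1.var()
    n0, n1 = x0.size, x1.size
    if form == "grand_mean":
        num = n0 * (mu0 - mu) ** 2 + n1 * (mu1 - mu) ** 2
        den = max(n0 * v0 + n1 * v1, VAR_FLOOR)
    elif form == "two_class":
        num = (mu0 - mu1) ** 2
        den = max(v0 + v1, VAR_FLOOR)
    else:
        raise ValueError(f"unknown form {form!r}")
    return float(num / den)


def compute_index_stats(
    data: pd.DataFrame,
    feature_names: list[str],
    label_col: str = "label",
    fisher_form: str = "grand_mean",
) -> list[IndexStats]:
    """Welch t and Fisher score for every index of a labeled feature table.

    Class 0 (normal) is the first t-test argument, so the sign convention
    is normal minus impaired.
    """
    out = []
    labels = data[label_col].to_numpy()
    for name in feature_names:
        x = data[name].to_numpy(dtype=float)
        t, df, p = welch_t(x[labels == 0], x[labels == 1])
        out.append(
            IndexStats(
                index_name=name,
                t=t,
                df=df,
                p=p,
                fisher=fisher_score(x, labels, form=fisher_form),
            )
        )
    return out


def rank_report(
    stats_list: list[IndexStats], alpha: float = 0.05, bonferroni: bool = True
) -> pd.DataFrame:
    """Ranked report of per-index statistics, sorted by |t| descending.

    Flags significance at ``alpha`` and, when ``bonferroni`` is set, at
    ``alpha / n_indices`` (0.002 for 25 indices at alpha 0.05).  Degrees of
    freedom are rounded to integers for display, matching how such tables
    are conventionally printed.
    """
    n = len(stats_list)
    rows = []
    for s in sorted(stats_list, key=lambda s: abs(s.t), reverse=True):
        row = {
            "index": s.index_name,
            "t": s.t,
            "df": int(round(s.df)),
            "p": s.p,
            "fisher": s.fisher,
            f"sig_{alpha:g}": s.p < alpha,
        }
        if bonferroni:
            row["sig_bonferroni"] = s.p < alpha / n
        rows.append(row)
    return pd.DataFrame(rows)
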