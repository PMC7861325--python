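"""Impairment threshold derivation and normal/impaired labeling.

Normalized PVT scores are compared across sessions (hours awake) with a
one-way ANOVA and Tukey-Kramer post-hoc pairwise comparisons.  The
impairment onset is the earliest session whose across-subject mean score
significantly exceeds the early baseline sessions; the normal/impaired
threshold tau is that session's mean normalized score, and any
observation strictly above tau is labeled impaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ImpairmentThreshold:
    onset_session: int | None
    tau: float | None
    anova_F: float
    anova_p: float
    df_between: int
    df_within: int
    pairwise_p: pd.DataFrame  # sessions x sessions, symmetric, unit diagonal
    baseline_sessions: tuple[int, ...] = ()

    @property
    def impairment_detected(self) -> bool:
        return self.onset_session is not None


def _session_groups(table: pd.DataFrame, score_col: str) -> dict[int, np.ndarray]:
    """Per-session score vectors, dropping missing scores and (with a
    warning) sessions with fewer than 2 observations."""
    groups: dict[int, np.ndarray] = {}
    for sess, sub in table.groupby("session_index"):
        vals = sub[score_col].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"session {sess} has <2 observations; excluded from ANOVA")
            continue
        groups[int(sess)] = vals
    return groups


def anova_sessions(
    table: pd.DataFrame, score_col: str = "normalized_score"
) -> tuple[float, int, int, float]:
    """One-way ANOVA of scores across sessions (unbalanced allowed).

    Returns (F, df_between, df_within, p).
    """
    groups = _session_groups(table, score_col)
    if len(groups) < 2:
        raise ValueError("need >= 2 sessions with >= 2 observations each")
    arrays = list(groups.values())
    F, p = stats.f_oneway(*arrays)
    k = len(arrays)
    N = sum(a.size for a in arrays)
    return float(F), k - 1, N - k, float(p)


def tukey_kramer(
    table: pd.DataFrame, score_col: str = "normalized_score"
) -> pd.DataFrame:
    """Tukey-Kramer pairwise p-values between sessions.

    Studentized-range based comparisons with the Tukey-Kramer unequal-n
    correction; returns a symmetric sessions x sessions DataFrame with
    unit diagonal.
    """
    groups = _session_groups(table, score_col)
    keys = sorted(groups)
    res = stats.tukey_hsd(*[groups[k] for k in keys])
    mat = pd.DataFrame(np.asarray(res.pvalue), index=keys, columns=keys)
    np.fill_diagonal(mat.values, 1.0)
    return mat


def derive_threshold(
    table: pd.DataFrame,
    baseline_sessions: tuple[int, ...] | None = None,
    alpha: float = 0.05,
    score_col: str = "normalized_score",
) -> ImpairmentThreshold:
    """Locate the impairment onset session and the threshold tau.

    Onset is the earliest session whose mean score exceeds the mean of
    every baseline session AND whose Tukey-Kramer p-value versus every
    baseline session is below ``alpha``.  Baseline defaults to the first
    three analysed sessions (the stable early-wakefulness window).  tau is
    the across-subject mean normalized score of the onset session.  If no
    session qualifies the threshold is returned with
    ``onset_session=None`` ("no impairment detected").
    """
    F, dfb, dfw, p = anova_sessions(table, score_col)
    pairwise = tukey_kramer(table, score_col)
    sessions = list(pairwise.index)
    if baseline_sessions is None:
        baseline_sessions = tuple(sessions[:3])
    unknown = set(baseline_sessions) - set(sessions)
    if unknown:
        raise ValueError(f"baseline sessions not in table: {sorted(unknown)}")

    means = table.groupby("session_index")[score_col].mean()
    onset = None
    for sess in sessions:
        if sess in baseline_sessions:
            continue
        above = all(means[sess] > means[b] for b in baseline_sessions)
        signif = all(pairwise.loc[sess, b] < alpha for b in baseline_sessions)
        if above and signif:
            onset = sess
            break
    tau = float(means[onset]) if onset is not None else None
    return ImpairmentThreshold(
        onset_session=onset,
        tau=tau,
        anova_F=F,
        anova_p=p,
        df_between=dfb,
        df_within=dfw,
        pairwise_p=pairwise,
        baseline_sessions=tuple(baseline_sessions),
    )


def label(
    table: pd.DataFrame, tau: float, score_col: str = "normalized_score"
) -> pd.DataFrame:
    """Attach binary labels: impaired (1) iff score strictly above tau.

    Rows with a missing score are dropped (logged via warning).  A score
    exactly equal to tau is labeled normal.
    """
    if tau is None:
        raise ValueError("tau undefined (no impairment detected)")
    out = table.copy()
    missing = out[score_col].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} rows with missing scores")
        out = out[~missing]
    out["label"] = (out[score_col] > tau).astype(int)
    return out
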