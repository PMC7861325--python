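"""End-to-end assembly: study -> feature table -> scores -> labeled dataset.

The analysed dataset drops session 1 (practice/learning session) and
missing sessions; per-subject PVT scores are Euclidean-normalized over
the analysed sessions; the impairment threshold and labels come from the
labeling stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import labeling
from .labeling import ImpairmentThreshold
from .oculometrics import ALL_INDICES, BlinkParams, FixationParams, session_indices
from .pvt import ScoringParams, normalize_subject, score_session
from .synthetic import SyntheticStudy


def compute_feature_table(
    study: SyntheticStudy,
    blink_params: BlinkParams = BlinkParams(),
    fixation_params: FixationParams = FixationParams(),
    drop_first_session: bool = True,
) -> pd.DataFrame:
    """Per-session 25-index feature rows for every generated session."""
    rows = []
    minutes = study.config.session_duration / 60.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-event imputation warnings
        for rec in study.sessions:
            if rec.missing or rec.gaze is None or rec.ft is None:
                continue
            if drop_first_session and rec.session_index == 1:
                continue
            feats = session_indices(
                rec.gaze, rec.ft, session_minutes=minutes,
                blink_params=blink_params, fixation_params=fixation_params,
            )
            rows.append(
                {"subject_id": rec.subject_id, "session_index": rec.session_index,
                 "hours_awake": rec.hours_awake, **feats}
            )
    return pd.DataFrame(rows)


def compute_score_table(
    study: SyntheticStudy,
    params: ScoringParams = ScoringParams(),
    drop_first_session: bool = True,
) -> pd.DataFrame:
    """Raw and per-subject-normalized PVT scores for the analysed sessions.

    Missing sessions are excluded from each subject's Euclidean norm and
    absent from the output.
    """
    rows = []
    for rec in study.sessions:
        if rec.missing or rec.pvt is None:
            continue
        if drop_first_session and rec.session_index == 1:
            continue
        s = score_session(rec.pvt, params)
        rows.append(
            {"subject_id": rec.subject_id, "session_index": rec.session_index,
             "hours_awake": rec.hours_awake, "n_lapses": s.n_lapses,
             "n_major": s.n_major, "n_false_starts": s.n_false_starts,
             "score": s.score}
        )
    table = pd.DataFrame(rows)
    table["normalized_score"] = np.nan
    for subj, sub in table.groupby("subject_id"):
        table.loc[sub.index, "normalized_score"] = normalize_subject(
            sub["score"].to_numpy(dtype=float)
        )
    return table


def build_labeled_dataset(
    study: SyntheticStudy,
    feature_table: pd.DataFrame | None = None,
    score_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
    baseline_sessions: tuple[int, ...] | None = None,
) -> tuple[pd.DataFrame, ImpairmentThreshold]:
    """Label every observation and join with its feature row.

    Returns (labeled feature table, threshold).  Raises if no impairment
    onset is detectable (flat cohorts carry no class structure).
    """
    if score_table is None:
        score_table = compute_score_table(study)
    threshold = labeling.derive_threshold(
        score_table, baseline_sessions=baseline_sessions, alpha=alpha
    )
    if not threshold.impairment_detected:
        raise ValueError("no impairment detected; cannot define classes")
    labeled_scores = labeling.label(score_table, threshold.tau)
    if feature_table is None:
        feature_table = compute_feature_table(study)
    merged = feature_table.merge(
        labeled_scores[["subject_id", "session_index", "normalized_score", "label"]],
        on=["subject_id", "session_index"],
        how="inner",
    )
    return merged, threshold


def feature_names() -> list[str]:
    return list(ALL_INDICES)
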