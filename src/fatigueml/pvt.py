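"""Psychomotor vigilance task (PVT) session scoring.

The per-session performance index counts lapses (reaction time > 500 ms),
major lapses (> 1000 ms, which also count as lapses and therefore carry
double weight) and false starts (responses with no stimulus present):

    score = #lapses + #major lapses + #false starts.

Scores are then scale-adjusted per subject by dividing each subject's
session scores by the Euclidean norm of that subject's 12 analysed
sessions (session 1 is excluded upstream as a practice/learning session).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PVTEventLog",
    "ScoringParams",
    "PVTSessionScore",
    "score_session",
    "normalize_subject",
]


@dataclass
class PVTEventLog:
    """Stimulus/response record for one 10-min PVT session."""

    rts: np.ndarray  # reaction time per stimulus, ms
    false_start_times: np.ndarray  # seconds from session start
    stimulus_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject_id: int = 0
    session_index: int = 1
    hours_awake: float = 0.0

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.false_start_times = np.asarray(self.false_start_times, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.rts.size and np.any(self.rts < 0):
            raise ValueError("reaction times must be non-negative")


@dataclass(frozen=True)
class ScoringParams:
    lapse_ms: float = 500.0
    major_lapse_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.major_lapse_ms > self.lapse_ms > 0):
            raise ValueError("require major_lapse_ms > lapse_ms > 0")


@dataclass(frozen=True)
class PVTSessionScore:
    n_lapses: int
    n_major: int
    n_false_starts: int

    @property
    def score(self) -> int:
        return self.n_lapses + self.n_major + self.n_false_starts


def score_session(log: PVTEventLog, params: ScoringParams = ScoringParams()) -> PVTSessionScore:
    """Count lapses / major lapses / false starts for one session.

    Thresholds are strict: an RT of exactly 500 ms is not a lapse.  A
    major lapse (> 1000 ms) is also a lapse, so it contributes twice to
    the combined score.
    """
    rts = log.rts
    n_lapses = int(np.count_nonzero(rts > params.lapse_ms))
    n_major = int(np.count_nonzero(rts > params.major_lapse_ms))
    return PVTSessionScore(
        n_lapses=n_lapses,
        n_major=n_major,
        n_false_starts=int(log.false_start_times.size),
    )


def normalize_subject(scores: np.ndarray) -> np.ndarray:
    """Divide one subject's session scores by their Euclidean norm.

    NaN entries mark missing sessions; they are excluded from the norm and
    stay NaN in the output.  The non-missing output entries have unit
    Euclidean norm unless every score is zero, in which case the scores
    are returned unchanged with a warning (the norm is undefined).
    """
    scores = np.asarray(scores, dtype=float)
    present = ~np.isnan(scores)
    if not np.any(present):
        raise ValueError("need at least one non-missing score")
    norm = float(np.sqrt(np.sum(scores[present] ** 2)))
    if norm == 0.0:
        warnings.warn("all session scores are zero; norm undefined, returning zeros")
        return scores.copy()
    out = scores / norm
    return out
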