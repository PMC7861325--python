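import numpy as np
import pandas as pd
import pytest

from fatigueml.pipeline import build_labeled_dataset, feature_names
from fatigueml.synthetic import StudyConfig, generate_study


def small_config(seed: int = 11, **overrides) -> StudyConfig:
    """Reduced-scale study used across the suite: fewer subjects, shorter
    sessions and lower sampling rates than the full protocol, which leaves
    every pipeline property intact while keeping runtimes small."""
    params = dict(
        n_subjects=8, session_duration=120.0, gaze_rate=25.0, ft_rate=5.0, seed=seed
    )
    params.update(overrides)
    return StudyConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def labeled_small(small_study):
    data, threshold = build_labeled_dataset(small_study)
    return data, threshold


FEATURES = feature_names()


def toy_labeled_table(
    seed: int,
    n_subjects: int = 10,
    rows_per_subject: int = 10,
    n_features: int = 5,
    n_informative: int = 3,
    shift: float = 1.5,
) -> pd.DataFrame:
    """Directly constructed labeled feature table: Gaussian features, the
    first ``n_informative`` shifted by ``shift`` SDs under the positive
    class, subjects as grouping keys."""
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(1, n_subjects + 1):
        for _ in range(rows_per_subject):
            y = int(rng.random() < 0.4)
            x = rng.normal(0.0, 1.0, n_features)
            x[:n_informative] += shift * y
            rows.append(
                {"subject_id": subj, "label": y}
                | {f"f{j}": x[j] for j in range(n_features)}
            )
    return pd.DataFrame(rows)
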