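#!/usr/bin/env python
"""Score the PVT sessions and derive the impairment threshold and labels.

Computes each session's PVT score (lapses + major lapses + false starts,
majors double-weighted), normalizes per subject, locates the impairment
onset session by one-way ANOVA + Tukey-Kramer against the early baseline
sessions, and labels every observation normal/impaired against the
threshold tau.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from fatigueml import labeling
from fatigueml.io import read_pvt_csv, read_study_config
from fatigueml.pvt import normalize_subject, score_session


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("scratch/study"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()
    cfg = read_study_config(args.data)

    rows = []
    for subj_dir in sorted(args.data.glob("sub-*")):
        subject_id = int(subj_dir.name.split("-")[1])
        for pvt_path in sorted(subj_dir.glob("sess*_pvt.csv")):
            session = int(pvt_path.name[4:6])
            if session == 1:  # practice session
                continue
            log = read_pvt_csv(pvt_path, subject_id=subject_id, session_index=session)
            s = score_session(log)
            rows.append({
                "subject_id": subject_id, "session_index": session,
                "hours_awake": cfg.hours_awake(session),
                "n_lapses": s.n_lapses, "n_major": s.n_major,
                "n_false_starts": s.n_false_starts, "score": s.score,
            })
    scores = pd.DataFrame(rows)
    for subj, sub in scores.groupby("subject_id"):
        scores.loc[sub.index, "normalized_score"] = normalize_subject(
            sub["score"].to_numpy(dtype=float)
        )

    threshold = labeling.derive_threshold(scores, alpha=args.alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labeled = labeling.label(scores, threshold.tau)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    scores.to_csv(args.out_dir / "pvt_scores.csv", index=False)
    labeled.to_csv(args.out_dir / "labeled_scores.csv", index=False)
    (args.out_dir / "threshold.json").write_text(json.dumps({
        "onset_session": threshold.onset_session,
        "onset_hours_awake": cfg.hours_awake(threshold.onset_session),
        "tau": threshold.tau,
        "anova_F": threshold.anova_F,
        "anova_p": threshold.anova_p,
        "df": [threshold.df_between, threshold.df_within],
        "baseline_sessions": list(threshold.baseline_sessions),
    }, indent=1))

    counts = labeled["label"].value_counts().to_dict()
    print(f"ANOVA: F({threshold.df_between}, {threshold.df_within}) = "
          f"{threshold.anova_F:.2f}, p = {threshold.anova_p:.2e}")
    print(f"onset session {threshold.onset_session} "
          f"({cfg.hours_awake(threshold.onset_session):.0f} h awake), tau = {threshold.tau:.3f}")
    print(f"labels: {counts.get(0, 0)} normal / {counts.get(1, 0)} impaired")


if __name__ == "__main__":
    main()
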