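#!/usr/bin/env python
"""Extract the 25 per-session indices from the raw study tree.

Reads the gaze and facial CSVs written by 01_simulate.py, runs blink and
fixation detection plus facial-channel means, and writes one feature row
per subject-session (session 1, the practice session, is dropped).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from fatigueml.oculometrics import session_indices
from fatigueml.io import read_ft_csv, read_gaze_csv, read_study_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("scratch/study"))
    parser.add_argument("--out", type=Path, default=Path("results/feature_table.csv"))
    args = parser.parse_args()
    config = read_study_config(args.data)

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for subj_dir in sorted(args.data.glob("sub-*")):
            subject_id = int(subj_dir.name.split("-")[1])
            for gaze_path in sorted(subj_dir.glob("sess*_gaze.csv")):
                session = int(gaze_path.name[4:6])
                if session == 1:
                    continue
                gaze = read_gaze_csv(gaze_path, rate=config.gaze_rate)
                ft = read_ft_csv(gaze_path.with_name(f"sess{session:02d}_facial.csv"))
                minutes = config.session_duration / 60.0
                feats = session_indices(gaze, ft, session_minutes=minutes)
                rows.append({"subject_id": subject_id, "session_index": session, **feats})

    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(f"wrote {len(table)} feature rows to {args.out}")
    print(table[["blink_duration", "blink_frequency", "fixation_duration",
                 "eye_closure"]].describe().loc[["mean", "std"]].round(2))


if __name__ == "__main__":
    main()
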