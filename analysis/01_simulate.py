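#!/usr/bin/env python
"""Simulate the sleep-deprivation cohort and write its raw data tree.

Generates the default study shape -- 20 subjects, 13 two-hourly PVT
sessions with gaze and facial-channel recordings, ~3% of sessions lost --
and writes per-subject session CSVs plus the ground-truth JSON.  Raw gaze
streams are large, so the tree goes under scratch/ by default.
"""

import argparse
from pathlib import Path

from fatigueml.io import write_study
from fatigueml.synthetic import StudyConfig, generate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("scratch/study"))
    parser.add_argument("--subjects", type=int, default=20)
    parser.add_argument(
        "--quick", action="store_true",
        help="reduced scale (short sessions, low sampling rates)",
    )
    args = parser.parse_args()

    kwargs = dict(n_subjects=args.subjects, seed=args.seed)
    if args.quick:
        kwargs.update(session_duration=120.0, gaze_rate=25.0, ft_rate=5.0)
    config = StudyConfig(**kwargs)
    study = generate_study(config)
    write_study(study, args.out)

    n_missing = sum(rec.missing for rec in study.sessions)
    print(f"wrote study to {args.out}")
    print(f"  subjects: {config.n_subjects}, sessions each: {config.n_sessions}")
    print(f"  missing sessions: {n_missing} of {len(study.sessions)}")
    onsets = sorted(study.ground_truth.onset_hours_awake.values())
    print(f"  true impairment onsets (h awake): {onsets[0]:.1f}-{onsets[-1]:.1f}, "
          f"median {onsets[len(onsets)//2]:.1f}")


if __name__ == "__main__":
    main()
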