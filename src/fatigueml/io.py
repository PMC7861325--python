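"""On-disk interchange formats.

One directory per subject; per session a gaze CSV (t_s, xL, yL, xR, yR),
a facial CSV (t_s + 21 named channels) and a PVT event CSV
(event_type in {stimulus, response, false_start}, t_s, rt_ms), plus a
study-level ground-truth JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .oculometrics import FT_CHANNELS, GazeRecording
from .pvt import PVTEventLog
from .synthetic import StudyConfig, SyntheticStudy


def write_gaze_csv(gaze: GazeRecording, path: Path) -> None:
    pd.DataFrame(
        {"t_s": gaze.t, "xL": gaze.xL, "yL": gaze.yL, "xR": gaze.xR, "yR": gaze.yR}
    ).to_csv(path, index=False)


def read_gaze_csv(path: Path, rate: float) -> GazeRecording:
    df = pd.read_csv(path)
    return GazeRecording(
        t=df["t_s"].to_numpy(), xL=df["xL"].to_numpy(), yL=df["yL"].to_numpy(),
        xR=df["xR"].to_numpy(), yR=df["yR"].to_numpy(), rate=rate,
    )


def write_ft_csv(ft: dict[str, np.ndarray], rate: float, path: Path) -> None:
    n = len(next(iter(ft.values())))
    out = {"t_s": np.arange(n) / rate}
    out.update({ch: ft[ch] for ch in FT_CHANNELS})
    pd.DataFrame(out).to_csv(path, index=False)


def read_ft_csv(path: Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {ch: df[ch].to_numpy(dtype=float) for ch in FT_CHANNELS}


def write_pvt_csv(log: PVTEventLog, path: Path) -> None:
    rows = []
    for t, rt in zip(log.stimulus_times, log.rts):
        rows.append({"event_type": "stimulus", "t_s": t, "rt_ms": ""})
        rows.append({"event_type": "response", "t_s": t + rt / 1000.0, "rt_ms": rt})
    for t in log.false_start_times:
        rows.append({"event_type": "false_start", "t_s": t, "rt_ms": ""})
    pd.DataFrame(rows, columns=["event_type", "t_s", "rt_ms"]).sort_values(
        "t_s", kind="stable"
    ).to_csv(path, index=False)


def read_pvt_csv(path: Path, subject_id: int = 0, session_index: int = 1,
                 hours_awake: float = 0.0) -> PVTEventLog:
    df = pd.read_csv(path)
    resp = df[df["event_type"] == "response"]
    stim = df[df["event_type"] == "stimulus"]
    fs = df[df["event_type"] == "false_start"]
    return PVTEventLog(
        rts=resp["rt_ms"].to_numpy(dtype=float),
        false_start_times=fs["t_s"].to_numpy(dtype=float),
        stimulus_times=stim["t_s"].to_numpy(dtype=float),
        subject_id=subject_id,
        session_index=session_index,
        hours_awake=hours_awake,
    )


def read_study_config(root: Path) -> StudyConfig:
    """Load the config manifest written alongside a study tree."""
    raw = json.loads((Path(root) / "study_config.json").read_text())
    raw["isi_range"] = tuple(raw["isi_range"])
    return StudyConfig(**raw)


def write_study(study: SyntheticStudy, root: Path) -> None:
    """Write the whole study tree: sub-XX/sessYY_{gaze,facial,pvt}.csv plus
    the config manifest and ground_truth.json at the root."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    (root / "study_config.json").write_text(
        json.dumps(dataclasses.asdict(study.config), indent=1)
    )
    for rec in study.sessions:
        if rec.missing:
            continue
        subj_dir = root / f"sub-{rec.subject_id:02d}"
        subj_dir.mkdir(exist_ok=True)
        prefix = subj_dir / f"sess{rec.session_index:02d}"
        if rec.pvt is not None:
            write_pvt_csv(rec.pvt, prefix.with_name(prefix.name + "_pvt.csv"))
        if rec.gaze is not None:
            write_gaze_csv(rec.gaze, prefix.with_name(prefix.name + "_gaze.csv"))
        if rec.ft is not None:
            write_ft_csv(rec.ft, study.config.ft_rate, prefix.with_name(prefix.name + "_facial.csv"))
    truth = {
        "onset_hours_awake": {str(k): v for k, v in study.ground_truth.onset_hours_awake.items()},
        "impairment_level": {
            f"{s}:{sess}": lvl for (s, sess), lvl in study.ground_truth.impairment_level.items()
        },
        "missing_sessions": [
            [rec.subject_id, rec.session_index] for rec in study.sessions if rec.missing
        ],
    }
    (root / "ground_truth.json").write_text(json.dumps(truth, indent=1))
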