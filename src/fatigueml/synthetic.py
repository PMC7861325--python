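"""Synthetic sleep-deprivation study generator.

Emulates the structure of a 24-h total-sleep-deprivation protocol: 20
subjects complete a 10-min PVT every 2 h (13 sessions, the first of which
is flagged as a practice session), while a 50 Hz binocular gaze stream and
21 facial-channel probability series are recorded.  Each subject has a
latent impairment onset (hours awake); past onset, an impairment level
grows linearly with hours awake and drives the lapse probability, blink
duration/frequency, fixation duration, and shifts in the facial-channel
means.  About 3% of sessions are lost to simulated technical malfunction.

The generator keeps a private ground-truth ledger (true blink and
fixation events, true onset) so detectors and the labeling stage can be
checked against a known answer.

All randomness flows through per-(subject, session) substreams spawned
from the master seed, so enlarging the study does not perturb the draws
of earlier subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .oculometrics import FT_CHANNELS, GazeRecording
from .pvt import PVTEventLog

#: Population-level facial-channel resting means, one per channel, in [0, 1].
#: Pose channels (pitch/yaw/roll) and interocular distance are pre-scaled to
#: [0, 1] by the generator.
FT_BASE_MEANS: dict[str, float] = {
    "brow_furrow": 0.10,
    "brow_raise": 0.15,
    "engagement": 0.40,
    "lip_corner_depressor": 0.08,
    "smile": 0.12,
    "valence": 0.45,
    "attention": 0.60,
    "interocular_distance": 0.50,
    "pitch": 0.50,
    "yaw": 0.50,
    "roll": 0.50,
    "inner_brow_raise": 0.12,
    "eye_closure": 0.15,
    "nose_wrinkle": 0.06,
    "upper_lip_raise": 0.06,
    "lip_suck": 0.08,
    "lip_press": 0.10,
    "mouth_open": 0.15,
    "chin_raise": 0.08,
    "smirk": 0.08,
    "lip_pucker": 0.08,
}

#: Signed per-channel shift (probability units) applied at full impairment.
#: Signs follow the observed direction of each channel's class difference
#: (e.g., eye closure, brow raise and mouth open increase when impaired;
#: smile and head roll decrease); magnitudes taper from strong drowsiness
#: markers down to null channels.
FT_IMPAIRMENT_SHIFTS: dict[str, float] = {
    "eye_closure": 0.072,
    "brow_raise": 0.06,
    "mouth_open": 0.048,
    "lip_pucker": 0.036,
    "inner_brow_raise": 0.036,
    "lip_press": 0.03,
    "smile": -0.03,
    "pitch": 0.03,
    "nose_wrinkle": 0.024,
    "attention": 0.024,
    "upper_lip_raise": 0.021,
    "lip_corner_depressor": 0.018,
    "roll": -0.018,
    "smirk": 0.012,
    "engagement": 0.012,
    "chin_raise": 0.012,
    "yaw": -0.009,
    "interocular_distance": 0.006,
    "valence": 0.006,
    "lip_suck": -0.003,
    "brow_furrow": 0,
}


@dataclass(frozen=True)
class StudyConfig:
    """Shape of the simulated study; defaults match the emulated protocol."""

    n_subjects: int = 20
    n_sessions: int = 13  # 2-h spacing; session 1 flagged for exclusion
    session_duration: float = 600.0  # seconds
    gaze_rate: float = 50.0  # Hz
    ft_rate: float = 10.0  # Hz
    isi_range: tuple[float, float] = (2.0, 10.0)  # seconds
    missing_fraction: float = 0.03
    session_spacing_hours: float = 2.0
    first_session_hours_awake: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.session_duration < 0:
            raise ValueError("session_duration must be >= 0")
        if not self.isi_range[0] < self.isi_range[1]:
            raise ValueError("isi_range must be increasing")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.gaze_rate <= 0 or self.ft_rate <= 0:
            raise ValueError("sampling rates must be positive")

    def hours_awake(self, session_index: int) -> float:
        return self.first_session_hours_awake + self.session_spacing_hours * (
            session_index - 1
        )


@dataclass
class SubjectProfile:
    """Latent per-subject parameters driving the simulated signals."""

    baseline_rt_median: float = 280.0  # ms, lognormal body median
    baseline_rt_sigma: float = 0.14  # lognormal shape
    lapse_base: float = 0.025  # lapse probability when unimpaired
    lapse_rate_slope: float = 0.035  # lapse probability per impairment-hour
    lapse_tail_mean: float = 280.0  # ms above the tail floor for lapse RTs
    lapse_tail_floor: float = 500.0  # ms, lower bound of lapse RTs
    false_start_rate: float = 1.0  # Poisson mean per session
    blink_dur_base: float = 150.0  # ms
    blink_dur_slope: float = 6.0  # ms per impairment-hour
    blink_dur_session_sd: float = 0.15  # session-level lognormal jitter
    blink_freq_base: float = 10.0  # per minute
    blink_freq_slope: float = 0.25  # per minute per impairment-hour
    blink_freq_session_sd: float = 0.20  # session-level lognormal jitter
    fix_dur_base: float = 260.0  # ms
    fix_dur_slope: float = 0.008  # relative increase per impairment-hour
    fix_dur_session_sd: float = 0.12  # session-level lognormal jitter
    onset_hours_awake: float = 17.0
    ft_channel_means: dict[str, float] = field(
        default_factory=lambda: dict(FT_BASE_MEANS)
    )
    ft_impairment_shift: dict[str, float] = field(
        default_factory=lambda: dict(FT_IMPAIRMENT_SHIFTS)
    )
    ft_session_sd: float = 0.06  # session-to-session channel variability
    ft_sample_sd: float = 0.08  # within-session sample noise

    def __post_init__(self) -> None:
        for name, value in (
            ("lapse_base", self.lapse_base),
            ("lapse_rate_slope", self.lapse_rate_slope),
            ("false_start_rate", self.false_start_rate),
            ("blink_freq_base", self.blink_freq_base),
            ("blink_dur_base", self.blink_dur_base),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        for ch, mean in self.ft_channel_means.items():
            shifted = mean + self.ft_impairment_shift.get(ch, 0.0)
            if not (0.0 <= mean <= 1.0 and 0.0 <= shifted <= 1.0):
                raise ValueError(f"channel {ch}: mean and mean+shift must stay in [0,1]")

    def impairment(self, hours_awake: float, spacing: float = 2.0) -> float:
        """Impairment level in hours: 0 before onset, then grows with time awake.

        The onset session itself already carries one inter-session spacing
        of drive, so the first affected session is measurably elevated.
        """
        if hours_awake < self.onset_hours_awake:
            return 0.0
        return hours_awake - self.onset_hours_awake + spacing


def sample_profiles(config: StudyConfig, rng: np.random.Generator) -> list[SubjectProfile]:
    """Draw per-subject profiles around the population defaults."""
    profiles = []
    for _ in range(config.n_subjects):
        means = {
            ch: float(np.clip(m + rng.normal(0.0, 0.05), 0.06, 0.85))
            for ch, m in FT_BASE_MEANS.items()
        }
        profiles.append(
            SubjectProfile(
                baseline_rt_median=rng.uniform(260.0, 300.0),
                baseline_rt_sigma=rng.uniform(0.10, 0.18),
                lapse_base=rng.uniform(0.01, 0.04),
                lapse_rate_slope=rng.uniform(0.025, 0.05),
                false_start_rate=rng.uniform(0.5, 1.5),
                blink_dur_base=rng.uniform(120.0, 180.0),
                blink_dur_slope=rng.uniform(4.0, 8.0),
                blink_freq_base=rng.uniform(8.0, 14.0),
                blink_freq_slope=rng.uniform(0.15, 0.35),
                fix_dur_base=rng.uniform(220.0, 300.0),
                fix_dur_slope=rng.uniform(0.004, 0.012),
                onset_hours_awake=float(np.clip(rng.normal(17.0, 3.0), 11.0, 23.0)),
                ft_channel_means=means,
            )
        )
    return profiles


@dataclass
class SessionRecord:
    """Everything generated for one subject-session slot."""

    subject_id: int
    session_index: int
    hours_awake: float
    impairment: float
    missing: bool
    pvt: PVTEventLog | None = None
    gaze: GazeRecording | None = None
    ft: dict[str, np.ndarray] | None = None
    # ground-truth ledgers (generator-private; used only as test oracles)
    true_blinks: list[tuple[float, float]] = field(default_factory=list)
    true_fixations: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """True impairment structure of the simulated cohort."""

    onset_hours_awake: dict[int, float]
    impairment_level: dict[tuple[int, int], float]  # (subject, session) -> level


@dataclass
class SyntheticStudy:
    config: StudyConfig
    profiles: list[SubjectProfile]
    sessions: list[SessionRecord]
    ground_truth: GroundTruth

    def session(self, subject_id: int, session_index: int) -> SessionRecord:
        for rec in self.sessions:
            if rec.subject_id == subject_id and rec.session_index == session_index:
                return rec
        raise KeyError((subject_id, session_index))


def _session_rng(seed: int, subject_id: int, session_index: int, stream: int) -> np.random.Generator:
    """Independent substream per (subject, session, signal)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_id, session_index, stream))
    )


def generate_pvt_session(
    profile: SubjectProfile,
    hours_awake: float,
    config: StudyConfig,
    rng: np.random.Generator,
    impairment: float | None = None,
) -> PVTEventLog:
    """Simulate one 10-min PVT session.

    Stimuli follow one another at a uniform 2-10 s inter-stimulus interval
    measured from the previous response.  Each RT is drawn from a lognormal
    body (median ~280 ms); with probability min(1, base + slope x
    impairment) the RT is instead a lapse drawn above 500 ms (exponential
    tail, so some lapses exceed 1000 ms).  False starts are a Poisson
    count placed uniformly in session time.
    """
    if impairment is None:
        impairment = profile.impairment(hours_awake, config.session_spacing_hours)
    lapse_p = min(1.0, profile.lapse_base + profile.lapse_rate_slope * impairment)

    stim_times: list[float] = []
    rts: list[float] = []
    t = 0.0
    duration = config.session_duration
    lo, hi = config.isi_range
    while True:
        t = t + rng.uniform(lo, hi)
        if t >= duration:
            break
        stim_times.append(t)
        if rng.random() < lapse_p:
            rt = profile.lapse_tail_floor + rng.exponential(profile.lapse_tail_mean)
        else:
            rt = profile.baseline_rt_median * np.exp(
                rng.normal(0.0, profile.baseline_rt_sigma)
            )
        rts.append(rt)
        t = t + rt / 1000.0

    n_fs = rng.poisson(profile.false_start_rate) if duration > 0 else 0
    fs_times = np.sort(rng.uniform(0.0, duration, size=n_fs)) if n_fs else np.empty(0)
    return PVTEventLog(
        rts=np.asarray(rts),
        false_start_times=fs_times,
        stimulus_times=np.asarray(stim_times),
        hours_awake=hours_awake,
    )


def generate_gaze(
    profile: SubjectProfile,
    impairment: float,
    config: StudyConfig,
    rng: np.random.Generator,
    blink_freq_override: float | None = None,
) -> tuple[GazeRecording, list[tuple[float, float]], list[tuple[float, float]]]:
    """Simulate a binocular gaze stream with planted fixations and blinks.

    Returns (recording, true_blinks, true_fixations); events are
    (start_s, end_s) pairs aligned to sample boundaries.  The gaze follows
    a fixation-saccade process (piecewise-constant centres plus small
    jitter) well away from the origin, so only blink samples -- runs where
    both eyes read (0, 0) -- fall below the downstream magnitude threshold.
    """
    rate = config.gaze_rate
    n = int(round(config.session_duration * rate))
    t = np.arange(n) / rate
    if n == 0:
        empty = np.empty(0)
        return GazeRecording(t=empty, xL=empty, yL=empty, xR=empty, yR=empty, rate=rate), [], []

    # session-level variability: real sessions vary around the latent trend
    fix_mean_ms = (
        profile.fix_dur_base
        * (1.0 + profile.fix_dur_slope * impairment)
        * rng.lognormal(0.0, profile.fix_dur_session_sd)
    )
    # piecewise-constant fixation centres inside a screen-like box
    x = np.empty(n)
    y = np.empty(n)
    true_fixations: list[tuple[float, float]] = []
    i = 0
    cx, cy = rng.uniform(250.0, 750.0), rng.uniform(200.0, 600.0)
    while i < n:
        dur_ms = max(150.0, rng.lognormal(np.log(fix_mean_ms), 0.3))
        seg = max(int(round(dur_ms / 1000.0 * rate)), int(np.ceil(0.15 * rate)))
        j = min(n, i + seg)
        x[i:j] = cx
        y[i:j] = cy
        true_fixations.append((i / rate, j / rate))
        i = j
        # saccade: jump at least 60 units so fixations never merge
        for _ in range(20):
            nx = cx + rng.uniform(-200.0, 200.0)
            ny = cy + rng.uniform(-150.0, 150.0)
            if 200.0 <= nx <= 800.0 and 150.0 <= ny <= 650.0 and abs(nx - cx) + abs(ny - cy) >= 60.0:
                break
        cx, cy = nx, ny

    jitter = 1.0
    xL = x + rng.normal(0.0, jitter, n)
    yL = y + rng.normal(0.0, jitter, n)
    xR = x + rng.normal(0.0, jitter, n)
    yR = y + rng.normal(0.0, jitter, n)

    # blinks: Poisson count, normal durations (floored at two sample periods
    # so every planted blink clears the >20 ms rule at 50 Hz), non-overlapping
    blink_freq = (
        blink_freq_override
        if blink_freq_override is not None
        else (profile.blink_freq_base + profile.blink_freq_slope * impairment)
        * rng.lognormal(0.0, profile.blink_freq_session_sd)
    )
    blink_dur_ms = (
        profile.blink_dur_base + profile.blink_dur_slope * impairment
    ) * rng.lognormal(0.0, profile.blink_dur_session_sd)
    n_blinks = rng.poisson(blink_freq * config.session_duration / 60.0)
    true_blinks: list[tuple[float, float]] = []
    if n_blinks > 0:
        starts = np.sort(rng.uniform(0.0, config.session_duration, size=n_blinks))
        min_sep_samples = 3
        last_end = -min_sep_samples - 1
        for s in starts:
            dur = max(2.0 / rate * 1000.0, rng.normal(blink_dur_ms, 25.0))
            i0 = int(round(s * rate))
            n_samp = int(round(dur / 1000.0 * rate))
            i1 = min(n, i0 + n_samp)
            if i0 <= last_end + min_sep_samples or i1 >= n - 1 or i1 <= i0:
                continue
            xL[i0:i1] = yL[i0:i1] = xR[i0:i1] = yR[i0:i1] = 0.0
            true_blinks.append((i0 / rate, i1 / rate))
            last_end = i1
    gaze = GazeRecording(t=t, xL=xL, yL=yL, xR=xR, yR=yR, rate=rate)
    return gaze, true_blinks, true_fixations


def generate_ft_series(
    profile: SubjectProfile,
    impairment: float,
    config: StudyConfig,
    rng: np.random.Generator,
    impairment_scale_hours: float = 6.0,
) -> dict[str, np.ndarray]:
    """Simulate the 21 facial-channel probability series for one session.

    Each channel is i.i.d. noise around the subject's channel mean plus an
    impairment-scaled shift (saturating after ``impairment_scale_hours``
    past onset) plus a session-level random effect, clipped to [0, 1].
    """
    n = int(round(config.session_duration * config.ft_rate))
    g = min(1.0, impairment / impairment_scale_hours) if impairment_scale_hours > 0 else float(impairment > 0)
    out: dict[str, np.ndarray] = {}
    for ch in FT_CHANNELS:
        level = (
            profile.ft_channel_means[ch]
            + profile.ft_impairment_shift.get(ch, 0.0) * g
            + rng.normal(0.0, profile.ft_session_sd)
        )
        samples = level + rng.normal(0.0, profile.ft_sample_sd, size=n)
        out[ch] = np.clip(samples, 0.0, 1.0)
    return out


def generate_study(
    config: StudyConfig,
    profiles: list[SubjectProfile] | None = None,
    include_gaze: bool = True,
    include_ft: bool = True,
) -> SyntheticStudy:
    """Simulate the full cohort: every subject-session slot.

    ``profiles=None`` draws subject profiles from the population defaults.
    Gaze/facial generation can be switched off for PVT-only studies (the
    labeling stage needs only scores).  Missing sessions are marked, not
    generated.  Deterministic for a fixed ``config.seed``.
    """
    master = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    if profiles is None:
        profiles = sample_profiles(config, master)
    if len(profiles) != config.n_subjects:
        raise ValueError("need one profile per subject")

    sessions: list[SessionRecord] = []
    onset = {}
    level = {}
    for subj in range(1, config.n_subjects + 1):
        profile = profiles[subj - 1]
        onset[subj] = profile.onset_hours_awake
        for sess in range(1, config.n_sessions + 1):
            hours = config.hours_awake(sess)
            impair = profile.impairment(hours, config.session_spacing_hours)
            level[(subj, sess)] = impair
            miss_rng = _session_rng(config.seed, subj, sess, stream=0)
            missing = bool(miss_rng.random() < config.missing_fraction)
            rec = SessionRecord(
                subject_id=subj,
                session_index=sess,
                hours_awake=hours,
                impairment=impair,
                missing=missing,
            )
            if not missing:
                pvt_rng = _session_rng(config.seed, subj, sess, stream=1)
                rec.pvt = generate_pvt_session(profile, hours, config, pvt_rng, impairment=impair)
                rec.pvt.subject_id = subj
                rec.pvt.session_index = sess
                if include_gaze:
                    gaze_rng = _session_rng(config.seed, subj, sess, stream=2)
                    rec.gaze, rec.true_blinks, rec.true_fixations = generate_gaze(
                        profile, impair, config, gaze_rng
                    )
                if include_ft:
                    ft_rng = _session_rng(config.seed, subj, sess, stream=3)
                    rec.ft = generate_ft_series(profile, impair, config, ft_rng)
            sessions.append(rec)
    return SyntheticStudy(
        config=config,
        profiles=profiles,
        sessions=sessions,
        ground_truth=GroundTruth(onset_hours_awake=onset, impairment_level=level),
    )
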