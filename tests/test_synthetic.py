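import dataclasses

import numpy as np
import pytest

from fatigueml import labeling
from fatigueml.oculometrics import BlinkParams, FT_CHANNELS, detect_blinks, eye_magnitude
from fatigueml.pipeline import compute_score_table
from fatigueml.pvt import score_session
from fatigueml.synthetic import (
    StudyConfig,
    SubjectProfile,
    generate_ft_series,
    generate_gaze,
    generate_pvt_session,
    generate_study,
    sample_profiles,
)

from conftest import small_config


class TestStudyConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 1},
            {"isi_range": (10.0, 2.0)},
            {"missing_fraction": 1.0},
            {"gaze_rate": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StudyConfig(**kwargs)

    def test_hours_awake_schedule(self):
        cfg = StudyConfig()
        assert cfg.hours_awake(1) == 1.0
        assert cfg.hours_awake(9) == 17.0
        assert cfg.hours_awake(13) == 25.0


class TestGenerateStudy:
    def test_deterministic_for_fixed_seed(self):
        cfg = small_config(seed=21, n_subjects=3)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for ra, rb in zip(a.sessions, b.sessions):
            assert ra.missing == rb.missing
            if ra.missing:
                continue
            assert np.array_equal(ra.pvt.rts, rb.pvt.rts)
            assert np.array_equal(ra.gaze.xL, rb.gaze.xL)
            assert np.array_equal(ra.ft["smile"], rb.ft["smile"])
            assert ra.true_blinks == rb.true_blinks

    def test_session_count_without_missingness(self):
        cfg = StudyConfig(missing_fraction=0.0, seed=2)
        study = generate_study(cfg, include_gaze=False, include_ft=False)
        assert len(study.sessions) == 260  # 20 subjects x 13 sessions
        assert not any(rec.missing for rec in study.sessions)

    def test_adding_subjects_preserves_earlier_draws(self):
        small = generate_study(small_config(seed=5, n_subjects=4), include_gaze=False, include_ft=False)
        # reuse the same profiles for the first 4 subjects of a larger cohort
        cfg6 = small_config(seed=5, n_subjects=6)
        rng = np.random.default_rng(0)
        profiles6 = small.profiles + sample_profiles(
            dataclasses.replace(cfg6, n_subjects=2), rng
        )
        big = generate_study(cfg6, profiles=profiles6, include_gaze=False, include_ft=False)
        for subj in range(1, 5):
            for sess in range(1, cfg6.n_sessions + 1):
                ra = small.session(subj, sess)
                rb = big.session(subj, sess)
                assert ra.missing == rb.missing
                if not ra.missing:
                    assert np.array_equal(ra.pvt.rts, rb.pvt.rts)


class TestGeneratePVT:
    def test_zero_duration_gives_empty_log(self):
        cfg = StudyConfig(session_duration=0.0)
        log = generate_pvt_session(SubjectProfile(), 1.0, cfg, np.random.default_rng(0))
        assert log.rts.size == 0
        assert log.false_start_times.size == 0

    def test_forced_lapses_make_every_response_a_major_lapse(self):
        profile = SubjectProfile(lapse_base=1.0, lapse_tail_floor=1001.0)
        log = generate_pvt_session(profile, 1.0, StudyConfig(), np.random.default_rng(1))
        s = score_session(log)
        assert s.n_lapses == log.rts.size
        assert s.n_major == log.rts.size

    def test_stimulus_count_within_isi_bounds(self):
        log = generate_pvt_session(SubjectProfile(), 1.0, StudyConfig(), np.random.default_rng(2))
        assert 50 <= log.stimulus_times.size <= 300

    def test_stimulus_times_strictly_increasing(self):
        log = generate_pvt_session(SubjectProfile(), 25.0, StudyConfig(), np.random.default_rng(3))
        assert np.all(np.diff(log.stimulus_times) > 0)

    def test_impairment_increases_expected_score(self):
        """Paired-seed Monte-Carlo: higher impairment => higher mean score."""
        profile = SubjectProfile()
        cfg = StudyConfig(session_duration=300.0)
        low, high = [], []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            low.append(score_session(
                generate_pvt_session(profile, 5.0, cfg, rng, impairment=0.0)
            ).score)
            rng = np.random.default_rng(seed)
            high.append(score_session(
                generate_pvt_session(profile, 21.0, cfg, rng, impairment=8.0)
            ).score)
        assert np.mean(high) > np.mean(low)


class TestGenerateGaze:
    def test_zero_blink_frequency_gives_zero_detected_blinks(self):
        cfg = small_config(n_subjects=2)
        gaze, blinks, _ = generate_gaze(
            SubjectProfile(), 0.0, cfg, np.random.default_rng(0), blink_freq_override=0.0
        )
        assert blinks == []
        assert detect_blinks(eye_magnitude(gaze), gaze.rate, BlinkParams()) == []

    def test_detector_matches_generator_ledger(self):
        cfg = StudyConfig(n_subjects=2, session_duration=60.0, gaze_rate=50.0)
        gaze, blinks, _ = generate_gaze(SubjectProfile(), 2.0, cfg, np.random.default_rng(4))
        detected = detect_blinks(eye_magnitude(gaze), gaze.rate, BlinkParams())
        assert len(detected) == len(blinks)
        for ev, (s, e) in zip(detected, blinks):
            assert ev.start == pytest.approx(s, abs=1.0 / cfg.gaze_rate)
            assert ev.end == pytest.approx(e, abs=1.0 / cfg.gaze_rate)

    def test_impairment_lengthens_generated_blinks(self):
        cfg = StudyConfig(n_subjects=2, session_duration=120.0, gaze_rate=50.0)
        profile = SubjectProfile(blink_dur_session_sd=0.0)
        _, blinks_lo, _ = generate_gaze(profile, 0.0, cfg, np.random.default_rng(6))
        _, blinks_hi, _ = generate_gaze(profile, 8.0, cfg, np.random.default_rng(6))
        mean = lambda evs: np.mean([e - s for s, e in evs])
        assert mean(blinks_hi) > mean(blinks_lo)


class TestGenerateFT:
    def test_noiseless_series_hits_channel_means_exactly(self):
        profile = SubjectProfile(ft_session_sd=0.0, ft_sample_sd=0.0,
                                 ft_impairment_shift={ch: 0.0 for ch in FT_CHANNELS})
        cfg = small_config(n_subjects=2)
        out = generate_ft_series(profile, 5.0, cfg, np.random.default_rng(0))
        for ch in FT_CHANNELS:
            assert np.mean(out[ch]) == pytest.approx(profile.ft_channel_means[ch])

    def test_eye_closure_shift_direction_under_impairment(self):
        # eye closure is higher in the impaired class (negative t under the
        # normal-minus-impaired convention)
        profile = SubjectProfile(ft_session_sd=0.0)
        cfg = small_config(n_subjects=2)
        normal = generate_ft_series(profile, 0.0, cfg, np.random.default_rng(1))
        impaired = generate_ft_series(profile, 8.0, cfg, np.random.default_rng(1))
        assert np.mean(impaired["eye_closure"]) > np.mean(normal["eye_closure"])

    def test_values_clipped_to_unit_interval(self):
        profile = SubjectProfile(ft_sample_sd=0.5)
        out = generate_ft_series(profile, 4.0, small_config(n_subjects=2), np.random.default_rng(2))
        for ch in FT_CHANNELS:
            assert out[ch].min() >= 0.0
            assert out[ch].max() <= 1.0

    def test_invalid_channel_means_rejected(self):
        with pytest.raises(ValueError):
            SubjectProfile(ft_channel_means={**dict.fromkeys(FT_CHANNELS, 0.5), "smile": 1.2})


class TestFlatCohort:
    def test_no_lapse_slope_leaves_sessions_indistinguishable(self):
        """With no impairment drive the ANOVA across sessions is null: p
        should exceed 0.05 for the overwhelming majority of seeds."""
        flat = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = StudyConfig(seed=seed, session_duration=300.0)
            rng = np.random.default_rng(1000 + seed)
            profiles = sample_profiles(cfg, rng)
            profiles = [dataclasses.replace(p, lapse_rate_slope=0.0) for p in profiles]
            study = generate_study(cfg, profiles=profiles, include_gaze=False, include_ft=False)
            scores = compute_score_table(study)
            _, _, _, p = labeling.anova_sessions(scores)
            flat += p > 0.05
        assert flat >= 0.85 * n_seeds
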