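"""Acoustic framing, Yin pitch, motif detection, syllable rules."""

import numpy as np
import pandas as pd
import pytest

from syrinxlab.song import (AcousticFrameSeries, AudioRecording, FrameParams,
                            apply_duration_rules, bandpass,
                            compare_pre_post, compare_syllable_tables,
                            compute_frame_features, detect_and_align_motifs,
                            segment_syllables, syllable_f0_stats)
from syrinxlab.synth import (SongConfig, SyllableSpec, embed_motifs,
                             generate_song_audio)

FS = 44100.0


def brute_force_rules(sound, hop_ms, min_sound_ms=30.0, min_silence_ms=40.0):
    """Literal rule applier: scan runs one by one, remove short sounds,
    then short interior silences."""
    s = list(bool(v) for v in sound)
    n = len(s)

    def scan(values):
        segs = []
        i = 0
        while i < n:
            j = i
            while j < n and values[j] == values[i]:
                j += 1
            segs.append((i, j, values[i]))
            i = j
        return segs

    for i0, i1, val in scan(s):
        if val and (i1 - i0) * hop_ms < min_sound_ms:
            for k in range(i0, i1):
                s[k] = False
    segs = scan(s)
    for idx, (i0, i1, val) in enumerate(segs):
        if (not val and 0 < idx < len(segs) - 1
                and (i1 - i0) * hop_ms < min_silence_ms):
            for k in range(i0, i1):
                s[k] = True
    return np.array(s, dtype=bool)


def frames_from_binary(sound, hop_ms=0.5, loud=70.0, quiet=-np.inf):
    sl = np.where(sound, loud, quiet)
    n = len(sound)
    t = np.arange(n) * hop_ms * 1e-3
    nan = np.full(n, np.nan)
    return AcousticFrameSeries(t, np.where(sound, 1.0, 0.0), sl, nan, nan, nan,
                               hop_ms * 1e-3, 4e-3)


def frames_from_f0(f0, hop_ms=0.5, loud=70.0):
    n = len(f0)
    t = np.arange(n) * hop_ms * 1e-3
    sl = np.full(n, loud)
    return AcousticFrameSeries(t, np.ones(n), sl, np.zeros(n),
                               np.asarray(f0, float), np.zeros(n),
                               hop_ms * 1e-3, 4e-3)


class TestFrameFeatures:
    def test_calibration_tone_level_and_pitch(self):
        # 1 kHz at 1 Pa RMS is the 94 dB re 20 uPa calibration point
        t = np.arange(int(FS * 0.25)) / FS
        audio = AudioRecording(np.sqrt(2) * np.sin(2 * np.pi * 1000 * t), FS)
        fr = compute_frame_features(audio)
        mid = slice(100, len(fr) - 100)
        assert np.median(fr.source_level[mid]) == pytest.approx(94.0, abs=0.1)
        assert np.median(fr.f0[mid]) == pytest.approx(1000.0, rel=0.01)

    def test_wiener_entropy_limits(self):
        rng = np.random.default_rng(0)
        noise = AudioRecording(rng.normal(0, 0.1, int(FS * 0.25)), FS)
        tone_t = np.arange(int(FS * 0.25)) / FS
        tone = AudioRecording(np.sin(2 * np.pi * 1000 * tone_t), FS)
        wn = compute_frame_features(noise).wiener_entropy
        wt = compute_frame_features(tone).wiener_entropy
        mid = slice(100, len(wn) - 100)
        assert np.median(wn[mid]) > -3.0
        assert np.median(wt[mid]) < -20.0

    def test_harmonic_stack_f0_and_aperiodicity(self):
        cfg = SongConfig(syllables=(SyllableSpec(100.0, 0.0, 720.0, None, 70.0, 8),))
        audio, _ = generate_song_audio(cfg)
        fr = compute_frame_features(audio)
        steady = (fr.frame_times > 0.065) & (fr.frame_times < 0.135)
        assert np.nanmedian(fr.f0[steady]) == pytest.approx(720.0, rel=0.01)
        assert np.nanmedian(fr.aperiodicity[steady]) < 0.2

    @pytest.mark.parametrize("seed", range(10))
    def test_yin_recovers_random_stack_f0(self, seed):
        rng = np.random.default_rng(seed)
        f0 = float(rng.uniform(500, 4000))
        n_harm = int(rng.integers(6, 11))
        cfg = SongConfig(syllables=(SyllableSpec(80.0, 0.0, f0, None, 70.0, n_harm),))
        audio, _ = generate_song_audio(cfg, seed=seed)
        fr = compute_frame_features(audio)
        steady = (fr.frame_times > 0.065) & (fr.frame_times < 0.115)
        assert np.nanmedian(fr.f0[steady]) == pytest.approx(f0, rel=0.01)

    def test_silent_frames_report_missing(self):
        audio = AudioRecording(np.zeros(int(FS * 0.05)), FS)
        fr = compute_frame_features(audio)
        assert np.all(np.isneginf(fr.source_level))
        assert np.all(np.isnan(fr.f0))

    def test_zero_phase_filter_keeps_impulse_position(self):
        x = np.zeros(4096)
        x[2048] = 1.0
        y = bandpass(x, FS, (200.0, 12000.0))
        assert int(np.argmax(np.abs(y))) == 2048


@pytest.fixture(scope="module")
def motif():
    audio, truth = generate_song_audio(seed=0)
    return audio, truth


class TestMotifDetection:
    def test_single_insert_found_at_onset(self, motif):
        audio, _ = motif
        x = embed_motifs(audio.samples, [3.0], 6.0, FS)
        dets = detect_and_align_motifs(AudioRecording(x, FS),
                                       AudioRecording(audio.samples, FS))
        assert len(dets) == 1
        assert dets[0].onset_s == pytest.approx(3.0, abs=0.5e-3)

    def test_jittered_inserts_recovered_with_submillisecond_alignment(self, motif):
        audio, _ = motif
        rng = np.random.default_rng(1)
        onsets = np.arange(12) * 1.0 + 0.5 + rng.uniform(-0.01, 0.01, 12)
        x = embed_motifs(audio.samples, onsets, 13.0, FS,
                        noise_rms_pa=2e-4, seed=2)
        dets = detect_and_align_motifs(AudioRecording(x, FS),
                                       AudioRecording(audio.samples, FS),
                                       sl_threshold_db=50.0)
        assert len(dets) == len(onsets)
        resid = np.array([d.onset_s for d in dets]) - onsets
        assert np.std(resid - resid.mean()) < 1e-3

    def test_white_noise_yields_no_detections(self, motif):
        audio, _ = motif
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.05, int(FS * 4))
        dets = detect_and_align_motifs(AudioRecording(x, FS),
                                       AudioRecording(audio.samples, FS),
                                       corr_threshold=0.5)
        assert dets == []

    def test_uncommon_syntax_dropped(self, motif):
        audio, _ = motif
        short_cfg = SongConfig(syllables=(SyllableSpec(80.0, 0.0, 720.0),))
        oddball, _ = generate_song_audio(short_cfg)
        x = embed_motifs(audio.samples, [0.5, 1.5, 2.5], 4.5, FS)
        pad = np.zeros(len(audio.samples) - len(oddball.samples))
        odd_padded = np.concatenate([oddball.samples, pad])
        x = embed_motifs(odd_padded, [3.5], 4.5, FS) + x
        dets = detect_and_align_motifs(AudioRecording(x, FS),
                                       AudioRecording(audio.samples, FS),
                                       corr_threshold=0.4,
                                       sl_threshold_db=50.0)
        keys = {d.syntax_key for d in dets}
        assert len(keys) == 1
        assert all(d.syntax_key[0] == 3 for d in dets)


class TestSyllableSegmentation:
    def test_two_syllables_and_motif_duration(self):
        sound = np.zeros(600, bool)
        sound[40:200] = True   # 80 ms
        sound[300:500] = True  # 100 ms, after a 50 ms gap
        fr = frames_from_binary(sound)
        table, duration = segment_syllables(fr, sl_threshold_db=40.0)
        assert len(table) == 2
        assert list(table["duration_ms"]) == [80.0, 100.0]
        assert duration == pytest.approx(0.230)

    def test_blip_dropped_and_short_gap_merged(self):
        sound = np.zeros(800, bool)
        sound[40:80] = True    # 20 ms blip, dropped
        sound[280:400] = True  # 60 ms
        sound[460:600] = True  # 70 ms after a 30 ms gap: merged
        fr = frames_from_binary(sound)
        table, _ = segment_syllables(fr, sl_threshold_db=40.0)
        assert len(table) == 1
        assert table.loc[0, "duration_ms"] == pytest.approx(160.0)

    @pytest.mark.parametrize("block", range(5))
    def test_rules_match_brute_force_on_random_envelopes(self, block):
        rng = np.random.default_rng(100 + block)
        for _ in range(100):
            n = int(rng.integers(50, 400))
            # random run structure with durations straddling the rules
            sound = rng.random(n) < rng.uniform(0.3, 0.7)
            got = apply_duration_rules(sound, hop_ms=0.5)
            want = brute_force_rules(sound, hop_ms=0.5)
            assert np.array_equal(got, want)

    def test_rules_idempotent(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            sound = rng.random(300) < 0.5
            once = apply_duration_rules(sound)
            twice = apply_duration_rules(once)
            assert np.array_equal(once, twice)

    def test_silent_motif_flagged_empty(self):
        fr = frames_from_binary(np.zeros(200, bool))
        table, duration = segment_syllables(fr, sl_threshold_db=40.0)
        assert len(table) == 0 and duration == 0.0

    def test_motif_duration_equals_syllables_plus_gaps(self):
        sound = np.zeros(1000, bool)
        sound[100:250] = sound[350:500] = sound[600:780] = True
        fr = frames_from_binary(sound)
        table, duration = segment_syllables(fr, sl_threshold_db=40.0)
        total = table["duration_ms"].sum() + table["gap_after_ms"][:-1].sum()
        assert duration * 1e3 == pytest.approx(total)


class TestF0Stats:
    def test_constant_trace(self):
        fr = frames_from_f0(np.full(100, 500.0))
        syl = pd.DataFrame([{"index": 0, "onset_s": 0.0, "offset_s": 0.05,
                             "duration_ms": 50.0, "gap_after_ms": np.nan}])
        out = syllable_f0_stats(fr, syl)
        assert out.loc[0, "f0_mean"] == pytest.approx(500.0)
        assert out.loc[0, "f0_range"] == 0.0
        assert bool(out.loc[0, "robust_pitch"])

    def test_jump_splits_and_short_segments_drop(self):
        # 500, 510, 700, 710: split at the 190 Hz jump; both pieces
        # are 1 ms < 5 ms, so no robust pitch remains
        fr = frames_from_f0([500.0, 510.0, 700.0, 710.0])
        syl = pd.DataFrame([{"index": 0, "onset_s": 0.0, "offset_s": 0.002,
                             "duration_ms": 2.0, "gap_after_ms": np.nan}])
        out = syllable_f0_stats(fr, syl)
        assert not bool(out.loc[0, "robust_pitch"])
        assert np.isnan(out.loc[0, "f0_mean"])

    def test_linear_sweep_statistics(self):
        # 600 -> 900 Hz over 60 ms on the 0.5 ms grid
        f0 = np.linspace(600.0, 900.0, 120)
        fr = frames_from_f0(f0)
        syl = pd.DataFrame([{"index": 0, "onset_s": 0.0, "offset_s": 0.06,
                             "duration_ms": 60.0, "gap_after_ms": np.nan}])
        out = syllable_f0_stats(fr, syl)
        assert out.loc[0, "f0_mean"] == pytest.approx(750.0, rel=0.02)
        assert out.loc[0, "f0_range"] == pytest.approx(300.0, rel=0.02)

    def test_cleaning_never_adds_frames(self):
        rng = np.random.default_rng(5)
        f0 = np.where(rng.random(200) < 0.3, np.nan,
                      rng.uniform(400, 2000, 200))
        fr = frames_from_f0(f0)
        syl = pd.DataFrame([{"index": 0, "onset_s": 0.0, "offset_s": 0.1,
                             "duration_ms": 100.0, "gap_after_ms": np.nan}])
        out = syllable_f0_stats(fr, syl)
        if bool(out.loc[0, "robust_pitch"]):
            valid = f0[np.isfinite(f0)]
            assert out.loc[0, "f0_min"] >= valid.min() - 1e-9
            assert out.loc[0, "f0_max"] <= valid.max() + 1e-9


def _syllable_table(rng, n_motifs, n_syll, f0_shift=0.0):
    rows = []
    for s in range(n_syll):
        mu = 600.0 + 100.0 * s
        for _ in range(n_motifs):
            f0 = rng.normal(mu + f0_shift, 20.0)
            rows.append({"syllable": s, "f0_mean": f0,
                         "f0_range": rng.normal(100.0, 10.0),
                         "wiener_entropy_mean": rng.normal(-30.0, 3.0)})
    return pd.DataFrame(rows)


class TestComparePrePost:
    def test_shift_detected_as_increase(self):
        rng = np.random.default_rng(6)
        pre = _syllable_table(rng, 100, 3)
        post = _syllable_table(rng, 100, 3, f0_shift=50.0)
        rep = compare_syllable_tables(pre, post, features=("f0_mean",))
        # a 50 Hz shift at sigma = 20, n = 100 has essentially unit power
        assert (rep["category"] == "increase").all()

    def test_categories_are_closed_set(self):
        rng = np.random.default_rng(7)
        pre = _syllable_table(rng, 30, 4)
        post = _syllable_table(rng, 30, 4, f0_shift=10.0)
        rep = compare_syllable_tables(pre, post)
        assert set(rep["category"]) <= {"increase", "decrease", "ns"}

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        pre = _syllable_table(rng, 30, 200)
        post = _syllable_table(rng, 30, 200)
        rep = compare_syllable_tables(pre, post, features=("f0_mean",))
        frac = (rep["category"] != "ns").mean()
        assert frac == pytest.approx(0.05, abs=0.04)

    def test_few_motifs_excluded_with_warning(self):
        rng = np.random.default_rng(9)
        pre = _syllable_table(rng, 1, 1)
        post = _syllable_table(rng, 10, 1)
        with pytest.warns(UserWarning, match="fewer than"):
            rep = compare_syllable_tables(pre, post, features=("f0_mean",))
        assert len(rep) == 0

    def test_full_report_with_motif_tables(self):
        rng = np.random.default_rng(10)
        pre_m = pd.DataFrame({
            "animal": np.repeat(np.arange(5), 10),
            "motif_duration_s": rng.normal(0.69, 0.02, 50),
            "motif_source_level_db": rng.normal(51.7, 0.5, 50)})
        post_m = pd.DataFrame({
            "animal": np.repeat(np.arange(5), 10),
            "motif_duration_s": rng.normal(0.67, 0.02, 50),
            "motif_source_level_db": rng.normal(50.1, 0.5, 50)})
        rep = compare_pre_post(_syllable_table(rng, 20, 2),
                               _syllable_table(rng, 20, 2, f0_shift=40.0),
                               pre_m, post_m)
        assert {"syllable_tests", "category_fractions", "motif_tests"} <= set(rep)
        assert len(rep["motif_tests"]) == 2
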