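"""Song acoustics: framing, Yin f0 tracking, motif detection, syllable
segmentation and pre/post comparison.

Calibrated sound-pressure recordings are bandpass filtered (200-12,000 Hz,
2nd-order Butterworth, zero-phase) and framed into 4 ms windows advanced
in 0.5 ms steps. Per frame the pipeline computes power, source level
(dB rms re 20 µPa at 1 m, via the 1 Pa / 1 kHz calibration-tone chain),
Wiener entropy (spectral flatness in dB) and fundamental frequency by the
Yin algorithm (difference function, cumulative-mean-normalized difference,
absolute threshold, parabolic interpolation); "aperiodicity" is the
normalized-difference minimum at the chosen lag (0 = perfectly periodic).

Motifs are found by cross-correlating amplitude envelopes against a
template, refined by aligning source-level traces, and reduced to the
most common syllable syntax. Syllables are segmented by a fixed per-bird
source-level threshold with the 30 ms / 40 ms minimum sound / silence
duration rules, and per-syllable f0 statistics are computed after
removing spurious detections (adjacent-bin jumps > 100 Hz, trajectories
shorter than 5 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile
from scipy import stats

P_REF = 20e-6  # Pa, reference pressure for dB SPL

__all__ = [
    "AudioRecording",
    "FrameParams",
    "AcousticFrameSeries",
    "MotifInstance",
    "compute_frame_features",
    "detect_and_align_motifs",
    "apply_duration_rules",
    "segment_syllables",
    "syllable_f0_stats",
    "compare_syllable_tables",
    "compare_motif_tables",
    "compare_pre_post",
    "splice_motif_into_bout",
]


@dataclass
class AudioRecording:
    """Calibrated audio: ``samples`` in pascal after applying the
    calibration constant (Pa per digital unit)."""

    samples: np.ndarray
    sample_rate: float = 44100.0
    calibration: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 2 * 12000:
            raise ValueError("sample rate must exceed 24 kHz (2 x 12 kHz band)")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")

    @classmethod
    def from_wav(cls, path: str | Path, calibration: float) -> "AudioRecording":
        """Load a 16-bit PCM WAV and convert to pascal."""
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if data.dtype == np.int16:
            x = data.astype(float) / 32768.0
        elif data.dtype == np.int32:
            x = data.astype(float) / 2147483648.0
        else:
            x = data.astype(float)
        return cls(x * calibration, float(rate), calibration)

    def to_wav(self, path: str | Path) -> None:
        x = self.samples / self.calibration
        wavfile.write(path, int(self.sample_rate),
                      np.clip(x * 32768.0, -32768, 32767).astype(np.int16))

    def slice(self, start_s: float, stop_s: float) -> "AudioRecording":
        i0 = int(round(start_s * self.sample_rate))
        i1 = int(round(stop_s * self.sample_rate))
        return AudioRecording(self.samples[i0:i1], self.sample_rate, self.calibration)


@dataclass
class FrameParams:
    window_ms: float = 4.0
    hop_ms: float = 0.5
    band_hz: tuple[float, float] = (200.0, 12000.0)
    yin_fmin: float = 300.0
    yin_fmax: float = 8000.0
    yin_threshold: float = 0.15
    n_fft: int = 512
    spectrum_floor: float = 1e-12
    silence_power: float = 1e-16  # Pa^2 below which a frame counts as silent


@dataclass
class AcousticFrameSeries:
    """Per-frame acoustic features on the 0.5 ms hop grid.

    ``frame_times`` are frame start times in seconds; ``f0`` is NaN
    where no pitch was assigned (silent frames).
    """

    frame_times: np.ndarray
    power: np.ndarray
    source_level: np.ndarray
    wiener_entropy: np.ndarray
    f0: np.ndarray
    aperiodicity: np.ndarray
    hop_s: float
    window_s: float

    def __len__(self) -> int:
        return len(self.frame_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.frame_times, "power": self.power,
            "source_level_db": self.source_level,
            "wiener_entropy_db": self.wiener_entropy,
            "f0_hz": self.f0, "aperiodicity": self.aperiodicity,
        })


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """2nd-order Butterworth bandpass with zero-phase (forward-backward)
    application, so transients keep their timing."""
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _frame_starts(n: int, fs: float, params: FrameParams) -> np.ndarray:
    win = int(round(params.window_ms * 1e-3 * fs))
    n_frames = max(0, int(np.floor((n - win) / (params.hop_ms * 1e-3 * fs))) + 1)
    t = np.arange(n_frames) * params.hop_ms * 1e-3
    return np.round(t * fs).astype(int)


def _yin_track(
    x: np.ndarray, fs: float, centers: np.ndarray, params: FrameParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Yin over frames centred at sample indices `centers`.

    The integration window is extended beyond the nominal 4 ms bin to
    twice the longest candidate period, which the lowest f0 in the
    search range requires.
    """
    tau_min = max(2, int(np.floor(fs / params.yin_fmax)))
    tau_max = int(np.ceil(fs / params.yin_fmin))
    w = 2 * tau_max                       # integration window
    length = w + tau_max                  # samples needed per frame
    pad = length
    xp = np.pad(x, pad)
    starts = centers + pad - length // 2
    frames = xp[starts[:, None] + np.arange(length)[None, :]]

    # d_t(tau) = sum_j (x_j - x_{j+tau})^2 over the integration window
    sq = np.concatenate(
        [np.zeros((len(frames), 1)), np.cumsum(frames**2, axis=1)], axis=1
    )
    e0 = sq[:, w] - sq[:, 0]
    taus = np.arange(tau_max + 1)
    e_tau = sq[:, taus + w] - sq[:, taus]
    nfft = int(2 ** np.ceil(np.log2(2 * length)))
    spec_full = np.fft.rfft(frames, nfft, axis=1)
    spec_win = np.fft.rfft(frames[:, :w], nfft, axis=1)
    r = np.fft.irfft(spec_full * np.conj(spec_win), nfft, axis=1)[:, : tau_max + 1]
    d = np.maximum(e0[:, None] + e_tau - 2.0 * r, 0.0)

    # cumulative-mean-normalized difference
    with np.errstate(divide="ignore", invalid="ignore"):
        csum = np.cumsum(d[:, 1:], axis=1)
        dprime = d[:, 1:] * np.arange(1, tau_max + 1) / np.where(csum > 0, csum, np.inf)
    dprime = np.concatenate([np.ones((len(frames), 1)), dprime], axis=1)

    f0 = np.full(len(frames), np.nan)
    aper = np.full(len(frames), np.nan)
    for i in range(len(frames)):
        dp = dprime[i]
        below = np.flatnonzero(dp[tau_min : tau_max + 1] < params.yin_threshold)
        if below.size:
            tau = tau_min + int(below[0])
            while tau + 1 <= tau_max and dp[tau + 1] < dp[tau]:
                tau += 1
        else:
            tau = tau_min + int(np.argmin(dp[tau_min : tau_max + 1]))
        # parabolic interpolation of the minimum
        if tau_min < tau < tau_max:
            a, b, c = dp[tau - 1], dp[tau], dp[tau + 1]
            denom = a - 2 * b + c
            shift = 0.5 * (a - c) / denom if denom > 0 else 0.0
            shift = float(np.clip(shift, -1, 1))
        else:
            shift = 0.0
        f0[i] = fs / (tau + shift)
        aper[i] = float(np.clip(dp[tau], 0.0, 1.0))
    return f0, aper


def compute_frame_features(
    audio: AudioRecording, params: FrameParams | None = None
) -> AcousticFrameSeries:
    """Bandpass filter once, then compute per-frame acoustic features.

    Silent frames (power below ``params.silence_power``) report
    ``source_level = -inf`` and missing f0/aperiodicity.
    """
    params = params or FrameParams()
    fs = audio.sample_rate
    x = bandpass(audio.samples, fs, params.band_hz)
    win = int(round(params.window_ms * 1e-3 * fs))
    starts = _frame_starts(len(x), fs, params)
    if starts.size == 0:
        z = np.array([])
        return AcousticFrameSeries(z, z, z, z, z, z,
                                   params.hop_ms * 1e-3, params.window_ms * 1e-3)
    frames = x[starts[:, None] + np.arange(win)[None, :]]
    power = np.mean(frames**2, axis=1)
    silent = power <= params.silence_power
    with np.errstate(divide="ignore"):
        sl = 10.0 * np.log10(np.where(silent, 0.0, power) / P_REF**2)

    window = np.hanning(win)
    spec = np.abs(np.fft.rfft(frames * window, params.n_fft, axis=1)) ** 2
    spec = np.maximum(spec, params.spectrum_floor)
    # flatness over the analysis band only; outside it the bandpass
    # filter would dominate the geometric mean
    freqs = np.fft.rfftfreq(params.n_fft, 1.0 / fs)
    in_band = (freqs >= params.band_hz[0]) & (freqs <= params.band_hz[1])
    spec = spec[:, in_band]
    wiener = 10.0 * (np.mean(np.log10(spec), axis=1) - np.log10(np.mean(spec, axis=1)))

    f0, aper = _yin_track(x, fs, starts + win // 2, params)
    f0[silent] = np.nan
    aper[silent] = np.nan

    times = starts / fs
    return AcousticFrameSeries(times, power, sl, wiener, f0, aper,
                               params.hop_ms * 1e-3, params.window_ms * 1e-3)


# ---------------------------------------------------------------------------
# motif detection and alignment

@dataclass
class MotifInstance:
    onset_s: float
    samples: np.ndarray
    frames: AcousticFrameSeries
    syllables: pd.DataFrame | None
    syntax_key: tuple
    motif_duration_s: float
    motif_source_level_db: float
    aligned_offset_frames: int = 0


def _envelope(x: np.ndarray, fs: float, hop_s: float, win_s: float) -> np.ndarray:
    win = int(round(win_s * fs))
    starts = np.round(np.arange(0, max(len(x) - win, 0) + 1, hop_s * fs)).astype(int)
    if starts.size == 0:
        return np.array([])
    fr = x[starts[:, None] + np.arange(win)[None, :]]
    return np.sqrt(np.mean(fr**2, axis=1))


def _pearson_xcorr(long: np.ndarray, short: np.ndarray) -> np.ndarray:
    """Pearson correlation of `short` against every aligned window of
    `long` (valid lags only)."""
    n = len(short)
    s = short - short.mean()
    s_norm = np.sqrt(np.sum(s**2))
    csum = np.concatenate([[0.0], np.cumsum(long)])
    csum2 = np.concatenate([[0.0], np.cumsum(long**2)])
    dots = np.correlate(long, s, mode="valid")
    win_sum = csum[n:] - csum[:-n]
    win_sq = csum2[n:] - csum2[:-n]
    var = win_sq - win_sum**2 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = dots / (np.sqrt(np.maximum(var, 0.0)) * s_norm)
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def detect_and_align_motifs(
    audio: AudioRecording,
    template: AudioRecording,
    params: FrameParams | None = None,
    corr_threshold: float = 0.5,
    sl_threshold_db: float | None = None,
    max_align_shift_ms: float = 10.0,
    keep_most_common_syntax: bool = True,
    duration_quantum_ms: float = 20.0,
) -> list[MotifInstance]:
    """Detect motif instances by envelope cross-correlation and refine
    their alignment on the source-level trace.

    Candidate onsets are Pearson-correlation peaks of the amplitude
    envelope against the template envelope, above ``corr_threshold``,
    with non-overlap suppression over one template length. Each
    candidate is then shifted (within ``max_align_shift_ms``) to the lag
    maximizing correlation of its source-level trace with the session
    reference (the first detection). If ``sl_threshold_db`` is given,
    syllables are segmented per motif and, when
    ``keep_most_common_syntax``, motifs whose (syllable count,
    quantized-duration) signature differs from the modal one are
    dropped.
    """
    params = params or FrameParams()
    fs = audio.sample_rate
    if len(template.samples) > len(audio.samples):
        raise ValueError("template must not be longer than the recording")
    hop_s = params.hop_ms * 1e-3
    win_s = params.window_ms * 1e-3
    env_a = _envelope(bandpass(audio.samples, fs, params.band_hz), fs, hop_s, win_s)
    env_t = _envelope(bandpass(template.samples, fs, params.band_hz), fs, hop_s, win_s)
    if env_t.size < 2 or env_a.size < env_t.size:
        return []
    r = _pearson_xcorr(env_a, env_t)
    order = np.argsort(r)[::-1]
    n_t = len(env_t)
    taken = np.zeros(len(r), dtype=bool)
    onsets_frames: list[int] = []
    for idx in order:
        if r[idx] < corr_threshold:
            break
        if taken[idx]:
            continue
        onsets_frames.append(int(idx))
        lo = max(0, idx - n_t + 1)
        taken[lo : idx + n_t] = True
    onsets_frames.sort()

    tmpl_len = len(template.samples)
    motifs: list[MotifInstance] = []
    ref_sl: np.ndarray | None = None
    max_shift = int(round(max_align_shift_ms * 1e-3 / hop_s))
    for fr_idx in onsets_frames:
        onset = fr_idx * hop_s
        i0 = int(round(onset * fs))
        seg = audio.samples[i0 : i0 + tmpl_len]
        if len(seg) < tmpl_len:
            continue
        frames = compute_frame_features(
            AudioRecording(seg, fs, audio.calibration), params
        )
        shift = 0
        if ref_sl is None:
            ref_sl = np.where(np.isfinite(frames.source_level), frames.source_level, -120.0)
        else:
            sl = np.where(np.isfinite(frames.source_level), frames.source_level, -120.0)
            best = -np.inf
            for s in range(-max_shift, max_shift + 1):
                a = ref_sl[max(0, -s): len(sl) - max(0, s)]
                b = sl[max(0, s): len(sl) - max(0, -s)]
                if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
                    continue
                c = np.corrcoef(a, b)[0, 1]
                if c > best:
                    best, shift = c, s
            if shift:
                i0 = i0 + int(round(shift * hop_s * fs))
                i0 = max(0, min(i0, len(audio.samples) - tmpl_len))
                seg = audio.samples[i0 : i0 + tmpl_len]
                frames = compute_frame_features(
                    AudioRecording(seg, fs, audio.calibration), params
                )
        syllables = None
        syntax_key: tuple = ()
        duration = len(seg) / fs
        if sl_threshold_db is not None:
            syllables, duration = segment_syllables(frames, sl_threshold_db)
            syntax_key = (
                len(syllables),
                tuple(np.round(syllables["duration_ms"] / duration_quantum_ms)
                      .astype(int).tolist()),
            )
        sound = np.isfinite(frames.source_level)
        if sound.any():
            p = frames.power[sound]
            msl = 10.0 * np.log10(np.sum(p * p) / np.sum(p) / P_REF**2)
        else:
            msl = -np.inf
        motifs.append(MotifInstance(
            onset_s=i0 / fs, samples=seg, frames=frames, syllables=syllables,
            syntax_key=syntax_key, motif_duration_s=duration,
            motif_source_level_db=msl, aligned_offset_frames=shift,
        ))

    if keep_most_common_syntax and sl_threshold_db is not None and motifs:
        keys = pd.Series([m.syntax_key for m in motifs])
        modal = keys.mode().iloc[0]
        motifs = [m for m in motifs if m.syntax_key == modal]
    return motifs


# ---------------------------------------------------------------------------
# syllable segmentation

def apply_duration_rules(
    sound: np.ndarray,
    hop_ms: float = 0.5,
    min_sound_ms: float = 30.0,
    min_silence_ms: float = 40.0,
) -> np.ndarray:
    """Apply the minimum-duration rules to a binary sound mask.

    Sound runs shorter than ``min_sound_ms`` are removed first; then
    interior silence runs shorter than ``min_silence_ms`` are removed,
    merging their flanking sounds. Leading/trailing silence is never
    touched (it has no flanking sound on both sides).
    """
    out = np.asarray(sound, dtype=bool).copy()
    min_sound = int(np.ceil(min_sound_ms / hop_ms))
    min_sil = int(np.ceil(min_silence_ms / hop_ms))

    def runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
        if mask.size == 0:
            return []
        change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [mask.size]])
        return [(int(bounds[i]), int(bounds[i + 1]), bool(mask[bounds[i]]))
                for i in range(len(bounds) - 1)]

    for i0, i1, val in runs(out):
        if val and (i1 - i0) < min_sound:
            out[i0:i1] = False
    r = runs(out)
    for k, (i0, i1, val) in enumerate(r):
        if not val and 0 < k < len(r) - 1 and (i1 - i0) < min_sil:
            out[i0:i1] = True
    return out


def segment_syllables(
    frames: AcousticFrameSeries,
    sl_threshold_db: float,
    min_sound_ms: float = 30.0,
    min_silence_ms: float = 40.0,
) -> tuple[pd.DataFrame, float]:
    """Segment a motif's frames into syllables by source-level threshold.

    Returns the syllable table (onset/offset/duration/gap_after, all
    on the 0.5 ms frame grid) and the motif duration — the summed
    duration of all syllables and gaps, i.e. last offset minus first
    onset. An empty table with duration 0 flags a motif without sound.
    """
    hop_ms = frames.hop_s * 1e3
    sound = np.isfinite(frames.source_level) & (frames.source_level > sl_threshold_db)
    sound = apply_duration_rules(sound, hop_ms, min_sound_ms, min_silence_ms)
    idx = np.flatnonzero(sound)
    if idx.size == 0:
        return pd.DataFrame(columns=[
            "index", "onset_s", "offset_s", "duration_ms", "gap_after_ms"
        ]), 0.0
    # run starts/ends of the sound mask
    d = np.diff(np.concatenate([[0], sound.astype(np.int8), [0]]))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive
    t0 = frames.frame_times[0]
    rows = []
    for i, (a, b) in enumerate(zip(run_starts, run_ends)):
        onset = t0 + a * frames.hop_s
        offset = t0 + b * frames.hop_s
        gap = (run_starts[i + 1] - b) * frames.hop_s * 1e3 \
            if i + 1 < len(run_starts) else np.nan
        rows.append({"index": i, "onset_s": onset, "offset_s": offset,
                     "duration_ms": (b - a) * hop_ms, "gap_after_ms": gap})
    table = pd.DataFrame(rows)
    motif_duration = float((run_ends[-1] - run_starts[0]) * frames.hop_s)
    return table, motif_duration


def syllable_f0_stats(
    frames: AcousticFrameSeries,
    syllables: pd.DataFrame,
    max_jump_hz: float = 100.0,
    min_track_ms: float = 5.0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Clean per-syllable f0 traces and compute their statistics.

    Within each syllable the f0 trace is split wherever adjacent frames
    jump by more than ``max_jump_hz`` (or where f0 is missing); segments
    shorter than ``min_track_ms`` are discarded as spurious. If the
    surviving frames cover less than ``min_coverage`` of the syllable,
    pitch detection is marked non-robust and the statistics are NaN;
    otherwise mean/min/max/range are taken over surviving frames only.
    Wiener entropy is averaged over all syllable frames.
    """
    hop_ms = frames.hop_s * 1e3
    min_len = int(np.ceil(min_track_ms / hop_ms))
    out = syllables.copy()
    stats_cols = ["f0_mean", "f0_min", "f0_max", "f0_range",
                  "wiener_entropy_mean", "robust_pitch"]
    results = []
    t = frames.frame_times
    for _, row in syllables.iterrows():
        sel = (t >= row["onset_s"] - 1e-12) & (t < row["offset_s"] - 1e-12)
        f0 = frames.f0[sel]
        we = float(np.nanmean(frames.wiener_entropy[sel])) if sel.any() else np.nan
        keep = np.zeros(len(f0), dtype=bool)
        valid = np.isfinite(f0)
        i = 0
        while i < len(f0):
            if not valid[i]:
                i += 1
                continue
            j = i
            while (j + 1 < len(f0) and valid[j + 1]
                   and abs(f0[j + 1] - f0[j]) <= max_jump_hz):
                j += 1
            if (j - i + 1) >= min_len:
                keep[i : j + 1] = True
            i = j + 1
        coverage = keep.sum() / len(f0) if len(f0) else 0.0
        robust = coverage >= min_coverage
        if robust and keep.any():
            surv = f0[keep]
            results.append([float(np.mean(surv)), float(np.min(surv)),
                            float(np.max(surv)),
                            float(np.max(surv) - np.min(surv)), we, True])
        else:
            results.append([np.nan, np.nan, np.nan, np.nan, we, False])
    out[stats_cols] = pd.DataFrame(results, index=out.index, columns=stats_cols)
    return out


# ---------------------------------------------------------------------------
# pre/post comparison

def compare_syllable_tables(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    features: tuple[str, ...] = ("f0_mean", "f0_range", "wiener_entropy_mean"),
    alpha: float = 0.05,
    min_motifs: int = 2,
) -> pd.DataFrame:
    """Unpaired two-sided t-tests per syllable and feature.

    Both tables need columns ``syllable`` (index within the motif) and
    the feature columns, one row per motif iteration. Each test yields a
    category: "increase" / "decrease" when p < alpha (by sign of the
    post-pre difference), else "ns". Syllables with fewer than
    ``min_motifs`` iterations in either condition are excluded with a
    warning.
    """
    rows = []
    for syll in sorted(set(pre["syllable"]) & set(post["syllable"])):
        a_all = pre[pre["syllable"] == syll]
        b_all = post[post["syllable"] == syll]
        for feat in features:
            a = a_all[feat].dropna().to_numpy(float)
            b = b_all[feat].dropna().to_numpy(float)
            if len(a) < min_motifs or len(b) < min_motifs:
                warnings.warn(f"syllable {syll}/{feat}: fewer than "
                              f"{min_motifs} motifs, excluded")
                continue
            t, p = stats.ttest_ind(b, a)
            if p < alpha:
                cat = "increase" if b.mean() > a.mean() else "decrease"
            else:
                cat = "ns"
            rows.append({"syllable": syll, "feature": feat,
                         "t": float(t), "p": float(p),
                         "delta": float(b.mean() - a.mean()), "category": cat})
    return pd.DataFrame(rows)


def compare_motif_tables(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Paired two-sided t-tests on per-animal mean motif duration and
    source level. Tables need columns ``animal``, ``motif_duration_s``,
    ``motif_source_level_db``."""
    mpre = pre.groupby("animal")[["motif_duration_s", "motif_source_level_db"]].mean()
    mpost = post.groupby("animal")[["motif_duration_s", "motif_source_level_db"]].mean()
    common = mpre.index.intersection(mpost.index)
    rows = []
    for col in ("motif_duration_s", "motif_source_level_db"):
        a = mpre.loc[common, col].to_numpy(float)
        b = mpost.loc[common, col].to_numpy(float)
        t, p = stats.ttest_rel(b, a)
        rows.append({"feature": col, "n_animals": len(common),
                     "mean_pre": float(a.mean()), "mean_post": float(b.mean()),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def compare_pre_post(
    pre_syllables: pd.DataFrame,
    post_syllables: pd.DataFrame,
    pre_motifs: pd.DataFrame | None = None,
    post_motifs: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Full pre/post report: per-syllable feature tests, category
    fractions, and (when motif tables with an ``animal`` column are
    given) per-animal paired motif tests."""
    syll = compare_syllable_tables(pre_syllables, post_syllables, alpha=alpha)
    fractions = (
        syll.groupby("feature")["category"]
        .value_counts(normalize=True).unstack(fill_value=0.0)
        if len(syll) else pd.DataFrame()
    )
    report = {"syllable_tests": syll, "category_fractions": fractions}
    if pre_motifs is not None and post_motifs is not None:
        report["motif_tests"] = compare_motif_tables(pre_motifs, post_motifs)
    return report


def splice_motif_into_bout(
    bout: np.ndarray,
    new_motif: np.ndarray,
    onset_s: float,
    old_duration_s: float,
    sample_rate: float,
    fade_ms: float = 5.0,
) -> np.ndarray:
    """Replace a motif inside a song bout with another, using cosine
    cross-fades at the splice points to avoid clicks."""
    i0 = int(round(onset_s * sample_rate))
    i1 = int(round((onset_s + old_duration_s) * sample_rate))
    nf = int(round(fade_ms * 1e-3 * sample_rate))
    head, tail = bout[:i0], bout[i1:]
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nf) / max(nf, 1)))
    m = new_motif.copy().astype(float)
    if nf and len(m) >= 2 * nf:
        m[:nf] *= ramp
        m[-nf:] *= ramp[::-1]
    return np.concatenate([head, m, tail])
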