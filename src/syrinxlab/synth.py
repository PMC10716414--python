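"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator emulates the statistical and geometric structure the
corresponding analysis stage consumes — not photorealistic histology or
naturalistic birdsong timbre — and returns the truth needed to score the
stage: twitch transients of exactly known FWHM, tessellated sections
with a ground-truth label map and fibre types, harmonic-stack motifs
with known onsets/f0/source levels, paired peptide tables with known
fold changes, and Bernoulli keypeck streams with nightly side switches.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed reproduces outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .morphometry import SectionImage
from .muscle import ForceTrace
from .preference import KeypeckLog, nightly_assignment
from .song import P_REF, AudioRecording

__all__ = [
    "TwitchConfig",
    "TetanusConfig",
    "SectionConfig",
    "SyllableSpec",
    "SongConfig",
    "ProteomeConfig",
    "PecksConfig",
    "generate_twitch_trace",
    "generate_tetanus_trace",
    "generate_session",
    "generate_section_image",
    "generate_song_audio",
    "embed_motifs",
    "default_protein_panel",
    "generate_peptide_table_pair",
    "generate_keypeck_log",
]


# ---------------------------------------------------------------------------
# force traces

@dataclass
class TwitchConfig:
    """Two-exponential twitch transient tuned to an exact FWHM.

    Defaults follow the intact adult syringeal muscle: 4.89 ms FWHM.
    ``tau_ratio`` is decay/rise time-constant ratio; the transient is
    F(t) = A (exp(-t/tau_d) - exp(-t/tau_r)) after stimulus onset.
    """

    target_fwhm_ms: float = 4.89
    peak_mN: float = 1.0
    tau_ratio: float = 4.0
    sample_rate: float = 40000.0
    duration_s: float = 0.060
    onset_s: float = 0.010
    noise_mN: float = 0.0
    baseline_mN: float = 0.0


@dataclass
class TetanusConfig:
    """Tetanic contraction: exponential rise to a plateau over a 100 ms
    stimulation, then exponential relaxation."""

    plateau_mN: float = 12.0
    stim_duration_s: float = 0.100
    tau_on_s: float = 0.005
    tau_off_s: float = 0.015
    sample_rate: float = 40000.0
    duration_s: float = 0.250
    onset_s: float = 0.020
    noise_mN: float = 0.0
    baseline_mN: float = 0.0


def _two_exp_unit(t: np.ndarray | float, ratio: float) -> np.ndarray | float:
    """exp(-t/ratio) - exp(-t) for t >= 0 (rise constant 1)."""
    return np.exp(-np.asarray(t) / ratio) - np.exp(-np.asarray(t))


def _unit_fwhm(ratio: float) -> float:
    """Exact FWHM of the unit two-exponential (tau_r = 1), found by root
    search on the analytic expression."""
    if ratio <= 1:
        raise ValueError("tau_ratio must exceed 1")
    t_peak = ratio * np.log(ratio) / (ratio - 1)
    peak = float(_two_exp_unit(t_peak, ratio))
    half = peak / 2.0
    t_up = brentq(lambda t: _two_exp_unit(t, ratio) - half, 1e-12, t_peak)
    hi = t_peak
    while _two_exp_unit(hi, ratio) > half:
        hi *= 2.0
    t_dn = brentq(lambda t: _two_exp_unit(t, ratio) - half, t_peak, hi)
    return t_dn - t_up


def generate_twitch_trace(
    cfg: TwitchConfig | None = None, seed: int = 0
) -> tuple[ForceTrace, dict]:
    """Twitch trace whose true (noise-free) FWHM equals the target.

    The FWHM of the two-exponential scales linearly with the rise time
    constant at fixed ratio, so tau_r = target / FWHM(tau_r=1).
    """
    cfg = cfg or TwitchConfig()
    if cfg.target_fwhm_ms <= 0:
        raise ValueError("target FWHM must be positive")
    rng = np.random.default_rng(seed)
    tau_r_ms = cfg.target_fwhm_ms / _unit_fwhm(cfg.tau_ratio)
    t = np.arange(int(round(cfg.duration_s * cfg.sample_rate))) / cfg.sample_rate
    rel = (t - cfg.onset_s) * 1e3 / tau_r_ms
    shape = np.where(rel > 0, _two_exp_unit(np.maximum(rel, 0.0), cfg.tau_ratio), 0.0)
    t_peak = cfg.tau_ratio * np.log(cfg.tau_ratio) / (cfg.tau_ratio - 1)
    amp = cfg.peak_mN / float(_two_exp_unit(t_peak, cfg.tau_ratio))
    force = cfg.baseline_mN + amp * shape
    if cfg.noise_mN > 0:
        force = force + rng.normal(0.0, cfg.noise_mN, size=force.shape)
    trace = ForceTrace(t, force, cfg.sample_rate, "twitch", cfg.onset_s)
    truth = {"fwhm_ms": cfg.target_fwhm_ms, "peak_mN": cfg.peak_mN,
             "tau_rise_ms": tau_r_ms, "tau_decay_ms": tau_r_ms * cfg.tau_ratio,
             "onset_s": cfg.onset_s}
    return trace, truth


def generate_tetanus_trace(
    cfg: TetanusConfig | None = None, seed: int = 0
) -> tuple[ForceTrace, dict]:
    cfg = cfg or TetanusConfig()
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(cfg.duration_s * cfg.sample_rate))) / cfg.sample_rate
    rel = t - cfg.onset_s
    end = cfg.stim_duration_s
    rise = cfg.plateau_mN * (1.0 - np.exp(-np.maximum(rel, 0.0) / cfg.tau_on_s))
    level_end = cfg.plateau_mN * (1.0 - np.exp(-end / cfg.tau_on_s))
    fall = level_end * np.exp(-np.maximum(rel - end, 0.0) / cfg.tau_off_s)
    force = cfg.baseline_mN + np.where(rel <= 0, 0.0, np.where(rel <= end, rise, fall))
    if cfg.noise_mN > 0:
        force = force + rng.normal(0.0, cfg.noise_mN, size=force.shape)
    trace = ForceTrace(t, force, cfg.sample_rate, "tetanus", cfg.onset_s)
    truth = {"max_force_mN": float(level_end), "plateau_mN": cfg.plateau_mN}
    return trace, truth


def generate_session(
    twitch_cfg: TwitchConfig | None = None,
    tetanus_cfg: TetanusConfig | None = None,
    seed: int = 0,
    n_twitch: int = 7,
    n_tetanus: int = 3,
) -> tuple[list[ForceTrace], dict]:
    """One in-vitro recording session: seven twitches and three tetani."""
    traces: list[ForceTrace] = []
    truths = {"twitch": [], "tetanus": []}
    for i in range(n_twitch):
        tr, tru = generate_twitch_trace(twitch_cfg, seed * 1009 + i)
        traces.append(tr)
        truths["twitch"].append(tru)
    for i in range(n_tetanus):
        tr, tru = generate_tetanus_trace(tetanus_cfg, seed * 1013 + i)
        traces.append(tr)
        truths["tetanus"].append(tru)
    return traces, truths


# ---------------------------------------------------------------------------
# section images

@dataclass
class SectionConfig:
    """Tessellated muscle cross-section with two fibre populations.

    Superfast fibres draw areas from 200-1000 µm² and low MY-32
    intensity (N(20, 8²) clipped at 0); fast fibres from 100-400 µm²
    with high intensity (N(120, 30²) clipped at 255), straddling the
    classification cutoff of 50 with realistic separation. Fibres are
    laid out on a jittered grid with bright laminin rings and a
    moderately bright interstitium between fibres.
    """

    n_fibres: int = 300
    superfast_fraction: float = 0.66
    sf_area_um2: tuple[float, float] = (200.0, 1000.0)
    fast_area_um2: tuple[float, float] = (100.0, 400.0)
    sf_intensity: tuple[float, float] = (20.0, 8.0)
    fast_intensity: tuple[float, float] = (120.0, 30.0)
    microns_per_pixel: float = 1.0
    border_px: int = 2
    interior_intensity: float = 12.0
    ring_intensity: float = 190.0
    interstitial_intensity: float = 95.0
    noise_sd: float = 4.0
    max_axis_ratio: float = 1.4
    area_scale: float = 1.0  # multiplies both area ranges (atrophy emulation)
    intensity_shift: float = 0.0  # added to all fibre intensities


def _rasterize_ellipse(a: float, b: float, theta: float) -> np.ndarray:
    """Boolean stamp of an ellipse with semi-axes a, b (pixels) rotated
    by theta, on a tight local grid (pixel-centre rule)."""
    r = int(np.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx * ct + yy * st) / a
    v = (-xx * st + yy * ct) / b
    return u**2 + v**2 <= 1.0


def generate_section_image(
    cfg: SectionConfig | None = None, seed: int = 0
) -> tuple[SectionImage, np.ndarray, pd.DataFrame]:
    """Section image plus ground-truth label map and fibre table.

    Fibre types are Bernoulli draws at the configured superfast
    fraction; each fibre is an ellipse whose rasterized area is
    iteratively rescaled until it lands inside its type's configured
    area range. Returns ``(image, label_map, truth)`` where truth has
    columns ``fibre_id, fibre_type, area_um2, my32_true``.
    """
    cfg = cfg or SectionConfig()
    if not 0.0 <= cfg.superfast_fraction <= 1.0:
        raise ValueError("superfast_fraction must lie in [0, 1]")
    if cfg.n_fibres < 1:
        raise ValueError("need at least one fibre")
    rng = np.random.default_rng(seed)
    mpp = cfg.microns_per_pixel

    sf_range = (cfg.sf_area_um2[0] * cfg.area_scale, cfg.sf_area_um2[1] * cfg.area_scale)
    fa_range = (cfg.fast_area_um2[0] * cfg.area_scale, cfg.fast_area_um2[1] * cfg.area_scale)
    max_area_px = max(sf_range[1], fa_range[1]) / mpp**2
    a_max = np.sqrt(max_area_px * cfg.max_axis_ratio / np.pi)
    cell = int(np.ceil(2 * (a_max + cfg.border_px + 3)))
    ncols = int(np.ceil(np.sqrt(cfg.n_fibres)))
    nrows = int(np.ceil(cfg.n_fibres / ncols))
    h, w = nrows * cell + cell // 2, ncols * cell + cell // 2

    label_map = np.zeros((h, w), dtype=np.int32)
    lam = np.full((h, w), cfg.interstitial_intensity)
    my32 = np.full((h, w), 5.0)

    cells = [(r, c) for r in range(nrows) for c in range(ncols)]
    rng.shuffle(cells)
    is_sf = rng.random(cfg.n_fibres) < cfg.superfast_fraction
    rows = []
    for fid in range(cfg.n_fibres):
        sf = bool(is_sf[fid])
        lo, hi = sf_range if sf else fa_range
        margin = 0.08 * (hi - lo)
        target = rng.uniform(lo + margin, hi - margin)
        ratio = rng.uniform(1.0, cfg.max_axis_ratio)
        theta = rng.uniform(0, np.pi)
        a = np.sqrt(target / mpp**2 * ratio / np.pi)
        b = a / ratio
        stamp = _rasterize_ellipse(a, b, theta)
        for _ in range(6):
            area = stamp.sum() * mpp**2
            if lo <= area <= hi:
                break
            s = np.sqrt(target / max(area, mpp**2))
            a, b = a * s, b * s
            stamp = _rasterize_ellipse(a, b, theta)
        ring = _rasterize_ellipse(a + cfg.border_px, b + cfg.border_px, theta)

        r, c = cells[fid]
        cy = r * cell + cell // 2 + int(rng.integers(-2, 3)) + cell // 4
        cx = c * cell + cell // 2 + int(rng.integers(-2, 3)) + cell // 4
        rr = ring.shape[0] // 2
        y0, x0 = cy - rr, cx - rr
        ys = slice(max(y0, 0), min(y0 + ring.shape[0], h))
        xs = slice(max(x0, 0), min(x0 + ring.shape[1], w))
        sy = slice(ys.start - y0, ys.stop - y0)
        sx = slice(xs.start - x0, xs.stop - x0)
        interior = np.zeros_like(ring)
        off = (ring.shape[0] - stamp.shape[0]) // 2
        interior[off : off + stamp.shape[0], off : off + stamp.shape[1]] = stamp

        ring_only = ring & ~interior
        lam[ys, xs][ring_only[sy, sx]] = cfg.ring_intensity
        lam[ys, xs][interior[sy, sx]] = cfg.interior_intensity
        label_map[ys, xs][interior[sy, sx]] = fid + 1

        mu, sd = cfg.sf_intensity if sf else cfg.fast_intensity
        inten = float(np.clip(rng.normal(mu + cfg.intensity_shift, sd), 0.0, 255.0))
        my32[ys, xs][interior[sy, sx]] = inten
        rows.append({"fibre_id": fid + 1,
                     "fibre_type": "superfast" if sf else "fast",
                     "area_um2": float((label_map == fid + 1).sum() * mpp**2),
                     "my32_true": inten})

    lam = np.clip(lam + rng.normal(0, cfg.noise_sd, lam.shape), 0, 255)
    my32 = np.clip(my32 + rng.normal(0, cfg.noise_sd, my32.shape), 0, 255)
    image = SectionImage(lam, my32, np.ones((h, w), bool), mpp)
    return image, label_map, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# song audio

@dataclass
class SyllableSpec:
    """One harmonic-stack syllable: duration, trailing gap, a constant
    or linearly swept f0 and a target source level."""

    duration_ms: float = 80.0
    gap_after_ms: float = 50.0
    f0_start_hz: float = 720.0
    f0_end_hz: float | None = None  # None = constant f0
    source_level_db: float = 70.0
    n_harmonics: int = 8


@dataclass
class SongConfig:
    """A motif of harmonic-stack syllables rendered at 44.1 kHz.

    Harmonics roll off as 1/k and are truncated below the top of the
    analysis band so the bandpass filter leaves levels untouched. All
    durations are snapped to the 0.5 ms frame grid.
    """

    syllables: tuple[SyllableSpec, ...] = (
        SyllableSpec(80.0, 50.0, 720.0, None, 70.0),
        SyllableSpec(100.0, 50.0, 600.0, 900.0, 68.0),
        SyllableSpec(120.0, 0.0, 1400.0, None, 66.0),
    )
    sample_rate: float = 44100.0
    calibration: float = 1.0
    lead_ms: float = 50.0
    tail_ms: float = 50.0
    ramp_ms: float = 5.0
    harmonic_rolloff: float = 1.0  # amplitude ~ 1/k**rolloff
    band_top_hz: float = 11000.0
    noise_rms_pa: float = 0.0


def _snap(ms: float) -> float:
    return round(ms * 2.0) / 2.0


def generate_song_audio(
    cfg: SongConfig | None = None, seed: int = 0
) -> tuple[AudioRecording, dict]:
    """Render a motif; truth holds onsets, durations, f0 tracks and SL.

    Raises if any syllable's fundamental leaves the analysis band.
    """
    cfg = cfg or SongConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.sample_rate
    pieces: list[np.ndarray] = []
    lead = int(round(_snap(cfg.lead_ms) * 1e-3 * fs))
    pieces.append(np.zeros(lead))
    t_cursor = lead / fs
    onsets, durations, gaps, f0_tracks, levels = [], [], [], [], []
    for spec in cfg.syllables:
        dur_ms = _snap(spec.duration_ms)
        gap_ms = _snap(spec.gap_after_ms)
        n = int(round(dur_ms * 1e-3 * fs))
        t = np.arange(n) / fs
        f0_end = spec.f0_end_hz if spec.f0_end_hz is not None else spec.f0_start_hz
        if not (200.0 < min(spec.f0_start_hz, f0_end)
                and max(spec.f0_start_hz, f0_end) < cfg.band_top_hz):
            raise ValueError("f0 trajectory outside the analysis band")
        f0 = spec.f0_start_hz + (f0_end - spec.f0_start_hz) * t / (n / fs)
        phase = 2 * np.pi * np.cumsum(f0) / fs
        x = np.zeros(n)
        f0_max = max(spec.f0_start_hz, f0_end)
        for k in range(1, spec.n_harmonics + 1):
            if k * f0_max >= cfg.band_top_hz:
                break
            x += np.sin(k * phase) / k**cfg.harmonic_rolloff
        target_rms = P_REF * 10 ** (spec.source_level_db / 20.0)
        x *= target_rms / np.sqrt(np.mean(x**2))
        nr = int(round(cfg.ramp_ms * 1e-3 * fs))
        if nr and n >= 2 * nr:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            x[:nr] *= ramp
            x[-nr:] *= ramp[::-1]
        pieces.append(x)
        onsets.append(t_cursor)
        durations.append(dur_ms)
        gaps.append(gap_ms)
        f0_tracks.append(f0)
        levels.append(spec.source_level_db)
        t_cursor += dur_ms * 1e-3
        ng = int(round(gap_ms * 1e-3 * fs))
        pieces.append(np.zeros(ng))
        t_cursor += gap_ms * 1e-3
    pieces.append(np.zeros(int(round(_snap(cfg.tail_ms) * 1e-3 * fs))))
    samples = np.concatenate(pieces)
    if cfg.noise_rms_pa > 0:
        samples = samples + rng.normal(0.0, cfg.noise_rms_pa, samples.shape)
    motif_duration_ms = sum(durations) + sum(gaps[:-1]) if durations else 0.0
    truth = {"onsets_s": onsets, "durations_ms": durations, "gaps_ms": gaps,
             "f0_tracks_hz": f0_tracks, "source_levels_db": levels,
             "motif_duration_ms": motif_duration_ms}
    return AudioRecording(samples, fs, cfg.calibration), truth


def embed_motifs(
    motif: np.ndarray,
    onsets_s: Sequence[float],
    total_s: float,
    sample_rate: float = 44100.0,
    noise_rms_pa: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Place copies of a motif waveform at known onsets in a silent (or
    noisy) recording — ground truth for motif detection."""
    rng = np.random.default_rng(seed)
    n = int(round(total_s * sample_rate))
    x = (rng.normal(0.0, noise_rms_pa, n) if noise_rms_pa > 0 else np.zeros(n))
    for onset in onsets_s:
        i0 = int(round(onset * sample_rate))
        seg = motif[: max(0, min(len(motif), n - i0))]
        x[i0 : i0 + len(seg)] += seg
    return x


# ---------------------------------------------------------------------------
# proteome tables

def default_protein_panel() -> pd.DataFrame:
    """A realistic ~20-protein panel for the syringeal muscle proteome.

    Abundances are arbitrary units; the myosin pool is dominated by
    MYH13 (92 % of myosins) with the fast/developmental cluster pooled
    as MYH-fast. Histone H4 is included as the normalization reference.
    """
    myosin_pool = 30.0
    rows = [
        ("MYH13", "MYH13", "sarcomeric", 0.92 * myosin_pool, False),
        ("MYHF1", "MYH1A", "sarcomeric", 0.05 * myosin_pool, True),
        ("MYHF2", "MYH1B", "sarcomeric", 0.03 * myosin_pool, True),
        ("ACTA1", "ACTA1", "sarcomeric", 18.0, False),
        ("MYL1", "MYL1", "sarcomeric", 6.0, False),
        ("MYLPF", "MYLPF", "sarcomeric", 5.0, False),
        ("TNNT3", "TNNT3", "sarcomeric", 3.0, False),
        ("TNNC2", "TNNC2", "sarcomeric", 2.5, False),
        ("TNNI2", "TNNI2", "sarcomeric", 2.0, False),
        ("TTNX", "TTN", "sarcomeric", 1.5, False),
        ("ATP2A1", "ATP2A1", "ca_handling", 8.0, False),
        ("PVALB1", "PVALB", "ca_handling", 7.0, False),
        ("CASQ1", "CASQ1", "ca_handling", 2.0, False),
        ("RYR1", "RYR1", "ca_handling", 1.0, False),
        ("ATP5A", "ATP5F1A", "mitochondrial", 9.0, False),
        ("NDUFA9", "NDUFA9", "mitochondrial", 4.0, False),
        ("COX4", "COX4I1", "mitochondrial", 3.5, False),
        ("CKMT2", "CKMT2", "mitochondrial", 2.5, False),
        ("B5FXC8", "H4", "other", 1.0, False),
        ("ENO3", "ENO3", "other", 3.0, False),
        ("GAPDH", "GAPDH", "other", 2.5, False),
    ]
    return pd.DataFrame(
        rows, columns=["accession", "gene", "category", "abundance", "myh_fast_cluster"]
    )


@dataclass
class ProteomeConfig:
    panel: pd.DataFrame = field(default_factory=default_protein_panel)
    fc_map: dict = field(default_factory=dict)  # accession -> fold change
    cv: float = 0.10
    n_peptides: int = 5
    n_pairs: int = 3
    between_animal_cv: float = 0.15
    rbc_decoys: bool = False
    rbc_area: float = 2.0


def generate_peptide_table_pair(
    cfg: ProteomeConfig | None = None, seed: int = 0
) -> tuple[list[pd.DataFrame], list[pd.DataFrame], dict]:
    """Paired intact/treated peptide tables for ``n_pairs`` animals.

    Per protein and animal a shared base abundance (log-normal
    between-animal variation) spreads over >= 4 peptides with fixed
    relative ionization weights; treated areas are scaled by the
    protein's fold change and jittered with the configured technical CV.
    CV = 0 with an all-ones fc_map yields identical tables. Optional
    decoy rows carry the five red-blood-cell contaminant accessions.
    """
    cfg = cfg or ProteomeConfig()
    for fc in cfg.fc_map.values():
        if fc < 0:
            raise ValueError("fold changes must be non-negative")
    rng = np.random.default_rng(seed)
    panel = cfg.panel.reset_index(drop=True)
    n_pep = max(4, cfg.n_peptides)
    weights = rng.dirichlet(np.full(n_pep, 4.0), size=len(panel)) + 0.02
    sigma_b = np.sqrt(np.log(1 + cfg.between_animal_cv**2))
    sigma_t = np.sqrt(np.log(1 + cfg.cv**2)) if cfg.cv > 0 else 0.0

    def noise(shape) -> np.ndarray:
        if sigma_t == 0:
            return np.ones(shape)
        return rng.lognormal(-0.5 * sigma_t**2, sigma_t, shape)

    intact_tables, treated_tables = [], []
    for pair in range(cfg.n_pairs):
        base = panel["abundance"].to_numpy() * (
            rng.lognormal(-0.5 * sigma_b**2, sigma_b, len(panel))
            if cfg.between_animal_cv > 0 else 1.0
        )
        recs_i, recs_t = [], []
        for i, row in panel.iterrows():
            fc = cfg.fc_map.get(row["accession"], 1.0)
            w = weights[i]
            areas_i = base[i] * w * noise(n_pep)
            areas_t = base[i] * fc * w * noise(n_pep)
            for j in range(n_pep):
                pep = f"PEP_{row['accession']}_{j}"
                common = {"accession": row["accession"], "gene": row["gene"],
                          "peptide": pep,
                          "myh_fast_cluster": bool(row["myh_fast_cluster"])}
                recs_i.append({**common, "area": areas_i[j],
                               "sample": f"intact_{pair}"})
                recs_t.append({**common, "area": areas_t[j],
                               "sample": f"treated_{pair}"})
        if cfg.rbc_decoys:
            from .proteomics import RBC_ACCESSIONS
            for acc in sorted(RBC_ACCESSIONS):
                for j in range(4):
                    for recs, label in ((recs_i, "intact"), (recs_t, "treated")):
                        recs.append({
                            "accession": acc, "gene": acc, "peptide": f"PEP_{acc}_{j}",
                            "myh_fast_cluster": False,
                            "area": cfg.rbc_area * rng.lognormal(0, 0.2),
                            "sample": f"{label}_{pair}",
                        })
        intact_tables.append(pd.DataFrame(recs_i))
        treated_tables.append(pd.DataFrame(recs_t))
    truth = {"fc_map": dict(cfg.fc_map), "n_pairs": cfg.n_pairs,
             "panel": panel}
    return intact_tables, treated_tables, truth


# ---------------------------------------------------------------------------
# keypeck logs

@dataclass
class PecksConfig:
    p_focal: float = 0.66        # probability a peck goes to the pre stimulus
    n_per_day: int = 100
    days: int = 4
    focal: str = "pre"


def generate_keypeck_log(
    cfg: PecksConfig | None = None, seed: int = 0
) -> tuple[KeypeckLog, dict]:
    """Bernoulli keypeck stream over 4 days with nightly side switches.

    Each peck targets the focal stimulus with probability ``p_focal``;
    the pecked key follows that day's key-to-stimulus assignment, which
    alternates every night.
    """
    cfg = cfg or PecksConfig()
    if not 0.0 <= cfg.p_focal <= 1.0:
        raise ValueError("p_focal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    assignment = nightly_assignment("pre", cfg.days)
    rows = []
    n_focal = 0
    for day in range(1, cfg.days + 1):
        times = np.sort(rng.uniform(0, 12 * 3600, cfg.n_per_day))
        choose_focal = rng.random(cfg.n_per_day) < cfg.p_focal
        day_map = assignment[day]
        stim_of = {v: k for k, v in day_map.items()}  # stimulus -> key
        for ts, f in zip(times, choose_focal):
            stim = cfg.focal if f else ("post" if cfg.focal == "pre" else "pre")
            rows.append({"timestamp": (day - 1) * 86400.0 + ts,
                         "key": stim_of[stim], "day": day})
            n_focal += int(f)
    log = KeypeckLog(pd.DataFrame(rows), assignment, cfg.days)
    truth = {"p_focal": cfg.p_focal, "n_total": cfg.days * cfg.n_per_day,
             "n_focal": n_focal, "focal": cfg.focal}
    return log, truth
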