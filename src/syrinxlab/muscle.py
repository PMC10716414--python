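"""Isometric contraction metrics for syringeal muscle preparations.

Twitch contraction speed is summarised as the full width at half-maximal
force (FWHM, the t_50-50 interval between the upward and downward crossing
of 50 % of the baseline-to-peak force rise). Tetanic performance is
summarised as maximal isometric stress (MIS): peak baseline-subtracted
tetanic force divided by the preparation's cross-sectional area (CSA),
itself estimated from optimal length, dry mass (dry-to-wet conversion
factor 5) and muscle density (1060 kg/m^3).

Internally SI units are used for the CSA arithmetic; reported quantities
follow the field's conventions: mN, ms, mm^2 and mN/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ForceTrace",
    "TwitchMetrics",
    "PreparationGeometry",
    "TetanusMetrics",
    "compute_fwhm",
    "estimate_csa",
    "compute_mis",
    "summarize_session",
]


@dataclass
class ForceTrace:
    """A uniformly sampled isometric force recording.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing and uniform.
    force : array of float
        Force in millinewtons, finite.
    sample_rate : float
        Sampling rate in Hz. Recordings are digitized at 20 or 40 kHz by
        default; other rates are accepted.
    kind : {"twitch", "tetanus"}
    stimulus_onset : float
        Stimulus time in seconds on the ``time`` axis.
    """

    time: np.ndarray
    force: np.ndarray
    sample_rate: float
    kind: Literal["twitch", "tetanus"]
    stimulus_onset: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.size < 3:
            raise ValueError("trace needs at least 3 samples")
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force must be finite")
        if self.kind not in ("twitch", "tetanus"):
            raise ValueError(f"unknown trace kind {self.kind!r}")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        kind: Literal["twitch", "tetanus"],
        stimulus_onset: float = 0.0,
    ) -> "ForceTrace":
        """Read a ``time_s, force_mN`` CSV/TSV file."""
        df = pd.read_csv(path, sep=None, engine="python")
        if not {"time_s", "force_mN"} <= set(df.columns):
            raise ValueError("expected columns time_s, force_mN")
        t = df["time_s"].to_numpy(float)
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["force_mN"].to_numpy(float), rate, kind, stimulus_onset)


@dataclass
class TwitchMetrics:
    fwhm_ms: float
    peak_force_mN: float
    baseline_mN: float


@dataclass
class PreparationGeometry:
    """Geometry of a fibre-bundle preparation used to derive CSA.

    CSA (mm^2) = wet mass / (density * L0) with wet mass = dry mass x
    ``dry_wet_factor``. All fields must be positive.
    """

    optimal_length_mm: float
    dry_mass_mg: float
    dry_wet_factor: float = 5.0
    density_kg_m3: float = 1060.0
    csa_mm2: float | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("optimal_length_mm", "dry_mass_mg", "dry_wet_factor", "density_kg_m3"):
            if getattr(self, name) <= 0:
                raise ValueError("invalid geometry: all fields must be positive")


@dataclass
class TetanusMetrics:
    max_force_mN: float
    mis_mN_mm2: float


def _baseline(trace: ForceTrace, window_ms: float) -> float:
    """Mean force over the pre-stimulus window (falls back to the first
    sample if no samples precede the stimulus)."""
    lo = trace.stimulus_onset - window_ms * 1e-3
    sel = (trace.time >= lo) & (trace.time < trace.stimulus_onset)
    if not np.any(sel):
        return float(trace.force[0])
    return float(trace.force[sel].mean())


def _cross_time(t: np.ndarray, f: np.ndarray, i: int, level: float) -> float:
    """Linearly interpolated time where f crosses `level` between i and i+1."""
    f0, f1 = f[i], f[i + 1]
    if f1 == f0:
        return float(t[i])
    return float(t[i] + (level - f0) / (f1 - f0) * (t[i + 1] - t[i]))


def compute_fwhm(trace: ForceTrace, baseline_window_ms: float = 10.0) -> TwitchMetrics:
    """Full width at half-maximal force of a single twitch.

    The half-max level is baseline + 0.5 * (peak - baseline), with the
    baseline taken as the mean force over the ``baseline_window_ms``
    window preceding the stimulus. Crossing times are located with
    linear interpolation between adjacent samples, giving sub-sample
    precision; FWHM is the interval between the first upward crossing
    and the first subsequent downward crossing.

    Raises
    ------
    ValueError
        "no contraction" if the peak does not exceed baseline;
        "incomplete twitch" if either half-max crossing is missing.
    """
    if trace.kind != "twitch":
        raise ValueError("compute_fwhm requires a twitch trace")
    base = _baseline(trace, baseline_window_ms)
    after = trace.time >= trace.stimulus_onset
    if not np.any(after):
        raise ValueError("no contraction: stimulus after end of trace")
    start = int(np.argmax(after))
    t = trace.time[start:]
    f = trace.force[start:]
    peak = float(f.max())
    if peak <= base:
        raise ValueError("no contraction: peak does not exceed baseline")
    half = base + 0.5 * (peak - base)

    above = f >= half
    up = np.flatnonzero(~above[:-1] & above[1:])
    if up.size == 0:
        raise ValueError("incomplete twitch: no rising half-max crossing")
    i_up = int(up[0])
    down = np.flatnonzero(above[:-1] & ~above[1:])
    down = down[down >= i_up]
    if down.size == 0:
        raise ValueError("incomplete twitch: no falling half-max crossing")
    i_dn = int(down[0])

    t_up = _cross_time(t, f, i_up, half)
    t_dn = _cross_time(t, f, i_dn, half)
    return TwitchMetrics(fwhm_ms=(t_dn - t_up) * 1e3, peak_force_mN=peak, baseline_mN=base)


def estimate_csa(geometry: PreparationGeometry) -> float:
    """Cross-sectional area in mm^2 from preparation geometry.

    Wet mass = dry mass x dry_wet_factor; volume = wet mass / density;
    CSA = volume / L0. The result is stored back on ``geometry``.
    """
    wet_kg = geometry.dry_mass_mg * 1e-6 * geometry.dry_wet_factor
    volume_m3 = wet_kg / geometry.density_kg_m3
    csa_m2 = volume_m3 / (geometry.optimal_length_mm * 1e-3)
    geometry.csa_mm2 = csa_m2 * 1e6
    return geometry.csa_mm2


def compute_mis(
    trace: ForceTrace,
    geometry: PreparationGeometry,
    baseline_window_ms: float = 10.0,
) -> TetanusMetrics:
    """Maximal isometric stress: peak baseline-subtracted tetanic force / CSA.

    The tetanic maximum is the global maximum of the baseline-subtracted
    trace (no plateau fitting), floored at zero so an all-baseline trace
    reports MIS = 0.
    """
    if trace.kind != "tetanus":
        raise ValueError("compute_mis requires a tetanus trace")
    csa = geometry.csa_mm2 if geometry.csa_mm2 is not None else estimate_csa(geometry)
    if csa <= 0:
        raise ValueError("invalid geometry: CSA must be positive")
    base = _baseline(trace, baseline_window_ms)
    max_force = max(float(trace.force.max() - base), 0.0)
    return TetanusMetrics(max_force_mN=max_force, mis_mN_mm2=max_force / csa)


def summarize_session(
    traces: Iterable[ForceTrace],
    geometry: PreparationGeometry,
    baseline_window_ms: float = 10.0,
) -> pd.DataFrame:
    """Per-trace metrics for one recording session (typically seven
    twitches and three tetani), plus the arithmetic mean per kind.

    Returns a DataFrame with one row per trace and two summary rows
    (``mean_twitch``, ``mean_tetanus``) so both the per-twitch values
    and their average are available downstream.
    """
    rows: list[dict] = []
    for i, tr in enumerate(traces):
        if tr.kind == "twitch":
            m = compute_fwhm(tr, baseline_window_ms)
            rows.append(
                {"trace": i, "kind": "twitch", "fwhm_ms": m.fwhm_ms,
                 "peak_force_mN": m.peak_force_mN, "mis_mN_mm2": np.nan}
            )
        else:
            m2 = compute_mis(tr, geometry, baseline_window_ms)
            rows.append(
                {"trace": i, "kind": "tetanus", "fwhm_ms": np.nan,
                 "peak_force_mN": m2.max_force_mN, "mis_mN_mm2": m2.mis_mN_mm2}
            )
    df = pd.DataFrame(rows)
    summaries = []
    for kind, label in (("twitch", "mean_twitch"), ("tetanus", "mean_tetanus")):
        sub = df[df["kind"] == kind]
        if len(sub):
            summaries.append(
                {"trace": -1, "kind": label,
                 "fwhm_ms": sub["fwhm_ms"].mean(),
                 "peak_force_mN": sub["peak_force_mN"].mean(),
                 "mis_mN_mm2": sub["mis_mN_mm2"].mean()}
            )
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
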