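"""Operant song-preference analysis.

Females peck one of two keys to trigger playback of a song recorded
before or after the male's singing-prevention week. A test runs four
days and the key-to-stimulus assignment is switched every night to
control for side bias. Preference is the fraction of key pecks for the
focal stimulus pooled over the four days, tested against the 50 %
chance level with a likelihood-ratio G-test using Williams' small-sample
correction (for k = 2 cells, q = 1 + 1/(2n)).

Stimulus motifs are matched between conditions: a candidate must lie
within a duration window (default 4 ms, fallback 30 ms) and a source
level window (default 2 dB, fallback 6 dB) of its condition's mean
before one motif per condition is drawn at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KeypeckLog",
    "PreferenceResult",
    "StimulusPair",
    "GTestResult",
    "g_test_williams",
    "analyze_preference",
    "select_stimulus_pair",
    "nightly_assignment",
]


def nightly_assignment(
    first_day_left: str = "pre", days: int = 4
) -> dict[int, dict[str, str]]:
    """Key-to-stimulus map for each test day, switching every night."""
    other = "post" if first_day_left == "pre" else "pre"
    out = {}
    for d in range(1, days + 1):
        left = first_day_left if d % 2 == 1 else other
        right = other if left == first_day_left else first_day_left
        out[d] = {"left": left, "right": right}
    return out


@dataclass
class KeypeckLog:
    """Operant events plus the per-day key-to-stimulus assignment.

    ``events``: DataFrame with columns ``timestamp`` (seconds or any
    sortable scalar), ``key`` in {left, right}, ``day`` in 1..n_days.
    ``assignment``: day -> {"left": stimulus, "right": stimulus}.
    """

    events: pd.DataFrame
    assignment: Mapping[int, Mapping[str, str]]
    n_days: int = 4

    def __post_init__(self) -> None:
        missing = set(self.events["day"].unique()) - set(self.assignment)
        if missing:
            raise ValueError(f"day(s) without assignment: {sorted(missing)}")
        bad = set(self.events["key"].unique()) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown key(s): {sorted(bad)}")

    def stimulus_per_event(self) -> pd.Series:
        return self.events.apply(
            lambda r: self.assignment[int(r["day"])][r["key"]], axis=1
        )


@dataclass
class GTestResult:
    g: float
    williams_q: float
    g_adjusted: float
    p_value: float


@dataclass
class PreferenceResult:
    n_pre: int
    n_post: int
    preference: float
    g_statistic: float
    williams_q: float
    g_adjusted: float
    p_value: float
    significant: bool
    preferred: Literal["pre", "post", "none"]


def g_test_williams(n_a: int, n_b: int) -> GTestResult:
    """Goodness-of-fit G-test of two counts against a 50:50 null, with
    Williams' correction.

    G = 2 * sum O_i * ln(O_i / E_i) with E_i = n/2 (0*ln 0 := 0);
    q = 1 + (k^2 - 1) / (6 n (k - 1)) which for k = 2 is 1 + 1/(2n);
    G_adj = G / q is referred to chi-square with 1 df.
    """
    n = n_a + n_b
    if n < 1:
        raise ValueError("need at least one observation")
    e = n / 2.0
    g = 0.0
    for o in (n_a, n_b):
        if o > 0:
            g += o * np.log(o / e)
    g *= 2.0
    q = 1.0 + 1.0 / (2.0 * n)
    g_adj = g / q
    p = float(stats.chi2.sf(g_adj, df=1))
    return GTestResult(g=float(g), williams_q=q, g_adjusted=float(g_adj), p_value=p)


def analyze_preference(
    log: KeypeckLog,
    focal: Literal["pre", "post"] = "pre",
    alpha: float = 0.05,
) -> PreferenceResult:
    """Pooled 4-day preference for the focal stimulus with a
    Williams-corrected G-test against chance.

    ``preferred`` names the stimulus on the significant side of the
    deviation, or "none" when the test is not significant.
    """
    stim = log.stimulus_per_event()
    n_pre = int((stim == "pre").sum())
    n_post = int((stim == "post").sum())
    n_focal = n_pre if focal == "pre" else n_post
    total = n_pre + n_post
    if total == 0:
        raise ValueError("no keypecks in log")
    pref = n_focal / total
    gt = g_test_williams(n_pre, n_post)
    significant = gt.p_value < alpha
    if not significant:
        preferred: Literal["pre", "post", "none"] = "none"
    else:
        preferred = "pre" if n_pre > n_post else "post"
    return PreferenceResult(
        n_pre=n_pre, n_post=n_post, preference=pref,
        g_statistic=gt.g, williams_q=gt.williams_q,
        g_adjusted=gt.g_adjusted, p_value=gt.p_value,
        significant=significant, preferred=preferred,
    )


@dataclass
class StimulusPair:
    eligible_pre: pd.DataFrame
    eligible_post: pd.DataFrame
    selected_pre: pd.Series
    selected_post: pd.Series
    duration_window_ms: float
    sl_window_db: float
    used_fallback: bool


def _eligible(
    motifs: pd.DataFrame, duration_window_ms: float, sl_window_db: float
) -> pd.DataFrame:
    dur = motifs["motif_duration_s"].to_numpy(float)
    sl = motifs["motif_source_level_db"].to_numpy(float)
    ok = (np.abs(dur - dur.mean()) * 1e3 <= duration_window_ms) & (
        np.abs(sl - sl.mean()) <= sl_window_db
    )
    return motifs.loc[ok]


def select_stimulus_pair(
    pre_motifs: pd.DataFrame,
    post_motifs: pd.DataFrame,
    duration_window_ms: float = 4.0,
    sl_window_db: float = 2.0,
    fallback_duration_ms: float = 30.0,
    fallback_sl_db: float = 6.0,
    seed: int | np.random.Generator = 0,
) -> StimulusPair:
    """Pick one duration/SL-matched motif per condition, at random.

    A motif is eligible when its duration lies within the duration
    window of its condition's mean duration and its source level within
    the SL window of the mean SL. If either condition has no eligible
    motif, both windows widen to the fallback values; if an eligible
    set is still empty, raises ``ValueError("no matched motifs")``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    used_fallback = False
    elig_pre = _eligible(pre_motifs, duration_window_ms, sl_window_db)
    elig_post = _eligible(post_motifs, duration_window_ms, sl_window_db)
    if len(elig_pre) == 0 or len(elig_post) == 0:
        used_fallback = True
        duration_window_ms, sl_window_db = fallback_duration_ms, fallback_sl_db
        elig_pre = _eligible(pre_motifs, duration_window_ms, sl_window_db)
        elig_post = _eligible(post_motifs, duration_window_ms, sl_window_db)
        if len(elig_pre) == 0 or len(elig_post) == 0:
            raise ValueError("no matched motifs")
    sel_pre = elig_pre.iloc[int(rng.integers(len(elig_pre)))]
    sel_post = elig_post.iloc[int(rng.integers(len(elig_post)))]
    return StimulusPair(
        eligible_pre=elig_pre, eligible_post=elig_post,
        selected_pre=sel_pre, selected_post=sel_post,
        duration_window_ms=duration_window_ms, sl_window_db=sl_window_db,
        used_fallback=used_fallback,
    )
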