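"""Per-night sleep-period detection and sleep/wake classification.

The reference detector works on epoch ENMO: maximal runs where the 5-min
rolling median falls below a sustained-inactivity threshold (default
20 mg) lasting at least 30 min are sustained-inactivity blocks; blocks
separated by gaps shorter than 60 min are merged, and the longest merged
candidate within the noon-to-noon night anchor defines the sleep period
(onset = first block start, waking = last block end). The cohort-grade
algorithms in the literature use the wrist z-angle, which epoch ENMO does
not carry, so this ENMO-based detector is the built-in reference and the
interface accepts any callable with the same signature.

When a diary is available the search is guided: detection is restricted
to diary times plus/minus a guide window (default 2 h), falling back to
the diary times themselves when no inactivity block lies inside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import median_filter

from .types import EpochSeries, SleepAnnotation

__all__ = ["SptParams", "detect_spt", "merge_diary", "classify_sleep_wake",
           "night_anchors"]


@dataclass(frozen=True)
class SptParams:
    """Tuning of the sustained-inactivity sleep-period detector."""

    sib_thresh_mg: float = 20.0     # rolling-median threshold
    median_win_min: float = 5.0     # rolling median window
    min_block_min: float = 30.0     # minimum sustained-inactivity run
    max_gap_min: float = 60.0       # gaps below this merge adjacent blocks
    wake_thresh_mg: float = 30.0    # wake-within-sleep ENMO threshold
    min_wake_min: float = 2.0       # persistence for a wake bout


def night_anchors(series: EpochSeries, n_nights: Optional[int] = None) -> List[Tuple[np.datetime64, np.datetime64]]:
    """Noon-to-noon night anchor intervals covering the series."""
    first_noon = series.start.astype("datetime64[D]").astype("datetime64[s]") + np.timedelta64(12 * 3600, "s")
    if first_noon < series.start:
        first_noon += np.timedelta64(86400, "s")
    end = series.time_at(series.n_epochs)
    anchors = []
    t = first_noon
    while t + np.timedelta64(86400, "s") <= end:
        anchors.append((t, t + np.timedelta64(86400, "s")))
        t += np.timedelta64(86400, "s")
    if n_nights is not None:
        anchors = anchors[:n_nights]
    return anchors


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index pairs of True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _detect_blocks(series: EpochSeries, a: int, b: int, params: SptParams) -> List[Tuple[int, int]]:
    """Sustained-inactivity blocks within series[a:b], as absolute indices."""
    x = series.enmo[a:b]
    if x.size == 0:
        return []
    k = max(int(round(params.median_win_min * 60 / series.epoch_len_s)), 1)
    med = median_filter(x, size=k, mode="nearest")
    quiet = med < params.sib_thresh_mg
    min_len = int(round(params.min_block_min * 60 / series.epoch_len_s))
    return [(a + s, a + e) for s, e in _runs(quiet) if e - s >= min_len]


def detect_spt(
    series: EpochSeries,
    night_anchor: Tuple[np.datetime64, np.datetime64],
    params: SptParams = SptParams(),
    night_index: int = 0,
) -> Optional[SleepAnnotation]:
    """Detect the sleep period within one noon-to-noon anchor.

    Returns ``None`` when no sustained-inactivity block exists (the night
    is then invalid).
    """
    t0, t1 = night_anchor
    a, b = series.clip_index(t0), series.clip_index(t1)
    blocks = _detect_blocks(series, a, b, params)
    if not blocks:
        return None
    # merge blocks separated by gaps shorter than max_gap_min
    gap = int(round(params.max_gap_min * 60 / series.epoch_len_s))
    groups: List[List[Tuple[int, int]]] = [[blocks[0]]]
    for blk in blocks[1:]:
        if blk[0] - groups[-1][-1][1] < gap:
            groups[-1].append(blk)
        else:
            groups.append([blk])
    spans = [(g[0][0], g[-1][1]) for g in groups]
    onset_idx, wake_idx = max(spans, key=lambda s: s[1] - s[0])
    return SleepAnnotation(
        night_index=night_index,
        onset=series.time_at(onset_idx),
        wake=series.time_at(wake_idx),
        source="algorithmic",
    )


def merge_diary(
    series: EpochSeries,
    night_anchor: Tuple[np.datetime64, np.datetime64],
    diary_onset: Optional[np.datetime64],
    diary_wake: Optional[np.datetime64],
    params: SptParams = SptParams(),
    guide_window_h: float = 2.0,
    night_index: int = 0,
) -> Optional[SleepAnnotation]:
    """Diary-guided sleep-period detection for one night.

    Restricts the algorithmic search to diary times +/- ``guide_window_h``;
    if no inactivity block lies inside that corridor, the diary times are
    used directly (``source="diary_guided"``). With no diary entry the
    plain algorithmic result is passed through.
    """
    if diary_onset is None or diary_wake is None:
        return detect_spt(series, night_anchor, params, night_index)
    guide = np.timedelta64(int(guide_window_h * 3600), "s")
    lo = np.datetime64(diary_onset, "s") - guide
    hi = np.datetime64(diary_wake, "s") + guide
    t0, t1 = night_anchor
    restricted = (max(t0, lo), min(t1, hi))
    ann = detect_spt(series, restricted, params, night_index)
    if ann is not None:
        return ann
    return SleepAnnotation(
        night_index=night_index,
        onset=np.datetime64(diary_onset, "s"),
        wake=np.datetime64(diary_wake, "s"),
        source="diary_guided",
    )


def classify_sleep_wake(
    series: EpochSeries,
    annotation: SleepAnnotation,
    wake_thresh_mg: float = 30.0,
    min_wake_min: float = 2.0,
) -> np.ndarray:
    """Classify epochs of one sleep period as sleep (False) or wake (True).

    An epoch is wake iff it belongs to a run of epochs with ENMO above
    ``wake_thresh_mg`` lasting at least ``min_wake_min`` minutes; isolated
    shorter spikes count as sleep.
    """
    a = series.clip_index(annotation.onset)
    b = series.clip_index(annotation.wake)
    x = series.enmo[a:b]
    above = x > wake_thresh_mg
    min_len = max(int(round(min_wake_min * 60 / series.epoch_len_s)), 1)
    wake = np.zeros(x.size, dtype=bool)
    for s, e in _runs(above):
        if e - s >= min_len:
            wake[s:e] = True
    return wake
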