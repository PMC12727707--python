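"""The 36 behavioural circadian-rhythm metrics.

Four dimensions are covered for each participant with at least five valid
full day windows:

* rest-activity rhythm (6): cosinor mesor / amplitude / R^2 fitted to the
  log acceleration signal, interdaily stability (IS), intradaily
  variability (IV), relative amplitude;
* daytime activity (15): total duration, bout count and mean bout length
  for SB, LIPA and MVPA, mean waking acceleration, M10 mean, the
  day-time transition probabilities activity->rest and rest->activity,
  and the intensity-gradient intercept and slope;
* sleep (10): sleep duration, sleep efficiency, mean acceleration over
  the sleep period, L5 mean, sleep-bout count and mean length, the
  night-time transition probabilities sleep->wake and wake->sleep, WASO
  and mean wake-bout length;
* chronotype (5): sleep onset and waking times, M10 and L5 start times,
  and the cosinor acrotime, all on a noon-anchored hour scale (clock hour
  plus 24 when past midnight) so that times straddling midnight average
  correctly.

Cosinor, IS and IV are computed on the concatenated multi-day series;
bout, transition, sleep and timing metrics are computed per day window
and then averaged across valid windows, matching each metric's natural
support. Non-wear epochs are excluded from every denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .ingest import build_day_windows, filter_valid
from .sleep import SptParams, classify_sleep_wake, detect_spt, merge_diary, night_anchors
from .types import EpochSeries, SleepAnnotation

__all__ = [
    "CosinorFit",
    "METRIC_DIMENSIONS",
    "METRIC_NAMES",
    "fit_cosinor",
    "interdaily_stability",
    "intradaily_variability",
    "m10_l5",
    "relative_amplitude",
    "classify_intensity",
    "bout_stats",
    "transition_prob",
    "intensity_gradient",
    "noon_anchored_hour",
    "participant_metrics",
    "MetricExtractor",
]

METRIC_DIMENSIONS: Dict[str, List[str]] = {
    "RAR": [
        "cosinor_mesor",
        "cosinor_amplitude",
        "cosinor_r2",
        "IS",
        "IV",
        "relative_amplitude",
    ],
    "daytime": [
        "SB_total_min",
        "SB_n_bouts",
        "SB_mean_bout_min",
        "LIPA_total_min",
        "LIPA_n_bouts",
        "LIPA_mean_bout_min",
        "MVPA_total_min",
        "MVPA_n_bouts",
        "MVPA_mean_bout_min",
        "mean_acc_wake",
        "M10_mean",
        "TP_ar_d",
        "TP_ra_d",
        "IG_intercept",
        "IG_slope",
    ],
    "sleep": [
        "sleep_duration",
        "sleep_efficiency",
        "mean_acc_sleep",
        "L5_mean",
        "n_sleep_bouts",
        "mean_sleep_bout_min",
        "TP_sw_n",
        "TP_ws_n",
        "WASO",
        "mean_wake_bout_min",
    ],
    "chronotype": [
        "sleep_onset_time",
        "wake_time",
        "M10_start",
        "L5_start",
        "acrotime",
    ],
}

METRIC_NAMES: List[str] = [m for dim in METRIC_DIMENSIONS.values() for m in dim]
assert len(METRIC_NAMES) == 36

# intensity classification defaults (mg)
SB_THRESH_MG = 30.0
MVPA_THRESH_MG = 100.0


@dataclass
class CosinorFit:
    """Single-component 24-h cosinor fit of the log acceleration signal."""

    mesor: float
    amplitude: float
    acrotime: float  # clock hours in [0, 24)
    r2: float


def fit_cosinor(t_hours: np.ndarray, y: np.ndarray) -> CosinorFit:
    """Least-squares cosinor: y ~ 1 + cos(2*pi*t/24) + sin(2*pi*t/24).

    ``t_hours`` are clock hours since midnight; the amplitude is
    ``sqrt(beta_cos^2 + beta_sin^2)`` and the acrotime the peak time of
    the fitted cosine mapped to [0, 24).
    """
    t_hours = np.asarray(t_hours, float)
    y = np.asarray(y, float)
    if t_hours.size != y.size or t_hours.size < 3:
        raise ValueError("need matching t and y with at least 3 points")
    if np.ptp(y) == 0:
        warnings.warn("constant signal: cosinor amplitude 0, R^2 reported as 0")
        return CosinorFit(float(y[0]) if y.size else np.nan, 0.0, np.nan, 0.0)
    omega = 2 * np.pi / 24.0
    X = np.column_stack([np.ones_like(t_hours), np.cos(omega * t_hours), np.sin(omega * t_hours)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    amp = float(np.hypot(beta[1], beta[2]))
    acro = float((np.arctan2(beta[2], beta[1]) / omega) % 24.0)
    return CosinorFit(float(beta[0]), amp, acro, r2)


def _hourly_layout(hourly, hour_of_day):
    x = np.asarray(hourly, float)
    if x.ndim == 2:
        if x.shape[1] != 24:
            raise ValueError("2-D hourly input must have 24 columns")
        hod = np.tile(np.arange(24), x.shape[0])
        x = x.ravel()
    else:
        hod = (np.asarray(hour_of_day, int) if hour_of_day is not None
               else np.arange(x.size) % 24)
        if hod.shape != x.shape:
            raise ValueError("hour_of_day must match hourly length")
    ok = np.isfinite(x)
    return x[ok], hod[ok], ok


def interdaily_stability(hourly, hour_of_day=None) -> float:
    """Interdaily stability of the hourly activity profile, in [0, 1].

    ``IS = n * sum_h (xbar_h - xbar)^2 / (24 * sum_i (x_i - xbar)^2)``
    where ``xbar_h`` are the 24 across-day hourly means and ``n`` the
    number of (non-missing) hourly values. Accepts a (days, 24) matrix or
    a flat hourly series with optional hour-of-day labels; missing hours
    (NaN) are dropped from both numerator and denominator.
    """
    x, hod, _ = _hourly_layout(hourly, hour_of_day)
    if x.size < 48:
        raise ValueError("need at least two complete days of hourly means")
    grand = x.mean()
    denom = np.sum((x - grand) ** 2)
    if denom == 0:
        warnings.warn("zero-variance hourly series: IS undefined")
        return np.nan
    hour_means = np.array([x[hod == h].mean() for h in np.unique(hod)])
    num = x.size * np.sum((hour_means - grand) ** 2)
    return float(num / (hour_means.size * denom))


def intradaily_variability(hourly, hour_of_day=None) -> float:
    """Intradaily variability: normalised mean square of successive hourly
    differences (about 2 for white noise, near 0 for a smooth rhythm).
    Differences spanning a missing hour are skipped.
    """
    x = np.asarray(hourly, float)
    if x.ndim == 2:
        x = x.ravel()
    ok = np.isfinite(x)
    xs = x[ok]
    if xs.size < 48:
        raise ValueError("need at least two complete days of hourly means")
    grand = xs.mean()
    denom = np.sum((xs - grand) ** 2)
    if denom == 0:
        warnings.warn("zero-variance hourly series: IV undefined")
        return np.nan
    idx = np.flatnonzero(ok)
    adjacent = np.diff(idx) == 1
    diffs = np.diff(x[idx])[adjacent]
    n = xs.size
    return float(n * np.sum(diffs**2) / ((n - 1) * denom))


def noon_anchored_hour(clock_hour: float) -> float:
    """Map a clock hour in [0, 24) to the noon-anchored scale [12, 36)."""
    return clock_hour + 24.0 if clock_hour < 12.0 else clock_hour


def _day_anchors(series: EpochSeries, anchor_clock_h: int):
    """Complete 24-h day blocks starting at the given clock hour."""
    midnight = series.start.astype("datetime64[D]").astype("datetime64[s]")
    t = midnight + np.timedelta64(anchor_clock_h * 3600, "s")
    if t < series.start:
        t += np.timedelta64(86400, "s")
    end = series.time_at(series.n_epochs)
    anchors = []
    while t + np.timedelta64(86400, "s") <= end:
        anchors.append((t, t + np.timedelta64(86400, "s")))
        t += np.timedelta64(86400, "s")
    return anchors


def _rolling_window_extreme(day, ok, w, pick):
    """(extreme of >=half-observed rolling means, start index) or None."""
    if day.size < w:
        return None
    vals = np.where(ok, day, 0.0)
    c1 = np.concatenate([[0.0], np.cumsum(vals)])
    cn = np.concatenate([[0], np.cumsum(ok.astype(int))])
    sums = c1[w:] - c1[:-w]
    cnts = cn[w:] - cn[:-w]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(cnts >= w / 2, sums / cnts, np.nan)
    if not np.isfinite(means).any():
        return None
    j = int(pick(means))
    return float(means[j]), j


def m10_l5(
    series: EpochSeries,
    mask: Optional[np.ndarray] = None,
    m_hours: float = 10.0,
    l_hours: float = 5.0,
    max_missing_frac: float = 1.0 / 3.0,
) -> Dict[str, float]:
    """Most-active 10-h and least-active 5-h rolling windows per day.

    M10 is evaluated over complete calendar (midnight-to-midnight) days,
    which contain the daytime activity hump whole; L5 over noon-to-noon
    days, which contain the sleep period whole. Window means are rolling
    at epoch stride; means and start times are averaged across days
    (M10 start on the plain clock-hour scale, L5 start noon-anchored).
    Days missing more than ``max_missing_frac`` of their epochs are
    skipped, and a rolling window must itself be at least half observed.
    """
    eph = int(3600 / series.epoch_len_s)
    x = np.where(series.wear, series.enmo, np.nan)
    if mask is not None:
        x = np.where(mask, x, np.nan)
    results = {k: [] for k in ("M10_mean", "M10_start", "L5_mean", "L5_start")}
    jobs = (
        ("M10_mean", "M10_start", m_hours, np.nanargmax, 0),
        ("L5_mean", "L5_start", l_hours, np.nanargmin, 12),
    )
    for key_mean, key_start, w_h, pick, anchor_h in jobs:
        w = int(round(w_h * eph))
        for t0, t1 in _day_anchors(series, anchor_h):
            a, b = series.clip_index(t0), series.clip_index(t1)
            day = x[a:b]
            ok = np.isfinite(day)
            if day.size == 0 or (~ok).mean() > max_missing_frac:
                continue
            got = _rolling_window_extreme(day, ok, w, pick)
            if got is None:
                continue
            mean, j = got
            results[key_mean].append(mean)
            start_clock = (anchor_h + j / eph) % 24.0
            results[key_start].append(
                noon_anchored_hour(start_clock) if anchor_h == 12 else start_clock
            )
    return {k: (float(np.mean(v)) if v else np.nan) for k, v in results.items()}


def relative_amplitude(m10_mean: float, l5_mean: float) -> float:
    """(M10 - L5) / (M10 + L5); NaN when both are 0."""
    if not (np.isfinite(m10_mean) and np.isfinite(l5_mean)):
        return np.nan
    if m10_mean + l5_mean == 0:
        warnings.warn("M10 = L5 = 0: relative amplitude undefined")
        return np.nan
    return float((m10_mean - l5_mean) / (m10_mean + l5_mean))


def classify_intensity(
    enmo: np.ndarray,
    sb_thresh_mg: float = SB_THRESH_MG,
    mvpa_thresh_mg: float = MVPA_THRESH_MG,
) -> np.ndarray:
    """Classify waking epochs: 0 = SB (< sb threshold), 2 = MVPA
    (>= mvpa threshold), 1 = LIPA otherwise."""
    if not 0 < sb_thresh_mg < mvpa_thresh_mg:
        raise ValueError("require 0 < sb_thresh_mg < mvpa_thresh_mg")
    enmo = np.asarray(enmo, float)
    states = np.ones(enmo.size, dtype=np.int8)
    states[enmo < sb_thresh_mg] = 0
    states[enmo >= mvpa_thresh_mg] = 2
    return states


def _rle(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (run values, run lengths)."""
    values = np.asarray(values)
    if values.size == 0:
        return values, np.empty(0, dtype=int)
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [values.size]]))
    return values[starts], lengths


def _member(states: np.ndarray, targets) -> np.ndarray:
    """Membership mask via direct comparisons (faster than isin here)."""
    targets = np.atleast_1d(targets)
    member = states == targets[0]
    for t in targets[1:]:
        member = member | (states == t)
    return member


def bout_stats(
    states: np.ndarray, target, min_bout_epochs: int = 1
) -> Tuple[int, int, float]:
    """Bout statistics for a target state (or set of states).

    A bout is a maximal run of the target state lasting at least
    ``min_bout_epochs``. Returns (total epochs in bouts, bout count, mean
    bout length in epochs); an absent state yields (0, 0, 0.0).
    """
    states = np.asarray(states)
    member = _member(states, target)
    vals, lens = _rle(member)
    bout_lens = lens[vals & (lens >= min_bout_epochs)]
    if bout_lens.size == 0:
        return 0, 0, 0.0
    return int(bout_lens.sum()), int(bout_lens.size), float(bout_lens.mean())


def transition_prob(states: np.ndarray, from_states, to_states) -> float:
    """Per-epoch probability of switching from ``from_states`` into
    ``to_states``: transition count divided by the total number of epochs
    spent in ``from_states``. NaN when the from-set is empty."""
    states = np.asarray(states)
    in_from = _member(states, from_states)
    n_from = int(in_from.sum())
    if n_from == 0:
        return np.nan
    if states.size < 2:
        return 0.0
    trans = in_from[:-1] & _member(states[1:], to_states)
    return float(trans.sum() / n_from)


def intensity_gradient(
    waking_enmo: np.ndarray,
    epoch_len_s: int,
    bin_width_mg: float = 25.0,
    max_mg: float = 4000.0,
) -> Tuple[float, float]:
    """Intensity gradient: OLS of ln(minutes per bin) on ln(bin midpoint)
    over non-empty 25-mg intensity bins from 0 to 4000 mg. Returns
    (intercept, slope); fewer than 3 non-empty bins yields NaNs."""
    x = np.asarray(waking_enmo, float)
    x = x[np.isfinite(x)]
    edges = np.arange(0.0, max_mg + bin_width_mg, bin_width_mg)
    counts, _ = np.histogram(np.clip(x, 0, max_mg - 1e-9), bins=edges)
    minutes = counts * epoch_len_s / 60.0
    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = minutes > 0
    if keep.sum() < 3:
        warnings.warn("fewer than 3 non-empty intensity bins: IG undefined")
        return np.nan, np.nan
    lx, ly = np.log(mids[keep]), np.log(minutes[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    return float(intercept), float(slope)


# ---------------------------------------------------------------------------
# participant-level assembly
# ---------------------------------------------------------------------------


def _annotate_nights(
    series: EpochSeries,
    diary: Optional[pd.DataFrame],
    sleep_mode: str,
    spt_params: SptParams,
    guide_window_h: float,
) -> List[SleepAnnotation]:
    anchors = night_anchors(series)
    diary_by_night: Dict[int, Tuple[np.datetime64, np.datetime64]] = {}
    if diary is not None and len(diary):
        for _, row in diary.iterrows():
            diary_by_night[int(row["night_index"])] = (
                np.datetime64(pd.Timestamp(row["onset_time"]), "s"),
                np.datetime64(pd.Timestamp(row["wake_time"]), "s"),
            )
    annotations: List[SleepAnnotation] = []
    for i, anchor in enumerate(anchors):
        entry = diary_by_night.get(i)
        if sleep_mode == "diary":
            if entry is None:
                continue
            ann = SleepAnnotation(i, entry[0], entry[1], source="diary")
        elif sleep_mode == "diary_guided":
            ann = merge_diary(series, anchor, *(entry or (None, None)),
                              params=spt_params, guide_window_h=guide_window_h,
                              night_index=i)
        elif sleep_mode == "algorithmic":
            ann = detect_spt(series, anchor, spt_params, night_index=i)
        else:
            raise ValueError(f"unknown sleep_mode: {sleep_mode!r}")
        if ann is not None:
            annotations.append(ann)
    return annotations


def _nan_metrics(reason: str) -> Tuple[pd.Series, Dict]:
    return (pd.Series(np.nan, index=METRIC_NAMES),
            {"included": False, "reason": reason, "n_valid_windows": 0})


def participant_metrics(
    series: EpochSeries,
    diary: Optional[pd.DataFrame] = None,
    *,
    sleep_mode: str = "diary_guided",
    protocol: str = "diary_anchored",
    spt_params: SptParams = SptParams(),
    guide_window_h: float = 2.0,
    min_windows: int = 5,
    min_wear_frac: float = 2.0 / 3.0,
    sb_thresh_mg: float = SB_THRESH_MG,
    mvpa_thresh_mg: float = MVPA_THRESH_MG,
    min_bout_epochs: int = 1,
    log_offset: float = 1.0,
) -> Tuple[pd.Series, Dict]:
    """Compute the 36-metric vector for one participant.

    Returns ``(metrics, diagnostics)``; excluded participants (fewer than
    ``min_windows`` valid day windows) get an all-NaN vector and the
    exclusion reason in the diagnostics.
    """
    annotations = _annotate_nights(series, diary, sleep_mode, spt_params, guide_window_h)
    if len(annotations) < 2:
        return _nan_metrics("fewer than two annotated nights")
    windows = build_day_windows(series, annotations, protocol=protocol)
    valid, included = filter_valid(windows, min_windows, min_wear_frac)
    if not included:
        return _nan_metrics(f"only {len(valid)} valid windows")

    epoch_min = series.epoch_len_s / 60.0
    eph = int(3600 / series.epoch_len_s)
    n = series.n_epochs
    wear = series.wear
    enmo = series.enmo
    clock = series.clock_hours()

    analysed = np.zeros(n, dtype=bool)
    waking_mask = np.zeros(n, dtype=bool)
    bounds = []
    for win in valid:
        a = series.clip_index(win.wake_time)
        o = series.clip_index(win.onset_time)
        b = series.clip_index(win.next_wake)
        analysed[a:b] = True
        waking_mask[a:o] = True
        bounds.append((a, o, b, win))

    out: Dict[str, float] = {}

    # --- RAR: cosinor + IS/IV on the concatenated analysed series ---------
    fit_mask = analysed & wear
    fit = fit_cosinor(clock[fit_mask], np.log(enmo[fit_mask] + log_offset))
    out["cosinor_mesor"] = fit.mesor
    out["cosinor_amplitude"] = fit.amplitude
    out["cosinor_r2"] = fit.r2

    hour_idx = np.arange(n) // eph
    n_hours = int(hour_idx[-1]) + 1
    cnt = np.bincount(hour_idx, weights=fit_mask.astype(float), minlength=n_hours)
    tot = np.bincount(hour_idx, weights=np.where(fit_mask, enmo, 0.0), minlength=n_hours)
    with np.errstate(invalid="ignore", divide="ignore"):
        hourly = np.where(cnt >= eph / 2.0, tot / np.maximum(cnt, 1), np.nan)
    start_hour = int(series.start_clock_hour())
    hod = (start_hour + np.arange(n_hours)) % 24
    try:
        out["IS"] = interdaily_stability(hourly, hod)
        out["IV"] = intradaily_variability(hourly)
    except ValueError:
        out["IS"] = np.nan
        out["IV"] = np.nan

    m10 = m10_l5(series, mask=analysed)
    out["M10_mean"] = m10["M10_mean"]
    out["L5_mean"] = m10["L5_mean"]
    out["relative_amplitude"] = relative_amplitude(m10["M10_mean"], m10["L5_mean"])

    # --- daytime activity --------------------------------------------------
    # per-window state sequences; non-wear marked -1 so it breaks runs and
    # drops out of all denominators
    day_totals = {s: [] for s in (0, 1, 2)}
    day_bouts = {s: [] for s in (0, 1, 2)}
    pooled_bout_epochs = {s: 0 for s in (0, 1, 2)}
    pooled_bout_n = {s: 0 for s in (0, 1, 2)}
    tp_ar, tp_ra = [], []
    for a, o, b, win in bounds:
        seg_enmo = enmo[a:o]
        seg_wear = wear[a:o]
        states = classify_intensity(seg_enmo, sb_thresh_mg, mvpa_thresh_mg)
        states = np.where(seg_wear, states, -1).astype(np.int8)
        for s in (0, 1, 2):
            total, nb, _ = bout_stats(states, s, min_bout_epochs)
            day_totals[s].append(total * epoch_min)
            day_bouts[s].append(nb)
            pooled_bout_epochs[s] += total
            pooled_bout_n[s] += nb
        p = transition_prob(states, [1, 2], [0])
        if np.isfinite(p):
            tp_ar.append(p)
        p = transition_prob(states, [0], [1, 2])
        if np.isfinite(p):
            tp_ra.append(p)

    for s, name in ((0, "SB"), (1, "LIPA"), (2, "MVPA")):
        out[f"{name}_total_min"] = float(np.mean(day_totals[s]))
        out[f"{name}_n_bouts"] = float(np.mean(day_bouts[s]))
        out[f"{name}_mean_bout_min"] = (
            pooled_bout_epochs[s] / pooled_bout_n[s] * epoch_min
            if pooled_bout_n[s] else 0.0
        )
    wake_wear = waking_mask & wear
    out["mean_acc_wake"] = float(enmo[wake_wear].mean()) if wake_wear.any() else np.nan
    # transition probabilities reported per minute
    out["TP_ar_d"] = float(np.mean(tp_ar)) / epoch_min if tp_ar else np.nan
    out["TP_ra_d"] = float(np.mean(tp_ra)) / epoch_min if tp_ra else np.nan
    ig_int, ig_slope = intensity_gradient(enmo[wake_wear], series.epoch_len_s)
    out["IG_intercept"] = ig_int
    out["IG_slope"] = ig_slope

    # --- sleep -------------------------------------------------------------
    durs, effs, wasos, accs = [], [], [], []
    n_sleep_bouts, tp_sw, tp_ws = [], [], []
    pooled = {"sleep_epochs": 0, "sleep_bouts": 0, "wake_epochs": 0, "wake_bouts": 0}
    onset_hours, wake_hours = [], []
    for a, o, b, win in bounds:
        ann = SleepAnnotation(0, win.onset_time, win.next_wake)
        wake_states = classify_sleep_wake(series, ann, spt_params.wake_thresh_mg,
                                          spt_params.min_wake_min)
        seg_wear = wear[o:b]
        period_h = wake_states.size * epoch_min / 60.0
        # wear-masked night states: 1 = sleep, 0 = wake, -1 = non-wear
        night = np.where(seg_wear, np.where(wake_states, 0, 1), -1).astype(np.int8)
        s_tot, s_nb, _ = bout_stats(night, 1, 1)
        w_tot, w_nb, _ = bout_stats(night, 0, 1)
        worn = s_tot + w_tot
        if worn == 0 or period_h <= 0:
            continue
        sleep_h = s_tot * epoch_min / 60.0
        durs.append(sleep_h)
        effs.append(s_tot / worn)
        wasos.append(w_tot * epoch_min)
        accs.append(float(enmo[o:b][seg_wear].mean()) if seg_wear.any() else np.nan)
        n_sleep_bouts.append(s_nb)
        pooled["sleep_epochs"] += s_tot
        pooled["sleep_bouts"] += s_nb
        pooled["wake_epochs"] += w_tot
        pooled["wake_bouts"] += w_nb
        p = transition_prob(night, [1], [0])
        if np.isfinite(p):
            tp_sw.append(p)
        p = transition_prob(night, [0], [1])
        if np.isfinite(p):
            tp_ws.append(p)
        onset_hours.append(noon_anchored_hour(float(clock[o]) if o < n else np.nan))
        wake_hours.append(noon_anchored_hour(float(clock[b - 1] + epoch_min / 60.0)
                                             if b <= n else np.nan))
    if not durs:
        return _nan_metrics("no analysable nights")
    out["sleep_duration"] = float(np.mean(durs))
    out["sleep_efficiency"] = float(np.mean(effs))
    out["mean_acc_sleep"] = float(np.nanmean(accs))
    out["n_sleep_bouts"] = float(np.mean(n_sleep_bouts))
    out["mean_sleep_bout_min"] = (
        pooled["sleep_epochs"] / pooled["sleep_bouts"] * epoch_min
        if pooled["sleep_bouts"] else 0.0
    )
    out["TP_sw_n"] = float(np.mean(tp_sw)) / epoch_min if tp_sw else np.nan
    out["TP_ws_n"] = float(np.mean(tp_ws)) / epoch_min if tp_ws else np.nan
    out["WASO"] = float(np.mean(wasos))
    out["mean_wake_bout_min"] = (
        pooled["wake_epochs"] / pooled["wake_bouts"] * epoch_min
        if pooled["wake_bouts"] else 0.0
    )

    # --- chronotype ----------------------------------------------------
    out["sleep_onset_time"] = float(np.mean(onset_hours))
    out["wake_time"] = float(np.mean(wake_hours))
    out["M10_start"] = m10["M10_start"]
    out["L5_start"] = m10["L5_start"]
    out["acrotime"] = (noon_anchored_hour(fit.acrotime)
                       if np.isfinite(fit.acrotime) else np.nan)

    metrics = pd.Series(out).reindex(METRIC_NAMES)
    missing = metrics.index[metrics.isna()].tolist()
    diag = {
        "included": True,
        "reason": "",
        "n_valid_windows": len(valid),
        "missing_metrics": missing,
    }
    return metrics, diag


class MetricExtractor:
    """Stateless transformer: cohort epoch data -> participant x 36 table.

    Keyword arguments mirror :func:`participant_metrics`. The
    ``transform`` method accepts a mapping of participant id to
    :class:`~circaclust.types.EpochSeries` (or a
    :class:`~circaclust.simulate.CohortBundle`) plus an optional diary
    table, and returns the metric matrix; per-participant validity
    diagnostics are kept on ``diagnostics_``.
    """

    def __init__(self, **kwargs):
        self.params = kwargs

    def get_params(self, deep: bool = True) -> Dict:
        return dict(self.params)

    def set_params(self, **kwargs) -> "MetricExtractor":
        self.params.update(kwargs)
        return self

    def transform(self, epochs, diaries: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        from .simulate import CohortBundle  # local import to avoid cycle

        if isinstance(epochs, CohortBundle):
            diaries = epochs.diaries if diaries is None else diaries
            epochs = epochs.epochs
        rows, diags = {}, {}
        grouped = None
        if diaries is not None and len(diaries):
            grouped = dict(tuple(diaries.groupby("participant_id", sort=False)))
        for pid, series in epochs.items():
            diary = grouped.get(pid) if grouped else None
            metrics, diag = participant_metrics(series, diary, **self.params)
            rows[pid] = metrics
            diags[pid] = diag
        self.diagnostics_ = pd.DataFrame(diags).T
        table = pd.DataFrame(rows).T
        table.index.name = "participant_id"
        return table[METRIC_NAMES]
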