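"""The 36 circadian metrics: closed forms, oracles, and full-path toys."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from circaclust.metrics import (
    METRIC_DIMENSIONS,
    METRIC_NAMES,
    bout_stats,
    classify_intensity,
    fit_cosinor,
    intensity_gradient,
    interdaily_stability,
    intradaily_variability,
    m10_l5,
    noon_anchored_hour,
    participant_metrics,
    relative_amplitude,
    transition_prob,
)
from circaclust.simulate import ArchetypeSpec, simulate_participant
from circaclust.types import EpochSeries


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------


class TestCosinor:
    def test_exact_recovery_of_noiseless_cosine(self):
        t = np.arange(0, 48, 0.25)
        y = 2 + 1 * np.cos(2 * np.pi * (t - 15) / 24)
        fit = fit_cosinor(t % 24, y)
        assert fit.mesor == pytest.approx(2.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-10)
        assert fit.acrotime == pytest.approx(15.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_signal_zero_amplitude(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_cosinor(np.arange(48.0) % 24, np.full(48, 3.0))
        assert fit.amplitude == 0.0 and fit.r2 == 0.0

    def test_agrees_with_grid_plus_refine_oracle(self):
        rng = np.random.default_rng(7)
        t = rng.uniform(0, 48, 200) % 24
        y = 1.5 + 0.8 * np.cos(2 * np.pi * (t - 17.2) / 24) + rng.normal(0, 0.3, 200)
        omega = 2 * np.pi / 24

        def sse_at(phi):
            c = np.cos(omega * (t - phi))
            X = np.column_stack([np.ones_like(t), c])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ beta) ** 2)), beta

        phis = np.arange(0, 24, 0.005)
        sses = np.array([sse_at(p)[0] for p in phis])
        p0 = phis[np.argmin(sses)]
        res = minimize_scalar(lambda p: sse_at(p)[0],
                              bounds=(p0 - 0.01, p0 + 0.01), method="bounded",
                              options={"xatol": 1e-12})
        _, beta = sse_at(res.x)
        mesor_o, amp_o = beta[0], abs(beta[1])
        acro_o = (res.x + (12 if beta[1] < 0 else 0)) % 24
        fit = fit_cosinor(t, y)
        assert fit.mesor == pytest.approx(mesor_o, abs=1e-6)
        assert fit.amplitude == pytest.approx(amp_o, abs=1e-6)
        assert fit.acrotime == pytest.approx(acro_o, abs=1e-6)


# ---------------------------------------------------------------------------
# IS / IV
# ---------------------------------------------------------------------------


class TestNonparametricRar:
    def test_repeating_profile_has_unit_stability(self):
        rng = np.random.default_rng(0)
        profile = rng.uniform(0, 100, 24)
        assert interdaily_stability(np.tile(profile, (7, 1))) == pytest.approx(1.0)

    def test_iid_noise_stability_approaches_one_over_days(self):
        rng = np.random.default_rng(1)
        vals = [interdaily_stability(rng.normal(size=(7, 24))) for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(1 / 7, abs=0.01)

    def test_hourly_cosine_variability_closed_form(self):
        n = 7 * 24
        x = np.cos(2 * np.pi * np.arange(n) / 24)
        # brute-force evaluation of the defining formula
        expected = n * np.sum(np.diff(x) ** 2) / ((n - 1) * np.sum((x - x.mean()) ** 2))
        iv = intradaily_variability(x)
        assert iv == pytest.approx(expected, rel=1e-12)
        assert iv == pytest.approx(2 * (1 - np.cos(np.pi / 12)) * n / (n - 1), rel=0.01)

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(interdaily_stability(np.ones((3, 24))))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(intradaily_variability(np.ones(72)))

    def test_missing_hours_are_skipped_in_differences(self):
        x = np.cos(2 * np.pi * np.arange(96) / 24)
        gap = x.copy()
        gap[40] = np.nan
        # removing one interior hour removes its two adjacent differences
        assert np.isfinite(intradaily_variability(gap))


# ---------------------------------------------------------------------------
# M10 / L5 / relative amplitude
# ---------------------------------------------------------------------------


class TestM10L5:
    def test_rectangular_profile(self, make_series):
        # 100 mg for 12 h from 08:00, 0 otherwise, over 3 days
        enmo = np.zeros(1440 * 3)
        clock = (np.arange(1440 * 3) / 60.0) % 24  # starts at midnight
        enmo[(clock >= 8) & (clock < 20)] = 100.0
        series = make_series(enmo, start="2022-06-01T00:00:00")
        res = m10_l5(series)
        assert res["M10_mean"] == pytest.approx(100.0)
        assert res["L5_mean"] == pytest.approx(0.0)
        assert relative_amplitude(res["M10_mean"], res["L5_mean"]) == 1.0

    def test_constant_day_gives_zero_relative_amplitude(self, make_series):
        series = make_series(np.full(1440 * 2, 50.0), start="2022-06-01T00:00:00")
        res = m10_l5(series)
        assert res["M10_mean"] == res["L5_mean"] == pytest.approx(50.0)
        assert relative_amplitude(res["M10_mean"], res["L5_mean"]) == 0.0

    def test_matches_exhaustive_window_search(self, make_series):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 120, 1440)
        m_series = make_series(x, start="2022-06-01T00:00:00")
        res = m10_l5(m_series)
        w = 600
        means = np.array([x[j:j + w].mean() for j in range(1440 - w + 1)])
        j = int(np.argmax(means))
        assert res["M10_mean"] == pytest.approx(means[j], rel=1e-12)
        assert res["M10_start"] == pytest.approx(j / 60.0, abs=1e-9)
        l_series = make_series(x, start="2022-06-01T12:00:00")
        res_l = m10_l5(l_series)
        w = 300
        means = np.array([x[j:j + w].mean() for j in range(1440 - w + 1)])
        j = int(np.argmin(means))
        assert res_l["L5_mean"] == pytest.approx(means[j], rel=1e-12)
        assert res_l["L5_start"] == pytest.approx(
            noon_anchored_hour((12 + j / 60.0) % 24), abs=1e-9)

    def test_relative_amplitude_identities(self):
        assert relative_amplitude(30, 10) == pytest.approx(0.5)
        assert relative_amplitude(42, 42) == 0.0
        assert relative_amplitude(17, 0) == 1.0
        with pytest.warns(UserWarning):
            assert np.isnan(relative_amplitude(0, 0))


# ---------------------------------------------------------------------------
# intensity states, bouts, transitions, intensity gradient
# ---------------------------------------------------------------------------


class TestStatesAndBouts:
    def test_intensity_thresholds(self):
        assert classify_intensity(np.array([10.0]))[0] == 0
        assert classify_intensity(np.array([50.0]))[0] == 1
        assert classify_intensity(np.array([250.0]))[0] == 2
        # boundaries: SB iff < 30; MVPA iff >= 100
        assert classify_intensity(np.array([30.0]))[0] == 1
        assert classify_intensity(np.array([100.0]))[0] == 2

    def test_bout_example(self):
        states = np.array([1, 1, 1, 0, 0, 1, 0])  # A A A S S A S
        total, n, mean = bout_stats(states, 1)
        assert (total, n, mean) == (4, 2, 2.0)

    def test_absent_state_convention(self):
        assert bout_stats(np.array([0, 0]), 1) == (0, 0, 0.0)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=60),
           st.integers(1, 4))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bouts_match_run_length_oracle(self, seq, min_len):
        states = np.array(seq)
        runs = []
        current, length = None, 0
        for s in list(seq) + [None]:
            if s == current:
                length += 1
            else:
                if current == 1 and length >= min_len:
                    runs.append(length)
                current, length = s, 1
        expected = (sum(runs), len(runs),
                    float(np.mean(runs)) if runs else 0.0)
        assert bout_stats(states, 1, min_len) == expected

    def test_transition_example(self):
        states = np.array([1, 1, 1, 0, 0, 1, 0])
        assert transition_prob(states, 1, 0) == pytest.approx(0.5)

    def test_all_from_state_gives_zero(self):
        assert transition_prob(np.ones(10, int), 1, 0) == 0.0

    def test_empty_from_set_missing(self):
        assert np.isnan(transition_prob(np.zeros(5, int), 1, 0))

    @given(st.lists(st.integers(0, 1), min_size=2, max_size=80))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_reciprocal_mean_bout_identity(self, seq):
        # when the sequence ends in the to-state, every from-bout ends with
        # a transition, so TP = n_bouts / n_from = 1 / mean bout length
        seq = seq + [0]
        states = np.array(seq)
        if not (states == 1).any():
            return
        tp = transition_prob(states, 1, 0)
        _, n, mean = bout_stats(states, 1)
        assert tp == pytest.approx(1.0 / mean)


class TestIntensityGradient:
    def test_powerlaw_histogram_exact(self):
        # minutes per bin proportional to midpoint^-2: 225/25/9 epochs in
        # the first three 25-mg bins (60-s epochs, so minutes == counts)
        enmo = np.concatenate([
            np.full(225, 12.5), np.full(25, 37.5), np.full(9, 62.5)])
        intercept, slope = intensity_gradient(enmo, epoch_len_s=60)
        assert slope == pytest.approx(-2.0, abs=1e-12)
        assert intercept == pytest.approx(np.log(225 * 12.5**2), abs=1e-9)

    def test_single_bin_is_error_path(self):
        with pytest.warns(UserWarning, match="non-empty"):
            intercept, slope = intensity_gradient(np.full(100, 10.0), 60)
        assert np.isnan(intercept) and np.isnan(slope)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(5)
        enmo = rng.gamma(1.2, 40, 5000)
        intercept, slope = intensity_gradient(enmo, epoch_len_s=60)
        edges = np.arange(0, 4025, 25.0)
        counts, _ = np.histogram(np.clip(enmo, 0, 4000 - 1e-9), edges)
        keep = counts > 0
        lx = np.log((edges[:-1] + 12.5)[keep])
        ly = np.log(counts[keep] * 1.0)
        b = np.sum((lx - lx.mean()) * (ly - ly.mean())) / np.sum((lx - lx.mean()) ** 2)
        a = ly.mean() - b * lx.mean()
        assert slope == pytest.approx(b, rel=1e-9)
        assert intercept == pytest.approx(a, rel=1e-9)
        assert slope < 0  # decreasing histogram


# ---------------------------------------------------------------------------
# full-path toys: sleep metrics, chronotype, assembly
# ---------------------------------------------------------------------------


def _toy_participant(wake_block=None, onset_min=600, wake_min=1080, n_days=7):
    """Waking 60 mg, sleep (22:00-06:00) zero, optional nightly wake block.

    ``wake_block=(start_min_into_day, length_min, level_mg)``.
    """
    n = 1440 * n_days
    enmo = np.full(n, 60.0)
    rows = []
    start = np.datetime64("2022-06-01T12:00:00", "s")
    for d in range(n_days):
        a, b = d * 1440 + onset_min, d * 1440 + wake_min
        enmo[a:b] = 0.0
        if wake_block is not None:
            s, length, level = wake_block
            enmo[d * 1440 + s: d * 1440 + s + length] = level
        rows.append({
            "participant_id": "P0", "night_index": d,
            "onset_time": pd.Timestamp(start + np.timedelta64(a * 60, "s")),
            "wake_time": pd.Timestamp(start + np.timedelta64(b * 60, "s")),
        })
    series = EpochSeries("P0", start, 60, enmo, np.ones(n, bool))
    return series, pd.DataFrame(rows)


class TestSleepAndChronotypeToys:
    def test_efficiency_and_waso_arithmetic(self):
        # 8-h sleep period with a 48-min wake block: 7.2 h sleep,
        # efficiency 0.9, WASO 48 min, one wake bout of 48 min
        series, diary = _toy_participant(wake_block=(840, 48, 100.0))
        m, diag = participant_metrics(series, diary, sleep_mode="diary")
        assert diag["included"]
        assert m["sleep_duration"] == pytest.approx(7.2)
        assert m["sleep_efficiency"] == pytest.approx(0.9)
        assert m["WASO"] == pytest.approx(48.0)
        assert m["mean_wake_bout_min"] == pytest.approx(48.0)
        assert m["TP_sw_n"] == pytest.approx(1 / 432, rel=1e-9)

    def test_all_sleep_night(self):
        series, diary = _toy_participant()
        m, _ = participant_metrics(series, diary, sleep_mode="diary")
        assert m["sleep_efficiency"] == pytest.approx(1.0)
        assert m["WASO"] == 0.0
        assert m["mean_wake_bout_min"] == 0.0
        assert m["sleep_duration"] + m["WASO"] / 60 == pytest.approx(8.0)

    def test_constant_onset_chronotype(self):
        series, diary = _toy_participant(onset_min=630)  # 22:30 nightly
        m, _ = participant_metrics(series, diary, sleep_mode="diary")
        assert m["sleep_onset_time"] == pytest.approx(22.5, abs=0.02)

    def test_past_midnight_onsets_average_on_noon_scale(self):
        # alternate onsets 23:00 and 01:00 -> mean midnight (24.0), not 12:00
        series, diary = _toy_participant()
        n = series.n_epochs
        enmo = np.full(n, 60.0)
        rows = []
        start = series.start
        for d in range(7):
            onset_min = 660 if d % 2 == 0 else 780  # 23:00 / 01:00
            a, b = d * 1440 + onset_min, d * 1440 + onset_min + 420
            enmo[a:b] = 0.0
            rows.append({
                "participant_id": "P0", "night_index": d,
                "onset_time": pd.Timestamp(start + np.timedelta64(a * 60, "s")),
                "wake_time": pd.Timestamp(start + np.timedelta64(b * 60, "s")),
            })
        series2 = EpochSeries("P0", start, 60, enmo, np.ones(n, bool))
        m, _ = participant_metrics(series2, pd.DataFrame(rows), sleep_mode="diary")
        assert m["sleep_onset_time"] == pytest.approx(24.0, abs=0.02)

    def test_noon_anchored_mean_matches_circular_mean(self):
        rng = np.random.default_rng(9)
        hours = (24.0 + rng.uniform(-3, 3, 500)) % 24  # clustered at midnight
        anchored = [noon_anchored_hour(h) for h in hours]
        ang = 2 * np.pi * hours / 24
        circ = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))) / (2 * np.pi) * 24
        circ = noon_anchored_hour(circ % 24)
        assert np.mean(anchored) == pytest.approx(circ, abs=2 / 60)


class TestAssembly:
    def test_metric_vector_has_36_named_fields(self):
        series, diary = _toy_participant(wake_block=(840, 48, 100.0))
        m, _ = participant_metrics(series, diary, sleep_mode="diary")
        assert list(m.index) == METRIC_NAMES
        assert len(m) == 36

    def test_dimension_partition(self):
        sizes = {k: len(v) for k, v in METRIC_DIMENSIONS.items()}
        assert sizes == {"RAR": 6, "daytime": 15, "sleep": 10, "chronotype": 5}

    def test_no_mvpa_participant_gets_zero_bout_fields(self):
        # constant 60 mg waking: LIPA only, so MVPA bout fields are 0 and
        # the rest->activity transition (no SB epochs) is missing-by-rule
        series, diary = _toy_participant()
        m, _ = participant_metrics(series, diary, sleep_mode="diary")
        assert m["MVPA_total_min"] == 0.0
        assert m["MVPA_n_bouts"] == 0.0
        assert m["MVPA_mean_bout_min"] == 0.0
        assert np.isnan(m["TP_ra_d"])
        assert m["TP_ar_d"] == 0.0  # LIPA present, never leaves to SB

    def test_intensity_durations_conserve_waking_time(self):
        spec = ArchetypeSpec(
            name="mixed", mesor_log=2.5, amp_log=0.5, acrophase_h=14.0,
            sleep_onset_h=23.0, sleep_dur_h=8.0, frag_rate=1.0,
        )
        series, diary, _ = simulate_participant(spec, seed=4)
        m, _ = participant_metrics(series, diary, sleep_mode="diary")
        total = m["SB_total_min"] + m["LIPA_total_min"] + m["MVPA_total_min"]
        waking_min = np.mean([
            (row["onset_time"] - diary.iloc[i]["wake_time"]).total_seconds() / 60
            for i, row in diary.iloc[1:].reset_index(drop=True).iterrows()
        ])
        assert total == pytest.approx(waking_min, abs=1.0)

    def test_excluded_participant_is_all_missing_with_reason(self, make_series):
        series = make_series(np.full(1440 * 2, 50.0))
        m, diag = participant_metrics(series, None, sleep_mode="algorithmic")
        assert m.isna().all()
        assert not diag["included"]


def test_planted_parameters_recovered_from_metrics():
    """Simulator-planted acrophase, sleep duration and fragmentation are
    visible in the corresponding metrics."""
    spec = ArchetypeSpec(
        name="probe", mesor_log=2.5, amp_log=0.7, acrophase_h=15.0,
        sleep_onset_h=23.0, sleep_dur_h=7.5, onset_sd_h=0.2, dur_sd_h=0.2,
        frag_rate=3.0, restlessness_mg=60.0,
    )
    rows = []
    for seed in range(8):
        series, diary, _ = simulate_participant(spec, seed=seed)
        m, _ = participant_metrics(series, diary, sleep_mode="diary")
        rows.append(m)
    avg = pd.DataFrame(rows).mean()
    assert abs(avg["acrotime"] - 15.0) < 1.0
    # sleep + WASO reconstructs the planted sleep-period duration
    assert abs(avg["sleep_duration"] + avg["WASO"] / 60 - 7.5) < 0.3
    # wake bouts per sleep hour track frag_rate (restlessness above the
    # wake threshold); generous band: bout merging and clipping bias down
    wake_bouts_per_h = avg["WASO"] / avg["mean_wake_bout_min"] / avg["sleep_duration"]
    assert 1.5 < wake_bouts_per_h < 4.0
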