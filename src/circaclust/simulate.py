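"""Synthetic accelerometer cohorts with known circadian structure.

Every downstream stage of the pipeline (ingest, sleep detection, metric
extraction, clustering, association models) can be exercised against ground
truth because the generator plants the quantities the metrics estimate:

* a 24-h cosinor envelope modulating waking activity,
* a three-state (SB / LIPA / MVPA) semi-Markov waking process with
  geometric dwell times and lognormal emission noise,
* a nocturnal sleep period with night-to-night jitter, Poisson wake bouts
  and lognormal "restlessness" movement,
* chronotype offsets, optional non-wear gaps, per-night diaries,
  covariates with archetype shifts, and exponential survival times tied to
  a per-archetype log-hazard.

Nights are indexed noon-to-noon: the simulated record starts at 12:00 so
that every scheduled sleep period falls inside one noon-anchored block and
past-midnight onsets need no wrap-around handling (onset clock hours may
exceed 24).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import EpochSeries

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "CohortBundle",
    "DEFAULT_ARCHETYPES",
    "default_archetypes",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort",
    "triaxial_from_epochs",
    "survival_from_risk",
]

_STATES = ("SB", "LIPA", "MVPA")
_SEASONS = ("winter", "spring", "summer", "autumn")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one behavioural circadian phenotype.

    ``mesor_log``/``amp_log``/``acrophase_h`` define the cosinor envelope of
    waking activity on the log scale; sleep timing is drawn per night from
    ``sleep_onset_h`` (clock hours, values above 24 denote past-midnight
    onsets) and ``sleep_dur_h`` with Gaussian jitter. ``frag_rate`` is the
    expected number of wake bouts per sleep hour; ``restlessness_mg`` the
    mean ENMO emitted during those bouts. The waking process mixes SB, LIPA
    and MVPA with entry weights ``state_entry_probs`` and mean dwell times
    ``state_dwell_min`` (minutes). ``hazard_log_ratio`` scales the
    participant's mortality hazard in the survival simulation.
    """

    name: str
    mesor_log: float
    amp_log: float
    acrophase_h: float
    sleep_onset_h: float
    sleep_dur_h: float
    onset_sd_h: float = 0.5
    dur_sd_h: float = 0.5
    frag_rate: float = 1.0
    restlessness_mg: float = 10.0
    state_dwell_min: Tuple[float, float, float] = (15.0, 9.0, 5.0)
    state_entry_probs: Tuple[float, float, float] = (0.5, 0.38, 0.12)
    sb_mg: float = 10.0
    lipa_mg: float = 50.0
    mvpa_mg: float = 150.0
    hazard_log_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.amp_log < 0:
            raise ValueError("amp_log must be non-negative")
        if not 0 <= self.acrophase_h < 24:
            raise ValueError("acrophase_h must lie in [0, 24)")
        if not 2.0 < self.sleep_dur_h < 14.0:
            raise ValueError("sleep_dur_h must lie in (2, 14) hours")
        if self.frag_rate < 0:
            raise ValueError("frag_rate must be non-negative")
        probs = np.asarray(self.state_entry_probs, float)
        if probs.shape != (3,) or probs.min() < 0 or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("state_entry_probs must be 3 non-negative weights summing to 1")
        if not self.sb_mg < self.lipa_mg < self.mvpa_mg:
            raise ValueError("require sb_mg < lipa_mg < mvpa_mg")
        if min(self.state_dwell_min) <= 0:
            raise ValueError("state dwell means must be positive")


def default_archetypes(n: int = 9) -> List[ArchetypeSpec]:
    """Return ``n`` (4 or 9) well-separated default archetypes.

    The nine defaults loosely shadow the kinds of phenotype a behavioural
    circadian clustering distinguishes (robust vs poor rest-activity
    rhythm, high vs low daytime activity, short/fragmented vs long/
    efficient sleep, delayed chronotype, restless sleep). The 4-archetype
    set is a maximally distinct subset used for quick recovery checks.
    """
    if n == 4:
        keep = ("robust_active", "late_chronotype", "restless_sleep", "very_low_active")
        return [a for a in DEFAULT_ARCHETYPES if a.name in keep]
    if n == 9:
        return list(DEFAULT_ARCHETYPES)
    raise ValueError("default archetype sets exist for n in {4, 9}")


DEFAULT_ARCHETYPES: Tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec(
        "robust_active", 2.8, 0.9, 14.0, 22.8, 7.8, 0.4, 0.4, 0.8, 8.0,
        (12.0, 10.0, 6.0), (0.40, 0.42, 0.18), 12.0, 55.0, 170.0, 0.0),
    ArchetypeSpec(
        "robust_short_sleep", 2.6, 0.7, 14.5, 24.3, 6.0, 0.5, 0.5, 3.0, 18.0,
        (14.0, 9.0, 4.0), (0.48, 0.40, 0.12), 11.0, 52.0, 150.0, 0.15),
    ArchetypeSpec(
        "robust_good_sleep", 2.6, 0.7, 14.0, 22.5, 8.4, 0.4, 0.4, 0.6, 6.0,
        (13.0, 10.0, 4.0), (0.47, 0.42, 0.11), 11.0, 50.0, 140.0, 0.10),
    ArchetypeSpec(
        "mvpa_high", 2.7, 0.55, 13.5, 23.2, 7.4, 0.5, 0.5, 1.2, 10.0,
        (14.0, 8.0, 9.0), (0.46, 0.33, 0.21), 12.0, 55.0, 200.0, 0.05),
    ArchetypeSpec(
        "late_chronotype", 2.4, 0.35, 17.5, 27.0, 7.6, 0.7, 0.5, 1.8, 12.0,
        (16.0, 9.0, 4.0), (0.55, 0.36, 0.09), 10.0, 48.0, 135.0, 0.35),
    ArchetypeSpec(
        "low_active_good_sleep", 2.3, 0.35, 14.0, 22.8, 8.6, 0.5, 0.5, 0.8, 7.0,
        (20.0, 8.0, 3.0), (0.62, 0.32, 0.06), 9.0, 45.0, 125.0, 0.40),
    ArchetypeSpec(
        "low_active_poor_sleep", 2.3, 0.30, 14.5, 23.8, 5.4, 0.7, 0.6, 4.5, 22.0,
        (20.0, 8.0, 3.0), (0.63, 0.31, 0.06), 9.0, 45.0, 125.0, 0.55),
    ArchetypeSpec(
        "restless_sleep", 2.5, 0.40, 14.0, 23.3, 6.8, 0.5, 0.5, 5.5, 70.0,
        (15.0, 9.0, 5.0), (0.50, 0.38, 0.12), 11.0, 52.0, 150.0, 0.45),
    ArchetypeSpec(
        "very_low_active", 2.1, 0.15, 15.0, 25.5, 7.2, 0.8, 0.7, 3.5, 15.0,
        (28.0, 7.0, 2.0), (0.74, 0.23, 0.03), 8.0, 40.0, 115.0, 0.90),
)

# Covariate shifts per archetype: (age years, P(female) shift, BMI kg/m2).
_DEFAULT_COV_EFFECTS: Dict[str, Tuple[float, float, float]] = {
    "robust_active": (-2.0, 0.03, -1.5),
    "robust_short_sleep": (0.0, 0.0, 0.3),
    "robust_good_sleep": (-0.5, 0.05, -0.5),
    "mvpa_high": (-2.5, -0.10, -1.0),
    "late_chronotype": (-1.0, 0.0, 0.5),
    "low_active_good_sleep": (1.5, 0.0, 0.5),
    "low_active_poor_sleep": (1.5, -0.02, 1.0),
    "restless_sleep": (-0.5, -0.05, 0.3),
    "very_low_active": (3.5, 0.02, 2.5),
}


@dataclass
class CohortConfig:
    """Configuration of one simulated cohort."""

    n_participants: int
    archetypes: Sequence[ArchetypeSpec] = field(default_factory=lambda: list(DEFAULT_ARCHETYPES))
    archetype_weights: Optional[Sequence[float]] = None
    n_days: int = 7
    epoch_len_s: int = 60
    nonwear_prob: float = 0.1
    seed: int = 0
    noise_sd: float = 0.3
    covariate_effects: Optional[Dict[str, Tuple[float, float, float]]] = None
    baseline_hazard: float = 0.008  # events per person-year
    horizon_years: float = 12.0
    start_date: str = "2022-06-01"

    def __post_init__(self) -> None:
        if self.n_days < 5:
            raise ValueError("n_days must be at least 5")
        if 3600 % int(self.epoch_len_s) != 0:
            raise ValueError("epoch_len_s must divide 3600")
        if self.archetype_weights is None:
            k = len(self.archetypes)
            self.archetype_weights = [1.0 / k] * k
        w = np.asarray(self.archetype_weights, float)
        if w.shape != (len(self.archetypes),) or w.min() < 0 or abs(w.sum() - 1) > 1e-9:
            raise ValueError("archetype_weights must match archetypes and sum to 1")
        if not 0 <= self.nonwear_prob <= 1:
            raise ValueError("nonwear_prob must be a probability")


@dataclass
class CohortBundle:
    """Simulated cohort: epochs, diaries, covariates, survival, truth."""

    epochs: Dict[str, EpochSeries]
    diaries: pd.DataFrame
    covariates: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.Series  # participant_id -> archetype name
    config: Optional[CohortConfig] = None

    def participant_ids(self) -> List[str]:
        return list(self.epochs)


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    """Counter-scheme child RNG: SeedSequence(master, spawn_key=(index,))."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean."""
    if mean <= 0:
        return np.zeros(size)
    if sigma <= 0:
        return np.full(size, mean)
    return np.exp(rng.normal(np.log(mean) - 0.5 * sigma**2, sigma, size))


def simulate_participant(
    spec: ArchetypeSpec,
    n_days: int = 7,
    epoch_len_s: int = 60,
    seed: int | np.random.Generator = 0,
    *,
    participant_id: str = "P0",
    noise_sd: float = 0.3,
    start_date: str = "2022-06-01",
    normalize_envelope: bool = True,
    wake_bout_mean_min: float = 5.0,
) -> Tuple[EpochSeries, pd.DataFrame, Dict[str, float]]:
    """Simulate one participant's multi-day epoch record.

    The record starts at noon of ``start_date`` and covers ``n_days`` full
    24-h noon-to-noon blocks, each containing one scheduled sleep period.
    Returns the epoch series, a per-night diary table, and a ground-truth
    dict echoing the planted parameters.

    With ``normalize_envelope=True`` (default) the cosinor envelope
    ``exp(mesor_log + amp_log*cos(2*pi*(t-acrophase)/24))`` is rescaled to
    mean 1 over waking epochs so that the state means (``sb_mg`` etc.) are
    the realised waking intensity levels; with ``False`` the raw envelope
    multiplies the emissions, which makes the planted mesor directly
    recoverable from a cosinor fit of the log signal.
    """
    if n_days < 5:
        raise ValueError("n_days must be at least 5")
    if spec.sleep_dur_h >= 24:
        raise ValueError("degenerate spec: sleep_dur_h must be < 24")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    epochs_per_day = 86400 // epoch_len_s
    n = n_days * epochs_per_day
    dt_h = epoch_len_s / 3600.0
    start = np.datetime64(f"{start_date}T12:00:00", "s")
    hours = np.arange(n) * dt_h  # hours since noon of day 0
    clock = (12.0 + hours) % 24.0

    # --- nightly sleep schedule (noon-anchored; onset may pass midnight) ---
    onset_clock = rng.normal(spec.sleep_onset_h, spec.onset_sd_h, n_days)
    dur = np.clip(rng.normal(spec.sleep_dur_h, spec.dur_sd_h, n_days), 2.05, 13.95)
    onset_abs = 24.0 * np.arange(n_days) + (onset_clock - 12.0)  # h since start
    wake_abs = onset_abs + dur
    # keep each night inside its noon-to-noon block
    onset_abs = np.clip(onset_abs, 24.0 * np.arange(n_days) + 0.5, None)
    wake_abs = np.minimum(wake_abs, 24.0 * (np.arange(n_days) + 1) - 0.25)

    sleep_mask = np.zeros(n, dtype=bool)
    onset_idx = np.ceil(onset_abs / dt_h - 1e-9).astype(int)
    wake_idx = np.ceil(wake_abs / dt_h - 1e-9).astype(int)
    for a, b in zip(onset_idx, wake_idx):
        sleep_mask[a:b] = True

    enmo = np.zeros(n)

    # --- wake bouts within sleep: Poisson arrivals, exponential lengths ---
    bout_mask = np.zeros(n, dtype=bool)
    if spec.frag_rate > 0:
        for night in range(n_days):
            d = wake_abs[night] - onset_abs[night]
            k = rng.poisson(spec.frag_rate * d)
            if k == 0:
                continue
            starts = onset_abs[night] + rng.uniform(0, d, k)
            lengths = rng.exponential(wake_bout_mean_min / 60.0, k)
            for s, length in zip(starts, lengths):
                a = int(s / dt_h)
                b = min(int(np.ceil((s + length) / dt_h)), wake_idx[night])
                bout_mask[a:max(b, a + 1)] = True
    bout_mask &= sleep_mask
    n_bout = int(bout_mask.sum())
    if n_bout:
        enmo[bout_mask] = _lognormal_mean(rng, spec.restlessness_mg, noise_sd, n_bout)

    # --- waking semi-Markov chain over SB/LIPA/MVPA ---
    dwell_epochs = np.maximum(np.asarray(spec.state_dwell_min) * 60.0 / epoch_len_s, 1.0)
    probs = np.asarray(spec.state_entry_probs, float)
    mean_dwell = float(probs @ dwell_epochs)
    states = np.empty(0, dtype=np.int8)
    while states.size < n:
        m = int((n - states.size) / mean_dwell * 1.5) + 16
        runs = rng.choice(3, size=m, p=probs).astype(np.int8)
        lens = rng.geometric(1.0 / dwell_epochs[runs])
        states = np.concatenate([states, np.repeat(runs, lens)])
    states = states[:n]

    wake_epochs = ~sleep_mask
    state_mg = np.array([spec.sb_mg, spec.lipa_mg, spec.mvpa_mg])
    env = np.exp(spec.mesor_log + spec.amp_log * np.cos(2 * np.pi * (clock - spec.acrophase_h) / 24.0))
    if normalize_envelope:
        env = env / env[wake_epochs].mean()
    nw = int(wake_epochs.sum())
    noise = _lognormal_mean(rng, 1.0, noise_sd, nw) if noise_sd > 0 else np.ones(nw)
    enmo[wake_epochs] = state_mg[states[wake_epochs]] * env[wake_epochs] * noise

    series = EpochSeries(
        participant_id=participant_id,
        start=start,
        epoch_len_s=epoch_len_s,
        enmo=enmo,
        wear=np.ones(n, dtype=bool),
    )
    # diary reports the realised, epoch-aligned sleep boundaries
    ep = np.timedelta64(epoch_len_s, "s")
    diary = pd.DataFrame(
        {
            "participant_id": participant_id,
            "night_index": np.arange(n_days),
            "onset_time": [start + int(i) * ep for i in onset_idx],
            "wake_time": [start + int(i) * ep for i in wake_idx],
        }
    )
    truth = {
        "archetype": spec.name,
        "amp_log": spec.amp_log,
        "acrophase_h": spec.acrophase_h,
        "mean_sleep_dur_h": float(dur.mean()),
        "frag_rate": spec.frag_rate,
        "n_wake_bout_epochs": n_bout,
    }
    return series, diary, truth


def _inject_nonwear(series: EpochSeries, rng: np.random.Generator) -> None:
    """Zero out one daytime gap of 1-6 h and clear its wear flags."""
    dur_h = rng.uniform(1.0, 6.0)
    n_gap = int(dur_h * 3600 / series.epoch_len_s)
    start_idx = rng.integers(0, max(series.n_epochs - n_gap, 1))
    series.wear[start_idx:start_idx + n_gap] = False
    series.enmo[start_idx:start_idx + n_gap] = 0.0


def survival_from_risk(
    log_hazard_ratio: np.ndarray,
    rng: np.random.Generator,
    baseline_hazard: float = 0.008,
    horizon_years: float = 12.0,
) -> pd.DataFrame:
    """Exponential survival times with administrative censoring.

    Participant hazard is ``baseline_hazard * exp(log_hazard_ratio)``;
    follow-up is censored at ``horizon_years``.
    """
    lhr = np.asarray(log_hazard_ratio, float)
    rate = baseline_hazard * np.exp(lhr)
    t = rng.exponential(1.0 / rate)
    event = t <= horizon_years
    return pd.DataFrame({"time_years": np.minimum(t, horizon_years), "event": event.astype(int)})


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate a cohort of participants mixing the configured archetypes."""
    master = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2**20,)))
    n = config.n_participants
    labels = master.choice(len(config.archetypes), size=n, p=np.asarray(config.archetype_weights))

    cov_effects = config.covariate_effects or _DEFAULT_COV_EFFECTS
    epochs: Dict[str, EpochSeries] = {}
    diaries = []
    truth = {}
    ages, sexes, bmis, seasons = [], [], [], []
    lhr = np.empty(n)
    width = max(4, len(str(n)))
    for i in range(n):
        rng = _participant_rng(config.seed, i)
        spec = config.archetypes[labels[i]]
        pid = f"P{i:0{width}d}"
        series, diary, _ = simulate_participant(
            spec,
            n_days=config.n_days,
            epoch_len_s=config.epoch_len_s,
            seed=rng,
            participant_id=pid,
            noise_sd=config.noise_sd,
            start_date=config.start_date,
        )
        if rng.uniform() < config.nonwear_prob:
            _inject_nonwear(series, rng)
        epochs[pid] = series
        diaries.append(diary)
        truth[pid] = spec.name
        d_age, d_sex, d_bmi = cov_effects.get(spec.name, (0.0, 0.0, 0.0))
        ages.append(rng.normal(68.0 + d_age, 4.0))
        sexes.append(int(rng.uniform() < min(max(0.5 + d_sex, 0.0), 1.0)))
        bmis.append(rng.normal(26.5 + d_bmi, 3.5))
        seasons.append(_SEASONS[int(rng.integers(4))])
        lhr[i] = spec.hazard_log_ratio

    pids = list(epochs)
    covariates = pd.DataFrame(
        {
            "participant_id": pids,
            "age": np.round(ages, 1),
            "female": sexes,
            "bmi": np.round(bmis, 1),
            "season": seasons,
        }
    )
    surv_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2**20 + 1,)))
    survival = survival_from_risk(
        lhr, surv_rng, config.baseline_hazard, config.horizon_years
    )
    survival.insert(0, "participant_id", pids)
    return CohortBundle(
        epochs=epochs,
        diaries=pd.concat(diaries, ignore_index=True) if diaries else pd.DataFrame(
            columns=["participant_id", "night_index", "onset_time", "wake_time"]
        ),
        covariates=covariates,
        survival=survival,
        truth=pd.Series(truth, name="archetype"),
        config=config,
    )


def triaxial_from_epochs(
    series: EpochSeries, fs_hz: int = 20
) -> Tuple[np.ndarray, int]:
    """Raw-mode emitter: triaxial samples whose vector magnitude reproduces
    the target ENMO (gravity on the z axis). Exists to exercise the raw
    ingestion path; not a physiological accelerometer model."""
    mag = 1.0 + np.repeat(series.enmo, fs_hz * series.epoch_len_s) / 1000.0
    samples = np.zeros((mag.size, 3))
    samples[:, 2] = mag
    return samples, fs_hz


def write_cohort(bundle: CohortBundle, directory) -> Dict[str, Path]:
    """Write a cohort to delimited text files that round-trip via ingest.

    Produces ``epochs.csv`` (long format), ``diary.csv``,
    ``covariates.csv``, ``survival.csv`` and ``truth.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / f"{name}.csv"
             for name in ("epochs", "diary", "covariates", "survival", "truth")}

    frames = []
    for pid, series in bundle.epochs.items():
        frame = pd.DataFrame(
            {
                "participant_id": pid,
                "timestamp": pd.to_datetime(series.times()),
                "enmo_mg": series.enmo,
                "wear": series.wear.astype(int),
            }
        )
        if series.lux_hi is not None:
            frame["lux_hi"] = series.lux_hi.astype(int)
        frames.append(frame)
    if frames:
        long = pd.concat(frames, ignore_index=True)
    else:
        long = pd.DataFrame(columns=["participant_id", "timestamp", "enmo_mg", "wear"])
    long.to_csv(paths["epochs"], index=False)

    bundle.diaries.to_csv(paths["diary"], index=False)
    bundle.covariates.to_csv(paths["covariates"], index=False)
    bundle.survival.to_csv(paths["survival"], index=False)
    bundle.truth.rename_axis("participant_id").to_frame().to_csv(paths["truth"])
    return paths
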