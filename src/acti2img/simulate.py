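"""Seeded synthetic actigraphy cohorts with realistic group contrasts.

The generator emulates the qualitative structure of wrist-actigraphy count
data from depression/schizophrenia case-control studies: non-negative
integer counts at one-minute epochs, multi-day recordings, a circadian
day/night profile, overdispersed (negative-binomial-like) count noise, and
a condition group whose activity has a lower daytime mean, extra
zero-activity runs and sparse high-amplitude bursts - hence a heavier
right tail (higher sample skewness) than controls.

Background intensity for a participant with daytime amplitude ``A``::

    lambda(t) = A * max(0, sin(2*pi*(t - t_rise) / 1440))        (daytime)
    lambda(t) = night_baseline_frac * A                          (night)

Counts are Poisson draws with a gamma-mixed rate (negative-binomial
behaviour; ``dispersion`` is the gamma shape, smaller = noisier).  Night
epochs are then zeroed with probability ``night_zero_prob`` (sleep
stillness).  Condition participants additionally get daytime "rest
episodes" (runs of zero activity, psychomotor retardation) and sparse
bursts of very high counts at any hour (agitation / fragmented sleep);
bursts are applied after night zeroing because they represent actual
movement events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .io import ActigraphyRecording, CohortManifest, Group

MINUTES_PER_DAY = 1440


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Amplitudes are mean daytime counts at the circadian peak; rates are
    events per day; durations are in minutes.
    """

    n_condition: int = 30
    n_control: int = 30
    days_per_participant: int = 3
    amplitude_control: float = 300.0
    amplitude_condition: float = 120.0
    night_zero_prob: float = 0.9
    burst_rate_condition: float = 20.0
    dispersion: float = 5.0
    seed: int = 42
    # secondary shape parameters
    t_rise: int = 360  # minute of day when activity rises (06:00)
    night_baseline_frac: float = 0.05
    burst_magnitude: float = 4.0  # burst mean as multiple of amplitude_condition
    burst_duration_mean: float = 10.0
    rest_rate_condition: float = 6.0
    rest_duration_mean: float = 40.0
    start: str = "2020-03-02 00:00:00"

    def __post_init__(self) -> None:
        if self.n_condition < 0 or self.n_control < 0:
            raise ValueError("participant counts must be non-negative")
        if self.days_per_participant < 1:
            raise ValueError("days_per_participant must be >= 1")
        if self.amplitude_control < 0 or self.amplitude_condition < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.amplitude_condition > self.amplitude_control:
            raise ValueError("amplitude_condition must be <= amplitude_control")
        if not 0.0 <= self.night_zero_prob <= 1.0:
            raise ValueError("night_zero_prob must be in [0, 1]")
        if self.burst_rate_condition < 0 or self.rest_rate_condition < 0:
            raise ValueError("event rates must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def participant_seed(config_seed: int, index: int) -> int:
    """Deterministic per-participant seed derived from (cohort seed, index)."""
    ss = np.random.SeedSequence([int(config_seed), int(index)])
    return int(ss.generate_state(1)[0])


def _nb_counts(rng: np.random.Generator, lam: np.ndarray, shape: float) -> np.ndarray:
    """Poisson counts with gamma-mixed rate: mean lam, overdispersed."""
    if shape <= 0:  # pure Poisson limit disabled; shape 0 means no mixing
        return rng.poisson(lam)
    mixed = rng.gamma(shape, lam / shape)
    return rng.poisson(mixed)


def _episode_mask(
    rng: np.random.Generator,
    n: int,
    n_events: int,
    duration_mean: float,
    allowed: np.ndarray | None,
) -> np.ndarray:
    """Boolean mask covering ``n_events`` random episodes of geometric length."""
    mask = np.zeros(n, dtype=bool)
    if n_events <= 0:
        return mask
    if allowed is not None and allowed.any():
        starts = rng.choice(np.flatnonzero(allowed), size=n_events)
    else:
        starts = rng.integers(0, n, size=n_events)
    durations = rng.geometric(1.0 / max(duration_mean, 1.0), size=n_events)
    for s, d in zip(starts, durations):
        mask[s : s + int(d)] = True
    return mask


def simulate_participant(
    group: Group | str,
    config: SimulationConfig,
    participant_seed: int,
    participant_id: str | None = None,
) -> ActigraphyRecording:
    """Simulate one participant's multi-day minute-epoch recording.

    Deterministic given ``(config, participant_seed)``.
    """
    group = Group.coerce(group)
    rng = np.random.default_rng(participant_seed)
    n = config.days_per_participant * MINUTES_PER_DAY
    t = np.arange(n)
    phase = np.sin(2.0 * np.pi * (t - config.t_rise) / MINUTES_PER_DAY)
    day = phase > 0
    amplitude = (
        config.amplitude_condition
        if group is Group.CONDITION
        else config.amplitude_control
    )
    lam = np.where(
        day, amplitude * np.clip(phase, 0.0, None),
        config.night_baseline_frac * amplitude,
    )
    counts = _nb_counts(rng, lam, config.dispersion).astype(np.int64)

    # sleep stillness: zero night epochs with probability night_zero_prob
    night_zero = (~day) & (rng.random(n) < config.night_zero_prob)
    counts[night_zero] = 0

    if group is Group.CONDITION:
        days = config.days_per_participant
        # daytime rest episodes: zero-activity runs (psychomotor retardation)
        n_rest = rng.poisson(config.rest_rate_condition * days)
        rest = _episode_mask(rng, n, n_rest, config.rest_duration_mean, day)
        counts[rest] = 0
        # sparse high-amplitude bursts at any hour -> heavy right tail
        n_bursts = rng.poisson(config.burst_rate_condition * days)
        burst = _episode_mask(rng, n, n_bursts, config.burst_duration_mean, None)
        burst_level = config.burst_magnitude * config.amplitude_condition
        counts[burst] += rng.poisson(burst_level, size=int(burst.sum()))

    start = np.datetime64(config.start, "s")
    timestamps = start + np.arange(n).astype("timedelta64[m]").astype(
        "timedelta64[s]"
    )
    if participant_id is None:
        participant_id = f"{group.value}_{participant_seed & 0xFFFF:05d}"
    return ActigraphyRecording(
        participant_id=participant_id,
        group=group,
        timestamps=timestamps,
        counts=counts,
    )


def simulate_cohort(config: SimulationConfig) -> CohortManifest:
    """Simulate a full cohort; a pure function of ``config``.

    Participant ids are ``condition_00 .. condition_{n-1}`` and
    ``control_00 ..``; per-participant random streams are derived from
    ``config.seed`` and the participant index, so cohorts are bit-identical
    across calls with equal configs.
    """
    total = config.n_condition + config.n_control
    if total < 2 or config.n_condition == 0 or config.n_control == 0:
        raise ValueError(
            "cohort needs at least one condition and one control participant"
        )
    recordings = []
    specs: Iterable[tuple[Group, int]] = [
        (Group.CONDITION, i) for i in range(config.n_condition)
    ] + [(Group.CONTROL, i) for i in range(config.n_control)]
    for index, (grp, within) in enumerate(specs):
        rec = simulate_participant(
            grp,
            config,
            participant_seed(config.seed, index),
            participant_id=f"{grp.value}_{within:02d}",
        )
        recordings.append(rec)
    return CohortManifest(recordings)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=int(seed))
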