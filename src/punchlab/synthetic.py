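"""Seeded, ground-truthed synthetic punch data.

Emulates the study's sensors and cohorts: per-punch 6-channel wrist-IMU
segments (3-axis acceleration, +/-16 g; 3-axis angular rate, +/-2000 deg/s)
with additive Gaussian sensor noise, an air-chamber force-pad curve per punch
rising from onset to a peak force F over rise time t, and cohorts of boxers
with a shared technique template, per-boxer deviations and skill-dependent
quality.  All parameter envelopes are anchored to the published elite
best-punch table (:mod:`punchlab.reference`).

Signal model
------------
Each gyro / off-axis accelerometer channel is a Gaussian-windowed pulse
(amplitude, width and phase from the boxer's technique template, scaled with
punch speed).  The punch-axis acceleration (accelerometer Y, pointing along
the punch) is a half-sine spanning onset to impact whose amplitude is
calibrated so that the trapezoidal integral over the sampled window equals
the true impact speed exactly — the same quadrature the analysis side uses.
The pad force rises monotonically from 0 at onset to F at onset + t: a
near-instant jump to 45 % of peak (so threshold detectors see the onset
sample itself), a slow ramp to the half-peak crossing at 95 % of the rise
time (the impact instant), then a fast final ramp to the peak, followed by
exponential decay.  Rise times and onsets are quantized to the sample grid
so the force maximum falls exactly on a sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .signals import (
    ACCEL_RANGE_G,
    G_TO_MS2,
    GYRO_RANGE_DPS,
    PUNCH_AXIS,
    ForceCurve,
    ImuSegment,
)

logger = logging.getLogger(__name__)

#: Default IMU / pad sampling rate (Hz): a 100-sample window spans 0.2 s,
#: on the order of the observed rise times.
DEFAULT_RATE = 500.0

#: Fraction of the local peak force that defines the impact instant, and the
#: fraction of the rise time at which the generator places that crossing.
IMPACT_FORCE_FRAC = 0.5
IMPACT_RISE_FRAC = 0.95

#: Fraction of peak reached by the near-instant initial force jump.
_JUMP_FRAC = 0.45

#: Skill-to-parameter envelopes.  Chosen so that every elite draw, after the
#: hand asymmetry and per-punch effort/jitter factors, stays inside the
#: published envelopes; the speed ceiling additionally keeps the calibrated
#: punch-axis pulse under the +/-16 g accelerometer range for the shortest
#: elite rise times.
_FORCE_BASE_N = (897.0, 1280.0)
_RISE_BASE_S = (0.152, 0.400)
_SPEED_BASE_MPS = (6.85, 11.50)

#: Left hand is slightly weaker than the right, mirroring the per-hand
#: reference tables.
HAND_MULTIPLIER = {"left": 0.97, "right": 1.0}

#: Default additive sensor noise (sensor units).
ACCEL_NOISE_G = 0.05
GYRO_NOISE_DPS = 5.0
FORCE_NOISE_FRAC = 0.005

#: Fraction of a session labeled best in the generator ground truth.
BEST_FRACTION = 0.05


@dataclass
class TechniqueTemplate:
    """Per-boxer waveform template: one pulse per channel.

    Amplitudes are peak values in sensor units (g or deg/s), widths are
    Gaussian sigmas in seconds, phases are offsets of each channel's pulse
    center relative to the impact instant (negative = before impact).  The
    punch-axis entry is a placeholder: that channel is replaced by the
    speed-calibrated half-sine.
    """

    pulse_amplitudes: np.ndarray
    pulse_widths: np.ndarray
    pulse_phases: np.ndarray
    punch_axis: int = PUNCH_AXIS

    def __post_init__(self) -> None:
        self.pulse_amplitudes = np.asarray(self.pulse_amplitudes, dtype=float)
        self.pulse_widths = np.asarray(self.pulse_widths, dtype=float)
        self.pulse_phases = np.asarray(self.pulse_phases, dtype=float)
        if not (
            self.pulse_amplitudes.shape
            == self.pulse_widths.shape
            == self.pulse_phases.shape
            == (6,)
        ):
            raise ValueError("template needs 6 amplitudes, widths and phases")
        if np.any(self.pulse_widths <= 0):
            raise ValueError("pulse widths must be strictly positive")
        lim = np.array([ACCEL_RANGE_G] * 3 + [GYRO_RANGE_DPS] * 3)
        if np.any(np.abs(self.pulse_amplitudes) > lim):
            raise ValueError("template amplitudes exceed sensor ranges")


def default_template(rng: np.random.Generator | None = None) -> TechniqueTemplate:
    """The shared 'optimal' technique template, optionally perturbed per boxer.

    If ``rng`` is given, amplitudes/widths/phases are jittered by ~10 % to
    give each boxer an individual variant of the common technique.
    """
    amps = np.array([3.0, 8.0, 1.5, 400.0, 250.0, 150.0])
    widths = np.array([0.050, 0.040, 0.040, 0.050, 0.060, 0.050])
    phases = np.array([-0.030, 0.0, -0.020, -0.040, -0.050, -0.030])
    if rng is not None:
        amps = amps * (1.0 + 0.1 * rng.uniform(-1, 1, 6))
        widths = widths * (1.0 + 0.1 * rng.uniform(-1, 1, 6))
        phases = phases + 0.005 * rng.uniform(-1, 1, 6)
    return TechniqueTemplate(amps, widths, phases)


@dataclass
class CohortProfile:
    """Generator-side ground truth for one boxer."""

    boxer_id: str
    skill: float
    template: TechniqueTemplate
    force_scale: float
    rise_time_base: float
    velocity_base: float
    jitter_sd: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError("skill must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        if min(self.force_scale, self.rise_time_base, self.velocity_base) <= 0:
            raise ValueError("scale parameters must be strictly positive")


@dataclass
class GroundTruthPunch:
    """True kinematics of one simulated punch."""

    F_true: float
    t_true: float
    v_true: float
    onset_time: float
    impact_time: float
    peak_time: float
    is_best_true: bool = False
    clipped: bool = False


@dataclass
class SimulatedPunch:
    segment: ImuSegment
    force: ForceCurve
    truth: GroundTruthPunch


@dataclass
class PunchDataset:
    """One simulated session: a list of punches with ground truth attached."""

    punches: list[SimulatedPunch]
    hand: str
    rate: float
    boxer_id: str
    seed: int

    def __len__(self) -> int:
        return len(self.punches)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.punches):
            tr = p.truth
            rows.append(
                {
                    "punch_id": i,
                    "boxer": self.boxer_id,
                    "hand": self.hand,
                    "onset_s": tr.onset_time,
                    "impact_s": tr.impact_time,
                    "F_N": tr.F_true,
                    "t_s": tr.t_true,
                    "v_mps": tr.v_true,
                    "q_p": (tr.F_true / tr.t_true) * tr.v_true,
                    "is_best": tr.is_best_true,
                    "clipped": tr.clipped,
                }
            )
        return pd.DataFrame(rows)


def params_from_skill(u: float) -> tuple[float, float, float]:
    """Map an effective skill u in [0,1] to (force_scale, rise_time_base, velocity_base).

    Higher skill means a harder, faster punch with a shorter rise.
    """
    u = float(np.clip(u, 0.0, 1.0))
    f = _FORCE_BASE_N[0] + u * (_FORCE_BASE_N[1] - _FORCE_BASE_N[0])
    t = _RISE_BASE_S[1] - u * (_RISE_BASE_S[1] - _RISE_BASE_S[0])
    v = _SPEED_BASE_MPS[0] + u * (_SPEED_BASE_MPS[1] - _SPEED_BASE_MPS[0])
    return f, t, v


def jitter_for_skill(skill: float) -> float:
    """Per-punch multiplicative variability: elite boxers are more consistent."""
    return 0.02 + 0.08 * (1.0 - skill)


def make_cohort(
    n_boxers: int,
    skill_range: tuple[float, float],
    seed: int,
) -> list[CohortProfile]:
    """Create a seeded cohort of boxer profiles.

    Each boxer's skill is drawn uniformly from ``skill_range``; the physical
    parameter draws use an effective skill smeared by +/-0.15 around it, so
    boxers of equal skill still differ.
    """
    if n_boxers < 1:
        raise ValueError("n_boxers must be at least 1")
    lo, hi = float(skill_range[0]), float(skill_range[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("skill_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_boxers):
        skill = float(rng.uniform(lo, hi))
        u = float(rng.uniform(max(0.0, skill - 0.15), min(1.0, skill + 0.15)))
        f, t, v = params_from_skill(u)
        profiles.append(
            CohortProfile(
                boxer_id=f"boxer{i + 1:02d}",
                skill=skill,
                template=default_template(rng),
                force_scale=f,
                rise_time_base=t,
                velocity_base=v,
                jitter_sd=jitter_for_skill(skill),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles


def _bounded_jitter(rng: np.random.Generator, sd: float, size: int | None = None):
    """Multiplicative jitter: uniform with the requested sd, bounded support."""
    half = np.sqrt(3.0) * sd
    return rng.uniform(1.0 - half, 1.0 + half, size)


def _force_rise(s: np.ndarray, s_jump: float) -> np.ndarray:
    """Normalized monotone rise shape on s = tau / t_rise in [0, 1].

    Jumps to ``_JUMP_FRAC`` within ``s_jump``, ramps to the half-peak
    crossing exactly at ``IMPACT_RISE_FRAC``, then ramps to 1.
    """
    sk = IMPACT_RISE_FRAC
    jump = _JUMP_FRAC * np.clip(s / s_jump, 0.0, 1.0)
    slow = (IMPACT_FORCE_FRAC - _JUMP_FRAC) * np.clip(s / sk, 0.0, 1.0)
    fast = np.where(
        s > sk, (1.0 - IMPACT_FORCE_FRAC) * np.clip((s - sk) / (1.0 - sk), 0.0, 1.0), 0.0
    )
    return jump + slow + fast


def simulate_punch(
    profile: CohortProfile,
    rng: np.random.Generator,
    *,
    hand: str = "right",
    rate: float = DEFAULT_RATE,
    accel_noise_g: float = ACCEL_NOISE_G,
    gyro_noise_dps: float = GYRO_NOISE_DPS,
    force_noise_frac: float = FORCE_NOISE_FRAC,
) -> SimulatedPunch:
    """Simulate one punch: IMU segment, pad force curve, and ground truth.

    At zero noise the force curve rises monotonically from 0 at onset to
    ``F_true`` exactly at ``onset + t_true``, and the trapezoidal integral of
    the punch-axis acceleration over [onset, impact] equals ``v_true``.
    Sensor saturation is clipped to the hardware ranges and flagged in the
    ground truth.
    """
    if hand not in HAND_MULTIPLIER:
        raise ValueError("hand must be 'left' or 'right'")
    dt = 1.0 / rate
    mult = HAND_MULTIPLIER[hand]
    j = profile.jitter_sd

    # A shared per-punch effort factor couples force, speed and rise time
    # (a harder punch is also a faster one with a steeper force rise);
    # smaller independent jitters sit on top of it.
    effort = float(_bounded_jitter(rng, j))
    F_true = profile.force_scale * mult * effort * float(_bounded_jitter(rng, 0.5 * j))
    t_raw = profile.rise_time_base * float(_bounded_jitter(rng, 0.5 * j)) / effort
    t_true = max(4, int(round(t_raw * rate))) * dt  # rise time on the grid
    v_true = profile.velocity_base * mult * effort * float(_bounded_jitter(rng, 0.5 * j))

    onset_idx = int(round((0.20 + rng.uniform(0.0, 0.10)) * rate))
    onset_time = onset_idx * dt
    peak_time = onset_time + t_true
    impact_time = onset_time + IMPACT_RISE_FRAC * t_true

    duration = peak_time + 0.25
    n = int(round(duration * rate)) + 1
    times = np.arange(n) * dt

    # --- pad force -------------------------------------------------------
    s = (times - onset_time) / t_true
    force = np.zeros(n)
    rising = (s > 0) & (s <= 1)
    force[rising] = F_true * _force_rise(s[rising], s_jump=0.5 * dt / t_true)
    after = s > 1
    force[after] = F_true * np.exp(-(times[after] - peak_time) / 0.030)
    if force_noise_frac > 0:
        force = force + rng.normal(0.0, force_noise_frac * F_true, n)
        force = np.clip(force, 0.0, None)

    # --- punch-axis acceleration: calibrated half-sine -------------------
    channels = np.zeros((6, n))
    i0 = int(np.ceil(onset_time * rate - 1e-9))
    i1 = int(np.floor(impact_time * rate + 1e-9))
    phase = (times - onset_time) / (impact_time - onset_time)
    unit = np.where((phase >= 0) & (phase <= 1), np.sin(np.pi * phase), 0.0)
    unit_integral = float(np.trapezoid(unit[i0 : i1 + 1], dx=dt)) * G_TO_MS2
    amp_axis = v_true / unit_integral
    clipped = False
    if amp_axis > ACCEL_RANGE_G:
        clipped = True
        logger.warning(
            "punch-axis amplitude %.1f g exceeds sensor range; clipping", amp_axis
        )
    channels[profile.template.punch_axis] = amp_axis * unit

    # --- template pulses on the remaining channels -----------------------
    speed_factor = v_true / 10.0
    tmpl = profile.template
    for c in range(6):
        if c == tmpl.punch_axis:
            continue
        center = impact_time + tmpl.pulse_phases[c]
        pulse = tmpl.pulse_amplitudes[c] * speed_factor * np.exp(
            -0.5 * ((times - center) / tmpl.pulse_widths[c]) ** 2
        )
        channels[c] = pulse

    # --- sensor noise and saturation --------------------------------------
    if accel_noise_g > 0:
        channels[:3] += rng.normal(0.0, accel_noise_g, (3, n))
    if gyro_noise_dps > 0:
        channels[3:] += rng.normal(0.0, gyro_noise_dps, (3, n))
    lim = np.array([ACCEL_RANGE_G] * 3 + [GYRO_RANGE_DPS] * 3)[:, None]
    if np.any(np.abs(channels) > lim):
        clipped = True
        channels = np.clip(channels, -lim, lim)

    truth = GroundTruthPunch(
        F_true=F_true,
        t_true=t_true,
        v_true=v_true,
        onset_time=onset_time,
        impact_time=impact_time,
        peak_time=peak_time,
        clipped=clipped,
    )
    return SimulatedPunch(
        segment=ImuSegment(rate=rate, channels=channels, hand=hand),
        force=ForceCurve(rate=rate, force=force),
        truth=truth,
    )


def simulate_session(
    profile: CohortProfile,
    n_punches: int,
    seed: int,
    *,
    hand: str = "right",
    rate: float = DEFAULT_RATE,
    best_fraction: float = BEST_FRACTION,
    **noise: float,
) -> PunchDataset:
    """Simulate a session of independent punches with ground truth attached.

    The RNG stream is derived from (seed, profile seed, hand), so sessions
    with different seeds (e.g. a training and a test session for the same
    boxer) share no draws.  The top ``best_fraction`` of punches by punch
    quality q_p = (F/t)*v are flagged ``is_best_true`` (at least one punch).
    """
    if n_punches < 1:
        raise ValueError("n_punches must be at least 1")
    hand_tag = 0 if hand == "left" else 1
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(profile.seed), hand_tag])
    )
    punches = [
        simulate_punch(profile, rng, hand=hand, rate=rate, **noise)
        for _ in range(n_punches)
    ]
    qp = np.array([(p.truth.F_true / p.truth.t_true) * p.truth.v_true for p in punches])
    n_best = max(1, int(np.floor(best_fraction * n_punches)))
    order = np.lexsort((np.arange(n_punches), -qp))  # q_p desc, id asc
    for idx in order[:n_best]:
        punches[idx].truth.is_best_true = True
    return PunchDataset(
        punches=punches, hand=hand, rate=rate, boxer_id=profile.boxer_id, seed=seed
    )


def session_stream(dataset: PunchDataset) -> tuple[ImuSegment, ForceCurve]:
    """Concatenate a session's punches into one continuous stream.

    Punch segments are laid end to end on a common time axis; per-punch
    ground-truth times shift by the cumulative offset of each punch.
    """
    chans = np.concatenate([p.segment.channels for p in dataset.punches], axis=1)
    force = np.concatenate([p.force.force for p in dataset.punches])
    hand = dataset.hand
    return (
        ImuSegment(rate=dataset.rate, channels=chans, hand=hand),
        ForceCurve(rate=dataset.rate, force=force),
    )
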