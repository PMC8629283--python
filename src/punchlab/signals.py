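"""Signal processing for wrist-IMU streams and force-pad curves.

Turns raw streams into detected punches: per-channel scalar Kalman smoothing,
force onset/impact/peak detection with rise-time computation, impact-velocity
estimation by integrating the punch-axis acceleration, and extraction of the
600-value classifier input window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Standard gravity, used to convert accelerometer g units to m/s^2.
G_TO_MS2 = 9.80665

#: Fixed channel order of every 6-channel IMU container in the package.
CHANNEL_NAMES = ("ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps")

#: Sensor full-scale ranges: +/-16 g accelerometer, +/-2000 deg/s gyroscope.
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0

#: Channel index of the forward (punch-direction) acceleration axis; the
#: accelerometer Y axis points along the punch.
PUNCH_AXIS = 1

#: Classifier input layout: 6 channels x 100 samples ending at impact.
SAMPLES_PER_CHANNEL = 100
WINDOW_SIZE = 6 * SAMPLES_PER_CHANNEL


@dataclass
class ImuSegment:
    """A fixed-rate 6-channel window of acceleration and angular-rate samples.

    ``channels`` is a (6, n) array in the order :data:`CHANNEL_NAMES`:
    accelerations in g, angular rates in deg/s.
    """

    rate: float
    channels: np.ndarray
    hand: str = "right"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channels.shape[0] != 6:
            raise ValueError("ImuSegment requires exactly 6 channels")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + (self.n_samples - 1) / self.rate


@dataclass
class ForceCurve:
    """Sampled pad force in Newtons at a fixed rate."""

    rate: float
    force: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.force.size and self.force.min() < 0:
            raise ValueError("force values must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.force.size) / self.rate


@dataclass
class DetectedPunch:
    """One punch found on a force curve.

    ``t`` is the rise time, peak_time - onset_time; ``impact_time`` is where
    the force first crosses the impact fraction of the local peak on the
    rising edge.
    """

    onset_time: float
    impact_time: float
    peak_time: float
    F: float
    t: float


@dataclass
class PunchEvent:
    """A fully characterized punch: detection times, F/t/v and the classifier window."""

    onset_time: float
    peak_time: float
    impact_time: float
    F: float
    t: float
    v: float
    window: np.ndarray = field(default_factory=lambda: np.zeros(WINDOW_SIZE))
    hand: str = "right"
    label: str = "unlabeled"


def _kalman_1d(z: np.ndarray, process_var: float, measurement_var: float) -> np.ndarray:
    """Scalar random-walk Kalman filter over one channel.

    State is the (assumed slowly varying) true signal value; the filter is
    initialized from the first sample with a large prior variance so the
    first output equals the first measurement.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    x = z[0]
    p = 1e6 * measurement_var + process_var
    for i, zi in enumerate(z):
        p = p + process_var
        k = p / (p + measurement_var)
        x = x + k * (zi - x)
        p = (1.0 - k) * p
        out[i] = x
    return out


def kalman_smooth(
    segment: ImuSegment, process_var: float, measurement_var: float
) -> ImuSegment:
    """Kalman-filter every IMU channel with a 1-state random-walk model.

    Parameters
    ----------
    process_var
        Random-walk variance per sample (sensor units squared). Larger values
        track fast changes more closely.
    measurement_var
        Sensor noise variance (sensor units squared).
    """
    if process_var <= 0 or measurement_var <= 0:
        raise ValueError("process_var and measurement_var must be positive")
    filtered = np.vstack(
        [_kalman_1d(ch, process_var, measurement_var) for ch in segment.channels]
    )
    return replace(segment, channels=filtered)


def kalman_steady_state_gain(process_var: float, measurement_var: float) -> float:
    """Closed-form steady-state gain of the scalar random-walk filter."""
    q, r = process_var, measurement_var
    p = 0.5 * (-q + np.sqrt(q * q + 4.0 * q * r))  # a-posteriori variance
    return (p + q) / (p + q + r)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(width) / width
    return np.convolve(xp, kernel, mode="valid")[: x.size]


def detect_punches(
    curve: ForceCurve,
    onset_frac: float = 0.05,
    impact_frac: float = 0.5,
    *,
    min_peak_frac: float = 0.25,
    smooth_samples: int = 5,
    min_gap_s: float = 0.04,
    min_len: int = 3,
) -> list[DetectedPunch]:
    """Detect punches on a pad force curve.

    One event is returned per contiguous excursion of the (lightly smoothed)
    force above ``onset_frac`` of the curve maximum whose raw peak also
    reaches ``min_peak_frac`` of the curve maximum.  Within each excursion:
    the peak is the raw-force argmax, the onset is the last sample below
    ``onset_frac`` of the local peak before it, the impact is the first
    sample at or above ``impact_frac`` of the local peak after onset, and the
    rise time is ``peak_time - onset_time``.

    Excursions shorter than ``min_len`` samples are discarded and logged;
    excursions separated by less than ``min_gap_s`` are merged (guards
    against noise fragmenting a single punch).
    """
    if not (0.0 < onset_frac < impact_frac < 1.0):
        raise ValueError("require 0 < onset_frac < impact_frac < 1")
    f = np.asarray(curve.force, dtype=float)
    if f.size == 0 or f.max() <= 0:
        return []

    smooth = _moving_average(f, smooth_samples)
    global_peak = float(f.max())
    mask = smooth > onset_frac * global_peak

    # contiguous True runs
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    runs = list(zip(starts, stops))

    # merge runs separated by gaps shorter than min_gap_s
    min_gap = max(1, int(round(min_gap_s * curve.rate)))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[DetectedPunch] = []
    for s, e in merged:
        if e - s < min_len:
            logger.debug("discarding %d-sample excursion at index %d", e - s, s)
            continue
        peak_idx = s + int(np.argmax(f[s:e]))
        F = float(f[peak_idx])
        if F < min_peak_frac * global_peak:
            continue
        onset_thr = onset_frac * F
        below = np.flatnonzero(f[:peak_idx] < onset_thr)
        onset_idx = int(below[-1]) if below.size else s
        impact_thr = impact_frac * F
        above = np.flatnonzero(f[onset_idx : peak_idx + 1] >= impact_thr)
        impact_idx = onset_idx + int(above[0])
        dt = 1.0 / curve.rate
        onset_time = curve.start_time + onset_idx * dt
        peak_time = curve.start_time + peak_idx * dt
        impact_time = curve.start_time + impact_idx * dt
        t_rise = peak_time - onset_time
        if t_rise <= 0:
            continue
        events.append(DetectedPunch(onset_time, impact_time, peak_time, F, t_rise))
    return events


def estimate_impact_velocity(
    segment: ImuSegment,
    onset_time: float,
    impact_time: float,
    axis: int = PUNCH_AXIS,
) -> float:
    """Fist speed at impact from the punch-axis acceleration.

    Trapezoidal integral of the axis acceleration (g converted to m/s^2) over
    the samples falling in [onset_time, impact_time]; returns the absolute
    value (a speed, m/s).
    """
    if onset_time >= impact_time:
        raise ValueError("onset_time must precede impact_time")
    eps = 1e-9
    if onset_time < segment.start_time - eps or impact_time > segment.end_time + eps:
        raise ValueError("integration window outside segment bounds")
    i0 = int(np.ceil((onset_time - segment.start_time) * segment.rate - eps))
    i1 = int(np.floor((impact_time - segment.start_time) * segment.rate + eps))
    i0, i1 = max(i0, 0), min(i1, segment.n_samples - 1)
    a = segment.channels[axis, i0 : i1 + 1] * G_TO_MS2
    if a.size < 2:
        return 0.0
    return float(abs(np.trapezoid(a, dx=1.0 / segment.rate)))


def extract_window(
    segment: ImuSegment,
    impact_time: float,
    samples_per_channel: int = SAMPLES_PER_CHANNEL,
) -> np.ndarray:
    """Build the classifier input vector for one punch.

    The last ``samples_per_channel`` samples up to and including the impact
    sample are taken per channel and concatenated channel-major in the fixed
    order (ax, ay, az, gx, gy, gz), raw sensor units, unnormalized.  If the
    window extends before the segment start it is padded with the edge value
    (logged).
    """
    if samples_per_channel < 1:
        raise ValueError("samples_per_channel must be positive")
    eps = 1e-9
    if impact_time < segment.start_time - eps:
        raise ValueError("impact_time precedes segment start")
    impact_idx = int(np.floor((impact_time - segment.start_time) * segment.rate + 0.5))
    impact_idx = min(impact_idx, segment.n_samples - 1)
    lo = impact_idx - samples_per_channel + 1
    pad = max(0, -lo)
    if pad:
        logger.debug("window padded with %d edge samples", pad)
    block = segment.channels[:, max(lo, 0) : impact_idx + 1]
    if pad:
        block = np.concatenate(
            [np.repeat(block[:, :1], pad, axis=1), block], axis=1
        )
    return block.reshape(-1).astype(float)
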