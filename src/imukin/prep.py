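"""Signal preparation: synchronize, resample, build regressors, segment, frame.

Turns a raw (sensor, kinematics) session pair into the aligned 100 Hz
regressor/target series and then into overlapping 60-sample training windows:
frame ``i`` covers samples ``[i, i + 60)`` of the regressor and its target is
the joint angle at the window center, sample ``i + 30`` (0.6 s of data, from
t - 0.3 s to t + 0.3 s). The frame stride is 1 sample, and frames never cross
a segment or speed boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic import KinematicsRecording, SensorRecording, Session

TARGET_RATE = 100
FRAME_LEN = 60
FRAME_CENTER = FRAME_LEN // 2  # target sample within the window
GYRO_SCALE = 100.0  # gyroscope resultant divided by 100 into accel-like range

CHANNELS = ("accel_y", "gyro_resultant_xz")
JOINTS = ("knee", "hip")


class SynchronizationError(RuntimeError):
    """Raised when a recording does not expose three sync stomps."""


@dataclass
class RegressorSeries:
    """Single-channel 100 Hz regressor on the kinematics clock."""

    participant_id: str
    surface: str
    speed: float
    channel: str  # "accel_y" | "gyro_resultant_xz"
    sample_rate: int
    t: np.ndarray
    x: np.ndarray


@dataclass
class FrameSet:
    """Overlapping (window, target) training pairs.

    ``X`` has shape (N, 60, 1); ``Y`` has shape (N, 1); ``center_times[i]`` is
    the time of the sample ``Y[i]`` was read at.
    """

    X: np.ndarray
    Y: np.ndarray
    center_times: np.ndarray
    joint: str
    channel: str

    def __post_init__(self) -> None:
        assert self.X.ndim == 3 and self.X.shape[1:] == (FRAME_LEN, 1)
        assert self.Y.shape == (self.X.shape[0], 1)

    def __len__(self) -> int:
        return self.X.shape[0]


def concat_frames(parts: list[FrameSet]) -> FrameSet:
    """Pool FrameSets (e.g. the four treadmill speeds, in ascending order)."""
    if not parts:
        raise ValueError("no FrameSets to concatenate")
    joint = parts[0].joint
    channel = parts[0].channel
    if any(p.joint != joint or p.channel != channel for p in parts):
        raise ValueError("cannot pool FrameSets across joints or channels")
    return FrameSet(
        X=np.concatenate([p.X for p in parts]),
        Y=np.concatenate([p.Y for p in parts]),
        center_times=np.concatenate([p.center_times for p in parts]),
        joint=joint, channel=channel)


@dataclass(frozen=True)
class SegmentationPlan:
    """Buffered segmentation of a fixed-length session.

    The default mirrors the steady-state protocol for 3 min sessions: discard
    15 s head and tail buffers, split the remaining 150 s into 60/60/30 s
    segments and keep the first 60 s.
    """

    buffer_head: float = 15.0
    buffer_tail: float = 15.0
    split: tuple[float, ...] = (60.0, 60.0, 30.0)
    selected_segment: int = 0

    @property
    def session_duration(self) -> float:
        return self.buffer_head + self.buffer_tail + sum(self.split)

    @property
    def selected_span(self) -> tuple[float, float]:
        """[start, end) of the selected segment, in session time."""
        start = self.buffer_head + sum(self.split[:self.selected_segment])
        return start, start + self.split[self.selected_segment]


def _detect_stomps(t: np.ndarray, x: np.ndarray, rate: float, label: str) -> np.ndarray:
    """Centroid times of the three sync pulses in the first 10 s of ``x``.

    The pulses sit in a quiet preamble, so any sustained robust outlier run is
    an event; the first three runs are the stomps (running itself, if it has
    already started by 10 s, only ever adds later runs).
    """
    window = t < 10.0
    tw = t[window]
    z = np.abs(x[window] - np.median(x[window]))
    if z.max() <= 0:
        raise SynchronizationError(f"no sync spikes detectable on {label}")
    mad = np.median(z)
    threshold = max(6.0 * 1.4826 * mad, 1e-6 * z.max())
    idx = np.flatnonzero(z > threshold)
    if idx.size == 0:
        raise SynchronizationError(f"no sync spikes detectable on {label}")
    # merge runs separated by < 0.1 s; drop single-sample noise exceedances
    breaks = np.flatnonzero(np.diff(idx) > max(int(0.1 * rate), 1))
    groups = [g for g in np.split(idx, breaks + 1) if g.size >= 2]
    centers = np.array([tw[g].mean() for g in groups])
    if len(centers) < 3:
        raise SynchronizationError(
            f"only {len(centers)} sync spike(s) detected on {label}, need 3")
    return centers[:3]


def synchronize(sensor: SensorRecording, kin: KinematicsRecording) -> float:
    """Clock offset (s) of the sensor relative to the kinematics system.

    Detects the three stomp pulses on the sensor's accel-y channel and on the
    knee angle trace and returns the mean pairwise difference of their times;
    subtracting the offset from sensor timestamps aligns the two systems.
    """
    sen_events = _detect_stomps(sensor.t, sensor.accel_xyz[:, 1],
                                sensor.sample_rate, "sensor")
    kin_events = _detect_stomps(kin.t, kin.knee_flexion,
                                kin.sample_rate, "kinematics")
    return float(np.mean(sen_events - kin_events))


def resample_to_target_rate(t: np.ndarray, channels: np.ndarray, sample_rate: int,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Anti-alias low-pass and decimate sensor channels to 100 Hz.

    A zero-phase low-pass at 40 Hz precedes decimation, preserving gait
    content (below ~20 Hz) without phase distortion. ``channels`` is (n,) or
    (n, k); returns the decimated time grid and channels.
    """
    if sample_rate % TARGET_RATE != 0:
        raise ValueError(f"sample rate {sample_rate} not divisible by {TARGET_RATE}")
    factor = sample_rate // TARGET_RATE
    if factor == 1:
        return t, channels
    sos = sps.butter(4, 40.0, fs=sample_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, channels, axis=0)
    return t[::factor], filtered[::factor]


def build_regressor(t: np.ndarray, accel_xyz: np.ndarray, gyro_xyz: np.ndarray,
                    channel: str, *, participant_id: str = "", surface: str = "",
                    speed: float = float("nan")) -> RegressorSeries:
    """Construct the univariate regressor from 100 Hz sensor channels.

    ``accel_y`` passes the tibia-aligned y acceleration through unchanged;
    ``gyro_resultant_xz`` is sqrt(gx^2 + gz^2) / 100, the sagittal-plane
    angular-speed resultant rescaled into the accelerometer's numerical range.
    """
    if channel == "accel_y":
        x = np.asarray(accel_xyz)[:, 1].astype(float)
    elif channel == "gyro_resultant_xz":
        g = np.asarray(gyro_xyz)
        x = np.hypot(g[:, 0], g[:, 2]) / GYRO_SCALE
    else:
        raise ValueError(f"unknown regressor channel {channel!r}")
    return RegressorSeries(participant_id=participant_id, surface=surface,
                           speed=speed, channel=channel,
                           sample_rate=TARGET_RATE, t=np.asarray(t), x=x)


def segment_session(t: np.ndarray, x: np.ndarray,
                    plan: SegmentationPlan = SegmentationPlan(),
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Extract the plan's selected steady-state segment from a full session.

    The series must cover exactly the plan's session duration (to within one
    sample); returns the (t, x) slice over the selected span, e.g. [15, 75) s
    under the default plan.
    """
    t = np.asarray(t)
    duration = t[-1] - t[0] + 1.0 / TARGET_RATE
    if abs(duration - plan.session_duration) > 1.5 / TARGET_RATE:
        raise ValueError(
            f"session duration {duration:.2f} s does not match plan "
            f"({plan.session_duration:.0f} s)")
    start, end = plan.selected_span
    rel = t - t[0]
    mask = (rel >= start - 1e-9) & (rel < end - 1e-9)
    return t[mask], np.asarray(x)[mask]


def make_frames(regressor: RegressorSeries, target: np.ndarray, joint: str,
                ) -> FrameSet:
    """Slice a regressor/target pair into overlapping 60-sample windows.

    Frame ``i`` is ``x[i : i + 60]``; its target is ``target[i + 30]``. With
    stride 1 a series of length L yields N = L - 59 frames; targets whose
    window would overrun either edge are dropped.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}")
    x = np.asarray(regressor.x, dtype=np.float32)
    y = np.asarray(target, dtype=np.float32)
    if x.shape != y.shape:
        raise ValueError("regressor and target must share the 100 Hz grid")
    n = x.size - FRAME_LEN + 1
    if n < 1:
        raise ValueError(f"series of length {x.size} is shorter than one "
                         f"{FRAME_LEN}-sample frame")
    windows = np.lib.stride_tricks.sliding_window_view(x, FRAME_LEN)
    return FrameSet(
        X=np.ascontiguousarray(windows)[:, :, None],
        Y=y[FRAME_CENTER:FRAME_CENTER + n, None],
        center_times=np.asarray(regressor.t)[FRAME_CENTER:FRAME_CENTER + n],
        joint=joint, channel=regressor.channel)


def align_session(session: Session) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                             np.ndarray, np.ndarray]:
    """Synchronize and resample one session onto the kinematics 100 Hz grid.

    Returns ``(t, accel_xyz, gyro_xyz, knee, hip)`` all sampled on the
    kinematics clock: the sensor channels are low-passed, decimated to 100 Hz
    and interpolated at the kinematics timestamps shifted by the recovered
    clock offset.
    """
    sen, kin = session.sensor, session.kinematics
    offset = synchronize(sen, kin)
    t100, chans = resample_to_target_rate(
        sen.t, np.hstack([sen.accel_xyz, sen.gyro_xyz]), sen.sample_rate)
    # a physical instant tau appears at sensor-clock time tau + offset
    query = kin.t + offset
    aligned = np.column_stack([np.interp(query, t100, chans[:, j])
                               for j in range(chans.shape[1])])
    return kin.t, aligned[:, :3], aligned[:, 3:], kin.knee_flexion, kin.hip_flexion


def session_frames(session: Session, channel: str, joint: str,
                   plan: SegmentationPlan = SegmentationPlan()) -> FrameSet:
    """Full per-session pipeline: align, build regressor, segment, frame."""
    t, accel, gyro, knee, hip = align_session(session)
    reg = build_regressor(t, accel, gyro, channel,
                          participant_id=session.sensor.participant_id,
                          surface=session.surface, speed=session.speed)
    target = knee if joint == "knee" else hip
    t_seg, x_seg = segment_session(t, reg.x, plan)
    _, y_seg = segment_session(t, target, plan)
    seg = RegressorSeries(participant_id=reg.participant_id, surface=reg.surface,
                          speed=reg.speed, channel=channel,
                          sample_rate=TARGET_RATE, t=t_seg, x=x_seg)
    return make_frames(seg, y_seg, joint)
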