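"""Synthetic running-gait generator.

Produces per-participant treadmill and level-ground sessions with the
statistical structure the downstream analysis assumes: a knee flexion curve
with a small stance peak and a large swing peak per stride, a hip curve with a
single flexion peak per stride, and tibia-mounted IMU channels that are
deterministic functionals of the joint-angle derivatives plus Gaussian noise.
Treadmill surface compliance attenuates the dynamic accelerometer content more
than the gyroscope content, which is what drives the accelerometer's
treadmill-to-overground transfer penalty.

Every session starts with an 8 s quiet-standing preamble containing three
synchronization stomps (rectangular pulses on the sensor's accel-y channel and
on the knee angle), mimicking the three vertical foot strikes used to
synchronize two sensor systems; the sensor clock additionally lags the
kinematics clock by a random offset of up to 0.5 s, which the preparation
stage must recover.

Units: angles in degrees, acceleration in m/s^2, angular velocity in deg/s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SENSOR_RATE = 500
KIN_RATE = 100

#: duration of the quiet-standing synchronization preamble (s)
PREAMBLE_S = 8.0
#: true times of the three synchronization stomps (s, within the first 10 s)
SYNC_TIMES = (2.0, 3.5, 5.0)
#: stomp pulse width (s)
SYNC_PULSE_S = 0.040

# phase layout of the stride (fraction of the gait cycle)
_KNEE_STANCE_CENTER = 0.18
_KNEE_STANCE_WIDTH = 0.07
_KNEE_SWING_CENTER = 0.62
_KNEE_SWING_WIDTH = 0.10
_HIP_PEAK_PHASE = 0.85

#: per-stride amplitude variability (CV); the hip is deliberately less
#: consistent than the knee, reproducing the field observation that knee
#: trajectories are the more predictable of the two.
KNEE_AMP_CV = 0.02
HIP_AMP_CV = 0.06

GRAVITY_Y = 9.6  # m/s^2 projected on the tibia-aligned accel-y axis


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant gait morphology and sensor-coupling parameters."""

    participant_id: str
    cadence_base: float  # strides/min at 2.5 m/s
    cadence_speed_slope: float  # strides/min per (m/s)
    knee_swing_peak: float  # deg
    knee_stance_peak: float  # deg
    knee_min: float  # deg
    hip_peak: float  # deg
    hip_min: float  # deg
    coupling_gain_accel: float  # (m/s^2) per (deg/s^2) of knee acceleration
    coupling_gain_gyro: float  # (deg/s) per (deg/s) of knee velocity
    noise_sd_accel: float  # m/s^2
    noise_sd_gyro: float  # deg/s
    stride_jitter_cv: float  # unitless CV of the stride period
    rng_seed: int

    def __post_init__(self) -> None:
        if not self.knee_stance_peak < self.knee_swing_peak:
            raise ValueError("knee_stance_peak must be below knee_swing_peak")
        if not self.knee_min < self.knee_stance_peak:
            raise ValueError("knee_min must be below knee_stance_peak")
        if not self.hip_min < self.hip_peak:
            raise ValueError("hip_min must be below hip_peak")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.stride_jitter_cv <= 0.2:
            raise ValueError("stride_jitter_cv must lie in [0, 0.2]")

    def cadence(self, speed: float) -> float:
        """Stride rate (strides/min) at a given running speed (m/s)."""
        return self.cadence_base + self.cadence_speed_slope * (speed - 2.5)


@dataclass(frozen=True)
class SurfaceModel:
    """Surface-dependent distortion of the IMU channels.

    A compliant treadmill absorbs impact, attenuating the dynamic (non-gravity)
    accelerometer content; angular velocity is far less surface-sensitive, so
    the gyroscope attenuation is kept at or above the accelerometer's.
    """

    surface: str  # "treadmill" | "level_ground"
    accel_attenuation: float = 1.0  # multiplicative, in (0, 1]
    gyro_attenuation: float = 1.0
    extra_accel_noise_sd: float = 0.0  # m/s^2

    def __post_init__(self) -> None:
        if self.surface not in ("treadmill", "level_ground"):
            raise ValueError(f"unknown surface {self.surface!r}")
        for a in (self.accel_attenuation, self.gyro_attenuation):
            if not 0.0 < a <= 1.0:
                raise ValueError("attenuation factors must lie in (0, 1]")
        if self.gyro_attenuation < self.accel_attenuation:
            raise ValueError("gyro_attenuation must be >= accel_attenuation")
        if self.extra_accel_noise_sd < 0:
            raise ValueError("extra_accel_noise_sd must be >= 0")


#: default surfaces: the compliant treadmill attenuates dynamic acceleration
#: to 85% and adds a little belt-vibration noise; level ground is undistorted.
#: The attenuation strength is a free simulation parameter (no quantitative
#: characterization exists); 0.85 leaves the accelerometer clearly usable but
#: measurably behind the gyroscope after the surface transfer, matching the
#: qualitative pattern the analysis is designed to detect.
TREADMILL = SurfaceModel("treadmill", accel_attenuation=0.85,
                         gyro_attenuation=1.0, extra_accel_noise_sd=0.2)
LEVEL_GROUND = SurfaceModel("level_ground")


@dataclass
class SensorRecording:
    """Raw tibia IMU trace at 500 Hz, on the sensor's own clock."""

    participant_id: str
    surface: str
    speed: float
    sample_rate: int
    t: np.ndarray
    accel_xyz: np.ndarray  # (n, 3), m/s^2
    gyro_xyz: np.ndarray  # (n, 3), deg/s
    sync_events: list[float]  # stomp times on this recording's clock


@dataclass
class KinematicsRecording:
    """Hip/knee sagittal flexion at 100 Hz, on the reference clock."""

    participant_id: str
    surface: str
    speed: float
    sample_rate: int
    t: np.ndarray
    knee_flexion: np.ndarray  # deg
    hip_flexion: np.ndarray  # deg
    sync_events: list[float]


def make_cohort(n_participants: int, master_seed: int) -> list[ParticipantProfile]:
    """Draw a cohort of participant profiles from physiological ranges.

    Deterministic given ``master_seed``; each profile gets its own derived
    ``rng_seed`` so sessions can be re-simulated independently.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    ss = np.random.SeedSequence([int(master_seed), 0x5EED])
    children = ss.spawn(n_participants)
    profiles = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        knee_min = rng.uniform(8.0, 15.0)
        profiles.append(ParticipantProfile(
            participant_id=f"P{i + 1:02d}",
            cadence_base=rng.uniform(78.0, 88.0),
            cadence_speed_slope=rng.uniform(3.0, 5.0),
            knee_swing_peak=rng.uniform(95.0, 115.0),
            knee_stance_peak=rng.uniform(38.0, 48.0),
            knee_min=knee_min,
            hip_peak=rng.uniform(35.0, 45.0),
            hip_min=rng.uniform(-25.0, -15.0),
            coupling_gain_accel=rng.uniform(1.5e-3, 2.5e-3),
            coupling_gain_gyro=rng.uniform(0.9, 1.1),
            noise_sd_accel=rng.uniform(0.3, 0.8),
            noise_sd_gyro=rng.uniform(5.0, 15.0),
            stride_jitter_cv=rng.uniform(0.01, 0.03),
            rng_seed=int(child.generate_state(1, np.uint32)[0]),
        ))
    return profiles


def _stride_grid(rng: np.random.Generator, profile: ParticipantProfile,
                 speed: float, t_start: float, t_end: float) -> np.ndarray:
    """Stride boundary times covering [t_start, t_end] with period jitter."""
    period = 60.0 / profile.cadence(speed)
    bounds = [t_start]
    while bounds[-1] < t_end:
        jitter = rng.normal(0.0, profile.stride_jitter_cv) if profile.stride_jitter_cv > 0 else 0.0
        bounds.append(bounds[-1] + period * max(0.5, 1.0 + jitter))
    return np.asarray(bounds)


def _phase_and_cycle(t: np.ndarray, bounds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gait-cycle phase in [0, 1) and cycle index for each time point."""
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(bounds) - 2)
    phase = (t - bounds[idx]) / (bounds[idx + 1] - bounds[idx])
    return np.clip(phase, 0.0, 1.0 - 1e-12), idx


def _gauss_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((phase - center) / width) ** 2)


def _angle_curves(t: np.ndarray, profile: ParticipantProfile, bounds: np.ndarray,
                  knee_amp: np.ndarray, hip_amp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free knee/hip flexion (deg) on a jittered stride grid.

    The knee is two well-separated Gaussian bumps per cycle (small stance peak,
    large swing peak); the hip is a raised cosine with one peak per cycle.
    ``knee_amp``/``hip_amp`` are per-cycle amplitude multipliers.
    """
    phase, cyc = _phase_and_cycle(t, bounds)
    a_st = profile.knee_stance_peak - profile.knee_min
    a_sw = profile.knee_swing_peak - profile.knee_min
    knee = profile.knee_min + knee_amp[cyc] * (
        a_st * _gauss_bump(phase, _KNEE_STANCE_CENTER, _KNEE_STANCE_WIDTH)
        + a_sw * _gauss_bump(phase, _KNEE_SWING_CENTER, _KNEE_SWING_WIDTH))
    hip = profile.hip_min + hip_amp[cyc] * (profile.hip_peak - profile.hip_min) * 0.5 * (
        1.0 + np.cos(2.0 * np.pi * (phase - _HIP_PEAK_PHASE)))
    return knee, hip


def _standing_angles(profile: ParticipantProfile) -> tuple[float, float]:
    knee0 = profile.knee_min + 2.0
    hip0 = profile.hip_min + 0.3 * (profile.hip_peak - profile.hip_min)
    return knee0, hip0


def simulate_session(profile: ParticipantProfile, surface_model: SurfaceModel,
                     speed: float, duration: float,
                     seed: int | None = None,
                     knee_amp_cv: float = KNEE_AMP_CV,
                     hip_amp_cv: float = HIP_AMP_CV,
                     ) -> tuple[SensorRecording, KinematicsRecording]:
    """Simulate one running session of ``duration`` seconds.

    The first :data:`PREAMBLE_S` seconds are quiet standing with three
    synchronization stomps at :data:`SYNC_TIMES`; gait starts at the end of the
    preamble. The sensor recording is produced on its own clock, lagging the
    kinematics clock by a uniform random offset in [0, 0.5] s.

    Returns the pair ``(SensorRecording, KinematicsRecording)`` with exactly
    ``duration * 500`` and ``duration * 100`` samples respectively.
    """
    if duration < 30.0:
        raise ValueError(f"duration must be >= 30 s, got {duration}")
    if speed <= 0:
        raise ValueError("speed must be positive")
    rng = np.random.default_rng(profile.rng_seed if seed is None else seed)

    bounds = _stride_grid(rng, profile, speed, PREAMBLE_S, duration + 1.0)
    n_cycles = len(bounds) - 1
    knee_amp = 1.0 + rng.normal(0.0, 1.0, n_cycles) * knee_amp_cv
    hip_amp = 1.0 + rng.normal(0.0, 1.0, n_cycles) * hip_amp_cv
    clock_offset = rng.uniform(0.0, 0.5)

    def true_angles(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        knee, hip = _angle_curves(t, profile, bounds, knee_amp, hip_amp)
        knee0, hip0 = _standing_angles(profile)
        standing = t < PREAMBLE_S
        knee = np.where(standing, knee0, knee)
        hip = np.where(standing, hip0, hip)
        # sync stomps on the knee channel: brief flexion pulses
        for e in SYNC_TIMES:
            knee = knee + 15.0 * ((t >= e) & (t < e + SYNC_PULSE_S))
        return knee, hip

    # --- kinematics on the reference clock -------------------------------
    n_kin = int(round(duration * KIN_RATE))
    t_kin = np.arange(n_kin) / KIN_RATE
    knee_k, hip_k = true_angles(t_kin)

    # --- sensor channels on the lagged sensor clock ----------------------
    # A sample at sensor-clock time u reflects the physical state at u - lag,
    # i.e. physical events appear `lag` late on the sensor's time axis.
    n_sen = int(round(duration * SENSOR_RATE))
    t_sen = np.arange(n_sen) / SENSOR_RATE
    t_phys = t_sen - clock_offset
    knee_s, _ = true_angles(t_phys)
    dt = 1.0 / SENSOR_RATE
    knee_vel = np.gradient(knee_s, dt)  # deg/s
    knee_acc = np.gradient(knee_vel, dt)  # deg/s^2

    g_gain = profile.coupling_gain_gyro * surface_model.gyro_attenuation
    a_gain = profile.coupling_gain_accel * surface_model.accel_attenuation
    noise_a = np.hypot(profile.noise_sd_accel, surface_model.extra_accel_noise_sd)

    gyro = np.empty((n_sen, 3))
    gyro[:, 0] = 0.8 * g_gain * knee_vel
    gyro[:, 1] = 0.1 * g_gain * knee_vel
    gyro[:, 2] = 0.6 * g_gain * knee_vel
    gyro += rng.normal(0.0, profile.noise_sd_gyro, (n_sen, 3))

    dyn = a_gain * knee_acc
    accel = np.empty((n_sen, 3))
    accel[:, 0] = 0.3 * dyn
    accel[:, 1] = GRAVITY_Y + dyn
    accel[:, 2] = 0.2 * dyn
    accel += rng.normal(0.0, noise_a, (n_sen, 3))

    # sync stomps on accel-y: rectangular pulses, 5x the dynamic signal RMS
    pulse_amp = 5.0 * max(np.sqrt(np.mean(dyn ** 2)), 1.0)
    for e in SYNC_TIMES:
        mask = (t_phys >= e) & (t_phys < e + SYNC_PULSE_S)
        accel[mask, 1] += pulse_amp

    half = SYNC_PULSE_S / 2.0
    sensor = SensorRecording(
        participant_id=profile.participant_id, surface=surface_model.surface,
        speed=speed, sample_rate=SENSOR_RATE, t=t_sen,
        accel_xyz=accel, gyro_xyz=gyro,
        sync_events=[e + half + clock_offset for e in SYNC_TIMES])
    kin = KinematicsRecording(
        participant_id=profile.participant_id, surface=surface_model.surface,
        speed=speed, sample_rate=KIN_RATE, t=t_kin,
        knee_flexion=knee_k, hip_flexion=hip_k,
        sync_events=[e + half for e in SYNC_TIMES])
    return sensor, kin


TREADMILL_SPEEDS = (2.0, 2.5, 3.0, 3.5)
PREFERRED_SPEED_MEAN = 2.44
PREFERRED_SPEED_SD = 0.34
SESSION_DURATION_S = 180.0


@dataclass
class Session:
    """One simulated session: paired sensor and kinematics recordings."""

    sensor: SensorRecording
    kinematics: KinematicsRecording

    @property
    def surface(self) -> str:
        return self.sensor.surface

    @property
    def speed(self) -> float:
        return self.sensor.speed


def draw_preferred_speed(rng: np.random.Generator) -> float:
    """Preferred overground speed: N(2.44, 0.34) m/s truncated to (1.5, 3.5)."""
    while True:
        s = rng.normal(PREFERRED_SPEED_MEAN, PREFERRED_SPEED_SD)
        if 1.5 < s < 3.5:
            return s


def simulate_study(cohort: list[ParticipantProfile], seed: int,
                   treadmill: SurfaceModel = TREADMILL,
                   level_ground: SurfaceModel = LEVEL_GROUND,
                   duration: float = SESSION_DURATION_S,
                   ) -> dict[str, list[Session]]:
    """Simulate the full protocol for every participant.

    Each participant runs four treadmill sessions at 2.0/2.5/3.0/3.5 m/s and
    one level-ground session at a preferred speed drawn from N(2.44, 0.34) m/s
    truncated to (1.5, 3.5). Returns ``{participant_id: [5 sessions]}`` with
    the treadmill sessions first, in ascending speed order.
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    out: dict[str, list[Session]] = {}
    ss = np.random.SeedSequence([int(seed), 0x570D7])
    for profile, child in zip(cohort, ss.spawn(len(cohort))):
        rng = np.random.default_rng(child)
        sessions = []
        for sp in TREADMILL_SPEEDS:
            sess_seed = int(rng.integers(0, 2 ** 31))
            sessions.append(Session(*simulate_session(
                profile, treadmill, sp, duration, seed=sess_seed)))
        pref = draw_preferred_speed(rng)
        sess_seed = int(rng.integers(0, 2 ** 31))
        sessions.append(Session(*simulate_session(
            profile, level_ground, pref, duration, seed=sess_seed)))
        out[profile.participant_id] = sessions
    return out


# --------------------------------------------------------------------------
# on-disk format: CSV traces + JSON sidecar per session

def write_session(session: Session, outdir: str | Path) -> Path:
    """Write one session as two CSVs plus a JSON sidecar; returns the sidecar path."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sen, kin = session.sensor, session.kinematics
    stem = f"{sen.participant_id}_{sen.surface}_{sen.speed:.2f}"
    pd.DataFrame({
        "t": sen.t,
        "ax": sen.accel_xyz[:, 0], "ay": sen.accel_xyz[:, 1], "az": sen.accel_xyz[:, 2],
        "gx": sen.gyro_xyz[:, 0], "gy": sen.gyro_xyz[:, 1], "gz": sen.gyro_xyz[:, 2],
    }).to_csv(outdir / f"{stem}_sensor.csv", index=False)
    pd.DataFrame({"t": kin.t, "knee": kin.knee_flexion, "hip": kin.hip_flexion}
                 ).to_csv(outdir / f"{stem}_kinematics.csv", index=False)
    sidecar = outdir / f"{stem}.json"
    sidecar.write_text(json.dumps({
        "participant_id": sen.participant_id, "surface": sen.surface,
        "speed": sen.speed,
        "sensor_sample_rate": sen.sample_rate, "kin_sample_rate": kin.sample_rate,
        "sensor_sync_events": sen.sync_events, "kin_sync_events": kin.sync_events,
    }, indent=1))
    return sidecar


def read_session(sidecar: str | Path) -> Session:
    """Load a session written by :func:`write_session`."""
    import pandas as pd

    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    stem = sidecar.stem
    sen_df = pd.read_csv(sidecar.with_name(f"{stem}_sensor.csv"))
    kin_df = pd.read_csv(sidecar.with_name(f"{stem}_kinematics.csv"))
    sensor = SensorRecording(
        participant_id=meta["participant_id"], surface=meta["surface"],
        speed=meta["speed"], sample_rate=meta["sensor_sample_rate"],
        t=sen_df["t"].to_numpy(),
        accel_xyz=sen_df[["ax", "ay", "az"]].to_numpy(),
        gyro_xyz=sen_df[["gx", "gy", "gz"]].to_numpy(),
        sync_events=list(meta["sensor_sync_events"]))
    kin = KinematicsRecording(
        participant_id=meta["participant_id"], surface=meta["surface"],
        speed=meta["speed"], sample_rate=meta["kin_sample_rate"],
        t=kin_df["t"].to_numpy(),
        knee_flexion=kin_df["knee"].to_numpy(), hip_flexion=kin_df["hip"].to_numpy(),
        sync_events=list(meta["kin_sync_events"]))
    return Session(sensor, kin)
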