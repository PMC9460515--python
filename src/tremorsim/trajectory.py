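"""Baseline (healthy) motion synthesis for the three UPDRS tremor tasks.

The three tasks mirror the standard clinical tremor examination:

* ``postural_hold`` (UPDRS 3.15) — arms stretched out in front of the body,
  palms down; a stationary hold with physiological postural sway.
* ``finger_to_nose`` (UPDRS 3.16) — repeated finger-to-nose reaches, at
  least three per administration; synthesized as minimum-jerk
  point-to-point movements.
* ``rest`` (UPDRS 3.17) — sitting quietly with hands resting; a stationary
  position with the smallest sway level.

A trajectory (position + unit quaternion orientation in a fixed world
frame, z-up) is converted to ideal body-frame inertial data: specific
force in g, angular velocity in deg/s, and the projection of a constant
Earth magnetic field in uT.  A static sensor with identity orientation
reads exactly (0, 0, +1) g.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.spatial.transform import Rotation

from tremorsim.sensor_model import InertialRecord

__all__ = [
    "Trajectory", "TaskId", "MotionParams", "make_task_trajectory",
    "trajectory_to_inertial", "GRAVITY", "EARTH_FIELD_UT",
]

GRAVITY = 9.80665  # m/s^2
#: Constant Earth magnetic field in the world frame (uT), mid-latitude-like.
EARTH_FIELD_UT = np.array([20.0, 5.0, -45.0])

_QUAT_NORM_TOL = 1e-8


class TaskId(str, enum.Enum):
    """Closed enumeration of the supported assessment tasks."""

    postural_hold = "postural_hold"   # UPDRS 3.15
    finger_to_nose = "finger_to_nose"  # UPDRS 3.16
    rest = "rest"                      # UPDRS 3.17


@dataclass
class Trajectory:
    """Uniformly sampled pose path: position (3xN, m) + quaternion (4xN).

    Quaternion storage order is (x, y, z, w), matching scipy's convention;
    every sample must be unit norm.
    """

    sample_rate: float
    position: np.ndarray
    quaternion: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.quaternion = np.atleast_2d(np.asarray(self.quaternion, dtype=float))
        n = self.position.shape[1]
        if self.position.shape != (3, n) or self.quaternion.shape != (4, n):
            raise ValueError("position must be 3xN and quaternion 4xN with shared N")

    @property
    def n_samples(self) -> int:
        return self.position.shape[1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def validate(self) -> None:
        norms = np.linalg.norm(self.quaternion, axis=0)
        bad = np.abs(norms - 1.0) > _QUAT_NORM_TOL
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-unit quaternion at sample {i} (norm {norms[i]:.12f})")


@dataclass
class MotionParams:
    """Kinematic knobs of the synthetic tasks (free parameters; the original
    clinical recordings report no amplitudes, so these are chosen at
    physiologically plausible scales)."""

    rest_sway_m: float = 0.001          # position sway sigma at rest
    postural_sway_m: float = 0.003      # position sway sigma in postural hold
    sway_bandwidth_hz: float = 1.5      # low-pass corner of the sway drift
    rest_orient_deg: float = 0.5        # orientation sway sigma at rest
    postural_orient_deg: float = 1.5    # orientation sway sigma, postural
    reach_distance_m: float = 0.35      # finger-to-nose travel
    reach_cycle_s: float = 4.0          # out-and-back cycle (>= 3 per trial)
    reach_hold_frac: float = 0.125      # fraction of each half-cycle spent holding
    reach_orient_deg: float = 20.0      # pitch excursion tracking the reach
    # static hand posture per task (roll, pitch, yaw in deg): at rest the
    # hand lies relaxed on the armrest (rolled toward thumb-up); in the
    # postural hold the arm is outstretched palm-down with a slight wrist
    # drop; finger-to-nose starts from the outstretched posture
    rest_tilt_deg: tuple = (25.0, 0.0, 0.0)
    postural_tilt_deg: tuple = (0.0, -10.0, 0.0)
    reach_tilt_deg: tuple = (0.0, -10.0, 0.0)


def _bandlimited_noise(n: int, fs: float, sigma: float, cutoff: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean band-limited drift with standard deviation ``sigma``."""
    if sigma == 0.0:
        # keep the stream position moving so sigma=0 stays seed-compatible
        rng.normal(size=n)
        return np.zeros(n)
    white = rng.normal(size=n)
    wn = min(cutoff / (fs / 2.0), 0.99)
    b, a = sp_signal.butter(2, wn)
    x = sp_signal.filtfilt(b, a, white)
    sd = x.std()
    if sd == 0.0:
        return np.zeros(n)
    return x * (sigma / sd)


def _minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _reach_waveform(t: np.ndarray, cycle_s: float, hold_frac: float) -> np.ndarray:
    """Periodic 0->1->0 reach profile built from minimum-jerk segments."""
    phase = np.mod(t, cycle_s) / cycle_s
    half = 0.5
    move = 0.5 * (1.0 - 2.0 * hold_frac)  # moving fraction of each half-cycle
    out = np.empty_like(phase)
    # first half: go out; second half: come back
    fwd = phase < half
    out[fwd] = _minimum_jerk_profile(phase[fwd] / move)
    out[~fwd] = 1.0 - _minimum_jerk_profile((phase[~fwd] - half) / move)
    return out


def make_task_trajectory(task: TaskId, duration: float, fs: float,
                         motion_params: MotionParams | None = None,
                         seed=None) -> Trajectory:
    """Synthesize a deterministic (per seed) pose path for one task."""
    task = TaskId(task)
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not fs > 0:
        raise ValueError("fs must be > 0")
    mp = motion_params or MotionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    if task is TaskId.rest:
        sway, orient, tilt = mp.rest_sway_m, mp.rest_orient_deg, mp.rest_tilt_deg
        base_pos = np.zeros((3, n))
        pitch = np.zeros(n)
    elif task is TaskId.postural_hold:
        sway, orient, tilt = (mp.postural_sway_m, mp.postural_orient_deg,
                              mp.postural_tilt_deg)
        base_pos = np.zeros((3, n))
        pitch = np.zeros(n)
    else:  # finger_to_nose
        sway, orient, tilt = (mp.postural_sway_m, mp.postural_orient_deg,
                              mp.reach_tilt_deg)
        reach = _reach_waveform(t, mp.reach_cycle_s, mp.reach_hold_frac)
        base_pos = np.zeros((3, n))
        base_pos[0] = -mp.reach_distance_m * reach      # pull hand toward nose
        base_pos[2] = 0.3 * mp.reach_distance_m * reach  # and slightly up
        pitch = mp.reach_orient_deg * reach

    pos = base_pos + np.vstack(
        [_bandlimited_noise(n, fs, sway, mp.sway_bandwidth_hz, rng) for _ in range(3)])
    euler = np.vstack(
        [_bandlimited_noise(n, fs, orient, mp.sway_bandwidth_hz, rng) for _ in range(3)])
    euler += np.asarray(tilt, dtype=float)[:, None]
    euler[1] += pitch
    if np.any(euler):
        quat = Rotation.from_euler("xyz", euler.T, degrees=True).as_quat().T
    else:
        quat = np.tile(np.array([0.0, 0.0, 0.0, 1.0])[:, None], (1, n))
    return Trajectory(fs, pos, quat)


def _quat_rates_to_body_omega(q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
    """Body angular velocity (rad/s) from quaternion and its derivative.

    omega_body = 2 * vec(q_conj * qdot) for (x, y, z, w) quaternions.
    """
    x, y, z, w = q
    dx, dy, dz, dw = qdot
    ox = w * dx - x * dw - y * dz + z * dy
    oy = w * dy + x * dz - y * dw - z * dx
    oz = w * dz - x * dy + y * dx - z * dw
    return 2.0 * np.vstack([ox, oy, oz])


def trajectory_to_inertial(traj: Trajectory, gravity: float = GRAVITY,
                           earth_field: np.ndarray | None = None) -> InertialRecord:
    """Convert a pose path into ideal 9-axis inertial data.

    Body-frame specific force is R(q)^T (p_dd - g_vec) expressed in g
    (g_vec points along -z, so a static sensor reads +1 g on z); angular
    velocity comes from the quaternion derivative in deg/s; the
    magnetometer reads the body-frame projection of a constant Earth field.
    Derivatives use second-order central differences (one-sided at the
    endpoints).
    """
    if traj.n_samples < 5:
        raise ValueError("need at least 5 samples for numerical differentiation")
    traj.validate()
    dt = 1.0 / traj.sample_rate
    b_world = EARTH_FIELD_UT if earth_field is None else np.asarray(earth_field, float)

    pdd = np.gradient(np.gradient(traj.position, dt, axis=1), dt, axis=1)
    g_vec = np.array([0.0, 0.0, -gravity])
    f_world = pdd - g_vec[:, None]
    rot = Rotation.from_quat(traj.quaternion.T)
    accel_g = rot.inv().apply(f_world.T).T / gravity

    qdot = np.gradient(traj.quaternion, dt, axis=1)
    omega = _quat_rates_to_body_omega(traj.quaternion, qdot)
    gyro_dps = np.degrees(omega)

    mag = rot.inv().apply(np.tile(b_world, (traj.n_samples, 1))).T
    return InertialRecord(traj.sample_rate, accel_g, gyro_dps, mag)
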