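"""Keyframed joint-angle templates and PD-servo actuation profiles.

Templates are sequences of (time, pose) keyframes in flexion-positive joint
angles ``theta = (hip, knee, ankle)``, interpolated with a quintic smoothstep
(zero velocity and acceleration at every keyframe, so commanded motion is C2
and its spectral content stays well below typical low-pass cutoffs).

The servo torque is ``tau = Kp (theta_ref - theta) + Kd (thetadot_ref -
thetadot) + gravity compensation``, clipped at per-joint torque capacities.
Capacities scale with the subject's relative squat strength, which is what
couples the synthetic cohort's strength distribution to its jump mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ArgumentError
from .chain import ContactChain, phi_from_theta
from .cohort import SubjectRecord


def _theta_of_phi(phi_s: float, phi_t: float, phi_b: float) -> np.ndarray:
    # theta = (hip, knee, ankle) from absolute lean angles
    return np.array([phi_b - phi_t, phi_s - phi_t, phi_s])


def stand_theta() -> np.ndarray:
    return _theta_of_phi(0.05, -0.05, 0.08)


def crouch_theta(depth: float) -> np.ndarray:
    """Crouch pose; ``depth`` in [0, 1] scales countermovement/absorption depth."""
    return _theta_of_phi(
        0.38 + 0.30 * depth, -(0.62 + 0.33 * depth), 0.50 + 0.35 * depth
    )


def extend_theta() -> np.ndarray:
    """Near-full extension with ankle plantarflexion (takeoff target)."""
    return _theta_of_phi(-0.20, -0.24, -0.16)


def dj_land_theta(drop_factor: float = 0.5) -> np.ndarray:
    """Flexed touchdown pose for drop jumps; higher drops land more flexed,
    giving the joints leverage to absorb the vertical impact velocity."""
    f = float(np.clip(drop_factor, 0.0, 1.0))
    return _theta_of_phi(0.18 + 0.22 * f, -(0.25 + 0.28 * f), 0.20 + 0.24 * f)


@dataclass(frozen=True)
class ActuationProfile:
    """PD gains and per-joint torque capacities for the whole chain (N m)."""

    name: str
    kp: np.ndarray  # (hip, knee, ankle), N m / rad
    kd: np.ndarray  # N m s / rad
    caps: np.ndarray  # |tau| limits, N m

    def __post_init__(self) -> None:
        for arr in (self.kp, self.kd, self.caps):
            if np.asarray(arr).shape != (3,):
                raise ArgumentError("actuation gains must have shape (3,)")


def actuation_for_subject(subject: SubjectRecord, strength_scale: float = 1.0) -> ActuationProfile:
    """Default profile: capacities grow with body mass and relative strength."""
    m = subject.body_mass
    rel = subject.rel_strength * strength_scale
    caps = np.array([
        (2.2 + 2.4 * rel) * m,  # hip
        (2.0 + 2.2 * rel) * m,  # knee
        (2.4 + 1.4 * rel) * m,  # ankle
    ])
    kp = np.array([1400.0, 1400.0, 900.0]) * (m / 70.0)
    kd = np.array([110.0, 110.0, 70.0]) * (m / 70.0)
    return ActuationProfile(name=f"default(rel={rel:.2f})", kp=kp, kd=kd, caps=caps)


def _quintic_coeffs(p0, v0, p1, v1, duration):
    """Quintic polynomial coefficients (per joint) in normalized u = t/T with
    endpoint positions/velocities as given and zero endpoint accelerations."""
    T = duration
    b0, b1 = np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)
    w0, w1 = np.asarray(v0, dtype=float) * T, np.asarray(v1, dtype=float) * T
    # solve for u^3..u^5 terms given c0=p0, c1=w0, c2=0
    A = np.array([[1.0, 1.0, 1.0], [3.0, 4.0, 5.0], [6.0, 12.0, 20.0]])
    rhs = np.stack([b1 - b0 - w0, w1 - w0, np.zeros(3)])
    c345 = np.linalg.solve(A, rhs)
    return np.vstack([b0, w0, np.zeros(3), c345])  # (6, 3)


class JointTemplate:
    """Piecewise-quintic reference trajectory over keyframes.

    Each segment is a quintic with prescribed endpoint positions and
    velocities and zero endpoint accelerations; keyframe velocities default
    to zero (classic smoothstep) but the first keyframe may carry the
    touchdown joint velocity so drop-jump absorption starts C1-consistent
    with the impact.
    """

    def __init__(self, times, poses, extend_start: float, velocities=None):
        self.times = np.asarray(times, dtype=float)
        self.poses = np.asarray(poses, dtype=float)
        if self.times.ndim != 1 or self.poses.shape != (self.times.size, 3):
            raise ArgumentError("template needs k times and (k, 3) poses")
        if np.any(np.diff(self.times) <= 0):
            raise ArgumentError("keyframe times must be strictly increasing")
        self.velocities = (
            np.zeros_like(self.poses) if velocities is None
            else np.asarray(velocities, dtype=float)
        )
        if self.velocities.shape != self.poses.shape:
            raise ArgumentError("keyframe velocities must match poses in shape")
        self.extend_start = float(extend_start)
        self._coeffs = [
            _quintic_coeffs(
                self.poses[k], self.velocities[k],
                self.poses[k + 1], self.velocities[k + 1],
                self.times[k + 1] - self.times[k],
            )
            for k in range(self.times.size - 1)
        ]

    def __call__(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (theta_ref, thetadot_ref) at time ``t``."""
        times = self.times
        if t <= times[0]:
            return self.poses[0].copy(), self.velocities[0].copy()
        if t >= times[-1]:
            return self.poses[-1].copy(), np.zeros(3)
        k = int(np.searchsorted(times, t, side="right")) - 1
        T = times[k + 1] - times[k]
        u = (t - times[k]) / T
        powers = u ** np.arange(6)
        dpowers = np.concatenate([[0.0], np.arange(1, 6) * u ** np.arange(5)])
        c = self._coeffs[k]
        return powers @ c, (dpowers @ c) / T

    def end_time(self) -> float:
        return float(self.times[-1])


def cmj_template(depth: float, quiet: float = 0.5, t_down: float = 0.55,
                 t_hold: float = 0.05, t_up: float = 0.20) -> JointTemplate:
    stand, crouch, ext = stand_theta(), crouch_theta(depth), extend_theta()
    t1 = quiet
    t2 = t1 + t_down
    t3 = t2 + t_hold
    t4 = t3 + t_up
    vels = np.zeros((5, 3))
    # reference keeps accelerating through push-off so takeoff (force-zero
    # crossing) lands near full extension, not at mid-segment peak velocity
    vels[4] = 1.8 * (ext - crouch) / t_up
    return JointTemplate(
        times=[0.0, t1, t2, t3, t4],
        poses=[stand, stand, crouch, crouch, ext],
        velocities=vels,
        extend_start=t3,
    )


def dj_contact_template(depth: float, t_arrest: float,
                        theta_arrest: np.ndarray, thetadot_arrest: np.ndarray,
                        t_absorb_end: float,
                        t_hold: float = 0.03, t_up: float = 0.20) -> JointTemplate:
    """Absorb-then-extend template for the ground contact of a drop jump.

    The impact itself (touchdown to ``t_arrest``) is handled by a prescribed
    joint-deceleration stage in the simulator; this template takes over at
    the arrest pose/velocity and continues the absorption into the crouch
    before extending.
    """
    crouch, ext = crouch_theta(depth), extend_theta()
    t1 = max(t_absorb_end, t_arrest + 0.08)
    t2 = t1 + t_hold
    t3 = t2 + t_up
    vels = np.zeros((4, 3))
    vels[0] = thetadot_arrest
    vels[3] = 1.8 * (ext - crouch) / t_up
    return JointTemplate(
        times=[t_arrest, t1, t2, t3],
        poses=[theta_arrest, crouch, crouch, ext],
        velocities=vels,
        extend_start=t2,
    )


def control_torques(
    chain: ContactChain,
    template: JointTemplate,
    profile: ActuationProfile,
    t: float,
    phi: np.ndarray,
    phidot: np.ndarray,
) -> np.ndarray:
    """Total commanded joint torques (flexion-positive) at time ``t``."""
    from .chain import S_MATRIX

    theta = S_MATRIX @ phi
    thetadot = S_MATRIX @ phidot
    theta_ref, thetadot_ref = template(t)
    tau = profile.kp * (theta_ref - theta) + profile.kd * (thetadot_ref - thetadot)
    tau = tau + chain.gravity_compensation_torques(phi)
    return np.clip(tau, -profile.caps, profile.caps)
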