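"""Torque-driven forward simulation of countermovement and drop jumps.

The contact phase integrates the 3-DOF grounded chain with fixed-step RK4;
flight phases are ballistic.  Every trial carries its ground truth (joint
torques actually applied and the COM state), so downstream force-plate and
inverse-dynamics code can be validated to integrator tolerance.

Conventions: both plates see half of the chain's ground reaction force, the
left and right leg kinematics are identical (bilaterally symmetric jumps),
and per-side truth torques are half the chain torque, reported
extensor-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..anthro import segment_parameters
from ..constants import FORCE_CHANNELS, FORCE_RATE, GRAVITY, JOINTS, KINEMATIC_RATE, SIDES
from ..errors import ArgumentError, SimulationError
from ..trials import JumpType, RawTrial, TimeSeries
from .chain import ContactChain, S_MATRIX, phi_from_theta
from .cohort import SubjectRecord
from .templates import (
    ActuationProfile,
    JointTemplate,
    actuation_for_subject,
    cmj_template,
    crouch_theta,
    dj_contact_template,
    dj_land_theta,
)

_TAKEOFF_ARM_VEL = 0.15  # m/s upward COM velocity required before takeoff triggers
_FLIGHT_EASE = 0.08  # s, joint-velocity decay constant in flight


@dataclass(eq=False)
class SimulatedTrial(RawTrial):
    """A :class:`RawTrial` plus simulator ground truth.

    ``truth_torques`` holds per-side, per-joint extensor-positive torques
    (N m) and ``truth_com`` the vertical COM position/velocity/acceleration,
    both at the force rate.  ``truth_joints`` carries the exact joint angles
    and angular velocities (flexion-positive) at the force rate, for
    reconstruction-free invariant checks.
    """

    truth_torques: TimeSeries = None  # type: ignore[assignment]
    truth_com: TimeSeries = None  # type: ignore[assignment]
    truth_joints: TimeSeries | None = None


class _Recorder:
    """Accumulates full-rate simulation samples."""

    def __init__(self) -> None:
        self.theta: list[np.ndarray] = []
        self.thetadot: list[np.ndarray] = []
        self.grf: list[np.ndarray] = []
        self.cop: list[float] = []
        self.tau: list[np.ndarray] = []
        self.com: list[tuple[float, float, float]] = []

    def add(self, theta, thetadot, grf, cop, tau, com) -> None:
        self.theta.append(np.asarray(theta, dtype=float).copy())
        self.thetadot.append(np.asarray(thetadot, dtype=float).copy())
        self.grf.append(np.asarray(grf, dtype=float).copy())
        self.cop.append(float(cop))
        self.tau.append(np.asarray(tau, dtype=float).copy())
        self.com.append(tuple(float(x) for x in com))

    def __len__(self) -> int:
        return len(self.theta)


def _rk4_step(f, t: float, y: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(t, y)
    k2 = f(t + dt / 2, y + dt / 2 * k1)
    k3 = f(t + dt / 2, y + dt / 2 * k2)
    k4 = f(t + dt, y + dt * k3)
    return y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def _simulate_contact(
    chain: ContactChain,
    template: JointTemplate,
    profile: ActuationProfile,
    rec: _Recorder,
    t_start: float,
    dt: float,
    phi: np.ndarray,
    phidot: np.ndarray,
    jump_label: str,
    impact=None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Integrate the grounded chain until takeoff; returns (t, phi, phidot).

    ``impact`` = (end time, phiddot(t) callable): until that time the joint
    torques are computed by exact inverse dynamics of the prescribed
    deceleration (the eccentric arrest of a drop-jump landing); afterwards
    the PD servo tracks the template.
    """

    def control(t, phi_, phidot_):
        from .templates import control_torques

        if impact is not None and t < impact[0]:
            rhs = (
                chain.mass_matrix(phi_) @ impact[1](t)
                + chain.bias(phi_, phidot_)
                + chain.gravity_vector(phi_)
            )
            return np.linalg.solve(S_MATRIX.T, rhs)
        return control_torques(chain, template, profile, t, phi_, phidot_)

    def deriv(t, y):
        phi_, phidot_ = y[:3], y[3:]
        tau = control(t, phi_, phidot_)
        return np.concatenate([phidot_, chain.forward(phi_, phidot_, tau)])

    t = t_start
    y = np.concatenate([phi, phidot])
    t_limit = template.end_time() + 0.5
    while True:
        phi_, phidot_ = y[:3], y[3:]
        if not np.all(np.isfinite(y)):
            raise SimulationError(f"non-finite state in {jump_label}", phase="contact")
        tau = control(t, phi_, phidot_)
        phiddot = chain.forward(phi_, phidot_, tau)
        grf = chain.grf(phi_, phidot_, phiddot)
        v_com = chain.com_velocity(phi_, phidot_)
        armed = t >= template.extend_start and v_com[1] > _TAKEOFF_ARM_VEL
        if grf[1] <= 0.0:
            if armed:
                return t, phi_.copy(), phidot_.copy()
            raise SimulationError(
                f"vertical force became non-positive before push-off in {jump_label} "
                f"(t={t:.4f}, v_com={v_com[1]:.3f}, extend_start={template.extend_start:.4f})",
                phase="contact",
            )
        cop = chain.centre_of_pressure(tau[2], grf)
        com_pos = chain.com_position(phi_)[1]
        com_acc = grf[1] / chain.m_total - chain.g
        rec.add(S_MATRIX @ phi_, S_MATRIX @ phidot_, grf, cop, tau, (com_pos, v_com[1], com_acc))
        if t - t_start > t_limit:
            raise SimulationError(
                f"no takeoff within {t_limit:.2f} s in {jump_label}", phase="contact"
            )
        y = _rk4_step(deriv, t, y, dt)
        t += dt


def _simulate_flight(
    chain: ContactChain,
    rec: _Recorder,
    dt: float,
    phi: np.ndarray,
    phidot: np.ndarray,
    z0: float,
    v0: float,
    z_end: float,
    g: float,
) -> None:
    """Ballistic COM, easing joint velocities; record until COM falls to z_end."""
    k = 0
    while True:
        dtk = k * dt
        z = z0 + v0 * dtk - 0.5 * g * dtk**2
        v = v0 - g * dtk
        ease = np.exp(-dtk / _FLIGHT_EASE)
        phi_k = phi + phidot * _FLIGHT_EASE * (1.0 - ease)
        rec.add(S_MATRIX @ phi_k, S_MATRIX @ (phidot * ease), np.zeros(2), 0.0, np.zeros(3), (z, v, -g))
        if v < 0 and z <= z_end:
            return
        if dtk > 3.0:
            raise SimulationError("flight phase did not terminate", phase="flight")
        k += 1


def simulate_trial(
    subject: SubjectRecord,
    jump_type: JumpType | str,
    drop_height: float | None = None,
    actuation: ActuationProfile | None = None,
    sim_rate: float = 2000.0,
    seed: int = 0,
    table: str = "winter",
    g: float = GRAVITY,
) -> SimulatedTrial:
    """Simulate one jump trial with known ground truth.

    Parameters
    ----------
    subject : SubjectRecord
        Supplies body mass/height (segment scaling) and, through the default
        actuation profile, torque capacities.
    jump_type : JumpType or str
        One of CMJ, DJ15 ... DJ75.
    drop_height : float, optional
        Platform height in m; defaults to the jump type's nominal height.
    actuation : ActuationProfile, optional
        Override the strength-scaled default.
    sim_rate : float
        Integrator rate; must be >= 1,000 Hz and an integer multiple of it.
    seed : int
        Deterministic trial-to-trial jitter of template depth and timing.
    """
    jump_type = JumpType(jump_type)
    if drop_height is None:
        drop_height = jump_type.nominal_drop_height
    if drop_height < 0:
        raise ArgumentError("drop_height must be >= 0")
    if jump_type is JumpType.CMJ and drop_height != 0:
        raise ArgumentError("CMJ trials have drop_height 0")
    if sim_rate < FORCE_RATE:
        raise ArgumentError(f"sim_rate must be >= {FORCE_RATE} Hz")
    if abs(sim_rate / FORCE_RATE - round(sim_rate / FORCE_RATE)) > 1e-9:
        raise ArgumentError("sim_rate must be an integer multiple of the force rate")

    rng = np.random.default_rng(seed)
    jitter = lambda scale: 1.0 + scale * float(rng.uniform(-1.0, 1.0))  # noqa: E731

    params = segment_parameters(subject.body_mass, subject.height, table)
    chain = ContactChain(params, leg_count=2, g=g)
    profile = actuation or actuation_for_subject(subject)
    dt = 1.0 / sim_rate
    rec = _Recorder()
    meta: dict = {
        "body_mass": subject.body_mass,
        "height": subject.height,
        "sex": subject.sex,
        "squat_1rm": subject.squat_1rm,
        "anthro_table": table,
        "sim_rate": sim_rate,
        "seed": seed,
        "actuation": profile.name,
    }

    if jump_type is JumpType.CMJ:
        depth = min(1.0, 0.70 * jitter(0.08))
        template = cmj_template(
            depth,
            quiet=0.5,
            t_down=0.55 * jitter(0.05),
            t_up=0.20 * jitter(0.05),
        )
        phi0 = phi_from_theta(template.poses[0])
        meta["truth_t_onset"] = template.times[1]
        t_to, phi_to, phidot_to = _simulate_contact(
            chain, template, profile, rec, 0.0, dt, phi0, np.zeros(3), "CMJ"
        )
    else:
        v0 = np.sqrt(2.0 * g * drop_height)
        t_contact = v0 / g
        n_drop = int(np.floor(t_contact / dt))
        depth = min(1.0, (0.45 + 0.55 * drop_height / 0.75) * jitter(0.06))
        phi_c = phi_from_theta(dj_land_theta(0.35 + 0.65 * drop_height / 0.75))
        # touchdown joint velocities along the natural flexion direction
        # (land pose -> crouch), knee-weighted and modulated by hip torque
        # capacity (weaker hips brake less hip-flexion velocity, shifting
        # absorption toward the knee), then scaled to the exact ballistic
        # vertical COM velocity; small anterior COM motion is tolerated
        j_com = chain.com_jacobian(phi_c)
        d = phi_from_theta(crouch_theta(depth)) - phi_c
        cap_ref_hip = (2.2 + 2.4 * 1.25) * subject.body_mass
        hip_weight = 0.9 * (profile.caps[0] / cap_ref_hip) ** 0.8
        theta_dir = S_MATRIX @ d
        theta_weighted = theta_dir * np.array([hip_weight, 1.2, 1.0])
        theta_dir = 0.4 * theta_dir + 0.6 * theta_weighted
        d = phi_from_theta(theta_dir)
        phidot_c = (-v0 / (j_com @ d)[1]) * d
        z_c = chain.com_position(phi_c)[1]
        # pre-contact free fall: linear joint motion, C1 at touchdown
        for k in range(n_drop):
            tk = k * dt
            phi_k = phi_c - phidot_c * (t_contact - tk)
            z = z_c + 0.5 * g * (t_contact - tk) ** 2
            rec.add(S_MATRIX @ phi_k, S_MATRIX @ phidot_c, np.zeros(2), 0.0, np.zeros(3), (z, -g * tk, -g))
        # contact integration starts on the sample grid, a fraction of a
        # step before nominal touchdown; the touchdown state and the arrest
        # profile are anchored there, with the joint velocities rescaled at
        # the start pose so the vertical COM velocity matches ballistics
        # (-g t) exactly at the first contact sample
        t_start = n_drop * dt
        phi_start = phi_c - phidot_c * (t_contact - t_start)
        v0 = g * t_start
        phidot_c = (-v0 / (chain.com_jacobian(phi_start) @ d)[1]) * d
        phi_c = phi_start
        # eccentric arrest: half-cosine joint deceleration from the impact
        # velocity down to a moderate handover velocity, with the duration
        # chosen so the touchdown GRF starts near 1.5 body weights
        v_hand = min(0.25, 0.10 * v0)
        phidot_h = phidot_c * (v_hand / v0)
        grf_free = chain.grf(phi_c, phidot_c, np.zeros(3))
        centrifugal = chain.m_total * g - grf_free[1]
        t_imp = 2.0 * chain.m_total * (v0 - v_hand) / max(
            centrifugal + 0.5 * chain.m_total * g, 1e-6
        )
        t_imp = float(np.clip(t_imp, 0.03, 0.18))
        t_arrest = t_start + t_imp
        amp = 2.0 * (phidot_h - phidot_c) / t_imp

        def phiddot_impact(t: float, t0=t_start, T=t_imp, A=amp) -> np.ndarray:
            u = np.clip((t - t0) / T, 0.0, 1.0)
            return A * 0.5 * (1.0 + np.cos(np.pi * u))

        phi_arrest = phi_start + phidot_c * t_imp + amp * t_imp**2 * (0.25 + 1.0 / np.pi**2)
        # remaining absorption paced so the crouch is reached without the
        # reference dropping into free fall
        z_arrest = chain.com_position(phi_arrest)[1]
        z_crouch = chain.com_position(phi_from_theta(crouch_theta(depth)))[1]
        dz_rem = max(z_arrest - z_crouch, 0.02)
        t_absorb_end = t_arrest + float(np.clip(2.5 * dz_rem / max(v_hand, 0.15), 0.18, 0.6))
        template = dj_contact_template(
            depth, t_arrest,
            S_MATRIX @ phi_arrest, S_MATRIX @ phidot_h,
            t_absorb_end,
            t_up=0.20 * jitter(0.05),
        )
        meta["truth_t_contact"] = t_start
        meta["truth_v_contact"] = -v0
        t_to, phi_to, phidot_to = _simulate_contact(
            chain, template, profile, rec, t_start, dt,
            phi_start, phidot_c,
            jump_type.value,
            impact=(t_arrest, phiddot_impact),
        )

    meta["truth_t_takeoff"] = t_to
    z_to = chain.com_position(phi_to)[1]
    v_to = chain.com_velocity(phi_to, phidot_to)[1]
    meta["truth_v_takeoff"] = v_to
    _simulate_flight(chain, rec, dt, phi_to, phidot_to, z_to, v_to, z_to, g)

    return _records_to_trial(subject, jump_type, drop_height, rec, sim_rate, meta)


def _records_to_trial(
    subject: SubjectRecord,
    jump_type: JumpType,
    drop_height: float,
    rec: _Recorder,
    sim_rate: float,
    meta: dict,
) -> SimulatedTrial:
    every = round(sim_rate / FORCE_RATE)
    kin_every = round(FORCE_RATE / KINEMATIC_RATE)

    theta = np.stack(rec.theta)[::every]
    thetadot = np.stack(rec.thetadot)[::every]
    grf = np.stack(rec.grf)[::every]
    cop = np.asarray(rec.cop)[::every]
    tau = np.stack(rec.tau)[::every]
    com = np.asarray(rec.com)[::every]

    n = theta.shape[0]
    force = {}
    for side in SIDES:
        vals = np.column_stack([grf[:, 1] / 2.0, grf[:, 0] / 2.0, cop])
        force[side] = TimeSeries.from_rate(vals, FORCE_RATE, units="N;N;m", channels=FORCE_CHANNELS)

    kin = {}
    for side in SIDES:
        kin[side] = TimeSeries.from_rate(
            theta[::kin_every], KINEMATIC_RATE, units="rad", channels=JOINTS
        )

    truth_com = TimeSeries.from_rate(com, FORCE_RATE, units="m;m/s;m/s^2", channels=("pos", "vel", "acc"))
    # per-side, extensor-positive: half the chain torque, sign-flipped from
    # the flexion-positive coordinates
    side_tau = -tau / 2.0
    torque_channels = tuple(f"{side}_{joint}" for side in SIDES for joint in JOINTS)
    torque_vals = np.column_stack([side_tau, side_tau])
    truth_torques = TimeSeries.from_rate(torque_vals, FORCE_RATE, units="N*m", channels=torque_channels)
    joint_channels = tuple(f"theta_{j}" for j in JOINTS) + tuple(f"thetadot_{j}" for j in JOINTS)
    truth_joints = TimeSeries.from_rate(
        np.column_stack([theta, thetadot]), FORCE_RATE,
        units="rad;rad/s", channels=joint_channels,
    )

    trial = SimulatedTrial(
        subject_ref=subject.subject_id,
        jump_type=jump_type,
        drop_height=drop_height,
        force=force,
        kinematics=kin,
        meta=meta,
        truth_torques=truth_torques,
        truth_com=truth_com,
        truth_joints=truth_joints,
    )
    trial.validate()
    return trial


def add_noise(
    trial: SimulatedTrial,
    force_sd: float = 0.0,
    angle_sd: float = 0.0,
    seed: int = 0,
) -> SimulatedTrial:
    """Additive Gaussian noise on force (Fz, Fy) and joint-angle channels.

    Ground-truth channels are untouched; deterministic for a given seed.
    """
    if force_sd < 0 or angle_sd < 0:
        raise ArgumentError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    force = {}
    for side in SIDES:
        ts = trial.force[side].copy()
        if force_sd > 0:
            ts.values[:, 0] += rng.normal(0.0, force_sd, ts.n)
            ts.values[:, 1] += rng.normal(0.0, force_sd, ts.n)
        force[side] = ts
    kin = {}
    for side in SIDES:
        ts = trial.kinematics[side].copy()
        if angle_sd > 0:
            ts.values += rng.normal(0.0, angle_sd, ts.values.shape)
        kin[side] = ts
    return SimulatedTrial(
        subject_ref=trial.subject_ref,
        jump_type=trial.jump_type,
        drop_height=trial.drop_height,
        force=force,
        kinematics=kin,
        meta={**trial.meta, "noise": {"force_sd": force_sd, "angle_sd": angle_sd, "seed": seed}},
        truth_torques=trial.truth_torques,
        truth_com=trial.truth_com,
        truth_joints=trial.truth_joints,
    )
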