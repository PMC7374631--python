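"""Planar bottom-up inverse dynamics and per-joint work decomposition.

Each side is treated as a foot-shank-thigh chain loaded by its own force
plate.  Segment kinematics are reconstructed from the (filtered, force-rate)
joint angles under the flat-foot assumption — valid over the analysis window
(contact through takeoff) that all work quantities are computed on.  The
Newton-Euler recursion walks foot -> shank -> thigh, carrying joint reaction
forces and solving each segment's moment balance for the net joint moment.

Moments are reported extensor-positive (ankle: plantarflexor-positive) and
normalized to body mass; joint angular velocities use the matching
extension-positive sign, so joint power is convention-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthro import SegmentParams, segment_parameters  # noqa: F401  (re-export)
from .constants import GRAVITY, JOINTS, SIDES
from .errors import AnalysisError, ArgumentError
from .com import WorkSummary, make_summary, signed_work_partition
from .signals import PhaseEvents
from .trials import TimeSeries


@dataclass(eq=False)
class JointKinetics:
    """Per-side moment/velocity/angle series on a common time base.

    ``moment``: N m/kg, extensor-positive, channels (hip, knee, ankle).
    ``omega``: rad/s, extension-positive.  ``theta``: rad, flexion-positive.
    """

    moment: dict[str, TimeSeries]
    omega: dict[str, TimeSeries]
    theta: dict[str, TimeSeries]
    convention: str = "extensor-positive"


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Moment about +x of force v applied at arm u, both (n, 2) as (y, z)."""
    return u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]


def _side_inverse_dynamics(
    theta: np.ndarray,
    t: np.ndarray,
    fz: np.ndarray,
    fy: np.ndarray,
    cop: np.ndarray,
    seg: SegmentParams,
    g: float,
) -> np.ndarray:
    """Extensor-positive (hip, knee, ankle) moments in N m, shape (n, 3)."""
    th_h, th_k, th_a = theta[:, 0], theta[:, 1], theta[:, 2]
    phi_s = th_a
    phi_t = th_a - th_k
    # (phi_b would be th_h + phi_t; the HAT is not part of the recursion)

    foot, shank, thigh = seg.foot, seg.shank, seg.thigh
    ankle = np.array([0.0, seg.ankle_height])
    foot_com = np.array(seg.foot_com_position)

    def unit(phi):
        return np.stack([np.sin(phi), np.cos(phi)], axis=1)

    u_s, u_t = unit(phi_s), unit(phi_t)
    knee = ankle + shank.length * u_s
    hip = knee + thigh.length * u_t
    r_sc = knee - shank.com_frac * shank.length * u_s
    r_tc = hip - thigh.com_frac * thigh.length * u_t

    def ddt(arr):
        return np.gradient(arr, t, axis=0)

    a_sc = ddt(ddt(r_sc))
    a_tc = ddt(ddt(r_tc))
    alpha_s = ddt(ddt(phi_s))
    alpha_t = ddt(ddt(phi_t))

    grf = np.stack([fy, fz], axis=1)
    r_cop = np.stack([cop, np.zeros_like(cop)], axis=1)

    # foot (assumed static): solve ankle reaction force and joint torque
    f_shank_on_foot = -grf + np.array([0.0, foot.mass * g])
    mu_grf = _cross2(r_cop - ankle, grf)
    mu_grav = _cross2((foot_com - ankle)[None, :].repeat(len(t), axis=0),
                      np.array([0.0, -foot.mass * g])[None, :].repeat(len(t), axis=0))
    tau_ankle = -(mu_grf + mu_grav)

    # shank
    f_foot_on_shank = -f_shank_on_foot
    f_thigh_on_shank = shank.mass * a_sc - f_foot_on_shank - np.array([0.0, -shank.mass * g])
    mu_knee_on_shank = (
        -shank.inertia * alpha_s
        + tau_ankle
        - _cross2(ankle - r_sc, f_foot_on_shank)
        - _cross2(knee - r_sc, f_thigh_on_shank)
    )
    tau_knee = -mu_knee_on_shank

    # thigh
    f_shank_on_thigh = -f_thigh_on_shank
    f_hat_on_thigh = thigh.mass * a_tc - f_shank_on_thigh - np.array([0.0, -thigh.mass * g])
    tau_hip = (
        -thigh.inertia * alpha_t
        - tau_knee
        - _cross2(knee - r_tc, f_shank_on_thigh)
        - _cross2(hip - r_tc, f_hat_on_thigh)
    )

    # flexion-coordinate torques -> extensor-positive moments
    return -np.stack([tau_hip, tau_knee, tau_ankle], axis=1)


def inverse_dynamics_planar(
    kinematics: dict[str, TimeSeries],
    grf: dict[str, TimeSeries],
    segparams: SegmentParams,
    mass: float,
    g: float = GRAVITY,
    contact_force_threshold: float = 50.0,
) -> JointKinetics:
    """Net hip/knee/ankle moments per side, normalized to body mass.

    ``kinematics`` must already be resampled (and filtered) onto the force
    time base; ``grf`` holds each side's plate record with channels
    (Fz, Fy, cop_y).  Raises :class:`AnalysisError` if the centre of
    pressure is missing while that plate is loaded.
    """
    if mass <= 0:
        raise ArgumentError("mass must be > 0")
    moment: dict[str, TimeSeries] = {}
    omega: dict[str, TimeSeries] = {}
    theta_out: dict[str, TimeSeries] = {}
    for side in SIDES:
        kin = kinematics[side]
        plate = grf[side]
        if kin.n != plate.n or np.max(np.abs(kin.t - plate.t)) > 1e-9:
            raise ArgumentError(f"{side}: kinematics not on the force time base")
        theta = np.atleast_2d(kin.values)
        fz = plate.channel("Fz")
        fy = plate.channel("Fy")
        cop = plate.channel("cop_y")
        loaded = fz > contact_force_threshold
        if np.any(~np.isfinite(cop[loaded])):
            raise AnalysisError(f"{side}: centre of pressure missing during contact")
        m_nm = _side_inverse_dynamics(theta, kin.t, fz, fy, cop, segparams, g)
        w = -np.gradient(theta, kin.t, axis=0)  # extension-positive velocity
        moment[side] = TimeSeries(t=kin.t.copy(), values=m_nm / mass, rate=kin.rate,
                                  units="N*m/kg", channels=JOINTS)
        omega[side] = TimeSeries(t=kin.t.copy(), values=w, rate=kin.rate,
                                 units="rad/s", channels=JOINTS)
        theta_out[side] = kin.copy()
    return JointKinetics(moment=moment, omega=omega, theta=theta_out)


def joint_work(kin: JointKinetics, events: PhaseEvents) -> dict[str, dict[str, WorkSummary]]:
    """Sign-partitioned work per side and joint over the analysis window (J/kg)."""
    start, end = events.window
    out: dict[str, dict[str, WorkSummary]] = {}
    for side in SIDES:
        mom = kin.moment[side]
        t = mom.t
        i0 = int(np.searchsorted(t, start - 1e-12))
        i1 = int(np.searchsorted(t, end + 1e-12))
        if i1 - i0 < 2:
            raise ArgumentError("analysis window contains fewer than 2 samples")
        out[side] = {}
        for j, joint in enumerate(JOINTS):
            power = mom.values[i0:i1, j] * kin.omega[side].values[i0:i1, j]
            w_neg, w_pos = signed_work_partition(power, t[i0:i1])
            out[side][joint] = make_summary(w_neg, w_pos, label=joint)
    return out


def bilateral_average(left: WorkSummary, right: WorkSummary) -> WorkSummary:
    """Mean of left/right work components; the ratio is recomputed from the
    averaged components (not averaged itself)."""
    if left.label != right.label:
        raise ArgumentError(f"joint mismatch: {left.label!r} vs {right.label!r}")
    w_neg = 0.5 * (left.w_neg + right.w_neg)
    w_pos = 0.5 * (left.w_pos + right.w_pos)
    return make_summary(w_neg, w_pos, label=left.label)
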