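"""Planar foot-shank-thigh-HAT chain dynamics for the jump simulator.

During ground contact the foot is fixed flat on the plate and the chain is a
3-DOF serial linkage.  Generalized coordinates are the absolute segment lean
angles from vertical, ``phi = (phi_shank, phi_thigh, phi_hat)``, positive
when the top of the segment leans anterior (+y).  The sagittal plane is
(y, z): y anterior, z up, moments about the +x axis.

Joint angles (flexion-positive) relate to ``phi`` through the constant matrix
``S``::

    theta = S @ phi,   theta = (hip, knee, ankle-dorsiflexion)

and joint torques ``tau`` (conjugate to ``theta``) enter the equations of
motion as generalized forces ``Q = S.T @ tau``.

With absolute angles the dynamics collapse to compact closed forms: the mass
matrix is ``P * cos(phi_j - phi_k) + diag(I)`` where ``P`` is a constant
coupling matrix, the velocity bias is ``-P * sin(phi_j - phi_k) @ phidot^2``,
and gravity is ``-g * q_k sin(phi_k)``.
"""

from __future__ import annotations

import numpy as np

from ..anthro import SegmentParams
from ..constants import GRAVITY

#: theta = S @ phi; rows are (hip, knee, ankle), phi = (shank, thigh, hat)
S_MATRIX = np.array(
    [
        [0.0, -1.0, 1.0],  # hip flexion = phi_hat - phi_thigh
        [1.0, -1.0, 0.0],  # knee flexion = phi_shank - phi_thigh
        [1.0, 0.0, 0.0],  # ankle dorsiflexion = phi_shank
    ]
)
S_INV_T = np.linalg.inv(S_MATRIX).T


def phi_from_theta(theta: np.ndarray) -> np.ndarray:
    """Invert ``theta = S @ phi`` (works on (3,) or (n, 3) arrays)."""
    return np.asarray(theta) @ np.linalg.inv(S_MATRIX).T


class ContactChain:
    """Equations of motion of the grounded chain scaled to one subject.

    ``leg_count=2`` lumps both legs into single shank/thigh/foot segments of
    doubled mass (the simulated jumps are bilaterally symmetric); per-side
    quantities are then exactly half of the chain's.
    """

    def __init__(self, params: SegmentParams, leg_count: int = 2, g: float = GRAVITY):
        self.params = params
        self.leg_count = leg_count
        self.g = g

        foot, shank, thigh, hat = params.foot, params.shank, params.thigh, params.hat
        self.m_foot = leg_count * foot.mass
        # moving segments: (shank, thigh, hat)
        self.m = np.array([leg_count * shank.mass, leg_count * thigh.mass, hat.mass])
        self.inertia = np.array(
            [leg_count * shank.inertia, leg_count * thigh.inertia, hat.inertia]
        )
        self.m_total = self.m_foot + self.m.sum()

        Ls, Lt, Lb = shank.length, thigh.length, hat.length
        cs, ct, cb = shank.com_frac, thigh.com_frac, hat.com_frac
        # A[i, j]: lever of unit vector u(phi_j) in moving-segment-i COM position
        # (segment COMs measured from the proximal end: shank from knee, thigh
        # from hip, HAT upward from hip).
        self.A = np.array(
            [
                [(1.0 - cs) * Ls, 0.0, 0.0],
                [Ls, (1.0 - ct) * Lt, 0.0],
                [Ls, Lt, cb * Lb],
            ]
        )
        self.P = (self.m[:, None, None] * self.A[:, :, None] * self.A[:, None, :]).sum(axis=0)
        self.q = self.m @ self.A  # first mass moments per coordinate

        self.ankle = np.array([0.0, params.ankle_height])
        self.foot_com = np.array(params.foot_com_position)
        self.knee_levers = np.array([Ls, 0.0, 0.0])
        self.hip_levers = np.array([Ls, Lt, 0.0])

    # -- kinematics -------------------------------------------------------

    def _trig(self, phi: np.ndarray):
        return np.sin(phi), np.cos(phi)

    def com_position(self, phi: np.ndarray) -> np.ndarray:
        """Whole-body COM (y, z), foot included."""
        s, c = self._trig(phi)
        moving = self.m.sum() * self.ankle + np.stack([self.q @ s, self.q @ c], axis=-1)
        return (self.m_foot * self.foot_com + moving) / self.m_total

    def com_jacobian(self, phi: np.ndarray) -> np.ndarray:
        """d(COM)/d(phi), shape (2, 3)."""
        s, c = self._trig(phi)
        return np.stack([self.q * c, -self.q * s]) / self.m_total

    def com_velocity(self, phi: np.ndarray, phidot: np.ndarray) -> np.ndarray:
        return self.com_jacobian(phi) @ phidot

    def joint_positions(self, phi: np.ndarray) -> dict[str, np.ndarray]:
        s, c = self._trig(phi)
        knee = self.ankle + np.array([self.knee_levers @ s, self.knee_levers @ c])
        hip = self.ankle + np.array([self.hip_levers @ s, self.hip_levers @ c])
        return {"ankle": self.ankle.copy(), "knee": knee, "hip": hip}

    # -- dynamics ---------------------------------------------------------

    def mass_matrix(self, phi: np.ndarray) -> np.ndarray:
        d = phi[:, None] - phi[None, :]
        return self.P * np.cos(d) + np.diag(self.inertia)

    def bias(self, phi: np.ndarray, phidot: np.ndarray) -> np.ndarray:
        d = phi[None, :] - phi[:, None]  # d[k, j] = phi_j - phi_k
        return -(self.P * np.sin(d)) @ (phidot**2)

    def gravity_vector(self, phi: np.ndarray) -> np.ndarray:
        return -self.g * self.q * np.sin(phi)

    def forward(self, phi: np.ndarray, phidot: np.ndarray, tau: np.ndarray) -> np.ndarray:
        """Angular accelerations given flexion-positive joint torques ``tau``."""
        Q = S_MATRIX.T @ tau
        rhs = Q - self.bias(phi, phidot) - self.gravity_vector(phi)
        return np.linalg.solve(self.mass_matrix(phi), rhs)

    def gravity_compensation_torques(self, phi: np.ndarray) -> np.ndarray:
        """Joint torques whose generalized force balances gravity."""
        return S_INV_T @ self.gravity_vector(phi)

    def grf(self, phi: np.ndarray, phidot: np.ndarray, phiddot: np.ndarray) -> np.ndarray:
        """Ground reaction force (Fy, Fz) from whole-chain Newton's law."""
        s, c = self._trig(phi)
        acc_sum_y = self.q @ (c * phiddot - s * phidot**2)
        acc_sum_z = self.q @ (-s * phiddot - c * phidot**2)
        return np.array([acc_sum_y, acc_sum_z + self.m_total * self.g])

    def centre_of_pressure(self, tau_ankle: float, grf: np.ndarray) -> float:
        """CoP anterior position (m, ankle at y=0) from foot moment balance."""
        fy, fz = grf
        if abs(fz) < 1e-9:
            return 0.0
        y_fc = self.foot_com[0]
        z_a = self.ankle[1]
        return (y_fc * self.m_foot * self.g - tau_ankle - z_a * fy) / fz

    def energy(self, phi: np.ndarray, phidot: np.ndarray) -> float:
        """Total mechanical energy of the chain (kinetic + gravitational)."""
        kinetic = 0.5 * phidot @ self.mass_matrix(phi) @ phidot
        potential = self.m_total * self.g * self.com_position(phi)[1]
        return float(kinetic + potential)
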