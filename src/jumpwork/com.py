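"""Centre-of-mass forward dynamics and work-loop decomposition.

COM acceleration is total vertical plate force divided by body mass (minus
gravity); velocity and displacement follow by cumulative trapezoidal
integration.  Work is decomposed by the sign of instantaneous COM power
``P = Fz_total * v`` — the negative and positive parts partition net work
exactly, and the net equals the enclosed area of the force-displacement work
loop.

All work values are expressed per kilogram of body mass (J/kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .constants import GRAVITY
from .errors import ArgumentError
from .signals import PhaseEvents
from .trials import JumpType, TimeSeries


@dataclass(eq=False)
class ComState:
    """Vertical COM acceleration, velocity and displacement over the window."""

    a: TimeSeries  # m/s^2
    v: TimeSeries  # m/s
    x: TimeSeries  # m, relative to the window start


@dataclass(eq=False)
class WorkLoop:
    """Paired drive-excursion curve over the analysis window.

    ``drive`` is force (N/kg) or moment (N m/kg); ``excursion`` is
    displacement (m) or angle (rad).
    """

    drive: np.ndarray
    excursion: np.ndarray
    events: PhaseEvents | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.drive = np.asarray(self.drive, dtype=float)
        self.excursion = np.asarray(self.excursion, dtype=float)
        if self.drive.shape != self.excursion.shape:
            raise ArgumentError("drive and excursion must have equal length")

    def enclosed_area(self) -> float:
        """Signed path integral of drive over excursion (equals net work)."""
        if self.drive.size < 2:
            return 0.0
        return float(np.trapezoid(self.drive, self.excursion))


@dataclass(frozen=True)
class WorkSummary:
    """Negative/positive/net work (J/kg) and the negative:positive ratio (%)."""

    w_neg: float
    w_pos: float
    w_net: float
    ratio: float  # percent; NaN when undefined
    ratio_defined: bool = True
    label: str | None = None


def neg_pos_ratio(w_neg: float, w_pos: float) -> tuple[float, bool]:
    """``|W_neg| / W_pos * 100`` (%), with a defined-flag.

    Returns ``(nan, False)`` when ``w_pos`` is zero; raises
    :class:`ArgumentError` for negative ``w_pos``.
    """
    if w_pos < 0:
        raise ArgumentError("w_pos must be >= 0")
    if w_pos == 0:
        return float("nan"), False
    return abs(w_neg) / w_pos * 100.0, True


def make_summary(w_neg: float, w_pos: float, label: str | None = None) -> WorkSummary:
    ratio, defined = neg_pos_ratio(w_neg, w_pos)
    return WorkSummary(w_neg=w_neg, w_pos=w_pos, w_net=w_neg + w_pos,
                       ratio=ratio, ratio_defined=defined, label=label)


def _window_slice(t: np.ndarray, events: PhaseEvents) -> slice:
    start, end = events.window
    i0 = int(np.searchsorted(t, start - 1e-12))
    i1 = int(np.searchsorted(t, end + 1e-12))
    if i1 - i0 < 2:
        raise ArgumentError("analysis window contains fewer than 2 samples")
    if t[0] > start + 1e-9 or t[-1] < end - 1e-9:
        raise ArgumentError("force series does not cover the analysis window")
    return slice(i0, i1)


def com_kinematics(
    force_total: TimeSeries,
    mass: float,
    events: PhaseEvents,
    jump_type: JumpType,
    drop_height: float = 0.0,
    g: float = GRAVITY,
    drop_scale: float = 1.0,
) -> ComState:
    """COM acceleration/velocity/displacement over the analysis window.

    Initial velocity is 0 at CMJ movement onset or ``-drop_scale *
    sqrt(2 g h)`` at drop-jump ground contact (``drop_scale`` expresses
    known step-off attrition of the nominal height; default 1).
    """
    if mass <= 0:
        raise ArgumentError("mass must be > 0")
    sl = _window_slice(force_total.t, events)
    t = force_total.t[sl]
    f = np.atleast_2d(force_total.values.T).T[sl, 0]
    a = f / mass - g
    v0 = 0.0 if jump_type is JumpType.CMJ else -drop_scale * np.sqrt(2.0 * g * drop_height)
    v = v0 + integrate.cumulative_trapezoid(a, t, initial=0.0)
    x = integrate.cumulative_trapezoid(v, t, initial=0.0)
    rate = force_total.rate
    return ComState(
        a=TimeSeries(t=t.copy(), values=a, rate=rate, units="m/s^2"),
        v=TimeSeries(t=t.copy(), values=v, rate=rate, units="m/s"),
        x=TimeSeries(t=t.copy(), values=x, rate=rate, units="m"),
    )


def signed_work_partition(power: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Split trapezoidal ``integral(P dt)`` into negative and positive parts.

    Each inter-sample trapezoid is attributed by the sign of its own
    contribution, so ``w_neg + w_pos`` equals the plain trapezoidal integral
    to machine precision.
    """
    contrib = 0.5 * (power[1:] + power[:-1]) * np.diff(t)
    return float(contrib[contrib < 0].sum()), float(contrib[contrib > 0].sum())


def com_work(
    force_total: TimeSeries,
    state: ComState,
    events: PhaseEvents,
    mass: float,
    mode: str = "total",
    g: float = GRAVITY,
) -> WorkSummary:
    """Sign-partitioned COM work over the analysis window, in J/kg.

    ``mode="total"`` uses ``P = Fz * v`` (gravity accounted through the
    displacement term of the energy balance); ``mode="net"`` uses
    ``P = (Fz - m g) * v``.
    """
    if mode not in ("total", "net"):
        raise ArgumentError(f"unknown COM work mode {mode!r}")
    sl = _window_slice(force_total.t, events)
    t = force_total.t[sl]
    f = np.atleast_2d(force_total.values.T).T[sl, 0]
    if t.shape != state.v.t.shape or np.max(np.abs(t - state.v.t)) > 1e-9:
        raise ArgumentError("force and COM state are not on the same window grid")
    drive = f if mode == "total" else f - mass * g
    power = drive * state.v.values / mass
    w_neg, w_pos = signed_work_partition(power, t)
    return make_summary(w_neg, w_pos, label="COM")


def com_workloop(
    force_total: TimeSeries,
    state: ComState,
    events: PhaseEvents,
    mass: float,
) -> WorkLoop:
    """Force-displacement loop (N/kg vs m) over the analysis window."""
    sl = _window_slice(force_total.t, events)
    f = np.atleast_2d(force_total.values.T).T[sl, 0]
    if f.shape != state.x.values.shape:
        raise ArgumentError("force and COM state are not on the same window grid")
    return WorkLoop(drive=f / mass, excursion=state.x.values.copy(), events=events, label="COM")
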