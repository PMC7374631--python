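"""Filtering, resampling and phase segmentation of jump trials.

The low-pass filter is the conventional biomechanics "zero-lag fourth-order"
Butterworth: a second-order design run forward and backward (effective
fourth order, zero phase).  Phase events bound the analysis window: movement
onset (CMJ) or first ground contact (DJ) through takeoff, with the lowest
COM position in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, interpolate, signal

from .constants import GRAVITY
from .errors import ArgumentError, EventDetectionError
from .trials import RawTrial, TimeSeries


@dataclass(frozen=True)
class EventConfig:
    """Thresholds for phase-event detection (all configurable).

    Contact/takeoff thresholding runs on the (lightly) ``event_cutoff``-
    filtered force so impact timing is preserved; the heavier
    ``filter_cutoff`` smoothing is used only for CMJ onset detection and the
    lowest-COM search.
    """

    contact_threshold: float = 20.0  # N, total vertical force
    contact_sustain: float = 0.01  # s, force must stay beyond threshold
    onset_fraction: float = 0.05  # of body weight
    onset_sustain: float = 0.05  # s
    event_cutoff: float | None = None  # Hz; None = raw force (sustain gives noise robustness)
    filter_cutoff: float = 11.0  # Hz
    filter_order: int = 4


@dataclass(frozen=True)
class PhaseEvents:
    """Timestamps bounding the analysis window of one trial.

    ``t_onset`` is set for CMJ trials, ``t_contact`` for drop jumps; the
    window runs from whichever is set through ``t_takeoff``.
    """

    t_takeoff: float
    t_lowest: float
    t_onset: float | None = None
    t_contact: float | None = None

    @property
    def start(self) -> float:
        t = self.t_onset if self.t_contact is None else self.t_contact
        assert t is not None
        return t

    @property
    def window(self) -> tuple[float, float]:
        return (self.start, self.t_takeoff)

    def __post_init__(self) -> None:
        if not (self.start < self.t_lowest < self.t_takeoff):
            raise EventDetectionError(
                f"event ordering violated: start={self.start:.4f}, "
                f"lowest={self.t_lowest:.4f}, takeoff={self.t_takeoff:.4f}"
            )


def lowpass_zero_lag(series: TimeSeries, cutoff: float, order: int = 4) -> TimeSeries:
    """Zero-lag Butterworth low-pass via forward-backward filtering.

    ``order`` is the *effective* order; the underlying single-pass design has
    ``order // 2`` poles, so the default 4 matches the usual dual-pass
    second-order convention.  Raises :class:`ArgumentError` if ``cutoff`` is
    at or above Nyquist or ``order`` is odd.
    """
    if cutoff >= series.rate / 2.0:
        raise ArgumentError(
            f"cutoff {cutoff} Hz must be below Nyquist ({series.rate / 2} Hz)"
        )
    if cutoff <= 0:
        raise ArgumentError("cutoff must be > 0")
    if order % 2 != 0 or order < 2:
        raise ArgumentError("order must be a positive even integer")
    sos = signal.butter(order // 2, cutoff, btype="low", fs=series.rate, output="sos")
    vals = np.atleast_2d(series.values.T).T
    out = np.empty_like(vals, dtype=float)
    for j in range(vals.shape[1]):
        out[:, j] = signal.sosfiltfilt(sos, vals[:, j])
    if series.values.ndim == 1:
        out = out[:, 0]
    return TimeSeries(t=series.t.copy(), values=out, rate=series.rate,
                      units=series.units, channels=series.channels)


def resample_uniform(series: TimeSeries, target_rate: float) -> TimeSeries:
    """Cubic-spline interpolation onto a uniform grid at ``target_rate``.

    The new grid spans the original interval starting at the original first
    sample.  Linear interpolation is used when fewer than 4 samples exist.
    """
    if target_rate <= 0:
        raise ArgumentError("target_rate must be > 0")
    if series.n < 2:
        raise ArgumentError("cannot resample a series with fewer than 2 samples")
    t0, t1 = series.t[0], series.t[-1]
    n_new = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    t_new = t0 + np.arange(n_new) / target_rate
    if series.n >= 4:
        interp = interpolate.CubicSpline(series.t, series.values, axis=0)
    else:
        interp = interpolate.interp1d(series.t, series.values, axis=0)
    return TimeSeries(t=t_new, values=np.asarray(interp(t_new)), rate=float(target_rate),
                      units=series.units, channels=series.channels)


def measure_body_weight(
    trial: RawTrial,
    window: tuple[float, float] = (0.05, 0.45),
    mass: float | None = None,
    g: float = GRAVITY,
) -> float:
    """Body weight in newtons.

    For CMJ trials: the mean total vertical force over a quiet-standing
    ``window`` (seconds).  For drop jumps there is no standing period in the
    record, so the fallback ``mass * g`` is used (mass from the argument or
    from trial metadata).
    """
    if trial.jump_type.is_drop_jump:
        m = mass if mass is not None else trial.meta.get("body_mass")
        if m is None:
            raise ArgumentError("drop-jump body weight needs a subject mass")
        return float(m) * g
    t0, t1 = window
    fz = trial.total_fz()
    if not (t1 > t0):
        raise ArgumentError("window must have positive length")
    if t0 < fz.t[0] - 1e-9 or t1 > fz.t[-1] + 1e-9:
        raise ArgumentError("quiet-standing window lies outside the recording")
    mask = (fz.t >= t0) & (fz.t <= t1)
    return float(np.mean(fz.values[mask]))


def _sustained_above(mask: np.ndarray, n_sustain: int) -> int | None:
    """First index where ``mask`` stays True for ``n_sustain`` samples."""
    if n_sustain <= 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    csum = np.convolve(mask.astype(int), np.ones(n_sustain, dtype=int), mode="valid")
    hits = np.flatnonzero(csum == n_sustain)
    return int(hits[0]) if hits.size else None


def detect_events(
    trial: RawTrial,
    bw: float,
    config: EventConfig = EventConfig(),
    g: float = GRAVITY,
) -> PhaseEvents:
    """Locate onset/contact, lowest-COM and takeoff times from plate force.

    Contact and takeoff use a total-force threshold; CMJ onset requires
    ``|Fz - BW|`` to exceed ``onset_fraction * BW`` for ``onset_sustain``
    seconds and then walks back to the last crossing of body weight.  The
    lowest-COM time comes from double integration of force over the window.
    """
    fz_raw = trial.total_fz()
    if config.event_cutoff is not None:
        f = lowpass_zero_lag(fz_raw, config.event_cutoff, config.filter_order).values
    else:
        f = fz_raw.values
    f_smooth = lowpass_zero_lag(fz_raw, config.filter_cutoff, config.filter_order).values
    t = fz_raw.t
    thr = config.contact_threshold
    n = f.shape[0]
    n_contact = max(1, int(round(config.contact_sustain * fz_raw.rate)))

    if not np.any(f > thr):
        raise EventDetectionError("no ground contact found (force never exceeds threshold)")

    if trial.jump_type.is_drop_jump:
        if f[0] > thr:
            raise EventDetectionError("drop-jump record does not start in flight")
        i_contact = _sustained_above(f > thr, n_contact)
        if i_contact is None:
            raise EventDetectionError("no ground contact after the drop")
        t_contact, t_onset = float(t[i_contact]), None
        i_start = i_contact
        v0 = -np.sqrt(2.0 * g * trial.drop_height)
    else:
        dev = np.abs(f_smooth - bw) > config.onset_fraction * bw
        n_sustain = max(1, int(round(config.onset_sustain * fz_raw.rate)))
        i_dev = _sustained_above(dev, n_sustain)
        if i_dev is None:
            raise EventDetectionError("no movement onset found in CMJ trial")
        # walk back to the last crossing of body weight before the deviation
        crossings = np.flatnonzero(np.diff(np.sign(f_smooth[: i_dev + 1] - bw)) != 0)
        i_start = int(crossings[-1]) if crossings.size else i_dev
        t_onset, t_contact = float(t[i_start]), None
        v0 = 0.0

    i_off = _sustained_above(f[i_start:] < thr, n_contact)
    if i_off is None:
        raise EventDetectionError("no takeoff found (force never drops below threshold)")
    i_takeoff = i_start + i_off
    if i_takeoff <= i_start + 1:
        raise EventDetectionError("takeoff coincides with window start")
    t_takeoff = float(t[i_takeoff])

    # lowest COM from forward dynamics inside the window
    m = bw / g
    sl = slice(i_start, i_takeoff + 1)
    a = f[sl] / m - g
    v = v0 + integrate.cumulative_trapezoid(a, t[sl], initial=0.0)
    x = integrate.cumulative_trapezoid(v, t[sl], initial=0.0)
    i_low = i_start + int(np.argmin(x))
    if i_low == i_start or i_low >= i_takeoff:
        raise EventDetectionError("no COM minimum inside the analysis window")

    return PhaseEvents(
        t_takeoff=t_takeoff,
        t_lowest=float(t[i_low]),
        t_onset=t_onset,
        t_contact=t_contact,
    )
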