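"""Trial data model and the on-disk trial format.

A trial couples two force-plate records (vertical force, anterior-posterior
force and centre of pressure at 1,000 Hz) with sagittal joint-angle records
for both legs (hip, knee, ankle at 200 Hz), plus jump metadata.

On disk a trial is a directory holding::

    trial.json        metadata sidecar (subject, jump type, rates, units)
    force.tsv         t, left_Fz, left_Fy, left_cop_y, right_Fz, right_Fy, right_cop_y
    kinematics.tsv    t, left_hip, left_knee, left_ankle, right_hip, right_knee, right_ankle
    truth.tsv         (optional) simulator ground truth: COM state and joint torques

All tables are tab-separated text with a header row and full float precision,
so a write/read round trip is lossless for finite values.  Times are seconds
from the start of the recording; forces are newtons; angles are radians.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import FORCE_CHANNELS, FORCE_RATE, JOINTS, KINEMATIC_RATE, SIDES
from .errors import FormatError, ValidationError

_FORMAT_TAG = "jumpwork-trial/1"
_TIME_TOL = 1e-9  # s, max deviation of sample spacing from 1/rate


class JumpType(str, enum.Enum):
    """The six jump conditions: countermovement jump and five drop heights."""

    CMJ = "CMJ"
    DJ15 = "DJ15"
    DJ30 = "DJ30"
    DJ45 = "DJ45"
    DJ60 = "DJ60"
    DJ75 = "DJ75"

    @property
    def nominal_drop_height(self) -> float:
        """Platform height in metres (0 for the countermovement jump)."""
        return _DROP_HEIGHTS[self]

    @property
    def is_drop_jump(self) -> bool:
        return self is not JumpType.CMJ


_DROP_HEIGHTS = {
    JumpType.CMJ: 0.0,
    JumpType.DJ15: 0.15,
    JumpType.DJ30: 0.30,
    JumpType.DJ45: 0.45,
    JumpType.DJ60: 0.60,
    JumpType.DJ75: 0.75,
}


@dataclass(eq=False)
class TimeSeries:
    """A uniformly sampled multichannel series.

    Parameters
    ----------
    t : ndarray, shape (n,)
        Sample times in seconds, uniform at ``1/rate``.
    values : ndarray, shape (n,) or (n, k)
        Channel data; 2-D arrays hold one channel per column.
    rate : float
        Sampling rate in Hz.
    units : str
        Unit string for the values (informational).
    channels : tuple of str, optional
        Column names for 2-D values.
    """

    t: np.ndarray
    values: np.ndarray
    rate: float
    units: str = ""
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channels is not None:
            self.channels = tuple(self.channels)

    @classmethod
    def from_rate(
        cls,
        values: np.ndarray,
        rate: float,
        t0: float = 0.0,
        units: str = "",
        channels: tuple[str, ...] | None = None,
    ) -> "TimeSeries":
        values = np.asarray(values, dtype=float)
        t = t0 + np.arange(values.shape[0]) / float(rate)
        return cls(t=t, values=values, rate=float(rate), units=units, channels=channels)

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n else 0.0

    def channel(self, name: str) -> np.ndarray:
        """Return one named column as a 1-D array."""
        if self.values.ndim == 1:
            if self.channels and self.channels[0] == name:
                return self.values
            raise KeyError(name)
        if not self.channels or name not in self.channels:
            raise KeyError(name)
        return self.values[:, self.channels.index(name)]

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            t=self.t.copy(),
            values=self.values.copy(),
            rate=self.rate,
            units=self.units,
            channels=self.channels,
        )

    def validate(self, name: str = "series") -> None:
        """Raise :class:`ValidationError` on any structural violation."""
        if self.n == 0:
            raise ValidationError(f"{name}: empty series")
        if self.values.shape[0] != self.n:
            raise ValidationError(
                f"{name}: length mismatch (t has {self.n}, values has {self.values.shape[0]})"
            )
        if self.rate <= 0:
            raise ValidationError(f"{name}: non-positive rate {self.rate}")
        if self.n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValidationError(f"{name}: time vector not strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.rate)) > _TIME_TOL:
                raise ValidationError(
                    f"{name}: sample spacing deviates from 1/rate by more than {_TIME_TOL} s"
                )
        if self.channels is not None:
            ncol = 1 if self.values.ndim == 1 else self.values.shape[1]
            if len(self.channels) != ncol:
                raise ValidationError(
                    f"{name}: {len(self.channels)} channel names for {ncol} columns"
                )

    def equals(self, other: "TimeSeries") -> bool:
        return (
            self.rate == other.rate
            and self.units == other.units
            and self.channels == other.channels
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.values, other.values)
        )


@dataclass(eq=False)
class RawTrial:
    """One recorded (or simulated) jump trial.

    ``force`` and ``kinematics`` map side (``"left"``/``"right"``) to a
    :class:`TimeSeries`; force channels are ``(Fz, Fy, cop_y)`` per plate and
    kinematic channels are ``(hip, knee, ankle)`` joint angles.  Both records
    share time origin 0 at the start of the recording.
    """

    subject_ref: str
    jump_type: JumpType
    drop_height: float
    force: dict[str, TimeSeries]
    kinematics: dict[str, TimeSeries]
    meta: dict = field(default_factory=dict)

    @property
    def force_rate(self) -> float:
        return float(self.meta.get("force_rate", FORCE_RATE))

    @property
    def kinematic_rate(self) -> float:
        return float(self.meta.get("kinematic_rate", KINEMATIC_RATE))

    def total_fz(self) -> TimeSeries:
        """Summed vertical force over both plates, at the force rate."""
        left, right = self.force["left"], self.force["right"]
        return TimeSeries(
            t=left.t.copy(),
            values=left.channel("Fz") + right.channel("Fz"),
            rate=left.rate,
            units="N",
            channels=("Fz",),
        )

    def validate(self, require_finite: bool = False) -> None:
        if self.drop_height < 0:
            raise ValidationError("drop_height must be >= 0")
        for group, mapping, want_channels, want_rate in (
            ("force", self.force, FORCE_CHANNELS, self.force_rate),
            ("kinematics", self.kinematics, JOINTS, self.kinematic_rate),
        ):
            for side in SIDES:
                if side not in mapping:
                    raise ValidationError(f"{group}: missing side '{side}'")
                ts = mapping[side]
                ts.validate(name=f"{group}[{side}]")
                if ts.channels != tuple(want_channels):
                    raise ValidationError(
                        f"{group}[{side}]: channels {ts.channels} != {tuple(want_channels)}"
                    )
                if abs(ts.rate - want_rate) > 1e-9:
                    raise ValidationError(
                        f"{group}[{side}]: rate {ts.rate} Hz != declared {want_rate} Hz"
                    )
                if require_finite and not np.all(np.isfinite(ts.values)):
                    bad = int(np.argwhere(~np.isfinite(np.atleast_2d(ts.values.T).T))[0][0])
                    raise ValidationError(
                        f"{group}[{side}]: non-finite value at sample {bad}"
                    )
        t0f = self.force["left"].t[0]
        t0k = self.kinematics["left"].t[0]
        if abs(t0f - t0k) > 1e-9:
            raise ValidationError(
                f"force and kinematics time origins differ ({t0f} vs {t0k})"
            )


def _write_table(path: Path, t: np.ndarray, columns: list[tuple[str, np.ndarray]]) -> None:
    header = "t\t" + "\t".join(name for name, _ in columns)
    data = np.column_stack([t] + [col for _, col in columns])
    np.savetxt(path, data, fmt="%.17g", delimiter="\t", header=header, comments="")


def _read_table(path: Path, expected_columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FormatError(f"missing file: {path.name}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in ["t"] + expected_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing channel column(s) {missing}")
    return df


def write_trial(trial: RawTrial, path: str | Path) -> None:
    """Serialize a trial to a directory (created if absent).

    Raises :class:`ValidationError` if the trial violates its invariants
    (including any non-finite force/kinematic sample) and ``OSError`` if the
    destination is unwritable.
    """
    trial.validate(require_finite=True)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "format": _FORMAT_TAG,
        "subject_ref": trial.subject_ref,
        "jump_type": trial.jump_type.value,
        "drop_height": trial.drop_height,
        "force_rate": trial.force_rate,
        "kinematic_rate": trial.kinematic_rate,
        "n_force": trial.force["left"].n,
        "n_kinematics": trial.kinematics["left"].n,
        "units": {"force": "N", "cop": "m", "angle": "rad", "time": "s"},
        "meta": trial.meta,
        "has_truth": hasattr(trial, "truth_torques"),
    }
    (path / "trial.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    fcols = []
    for side in SIDES:
        for ch in FORCE_CHANNELS:
            fcols.append((f"{side}_{ch}", trial.force[side].channel(ch)))
    _write_table(path / "force.tsv", trial.force["left"].t, fcols)

    kcols = []
    for side in SIDES:
        for joint in JOINTS:
            kcols.append((f"{side}_{joint}", trial.kinematics[side].channel(joint)))
    _write_table(path / "kinematics.tsv", trial.kinematics["left"].t, kcols)

    if meta["has_truth"]:
        truth_com: TimeSeries = trial.truth_com  # type: ignore[attr-defined]
        truth_torques: TimeSeries = trial.truth_torques  # type: ignore[attr-defined]
        cols = [(f"com_{c}", truth_com.channel(c)) for c in ("pos", "vel", "acc")]
        cols += [(f"torque_{c}", truth_torques.channel(c))
                 for c in truth_torques.channels or ()]
        truth_joints: TimeSeries | None = getattr(trial, "truth_joints", None)
        if truth_joints is not None:
            cols += [(c, truth_joints.channel(c)) for c in truth_joints.channels or ()]
        _write_table(path / "truth.tsv", truth_com.t, cols)


def read_trial(path: str | Path) -> RawTrial:
    """Read a trial directory written by :func:`write_trial`.

    Returns a :class:`RawTrial`, or a
    :class:`~jumpwork.synthetic.simulate.SimulatedTrial` when ground-truth
    tables are present.  Raises :class:`FormatError` naming the violation on
    any structural problem (missing channel, rate mismatch, non-monotone
    time, truncated table).
    """
    path = Path(path)
    sidecar = path / "trial.json"
    if not sidecar.exists():
        raise FormatError(f"missing file: trial.json in {path}")
    meta = json.loads(sidecar.read_text())
    if meta.get("format") != _FORMAT_TAG:
        raise FormatError(f"unrecognized format tag {meta.get('format')!r}")

    force_rate = float(meta["force_rate"])
    kin_rate = float(meta["kinematic_rate"])

    fcols = [f"{side}_{ch}" for side in SIDES for ch in FORCE_CHANNELS]
    fdf = _read_table(path / "force.tsv", fcols)
    kcols = [f"{side}_{joint}" for side in SIDES for joint in JOINTS]
    kdf = _read_table(path / "kinematics.tsv", kcols)

    for name, df, declared in (("force.tsv", fdf, meta.get("n_force")),
                               ("kinematics.tsv", kdf, meta.get("n_kinematics"))):
        if declared is not None and len(df) != declared:
            raise FormatError(f"{name}: {len(df)} rows but sidecar declares {declared}")
    expected_rows = round((fdf["t"].iloc[-1] - fdf["t"].iloc[0]) * force_rate) + 1
    if len(fdf) != expected_rows:
        raise FormatError(
            f"force.tsv: {len(fdf)} rows but time span implies {expected_rows}"
        )

    def build(df: pd.DataFrame, side: str, names: tuple[str, ...], rate: float, units: str, tag: str) -> TimeSeries:
        t = df["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{tag}: time column not strictly increasing")
        if len(t) > 1 and np.max(np.abs(np.diff(t) - 1.0 / rate)) > _TIME_TOL:
            raise FormatError(f"{tag}: sample spacing inconsistent with rate {rate} Hz")
        vals = df[[f"{side}_{c}" for c in names]].to_numpy()
        return TimeSeries(t=t, values=vals, rate=rate, units=units, channels=names)

    force = {s: build(fdf, s, FORCE_CHANNELS, force_rate, "N;N;m", "force.tsv") for s in SIDES}
    kin = {s: build(kdf, s, JOINTS, kin_rate, "rad", "kinematics.tsv") for s in SIDES}

    base = dict(
        subject_ref=meta["subject_ref"],
        jump_type=JumpType(meta["jump_type"]),
        drop_height=float(meta["drop_height"]),
        force=force,
        kinematics=kin,
        meta=meta.get("meta", {}),
    )

    if meta.get("has_truth"):
        tdf = _read_table(path / "truth.tsv", ["com_pos", "com_vel", "com_acc"])
        t = tdf["t"].to_numpy()
        truth_com = TimeSeries(
            t=t,
            values=tdf[["com_pos", "com_vel", "com_acc"]].to_numpy(),
            rate=force_rate,
            units="m;m/s;m/s^2",
            channels=("pos", "vel", "acc"),
        )
        torque_cols = tuple(c for c in tdf.columns if c.startswith("torque_"))
        truth_torques = TimeSeries(
            t=t,
            values=tdf[list(torque_cols)].to_numpy(),
            rate=force_rate,
            units="N*m",
            channels=tuple(c.removeprefix("torque_") for c in torque_cols),
        )
        joint_cols = tuple(c for c in tdf.columns
                           if c.startswith(("theta_", "thetadot_")))
        truth_joints = None
        if joint_cols:
            truth_joints = TimeSeries(
                t=t.copy(),
                values=tdf[list(joint_cols)].to_numpy(),
                rate=force_rate,
                units="rad;rad/s",
                channels=joint_cols,
            )
        from .synthetic.simulate import SimulatedTrial

        trial: RawTrial = SimulatedTrial(
            **base, truth_torques=truth_torques, truth_com=truth_com,
            truth_joints=truth_joints,
        )
    else:
        trial = RawTrial(**base)

    try:
        trial.validate()
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc
    return trial


def trial_to_dict(trial: RawTrial) -> dict:
    """Flat metadata summary of a trial (used by run logs)."""
    return {
        "subject_ref": trial.subject_ref,
        "jump_type": trial.jump_type.value,
        "drop_height": trial.drop_height,
        "n_force": trial.force["left"].n,
        "n_kin": trial.kinematics["left"].n,
    }
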