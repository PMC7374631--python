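"""Segment inertial parameters scaled from body mass and height.

Two standard anthropometric tables are provided.  Fractions are per-side for
the leg segments (foot, shank, thigh); ``hat`` is the single combined
head-arms-trunk segment.  ``com_frac`` is the centre-of-mass position as a
fraction of segment length from the proximal end; ``rog_frac`` is the radius
of gyration about the segment COM as a fraction of segment length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ArgumentError

# mass fraction of body mass, length fraction of height, COM fraction from
# proximal end, radius-of-gyration fraction (about COM).
_TABLES = {
    "winter": {
        "foot": dict(mass_frac=0.0145, length_frac=0.152, com_frac=0.50, rog_frac=0.475),
        "shank": dict(mass_frac=0.0465, length_frac=0.246, com_frac=0.433, rog_frac=0.302),
        "thigh": dict(mass_frac=0.100, length_frac=0.245, com_frac=0.433, rog_frac=0.323),
        # head + arms + trunk; length is greater trochanter -> glenohumeral
        "hat": dict(mass_frac=0.678, length_frac=0.288, com_frac=0.626, rog_frac=0.496),
    },
    "deleva": {
        "foot": dict(mass_frac=0.0137, length_frac=0.152, com_frac=0.4415, rog_frac=0.257),
        "shank": dict(mass_frac=0.0433, length_frac=0.246, com_frac=0.4459, rog_frac=0.251),
        "thigh": dict(mass_frac=0.1416, length_frac=0.245, com_frac=0.4095, rog_frac=0.329),
        "hat": dict(mass_frac=0.6780, length_frac=0.288, com_frac=0.626, rog_frac=0.496),
    },
}

#: ankle-joint height above the sole, as a fraction of height
_ANKLE_HEIGHT_FRAC = 0.039
#: ankle joint position along the foot, as a fraction of foot length from heel
_ANKLE_FROM_HEEL_FRAC = 0.25

SEGMENTS = ("foot", "shank", "thigh", "hat")


@dataclass(frozen=True)
class Segment:
    """Inertial properties of one rigid segment."""

    name: str
    mass: float  # kg
    length: float  # m
    com_frac: float  # from proximal end
    rog_frac: float

    @property
    def inertia(self) -> float:
        """Moment of inertia about the segment COM, kg m^2."""
        return self.mass * (self.rog_frac * self.length) ** 2


@dataclass(frozen=True)
class SegmentParams:
    """Scaled per-side segment parameters plus foot geometry."""

    table: str
    body_mass: float
    height: float
    foot: Segment
    shank: Segment
    thigh: Segment
    hat: Segment
    ankle_height: float  # m, joint centre above the ground with foot flat
    ankle_from_heel: float  # m, ankle joint anterior of the heel

    def segment(self, name: str) -> Segment:
        return getattr(self, name)

    @property
    def foot_com_position(self) -> tuple[float, float]:
        """Foot COM (y, z) with the ankle at y = 0 and foot flat on the ground."""
        y = self.foot.com_frac * self.foot.length - self.ankle_from_heel
        return (y, 0.5 * self.ankle_height)


def segment_parameters(mass: float, height: float, table: str = "winter") -> SegmentParams:
    """Scale an anthropometric table to a subject.

    Parameters
    ----------
    mass : float
        Body mass in kg (> 0).
    height : float
        Stature in m (> 0).
    table : str
        ``"winter"`` (default) or ``"deleva"``.
    """
    if mass <= 0:
        raise ArgumentError(f"mass must be > 0, got {mass}")
    if height <= 0:
        raise ArgumentError(f"height must be > 0, got {height}")
    if table not in _TABLES:
        raise ArgumentError(f"unknown anthropometric table {table!r}; choose from {sorted(_TABLES)}")
    rows = _TABLES[table]
    segs = {
        name: Segment(
            name=name,
            mass=mass * row["mass_frac"],
            length=height * row["length_frac"],
            com_frac=row["com_frac"],
            rog_frac=row["rog_frac"],
        )
        for name, row in rows.items()
    }
    return SegmentParams(
        table=table,
        body_mass=mass,
        height=height,
        ankle_height=_ANKLE_HEIGHT_FRAC * height,
        ankle_from_heel=_ANKLE_FROM_HEEL_FRAC * rows["foot"]["length_frac"] * height,
        **segs,
    )


def table_mass_fractions(table: str) -> dict[str, float]:
    """Mass fractions of the chosen table (transcription check hook)."""
    if table not in _TABLES:
        raise ArgumentError(f"unknown anthropometric table {table!r}")
    return {name: row["mass_frac"] for name, row in _TABLES[table].items()}
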