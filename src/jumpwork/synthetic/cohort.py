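"""Synthetic subject cohorts with per-sex anthropometric/strength distributions.

Default distribution parameters follow the per-sex means and SDs of the
emulated 21-subject cohort (9 men, 12 women).  Draws are normal, truncated at
±3 SD and at physiological floors, and fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ArgumentError


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identity, sex, anthropometrics and squat strength."""

    subject_id: str
    sex: str  # "M" or "W"
    body_mass: float  # kg
    height: float  # m
    squat_1rm: float  # kg

    def __post_init__(self) -> None:
        if self.sex not in ("M", "W"):
            raise ArgumentError(f"sex must be 'M' or 'W', got {self.sex!r}")
        if self.body_mass <= 0:
            raise ArgumentError("body_mass must be > 0")
        if self.height <= 0:
            raise ArgumentError("height must be > 0")
        if self.squat_1rm < 0:
            raise ArgumentError("squat_1rm must be >= 0")

    @property
    def rel_strength(self) -> float:
        """Squat 1RM divided by body mass (the strength-ranking key)."""
        return self.squat_1rm / self.body_mass


@dataclass(frozen=True)
class SexProfile:
    """Normal-distribution parameters (mean, SD) for one sex."""

    height_mean: float
    height_sd: float
    mass_mean: float
    mass_sd: float
    rm_mean: float
    rm_sd: float


def default_profiles() -> dict[str, SexProfile]:
    """Per-sex defaults matching the emulated cohort's subject characteristics."""
    return {
        "M": SexProfile(height_mean=1.77, height_sd=0.06, mass_mean=79.0, mass_sd=7.0,
                        rm_mean=116.0, rm_sd=25.0),
        "W": SexProfile(height_mean=1.66, height_sd=0.06, mass_mean=63.0, mass_sd=11.0,
                        rm_mean=66.0, rm_sd=22.0),
    }


@dataclass
class CohortSpec:
    """A generated cohort plus the parameters that produced it."""

    subjects: list[SubjectRecord]
    profiles: dict[str, SexProfile] = field(default_factory=default_profiles)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.subjects)

    def by_id(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float | None = None) -> float:
    """Draw N(mean, sd) truncated to [max(lo, mean-3sd), min(hi, mean+3sd)]."""
    if sd == 0:
        return mean
    lower = max(lo, mean - 3 * sd)
    upper = mean + 3 * sd if hi is None else min(hi, mean + 3 * sd)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lower, upper))


def generate_cohort(
    n_men: int,
    n_women: int,
    strength_profile: dict[str, SexProfile] | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Generate ``n_men + n_women`` subjects from per-sex truncated normals.

    Deterministic for a given ``seed``.  Raises :class:`ArgumentError` for
    negative counts or negative SDs.
    """
    if n_men < 0 or n_women < 0:
        raise ArgumentError("subject counts must be >= 0")
    profiles = dict(strength_profile or default_profiles())
    for sex, prof in profiles.items():
        if min(prof.height_sd, prof.mass_sd, prof.rm_sd) < 0:
            raise ArgumentError(f"negative SD in profile for sex {sex!r}")

    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    for sex, count in (("M", n_men), ("W", n_women)):
        prof = profiles[sex]
        for i in range(count):
            height = _truncated_normal(rng, prof.height_mean, prof.height_sd, lo=1.3)
            mass = _truncated_normal(rng, prof.mass_mean, prof.mass_sd, lo=40.0)
            rm = _truncated_normal(rng, prof.rm_mean, prof.rm_sd, lo=20.0)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{sex}{i + 1:02d}",
                    sex=sex,
                    body_mass=round(mass, 2),
                    height=round(height, 3),
                    squat_1rm=round(rm, 1),
                )
            )
    return CohortSpec(subjects=subjects, profiles=profiles, seed=seed)
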