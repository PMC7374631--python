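"""End-to-end orchestration: simulate -> preprocess -> analyze -> summarize.

A single :class:`RunConfig` drives the whole run; every defaulted value is
materialized into the run log together with a hash of the resolved
configuration, so reruns with the same config and seeds produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .com import com_kinematics, com_work, com_workloop
from .constants import JOINTS, SIDES
from .errors import ArgumentError, JumpworkError
from .joints import bilateral_average, inverse_dynamics_planar, joint_work, segment_parameters
from .signals import EventConfig, detect_events, lowpass_zero_lag, measure_body_weight, resample_uniform
from .stats import (
    STRENGTH_LABELS,
    assign_strength_groups,
    bonferroni_posthoc,
    build_group_tables,
    ensemble_average,
    two_way_anova,
)
from .synthetic import SubjectRecord, add_noise, generate_cohort, simulate_trial
from .trials import JumpType, RawTrial, TimeSeries, read_trial, write_trial

log = logging.getLogger(__name__)

ALL_JUMP_TYPES = [jt.value for jt in JumpType]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    n_men: int = 9
    n_women: int = 12
    seed: int = 0
    jump_types: list[str] = field(default_factory=lambda: list(ALL_JUMP_TYPES))
    sim_rate: float = 2000.0
    force_noise_sd: float = 0.0
    angle_noise_sd: float = 0.0
    filter_cutoff: float | None = 11.0  # Hz; None disables low-pass filtering
    filter_order: int = 4
    contact_threshold: float = 20.0  # N
    com_work_mode: str = "total"  # or "net"
    drop_scale: float = 1.0  # attrition factor on sqrt(2 g h)
    anthro_table: str = "winter"
    quiet_window: tuple[float, float] = (0.05, 0.45)
    write_trials: bool = False
    trial_dir: str | None = None  # analyze existing trials instead of simulating

    def validate(self) -> None:
        if self.n_men < 0 or self.n_women < 0:
            raise ArgumentError("cohort counts must be >= 0")
        if self.com_work_mode not in ("total", "net"):
            raise ArgumentError(f"unknown com_work_mode {self.com_work_mode!r}")
        unknown = set(self.jump_types) - set(ALL_JUMP_TYPES)
        if unknown:
            raise ArgumentError(f"unknown jump types {sorted(unknown)}")
        if self.filter_cutoff is not None and self.filter_cutoff <= 0:
            raise ArgumentError("filter_cutoff must be positive or None")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "quiet_window" in raw:
            raw["quiet_window"] = tuple(raw["quiet_window"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quiet_window"] = list(self.quiet_window)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TrialAnalysis:
    """Per-trial work summaries (COM + bilaterally averaged joints) + loop."""

    subject_id: str
    jump_type: str
    rows: list[dict]
    com_loop: object


@dataclass
class RunResult:
    per_trial: pd.DataFrame
    group_sex: pd.DataFrame
    group_strength: pd.DataFrame
    anova: dict
    ensembles: pd.DataFrame
    output_dir: Path | None


def validate_trial(trial: RawTrial) -> list[str]:
    """Report (not raise) structural problems of a trial."""
    report: list[str] = []
    try:
        trial.validate()
    except JumpworkError as exc:
        report.append(str(exc))
    for group, mapping in (("force", trial.force), ("kinematics", trial.kinematics)):
        for side, ts in mapping.items():
            bad = np.flatnonzero(~np.isfinite(np.atleast_2d(ts.values.T).T).all(axis=1))
            if bad.size:
                report.append(f"{group}[{side}]: non-finite sample at index {int(bad[0])}")
    if abs(trial.force_rate - 1000.0) > 1e-9:
        report.append(f"force rate {trial.force_rate} Hz differs from canonical 1000 Hz")
    if abs(trial.kinematic_rate - 200.0) > 1e-9:
        report.append(f"kinematic rate {trial.kinematic_rate} Hz differs from canonical 200 Hz")
    return report


def _subject_from_trial(trial: RawTrial) -> SubjectRecord:
    meta = trial.meta
    return SubjectRecord(
        subject_id=trial.subject_ref,
        sex=meta.get("sex", "M"),
        body_mass=float(meta["body_mass"]),
        height=float(meta["height"]),
        squat_1rm=float(meta.get("squat_1rm", 0.0)),
    )


def analyze_trial(trial: RawTrial, subject: SubjectRecord, config: RunConfig) -> TrialAnalysis:
    """Run one trial through segmentation, COM work and joint work."""
    mass = subject.body_mass
    event_cfg = EventConfig(
        contact_threshold=config.contact_threshold,
        filter_cutoff=config.filter_cutoff or 11.0,
        filter_order=config.filter_order,
    )
    bw = measure_body_weight(trial, window=config.quiet_window, mass=mass)
    events = detect_events(trial, bw, event_cfg)

    force_total = trial.total_fz()
    if config.filter_cutoff is not None:
        force_total = lowpass_zero_lag(force_total, config.filter_cutoff, config.filter_order)
    state = com_kinematics(
        force_total, mass, events, trial.jump_type,
        drop_height=trial.drop_height, drop_scale=config.drop_scale,
    )
    com_summary = com_work(force_total, state, events, mass, mode=config.com_work_mode)
    loop = com_workloop(force_total, state, events, mass)

    nf = trial.force["left"].n
    kinematics = {}
    grf = {}
    for side in SIDES:
        rs = resample_uniform(trial.kinematics[side], trial.force_rate)
        vals = rs.values
        if rs.n < nf:
            vals = np.vstack([vals, np.repeat(vals[-1:], nf - rs.n, axis=0)])
        ts = TimeSeries.from_rate(vals[:nf], trial.force_rate, units="rad", channels=JOINTS)
        if config.filter_cutoff is not None:
            ts = lowpass_zero_lag(ts, config.filter_cutoff, config.filter_order)
        kinematics[side] = ts
        plate = trial.force[side]
        if config.filter_cutoff is not None:
            filtered = lowpass_zero_lag(
                TimeSeries(t=plate.t, values=plate.values[:, :2], rate=plate.rate,
                           channels=("Fz", "Fy")),
                config.filter_cutoff, config.filter_order,
            )
            plate = TimeSeries(t=plate.t.copy(),
                               values=np.column_stack([filtered.values, plate.channel("cop_y")]),
                               rate=plate.rate, units=plate.units, channels=plate.channels)
        grf[side] = plate

    seg = segment_parameters(mass, subject.height, config.anthro_table)
    kinetics = inverse_dynamics_planar(kinematics, grf, seg, mass)
    per_side = joint_work(kinetics, events)

    rows = [{
        "subject_id": subject.subject_id,
        "sex": subject.sex,
        "jump_type": trial.jump_type.value,
        "quantity": "COM",
        "w_neg": com_summary.w_neg, "w_pos": com_summary.w_pos,
        "w_net": com_summary.w_net, "ratio": com_summary.ratio,
    }]
    for joint in JOINTS:
        merged = bilateral_average(per_side["left"][joint], per_side["right"][joint])
        rows.append({
            "subject_id": subject.subject_id,
            "sex": subject.sex,
            "jump_type": trial.jump_type.value,
            "quantity": joint,
            "w_neg": merged.w_neg, "w_pos": merged.w_pos,
            "w_net": merged.w_net, "ratio": merged.ratio,
        })
    return TrialAnalysis(
        subject_id=subject.subject_id,
        jump_type=trial.jump_type.value,
        rows=rows,
        com_loop=loop,
    )


def _load_or_simulate(config: RunConfig, out_dir: Path | None):
    """Yield (subject, trial) pairs per the config's source."""
    if config.trial_dir is not None:
        trial_paths = sorted(p for p in Path(config.trial_dir).iterdir() if p.is_dir())
        trials = [read_trial(p) for p in trial_paths]
        subjects = {t.subject_ref: _subject_from_trial(t) for t in trials}
        return list(subjects.values()), [(subjects[t.subject_ref], t) for t in trials]

    cohort = generate_cohort(config.n_men, config.n_women, seed=config.seed)
    pairs = []
    for si, subject in enumerate(cohort.subjects):
        for ji, jt in enumerate(config.jump_types):
            trial_seed = config.seed * 100003 + si * 101 + ji
            trial = simulate_trial(subject, jt, sim_rate=config.sim_rate, seed=trial_seed,
                                   table=config.anthro_table)
            if config.force_noise_sd > 0 or config.angle_noise_sd > 0:
                trial = add_noise(trial, config.force_noise_sd, config.angle_noise_sd,
                                  seed=trial_seed + 7)
            if config.write_trials and out_dir is not None:
                write_trial(trial, out_dir / "trials" / f"{subject.subject_id}_{jt}")
            pairs.append((subject, trial))
    return cohort.subjects, pairs


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full analysis; write delimited-text outputs if ``out_dir``.

    Stage failures are re-raised with the stage name and trial id attached.
    """
    config.validate()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    subjects, pairs = _load_or_simulate(config, out_path)
    from .synthetic.cohort import CohortSpec

    assignment = assign_strength_groups(
        CohortSpec(subjects=list(subjects), seed=config.seed),
        policy="error" if len(subjects) % 3 == 0 else "nearest",
    )

    all_rows: list[dict] = []
    loops: dict[tuple[str, str], list] = {}
    for subject, trial in pairs:
        try:
            analysis = analyze_trial(trial, subject, config)
        except JumpworkError as exc:
            raise type(exc)(
                f"[stage=analyze trial={subject.subject_id}/{trial.jump_type.value}] {exc}"
            ) from exc
        for row in analysis.rows:
            row["strength_group"] = assignment.strength_groups[subject.subject_id]
        all_rows.extend(analysis.rows)
        loops[(subject.subject_id, trial.jump_type.value)] = analysis.com_loop

    per_trial = pd.DataFrame(all_rows)

    group_sex = build_group_tables(per_trial, assignment.sex_groups, ["M", "W"])
    group_strength = build_group_tables(
        per_trial, assignment.strength_groups, list(STRENGTH_LABELS)
    )

    anova_out: dict = {}
    com_rows = per_trial[per_trial["quantity"] == "COM"]
    for outcome in ("w_neg", "w_pos", "w_net", "ratio"):
        entry: dict = {}
        for factor, col in (("sex", "sex"), ("strength", "strength_group")):
            try:
                res = two_way_anova(com_rows, outcome, col, "jump_type")
            except Exception as exc:  # degenerate designs surface as a note, not a crash
                entry[factor] = {"error": str(exc)}
                continue
            rec = {
                "effects": res.effects,
                "alpha": res.alpha,
                "degenerate": res.degenerate,
            }
            if res.significant(col):
                rec["posthoc"] = bonferroni_posthoc(res).to_dict(orient="records")
            entry[factor] = rec
        anova_out[outcome] = entry

    ens_rows = []
    for grouping, mapping in (("sex", assignment.sex_groups),
                              ("strength", assignment.strength_groups)):
        labels = ["M", "W"] if grouping == "sex" else list(STRENGTH_LABELS)
        for label in labels:
            members = [sid for sid, grp in mapping.items() if grp == label]
            for jt in config.jump_types:
                group_loops = [loops[(sid, jt)] for sid in members if (sid, jt) in loops]
                if not group_loops:
                    continue
                curve = ensemble_average(group_loops, group=label)
                for i in range(curve.drive.size):
                    ens_rows.append({
                        "grouping": grouping, "group": label, "jump_type": jt,
                        "point": i,
                        "drive": curve.drive[i], "excursion": curve.excursion[i],
                        "drive_sd": curve.drive_sd[i], "excursion_sd": curve.excursion_sd[i],
                        "n_members": curve.n_members,
                    })
    ensembles = pd.DataFrame(ens_rows)

    if out_path is not None:
        per_trial.to_csv(out_path / "per_trial.csv", index=False, float_format="%.10g")
        group_sex.to_csv(out_path / "group_sex.csv", index=False, float_format="%.10g")
        group_strength.to_csv(out_path / "group_strength.csv", index=False, float_format="%.10g")
        ensembles.to_csv(out_path / "ensembles.csv", index=False, float_format="%.10g")
        (out_path / "anova.json").write_text(json.dumps(anova_out, indent=1, sort_keys=True))
        run_log = {
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "n_subjects": len(subjects),
            "n_trials": len(pairs),
        }
        (out_path / "run.json").write_text(json.dumps(run_log, indent=1, sort_keys=True))

    return RunResult(
        per_trial=per_trial,
        group_sex=group_sex,
        group_strength=group_strength,
        anova=anova_out,
        ensembles=ensembles,
        output_dir=out_path,
    )
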