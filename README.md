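# jumpwork

Work-loop energetics of countermovement jumps (CMJ) and drop jumps (DJ15–DJ75)
from force-plate and joint-angle time series.

The pipeline computes, per trial:

- **COM dynamics** — vertical centre-of-mass acceleration from total plate
  force (`a = F/m − g`), velocity and displacement by forward integration,
  force–displacement work loops, and negative / positive / net work (J/kg)
  partitioned by the sign of instantaneous COM power, plus the
  negative:positive work ratio (%).
- **Joint kinetics** — planar bottom-up Newton–Euler inverse dynamics
  (foot → shank → thigh, one force plate per leg) giving hip/knee/ankle net
  moments (extensor-positive, N·m/kg), joint power, per-joint work
  decomposition, and bilateral averaging.
- **Group statistics** — sex groups and relative-strength tertiles
  (ranked on squat 1RM / body mass, 7/7/7 for a 21-subject cohort), group
  mean ± SD tables, 100-point ensemble work-loop curves, two-way GLM ANOVA
  (group × jump type, type-III) with Bonferroni post-hoc comparisons.

Because no public dataset accompanies the study design this emulates, the
package ships a physics-based **synthetic trial generator**: a torque-driven
planar foot–shank–thigh–HAT chain with PD-servo tracking of keyframed joint
templates, integrated with fixed-step RK4 during ground contact and ballistic
flight phases. Every simulated trial carries its ground truth (applied joint
torques, COM state, exact joint kinematics), so signal processing, COM work
and inverse dynamics are all validated against known answers: Newton
consistency to <0.1 %, impulse–momentum to trapezoidal tolerance, chain
energy bookkeeping to <1 %, and torque recovery to ≤2 % of peak.

## Command line

```sh
jumpwork all --seed 1 --out runs/demo            # simulate + analyze + stats
jumpwork simulate --seed 1 --out runs/sim        # also writes trial files
jumpwork analyze --trials runs/sim/trials --out runs/reanalysis
jumpwork stats --per-trial runs/demo/per_trial.csv --out runs/tables
```

All commands accept `--config config.yaml`; keys mirror
`jumpwork.pipeline.RunConfig` (cohort sizes, seeds, filter cutoff, event
thresholds, COM work mode `total`/`net`, anthropometric table
`winter`/`deleva`, noise levels, …). Outputs are delimited text
(`per_trial.csv`, `group_sex.csv`, `group_strength.csv`, `ensembles.csv`)
plus `anova.json` and a `run.json` log with the resolved config and its hash;
identical configs reproduce byte-identical outputs.

## Trial format

A trial is a directory of tab-separated tables with a JSON sidecar
(`trial.json`: subject, jump type, rates, row counts, units):

| file | columns |
| --- | --- |
| `force.tsv` | `t`, per-plate `Fz` (N), `Fy` (N), `cop_y` (m), left then right, 1 000 Hz |
| `kinematics.tsv` | `t`, per-side `hip`, `knee`, `ankle` flexion angles (rad), 200 Hz |
| `truth.tsv` | optional simulator ground truth (COM state, joint torques and kinematics) |

`jumpwork.trials.write_trial` / `read_trial` round-trip losslessly at full
float precision.

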