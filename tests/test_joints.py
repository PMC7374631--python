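import numpy as np
import pytest

from jumpwork.anthro import segment_parameters, table_mass_fractions
from jumpwork.com import make_summary
from jumpwork.constants import GRAVITY, JOINTS, SIDES
from jumpwork.errors import ArgumentError
from jumpwork.joints import bilateral_average, inverse_dynamics_planar, joint_work
from jumpwork.pipeline import RunConfig, analyze_trial
from jumpwork.signals import PhaseEvents, detect_events, measure_body_weight, resample_uniform
from jumpwork.synthetic.chain import ContactChain, phi_from_theta
from jumpwork.trials import TimeSeries


class TestSegmentParameters:
    def test_winter_mass_fractions_exact(self):
        # transcription check vs the published per-side fractions
        fr = table_mass_fractions("winter")
        assert fr["foot"] == 0.0145
        assert fr["shank"] == 0.0465
        assert fr["thigh"] == 0.100
        assert fr["hat"] == 0.678

    def test_zero_mass_rejected(self):
        with pytest.raises(ArgumentError):
            segment_parameters(0.0, 1.75)

    def test_unknown_table_rejected(self):
        with pytest.raises(ArgumentError, match="unknown"):
            segment_parameters(70.0, 1.75, table="nosuch")

    def test_linear_mass_scaling(self):
        a = segment_parameters(70.0, 1.75)
        b = segment_parameters(140.0, 1.75)
        for name in ("foot", "shank", "thigh", "hat"):
            assert b.segment(name).mass == pytest.approx(2 * a.segment(name).mass)

    def test_deleva_selectable(self):
        p = segment_parameters(70.0, 1.75, table="deleva")
        assert p.table == "deleva"
        assert p.thigh.mass == pytest.approx(70.0 * 0.1416)


def _static_side(seg, fz, fy, cop, theta, n=401, rate=1000.0):
    kin = {s: TimeSeries.from_rate(np.tile(theta, (n, 1)), rate, channels=JOINTS)
           for s in SIDES}
    plate = np.column_stack([np.full(n, fz), np.full(n, fy), np.full(n, cop)])
    grf = {s: TimeSeries.from_rate(plate, rate, channels=("Fz", "Fy", "cop_y"))
           for s in SIDES}
    return kin, grf


class TestInverseDynamics:
    def test_static_ankle_moment_closed_form(self):
        # hand statics about the ankle: M = Fz*d - m_foot*g*y_foot_com
        mass, height = 79.0, 1.77
        seg = segment_parameters(mass, height)
        d = 0.12
        fz = mass * GRAVITY / 2
        kin, grf = _static_side(seg, fz, 0.0, d, np.array([0.12, 0.10, 0.05]))
        out = inverse_dynamics_planar(kin, grf, seg, mass)
        m_ankle = out.moment["left"].values[200, 2] * mass
        expected = fz * d - seg.foot.mass * GRAVITY * seg.foot_com_position[0]
        assert m_ankle == pytest.approx(expected, rel=0.01)
        # and approximately the textbook Fz*d, foot weight being a small term
        assert m_ankle == pytest.approx(fz * d, rel=0.03)

    def test_torque_recovery_dj30(self, trials, subject):
        # simulator-truth oracle through the unfiltered analysis path
        trial = trials("DJ30", seed=0)
        m = subject.body_mass
        cfg = RunConfig(filter_cutoff=None)
        ev = detect_events(trial, measure_body_weight(trial, mass=m))
        nf = trial.force["left"].n
        kin = {}
        for side in SIDES:
            rs = resample_uniform(trial.kinematics[side], 1000.0)
            vals = rs.values
            if rs.n < nf:
                vals = np.vstack([vals, np.repeat(vals[-1:], nf - rs.n, axis=0)])
            kin[side] = TimeSeries.from_rate(vals[:nf], 1000.0, channels=JOINTS)
        seg = segment_parameters(m, subject.height, cfg.anthro_table)
        out = inverse_dynamics_planar(kin, trial.force, seg, m)
        i0 = int(round(ev.window[0] * 1000)) + 2
        i1 = int(round(ev.window[1] * 1000)) - 2
        for j, joint in enumerate(JOINTS):
            truth = trial.truth_torques.channel(f"left_{joint}")[i0:i1] / m
            est = out.moment["left"].values[i0:i1, j]
            rms = np.sqrt(np.mean((est - truth) ** 2))
            assert rms <= 0.02 * np.max(np.abs(truth)), joint

    def test_flight_phase_gravitational_only(self):
        # motionless limbs, no plate load: moments reduce to gravity terms,
        # which are bounded by (segment weights) x (lever arms)
        mass, height = 70.0, 1.75
        seg = segment_parameters(mass, height)
        kin, grf = _static_side(seg, 0.0, 0.0, 0.0, np.array([0.3, 0.4, 0.1]))
        out = inverse_dynamics_planar(kin, grf, seg, mass)
        bound = (seg.shank.mass + seg.thigh.mass + seg.foot.mass) * GRAVITY \
            * (seg.shank.length + seg.thigh.length)
        assert np.all(np.abs(out.moment["left"].values[200] * mass) < bound)

    def test_missing_cop_during_contact(self):
        seg = segment_parameters(70.0, 1.75)
        kin, grf = _static_side(seg, 400.0, 0.0, np.nan, np.array([0.1, 0.1, 0.05]))
        with pytest.raises(Exception, match="pressure"):
            inverse_dynamics_planar(kin, grf, seg, 70.0)


class TestJointWork:
    def test_isometric_zero_work(self):
        seg = segment_parameters(70.0, 1.75)
        kin, grf = _static_side(seg, 400.0, 0.0, 0.05, np.array([0.3, 0.5, 0.2]))
        out = inverse_dynamics_planar(kin, grf, seg, 70.0)
        ev = PhaseEvents(t_takeoff=0.35, t_lowest=0.2, t_onset=0.05)
        works = joint_work(out, ev)
        for joint in JOINTS:
            assert works["left"][joint].w_net == pytest.approx(0.0, abs=1e-12)

    def test_chain_energy_bookkeeping(self, trials, subject):
        # sum of net joint work (both sides) equals chain energy change
        trial = trials("DJ45", seed=0)
        m = subject.body_mass
        cfg = RunConfig(sim_rate=1000, filter_cutoff=None)
        analysis = analyze_trial(trial, subject, cfg)
        rows = {r["quantity"]: r for r in analysis.rows}
        total_net = sum(rows[j]["w_net"] for j in JOINTS) * 2 * m  # both sides, J

        chain = ContactChain(segment_parameters(m, subject.height))
        ev = detect_events(trial, measure_body_weight(trial, mass=m))
        i0 = int(round(ev.window[0] * 1000))
        i1 = int(round(ev.window[1] * 1000))
        theta = np.column_stack([trial.truth_joints.channel(f"theta_{j}") for j in JOINTS])
        thetadot = np.column_stack([trial.truth_joints.channel(f"thetadot_{j}") for j in JOINTS])
        phi = phi_from_theta(theta)
        phidot = phi_from_theta(thetadot)
        e0 = chain.energy(phi[i0], phidot[i0])
        e1 = chain.energy(phi[i1], phidot[i1])
        assert total_net == pytest.approx(e1 - e0, rel=0.01)

    def test_sign_flip_swaps_labels(self):
        # brute force on a 10-sample series: flipping the moment convention
        # (and with it the velocity convention) leaves the work split intact;
        # flipping only the moment swaps W_neg and W_pos magnitudes
        rng = np.random.default_rng(1)
        mom = rng.normal(size=10)
        omega = rng.normal(size=10)
        t = np.arange(10) / 1000.0
        from jumpwork.com import signed_work_partition

        w_neg, w_pos = signed_work_partition(mom * omega, t)
        w_neg_f, w_pos_f = signed_work_partition(-mom * omega, t)
        assert w_neg_f == pytest.approx(-w_pos)
        assert w_pos_f == pytest.approx(-w_neg)
        w_neg_b, w_pos_b = signed_work_partition((-mom) * (-omega), t)
        assert (w_neg_b, w_pos_b) == (w_neg, w_pos)


class TestBilateralAverage:
    def test_identity(self):
        s = make_summary(-1.5, 3.0, label="knee")
        merged = bilateral_average(s, s)
        assert merged.w_neg == s.w_neg and merged.w_pos == s.w_pos

    def test_arithmetic_mean(self):
        left = make_summary(-1.0, 2.0, label="hip")
        right = make_summary(-3.0, 4.0, label="hip")
        merged = bilateral_average(left, right)
        assert merged.w_net == pytest.approx((left.w_net + right.w_net) / 2)

    def test_ratio_recomputed_not_averaged(self):
        # constructed counterexample: mean of ratios != ratio of means
        left = make_summary(-1.0, 1.0, label="hip")   # ratio 100
        right = make_summary(-1.0, 4.0, label="hip")  # ratio 25
        merged = bilateral_average(left, right)
        assert merged.ratio == pytest.approx(2.0 / 5.0 * 100)
        assert merged.ratio != pytest.approx((100 + 25) / 2)

    def test_joint_mismatch_rejected(self):
        with pytest.raises(ArgumentError, match="mismatch"):
            bilateral_average(make_summary(-1, 2, label="hip"),
                              make_summary(-1, 2, label="knee"))
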