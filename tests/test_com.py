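import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jumpwork.com import (
    WorkLoop,
    com_kinematics,
    com_work,
    com_workloop,
    make_summary,
    neg_pos_ratio,
    signed_work_partition,
)
from jumpwork.constants import GRAVITY
from jumpwork.errors import ArgumentError
from jumpwork.signals import PhaseEvents, detect_events, measure_body_weight
from jumpwork.trials import JumpType, TimeSeries


def _events(start=0.0, lowest=0.5, takeoff=1.0, cmj=True):
    return PhaseEvents(
        t_takeoff=takeoff, t_lowest=lowest,
        t_onset=start if cmj else None,
        t_contact=None if cmj else start,
    )


def _force(values, rate=1000.0):
    return TimeSeries.from_rate(np.asarray(values, dtype=float), rate, units="N")


class TestComKinematics:
    def test_static_equilibrium(self):
        m = 70.0
        f = _force(np.full(1101, m * GRAVITY))
        st_ = com_kinematics(f, m, _events(), JumpType.CMJ)
        assert np.allclose(st_.a.values, 0.0, atol=1e-12)
        assert np.allclose(st_.v.values, 0.0, atol=1e-12)
        assert np.allclose(st_.x.values, 0.0, atol=1e-12)

    def test_free_fall(self):
        m = 70.0
        f = _force(np.zeros(1101))
        st_ = com_kinematics(f, m, _events(), JumpType.CMJ)
        t = st_.v.t - st_.v.t[0]
        assert np.allclose(st_.v.values, -GRAVITY * t, atol=1e-9)

    def test_dj_initial_condition(self):
        m = 70.0
        f = _force(np.full(1101, m * GRAVITY))
        st_ = com_kinematics(f, m, _events(cmj=False), JumpType.DJ45, drop_height=0.45)
        assert st_.v.values[0] == pytest.approx(-np.sqrt(2 * GRAVITY * 0.45))

    def test_dj60_velocity_matches_truth(self, trials, subject):
        # oracle: simulator COM state
        trial = trials("DJ60", seed=0)
        bw = measure_body_weight(trial, mass=subject.body_mass)
        ev = detect_events(trial, bw)
        st_ = com_kinematics(trial.total_fz(), subject.body_mass, ev,
                             trial.jump_type, trial.drop_height)
        i0 = int(round(ev.window[0] * 1000))
        i1 = i0 + st_.v.n
        truth = trial.truth_com.channel("vel")[i0:i1]
        rms = np.sqrt(np.mean((st_.v.values - truth) ** 2))
        assert rms / np.max(np.abs(truth)) < 0.02

    def test_window_not_covered(self):
        f = _force(np.zeros(500))
        with pytest.raises(ArgumentError):
            com_kinematics(f, 70.0, _events(takeoff=2.0), JumpType.CMJ)


class TestComWork:
    def test_nonnegative_velocity_gives_zero_negative_work(self):
        m = 70.0
        n = 1101
        f = _force(np.linspace(m * GRAVITY, m * GRAVITY + 500, n))
        st_ = com_kinematics(f, m, _events(), JumpType.CMJ)
        st_.v.values[:] = np.abs(st_.v.values)
        ws = com_work(f, st_, _events(), m)
        assert ws.w_neg == 0.0

    def test_energy_conservation_oracle(self, trials, subject):
        # net work equals Delta(v^2/2 + g x) of the integrated state
        trial = trials("DJ30", seed=0)
        m = subject.body_mass
        bw = measure_body_weight(trial, mass=m)
        ev = detect_events(trial, bw)
        ft = trial.total_fz()
        st_ = com_kinematics(ft, m, ev, trial.jump_type, trial.drop_height)
        ws = com_work(ft, st_, ev, m)
        d_energy = (0.5 * (st_.v.values[-1] ** 2 - st_.v.values[0] ** 2)
                    + GRAVITY * (st_.x.values[-1] - st_.x.values[0]))
        assert ws.w_net == pytest.approx(d_energy, rel=0.01)

    def test_time_reversal_swaps_components(self):
        # brute-force sign symmetry on a small synthetic loop
        rng = np.random.default_rng(0)
        power = rng.normal(size=50)
        t = np.arange(50) / 1000.0
        w_neg, w_pos = signed_work_partition(power, t)
        w_neg_r, w_pos_r = signed_work_partition(power[::-1] * -1, t)
        assert w_neg_r == pytest.approx(-w_pos)
        assert w_pos_r == pytest.approx(-w_neg)

    def test_decomposition_identity_machine_precision(self, trials, subject):
        trial = trials("DJ75", seed=0)
        m = subject.body_mass
        ev = detect_events(trial, measure_body_weight(trial, mass=m))
        ft = trial.total_fz()
        st_ = com_kinematics(ft, m, ev, trial.jump_type, trial.drop_height)
        ws = com_work(ft, st_, ev, m)
        assert ws.w_net == ws.w_neg + ws.w_pos  # exact by construction

    def test_net_force_mode(self, trials, subject):
        trial = trials("CMJ", seed=0)
        m = subject.body_mass
        ev = detect_events(trial, measure_body_weight(trial))
        ft = trial.total_fz()
        st_ = com_kinematics(ft, m, ev, trial.jump_type)
        total = com_work(ft, st_, ev, m, mode="total")
        net = com_work(ft, st_, ev, m, mode="net")
        # modes differ by the gravity term: W_net(total) - W_net(net) = g dx
        dx = st_.x.values[-1] - st_.x.values[0]
        assert total.w_net - net.w_net == pytest.approx(GRAVITY * dx, rel=1e-6, abs=1e-9)

    def test_unknown_mode_rejected(self, trials, subject):
        trial = trials("CMJ", seed=0)
        ev = detect_events(trial, measure_body_weight(trial))
        ft = trial.total_fz()
        st_ = com_kinematics(ft, subject.body_mass, ev, trial.jump_type)
        with pytest.raises(ArgumentError):
            com_work(ft, st_, ev, subject.body_mass, mode="banana")


class TestWorkLoop:
    def test_cmj_loop_area_matches_net_work(self, trials, subject):
        # Green's-theorem oracle: path integral of F dx vs time integral of F v dt
        trial = trials("CMJ", seed=0)
        m = subject.body_mass
        ev = detect_events(trial, measure_body_weight(trial))
        ft = trial.total_fz()
        st_ = com_kinematics(ft, m, ev, trial.jump_type)
        ws = com_work(ft, st_, ev, m)
        loop = com_workloop(ft, st_, ev, m)
        assert loop.enclosed_area() == pytest.approx(ws.w_net, rel=0.005)

    def test_spring_cycle_has_zero_area(self):
        # conservative cycle: F = -k x around a closed path
        theta = np.linspace(0, 2 * np.pi, 500)
        x = 0.1 * np.sin(theta)
        loop = WorkLoop(drive=-50.0 * x, excursion=x)
        assert abs(loop.enclosed_area()) < 1e-12

    def test_degenerate_single_point(self):
        loop = WorkLoop(drive=np.array([700.0]), excursion=np.array([0.0]))
        assert loop.enclosed_area() == 0.0


class TestRatio:
    def test_men_cmj_group_means(self):
        # printed group means: -2.4, 6.5 -> printed ratio 37
        ratio, defined = neg_pos_ratio(-2.4, 6.5)
        assert defined
        assert ratio == pytest.approx(36.92, abs=0.01)
        assert round(ratio) == 37

    def test_women_dj30_group_means(self):
        ratio, _ = neg_pos_ratio(-6.0, 6.0)
        assert ratio == pytest.approx(100.0)

    def test_zero_negative_work(self):
        ratio, defined = neg_pos_ratio(0.0, 5.0)
        assert defined and ratio == 0.0

    def test_zero_positive_work_flagged(self):
        ratio, defined = neg_pos_ratio(-1.0, 0.0)
        assert not defined and np.isnan(ratio)
        summary = make_summary(-1.0, 0.0)
        assert not summary.ratio_defined

    def test_negative_positive_work_rejected(self):
        with pytest.raises(ArgumentError):
            neg_pos_ratio(-1.0, -0.5)


@given(
    power=st.lists(st.floats(-1e4, 1e4, allow_nan=False), min_size=2, max_size=200),
)
@settings(max_examples=200, deadline=None)
def test_partition_identity_property(power):
    p = np.asarray(power)
    t = np.arange(p.size) / 1000.0
    w_neg, w_pos = signed_work_partition(p, t)
    assert w_neg <= 0.0 <= w_pos
    assert w_neg + w_pos == pytest.approx(np.trapezoid(p, t), rel=1e-12, abs=1e-9)
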