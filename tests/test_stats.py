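import numpy as np
import pandas as pd
import pytest

from jumpwork.com import WorkLoop
from jumpwork.errors import AnalysisError, ArgumentError
from jumpwork.stats import (
    anova_null_rejection_rate,
    assign_strength_groups,
    bonferroni_posthoc,
    build_group_tables,
    ensemble_average,
    two_way_anova,
    _design_matrices,
)
from jumpwork.synthetic.cohort import CohortSpec, SubjectRecord, generate_cohort


def _subject(sid, rel, sex="M", mass=70.0):
    return SubjectRecord(subject_id=sid, sex=sex, body_mass=mass,
                         height=1.75, squat_1rm=rel * mass)


class TestStrengthGroups:
    def test_21_subjects_partition_7_7_7(self, cohort):
        ga = assign_strength_groups(cohort)
        counts = {g: list(ga.strength_groups.values()).count(g) for g in ("HS", "MS", "LS")}
        assert counts == {"HS": 7, "MS": 7, "LS": 7}

    def test_ranking_by_rel_strength(self, cohort):
        ga = assign_strength_groups(cohort)
        rels = {s.subject_id: s.rel_strength for s in cohort.subjects}
        hs = min(rels[sid] for sid in ga.members("HS"))
        ms = [rels[sid] for sid in ga.members("MS")]
        ls = max(rels[sid] for sid in ga.members("LS"))
        assert hs >= max(ms) and min(ms) >= ls

    def test_tie_broken_by_subject_id(self):
        subs = [_subject(f"S{i}", 1.2) for i in range(6)]  # all tied
        ga = assign_strength_groups(CohortSpec(subjects=subs))
        assert ga.members("HS") == ["S0", "S1"]
        assert ga.members("LS") == ["S4", "S5"]

    def test_non_divisible_size_rejected(self):
        subs = [_subject(f"S{i}", 1.0 + i / 10) for i in range(20)]
        with pytest.raises(ArgumentError, match="tertiles"):
            assign_strength_groups(CohortSpec(subjects=subs))

    def test_nearest_policy(self):
        subs = [_subject(f"S{i}", 1.0 + i / 10) for i in range(20)]
        ga = assign_strength_groups(CohortSpec(subjects=subs), policy="nearest")
        sizes = [len(ga.members(g)) for g in ("HS", "MS", "LS")]
        assert sum(sizes) == 20 and max(sizes) - min(sizes) <= 1

    def test_permutation_invariance(self, cohort):
        ga1 = assign_strength_groups(cohort)
        shuffled = CohortSpec(subjects=list(reversed(cohort.subjects)), seed=cohort.seed)
        ga2 = assign_strength_groups(shuffled)
        assert ga1.strength_groups == ga2.strength_groups


class TestEnsemble:
    def _loop(self, scale=1.0, n=400):
        th = np.linspace(0, np.pi, n)
        x = -0.2 * scale * np.sin(th / 2) ** 2
        f = 700 + 400 * scale * np.sin(th)
        return WorkLoop(drive=f, excursion=x)

    def test_single_member_identity(self):
        loop = self._loop()
        curve = ensemble_average([loop])
        assert curve.drive.size == 100 and curve.excursion.size == 100
        assert curve.drive[0] == pytest.approx(loop.drive[0])
        assert curve.drive[-1] == pytest.approx(loop.drive[-1])
        assert curve.excursion[-1] == pytest.approx(loop.excursion[-1])

    def test_identical_members_zero_dispersion(self):
        curve = ensemble_average([self._loop(), self._loop()])
        assert np.allclose(curve.drive_sd, 0.0)
        assert np.allclose(curve.excursion_sd, 0.0)

    def test_congruent_loop_area_oracle(self):
        # numerical oracle: mean member area vs ensemble area on congruent loops
        loops = [self._loop(scale=s) for s in (0.9, 1.0, 1.1)]
        member_mean = np.mean([lp.enclosed_area() for lp in loops])
        curve = ensemble_average(loops)
        assert curve.enclosed_area() == pytest.approx(member_mean, rel=0.03)

    def test_empty_group_rejected(self):
        with pytest.raises(ArgumentError):
            ensemble_average([])


def _tidy(seed=0, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for sex, n in (("M", 9), ("W", 12)):
        for i in range(n):
            for jt in ["CMJ", "DJ15", "DJ30", "DJ45", "DJ60", "DJ75"]:
                y = rng.normal() + (effect if sex == "M" else 0.0)
                rows.append({"subject_id": f"{sex}{i}", "sex": sex,
                             "jump_type": jt, "w_net": y})
    return pd.DataFrame(rows)


class TestAnova:
    def test_fast_path_matches_statsmodels(self):
        df = _tidy(seed=3)
        res = two_way_anova(df, "w_net", "sex", "jump_type")
        full, red = _design_matrices(df["sex"].to_numpy(), df["jump_type"].to_numpy())
        y = df["w_net"].to_numpy()
        qf, _ = np.linalg.qr(full)
        qr_, _ = np.linalg.qr(red)
        tot = y @ y
        sse_f = tot - (qf.T @ y) @ (qf.T @ y)
        sse_r = tot - (qr_.T @ y) @ (qr_.T @ y)
        f_stat = (sse_r - sse_f) / (sse_f / (len(y) - full.shape[1]))
        assert f_stat == pytest.approx(res.effects["sex"]["F"], rel=1e-9)

    def test_null_calibration_smoke(self):
        rate = anova_null_rejection_rate(reps=4000, seed=11)
        assert 0.035 < rate < 0.065

    def test_injected_effect_power(self):
        # Monte-Carlo at the cohort's group sizes: 1 SD sex effect
        power = anova_null_rejection_rate(reps=400, seed=12, effect_a=1.0)
        assert power > 0.5

    def test_constant_outcome_flagged(self):
        df = _tidy()
        df["w_net"] = 3.0
        res = two_way_anova(df, "w_net", "sex", "jump_type")
        assert res.degenerate
        assert np.isnan(res.effects["sex"]["p"])

    def test_empty_cell_named(self):
        df = _tidy()
        df = df[~((df.sex == "W") & (df.jump_type == "DJ75"))]
        with pytest.raises(AnalysisError, match="DJ75"):
            two_way_anova(df, "w_net", "sex", "jump_type")

    def test_single_level_factor_rejected(self):
        df = _tidy()
        df["sex"] = "M"
        with pytest.raises(ArgumentError):
            two_way_anova(df, "w_net", "sex", "jump_type")


class TestBonferroni:
    def _result(self):
        rng = np.random.default_rng(0)
        rows = []
        for grp, n in (("HS", 7), ("MS", 7), ("LS", 7)):
            for i in range(n):
                for jt in ["CMJ", "DJ30"]:
                    rows.append({"g": grp, "jump_type": jt, "y": rng.normal()})
        return two_way_anova(pd.DataFrame(rows), "y", "g", "jump_type")

    def test_three_groups_three_pairs(self):
        ph = bonferroni_posthoc(self._result())
        assert len(ph) == 3
        assert (ph["n_pairs"] == 3).all()

    def test_adjusted_capped_at_one(self):
        ph = bonferroni_posthoc(self._result())
        big = ph[ph["p_raw"] > 1 / 3]
        assert (big["p_adj"] == np.minimum(1.0, big["p_raw"] * 3)).all()
        assert (ph["p_adj"] <= 1.0).all()

    def test_adjusted_at_least_raw(self):
        ph = bonferroni_posthoc(self._result())
        assert (ph["p_adj"] >= ph["p_raw"]).all()

    def test_unknown_pair_rejected(self):
        with pytest.raises(ArgumentError, match="unknown pair"):
            bonferroni_posthoc(self._result(), pairs=[("HS", "XX")])


class TestGroupTables:
    def _results(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid in ("A", "B", "C"):
            for jt in ("CMJ", "DJ30"):
                for q in ("COM", "hip", "knee", "ankle"):
                    w_pos = abs(rng.normal(3, 0.5))
                    w_neg = -abs(rng.normal(2, 0.5))
                    rows.append({"subject_id": sid, "jump_type": jt, "quantity": q,
                                 "w_neg": w_neg, "w_pos": w_pos,
                                 "w_net": w_neg + w_pos,
                                 "ratio": abs(w_neg) / w_pos * 100})
        return pd.DataFrame(rows)

    def test_table_shape(self):
        df = self._results()
        table = build_group_tables(df, {"A": "G1", "B": "G1", "C": "G2"})
        # 2 jumps x 4 quantities x 2 groups
        assert len(table) == 16

    def test_single_member_sd_flag(self):
        table = build_group_tables(self._results(), {"A": "G1", "B": "G1", "C": "G2"})
        solo = table[table["group"] == "G2"]
        assert (solo["sd_flagged"]).all()
        assert (solo["w_neg_sd"] == 0.0).all()

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        # constructed asymmetric counterexample
        rows = []
        for sid, w_neg, w_pos in (("A", -1.0, 1.0), ("B", -1.0, 4.0)):
            rows.append({"subject_id": sid, "jump_type": "CMJ", "quantity": "COM",
                         "w_neg": w_neg, "w_pos": w_pos, "w_net": w_neg + w_pos,
                         "ratio": abs(w_neg) / w_pos * 100})
        table = build_group_tables(pd.DataFrame(rows), {"A": "G", "B": "G"})
        row = table.iloc[0]
        assert row["ratio_mean"] == pytest.approx((100 + 25) / 2)
        assert row["ratio_of_means"] == pytest.approx(2.0 / 5.0 * 100)
        assert row["ratio_mean"] != pytest.approx(row["ratio_of_means"])

    def test_missing_subject_excluded_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            build_group_tables(self._results(), {"A": "G1", "B": "G1"})
        assert "excluding" in caplog.text
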