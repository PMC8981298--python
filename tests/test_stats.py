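"""Statistical battery: normality gate, mixed ANOVA, group tests, correlation."""

import numpy as np
import pandas as pd
import pytest

from freegait.stats import (auc_from_u, compare_groups,
                            lab_realworld_correlation, mixed_anova,
                            normality_gate)
from oracles import (auc_pair_oracle, fixture_to_long, random_anova_fixture,
                     split_plot_anova_oracle)


class TestNormalityGate:
    def test_gaussian_samples_pass(self):
        rng = np.random.default_rng(1)
        g = {"PD": rng.normal(0, 1, 100), "HC": rng.normal(0, 1, 100)}
        assert normality_gate(g) == "normal"

    def test_heavy_lognormal_fails(self):
        rng = np.random.default_rng(2)
        g = {"PD": np.exp(rng.normal(0, 1.5, 50)), "HC": rng.normal(0, 1, 50)}
        assert normality_gate(g) == "non_normal"

    def test_tiny_sample_warns_and_defaults_to_rank_test(self):
        with pytest.warns(UserWarning):
            assert normality_gate({"PD": [1.0, 2.0], "HC": [1.0, 2.0, 3.0]}) \
                == "non_normal"


class TestMixedAnova:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = random_anova_fixture(rng)
        mine = mixed_anova(fixture_to_long(data))
        oracle = split_plot_anova_oracle(data)
        for eff in ("group", "condition", "interaction"):
            m = getattr(mine, eff)
            F, p, eta = oracle[eff]
            assert m.F == pytest.approx(F, abs=1e-10)
            assert m.partial_eta_sq == pytest.approx(eta, abs=1e-10)
            assert m.p == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_pingouin_cross_check(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(40 + seed)
        data = random_anova_fixture(rng)
        long = fixture_to_long(data)
        mine = mixed_anova(long)
        theirs = pg.mixed_anova(long, dv="value", within="condition",
                                between="group", subject="participant_id"
                                ).set_index("Source")
        for eff, key in (("group", "group"), ("condition", "condition"),
                         ("interaction", "Interaction")):
            assert getattr(mine, eff).F == pytest.approx(theirs.loc[key, "F"], abs=1e-9)

    def test_greenhouse_geisser_epsilon_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        from scipy.stats import f as fdist
        rng = np.random.default_rng(77)
        data = random_anova_fixture(rng, max_subjects=6, max_conditions=4)
        long = fixture_to_long(data)
        mine = mixed_anova(long, greenhouse_geisser=True)
        theirs = pg.mixed_anova(long, dv="value", within="condition",
                                between="group", subject="participant_id"
                                ).set_index("Source")
        eps = float(theirs.loc["condition", "eps"])
        e = mine.condition
        expected = float(fdist.sf(e.F, eps * e.df1, eps * e.df2))
        assert e.p_gg == pytest.approx(expected, abs=1e-9)
        assert np.isfinite(mine.interaction.p_gg)
        # uncorrected p stays primary and unchanged
        assert e.p == pytest.approx(theirs.loc["condition", "p_unc"], abs=1e-9)

    def test_null_group_effect_gives_zero_f(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, (4, 3))
        data = {"A": {f"A{i}": list(base[i]) for i in range(4)},
                "B": {f"B{i}": list(base[i]) for i in range(4)}}  # mirrored
        res = mixed_anova(fixture_to_long(data))
        assert res.group.F == pytest.approx(0.0, abs=1e-12)
        assert res.group.partial_eta_sq == pytest.approx(0.0, abs=1e-12)

    def test_incomplete_participants_dropped_and_counted(self):
        rng = np.random.default_rng(6)
        long = fixture_to_long(random_anova_fixture(rng))
        long = long[~((long.participant_id == "A0") & (long.condition == "c0"))]
        res = mixed_anova(long)
        assert res.n_dropped == 1


class TestGroupComparison:
    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_pair_ordering_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        pd_vals = rng.integers(0, 8, 15).astype(float)  # integer ties on purpose
        hc_vals = rng.integers(0, 8, 12).astype(float)
        assert auc_from_u(pd_vals, hc_vals) == pytest.approx(
            auc_pair_oracle(pd_vals, hc_vals), abs=1e-12)

    def _table(self, pd_vals, hc_vals):
        rows = [{"participant_id": f"P{i}", "group": "PD", "condition": "x",
                 "v": v} for i, v in enumerate(pd_vals)]
        rows += [{"participant_id": f"H{i}", "group": "HC", "condition": "x",
                  "v": v} for i, v in enumerate(hc_vals)]
        return pd.DataFrame(rows)

    def test_perfect_separation_gives_auc_one(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.normal(10, 1, 20), rng.normal(0, 1, 20))
        r = compare_groups(t, "v", "x")
        assert r.auc == 1.0 and r.direction == "PD_higher"

    def test_identical_values_give_null_result(self):
        t = self._table([1.0] * 5, [1.0] * 6)
        r = compare_groups(t, "v", "x")
        assert r.p == 1.0 and r.auc == 0.5

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 300
        for _ in range(reps):
            t = self._table(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
            if compare_groups(t, "v", "x").p < 0.05:
                rej += 1
        assert 0.01 < rej / reps < 0.11


class TestCorrelation:
    def _table(self, lab_vals, rw_vals):
        rows = []
        for i, (a, b) in enumerate(zip(lab_vals, rw_vals)):
            rows.append({"participant_id": f"P{i}", "group": "PD",
                         "condition": "lab", "step_velocity": a})
            rows.append({"participant_id": f"P{i}", "group": "PD",
                         "condition": "all_wb", "step_velocity": b})
        return pd.DataFrame(rows)

    def test_identity_copy_gives_r_one(self):
        vals = [1.0, 1.1, 0.9, 1.3, 0.8]
        out = lab_realworld_correlation(self._table(vals, vals),
                                        characteristics=["step_velocity"])
        assert out.iloc[0]["r"] == pytest.approx(1.0)

    def test_hand_fixture_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        expected = (np.cov(x, y, ddof=1)[0, 1]
                    / (np.std(x, ddof=1) * np.std(y, ddof=1)))
        out = lab_realworld_correlation(self._table(x, y),
                                        characteristics=["step_velocity"])
        assert out.iloc[0]["r"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_yields_missing(self):
        out = lab_realworld_correlation(self._table([1, 1, 1, 1], [1, 2, 3, 4]),
                                        characteristics=["step_velocity"])
        assert np.isnan(out.iloc[0]["r"])
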