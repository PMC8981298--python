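"""Classification protocol: design building, splits, metrics, rankings."""

import numpy as np
import pandas as pd
import pytest

from freegait.aggregation import CONDITIONS
from freegait.characteristics import CHARACTERISTICS
from freegait.classify import (Design, _make_pipe, _participant_split,
                               build_design, rank_features, small_grids,
                               train_evaluate)


def synthetic_table(n_pd=10, n_hc=10, seed=0, shift=0.0, holes=()):
    """Aggregated-style table with Gaussian features; ``shift`` moves every
    PD feature by that many SDs; ``holes`` = (participant, condition) cells
    forced to all-NaN."""
    rng = np.random.default_rng(seed)
    rows = []
    for grp, n in (("PD", n_pd), ("HC", n_hc)):
        for i in range(n):
            pid = f"{grp}{i:02d}"
            base = rng.normal(0, 1, len(CHARACTERISTICS))
            for cond in CONDITIONS:
                feats = base + rng.normal(0, 0.3, len(CHARACTERISTICS))
                if grp == "PD":
                    feats = feats + shift
                row = {"participant_id": pid, "group": grp, "condition": cond,
                       "n_bouts": 5, "n_days": 1,
                       **dict(zip(CHARACTERISTICS, feats))}
                if (pid, cond) in holes:
                    row.update({c: np.nan for c in CHARACTERISTICS})
                rows.append(row)
    return pd.DataFrame(rows)


def oracle_design(n_per_group=10, seed=0):
    """One feature equals the label; thirteen are noise."""
    rng = np.random.default_rng(seed)
    t = synthetic_table(n_per_group, n_per_group, seed=seed)
    t[CHARACTERISTICS[3]] = (t["group"] == "PD").astype(float) \
        + 0.01 * rng.standard_normal(len(t))
    return build_design(t)


class TestBuildDesign:
    def test_row_count_bounded_by_participants_times_conditions(self):
        d = build_design(synthetic_table(2, 2))
        assert len(d.X) <= 4 * len(CONDITIONS)
        assert len(d.X) == len(d.y) == len(d.participants)

    def test_planted_hole_drops_exactly_one_row(self):
        full = build_design(synthetic_table(2, 2))
        holed = build_design(synthetic_table(2, 2, holes={("PD00", "le10")}))
        assert len(holed.X) == len(full.X) - 1

    def test_mostly_missing_participant_excluded(self):
        holes = {("PD00", c) for c in CONDITIONS[:12]}
        d = build_design(synthetic_table(3, 3, holes=holes))
        assert "PD00" in d.excluded
        assert "PD00" not in set(d.participants)

    def test_imputer_uses_training_medians_only(self):
        d = build_design(synthetic_table(4, 4, holes={("PD00", "le10")}))
        train_m, _ = _participant_split(d, seed=0)
        pipe = _make_pipe(__import__("sklearn.dummy", fromlist=["DummyClassifier"]
                                     ).DummyClassifier(strategy="most_frequent"))
        pipe.fit(d.X[train_m], d.y[train_m])
        stats = pipe.named_steps["impute"].statistics_
        expected = np.nanmedian(d.X[train_m].to_numpy(), axis=0)
        assert np.allclose(stats, expected)


class TestSplit:
    @pytest.mark.parametrize("seed", range(5))
    def test_no_participant_in_both_partitions(self, seed):
        d = build_design(synthetic_table(7, 9, seed=seed))
        train_m, test_m = _participant_split(d, seed)
        assert not set(d.participants[train_m]) & set(d.participants[test_m])
        assert train_m.sum() + test_m.sum() == len(d.X)

    def test_split_is_group_stratified(self):
        d = build_design(synthetic_table(10, 10))
        _, test_m = _participant_split(d, 3)
        test_pids = set(d.participants[test_m])
        assert sum(p.startswith("PD") for p in test_pids) == 3
        assert sum(p.startswith("HC") for p in test_pids) == 3


class TestTrainEvaluate:
    def test_separable_cohort_classified_perfectly(self):
        d = build_design(synthetic_table(8, 8, shift=10.0))
        rep = train_evaluate(d, seeds=[0, 1], grids=small_grids())
        per_cond = rep.summary[rep.summary.condition != "pooled"]
        assert (per_cond["accuracy_mean"] == 100.0).all()

    def test_report_deterministic_across_reruns(self):
        d = build_design(synthetic_table(8, 8, shift=10.0))
        a = train_evaluate(d, seeds=[0, 1], grids=small_grids()).to_json()
        b = train_evaluate(d, seeds=[0, 1], grids=small_grids()).to_json()
        assert a == b

    def test_metrics_invariant_to_row_order(self):
        d = build_design(synthetic_table(6, 6, shift=2.0))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(d.X))
        d2 = Design(X=d.X.iloc[perm].reset_index(drop=True), y=d.y[perm],
                    participants=d.participants[perm],
                    conditions=d.conditions[perm])
        a = train_evaluate(d, seeds=[0], grids=small_grids())
        b = train_evaluate(d2, seeds=[0], grids=small_grids())
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_accuracy_bounded_by_sensitivity_specificity(self):
        d = build_design(synthetic_table(6, 8, shift=1.0))
        rep = train_evaluate(d, seeds=[0, 1], grids=small_grids())
        ok = rep.per_seed.dropna(subset=["sensitivity", "specificity"])
        lo = ok[["sensitivity", "specificity"]].min(axis=1) - 1e-9
        hi = ok[["sensitivity", "specificity"]].max(axis=1) + 1e-9
        assert ((ok.accuracy >= lo) & (ok.accuracy <= hi)).all()


class TestRankFeatures:
    def test_oracle_feature_ranks_first_in_both_methods(self):
        d = oracle_design()
        rankings, inter = rank_features(d, seed=0)
        oracle = CHARACTERISTICS[3]
        assert rankings["rf_importance"][0] == oracle
        assert rankings["rfe_svm"][0] == oracle
        assert oracle in inter

    def test_intersection_is_set_intersection_of_top5(self):
        d = oracle_design(seed=1)
        rankings, inter = rank_features(d, seed=1)
        expected = sorted(set(rankings["rf_importance"][:5])
                          & set(rankings["rfe_svm"][:5]))
        assert inter == expected

    def test_duplicated_feature_eliminated_before_informative_one(self):
        """RFE with a linear SVM drops one of two identical informative
        features before it drops a distinct informative feature (the
        duplicate is redundant once its twin is present)."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = synthetic_table(8, 8, seed=seed)
            y = (t["group"] == "PD").astype(float)
            sig = y + 0.05 * rng.standard_normal(len(t))
            t[CHARACTERISTICS[0]] = sig
            t[CHARACTERISTICS[1]] = sig  # exact duplicate
            t[CHARACTERISTICS[2]] = y + 0.05 * rng.standard_normal(len(t))
            d = build_design(t)
            rankings, _ = rank_features(d, seed=seed)
            order = rankings["rfe_svm"]
            dup_worst = max(order.index(CHARACTERISTICS[0]),
                            order.index(CHARACTERISTICS[1]))
            if dup_worst > order.index(CHARACTERISTICS[2]):
                wins += 1
        assert wins >= 3
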