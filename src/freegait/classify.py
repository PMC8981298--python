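"""PD/HC classification protocol: RF, SVM and a soft-voting ensemble.

One pooled design matrix holds a row per (participant, aggregation
condition) with the 14 characteristics as features.  For each of 10 random
seeds the data is split 70/30 *at the participant level* (stratified by
group) so no participant contributes rows to both partitions; grid-searched
hyperparameters come from participant-grouped 10-fold cross-validation on
the training partition; the refit models are then tested separately on the
test rows of every condition.  Metrics are reported as mean +/- SD over the
seed repeats, with PD as the positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .aggregation import CONDITIONS
from .characteristics import CHARACTERISTICS

POSITIVE = "PD"
METRICS = ["accuracy", "f1", "auc", "sensitivity", "specificity"]


def default_grids() -> dict[str, dict]:
    return {
        "rf": {"clf__n_estimators": [100, 300, 500],
               "clf__max_depth": [None, 5, 10],
               "clf__max_features": ["sqrt", "log2"]},
        "svm": [{"clf__estimator__kernel": ["rbf"],
                 "clf__estimator__C": [0.1, 1.0, 10.0, 100.0],
                 "clf__estimator__gamma": ["scale"]},
                {"clf__estimator__kernel": ["linear"],
                 "clf__estimator__C": [0.1, 1.0, 10.0, 100.0]}],
    }


def small_grids() -> dict[str, dict]:
    """Reduced search space for desk-scale repeated-cohort experiments."""
    return {
        "rf": {"clf__n_estimators": [300], "clf__max_depth": [None, 5]},
        "svm": [{"clf__estimator__kernel": ["rbf"],
                 "clf__estimator__C": [1.0, 10.0],
                 "clf__estimator__gamma": ["scale"]}],
    }


@dataclass
class Design:
    X: pd.DataFrame              # rows x 14 features (NaN allowed)
    y: np.ndarray                # 1 = PD, 0 = HC
    participants: np.ndarray     # participant id per row
    conditions: np.ndarray       # condition label per row
    excluded: list[str] = field(default_factory=list)


def build_design(table: pd.DataFrame, include_lab: bool = True,
                 max_missing_frac: float = 0.5) -> Design:
    """Feature matrix from an aggregated table.

    One row per (participant, condition); participants missing more than
    half of their condition rows (all-NaN features) are excluded and listed.
    Missing cells stay NaN here — imputation happens inside the model
    pipeline with training-fold medians only, so test data can never leak
    into the imputer.
    """
    conds = [c for c in CONDITIONS if include_lab or c != "lab"]
    sub = table[table["condition"].isin(conds)].copy()
    if sub["group"].nunique() < 2:
        raise ValueError("need both groups present")
    feat = sub[CHARACTERISTICS].astype(float)
    empty = feat.isna().all(axis=1)
    missing_frac = empty.groupby(sub["participant_id"].values).mean()
    excluded = missing_frac.index[missing_frac > max_missing_frac].tolist()
    keep = ~sub["participant_id"].isin(excluded) & ~empty
    sub = sub[keep]
    return Design(
        X=sub[CHARACTERISTICS].astype(float).reset_index(drop=True),
        y=(sub["group"] == POSITIVE).to_numpy(dtype=int),
        participants=sub["participant_id"].to_numpy(),
        conditions=np.asarray(sub["condition"].astype(str)),
        excluded=excluded,
    )


def _participant_split(design: Design, seed: int, test_frac: float = 0.3
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Group-stratified participant-level 70/30 split; returns row masks."""
    rng = np.random.default_rng(seed)
    test_pids: list = []
    pid_group = pd.Series(design.y, index=design.participants).groupby(level=0).first()
    for cls in (0, 1):
        pids = np.sort(pid_group.index[pid_group == cls].to_numpy())
        pids = pids[rng.permutation(len(pids))]
        n_test = max(1, int(round(test_frac * len(pids))))
        test_pids.extend(pids[:n_test])
    test_mask = np.isin(design.participants, test_pids)
    return ~test_mask, test_mask


def _make_pipe(clf) -> Pipeline:
    return Pipeline([("impute", SimpleImputer(strategy="median")),
                     ("scale", StandardScaler()),
                     ("clf", clf)])


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       proba: np.ndarray) -> dict[str, float]:
    if len(np.unique(y_true)) < 2:
        return {m: np.nan for m in METRICS}
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"accuracy": 100.0 * (tp + tn) / len(y_true),
            "f1": 100.0 * f1,
            "auc": 100.0 * roc_auc_score(y_true, proba),
            "sensitivity": 100.0 * sens,
            "specificity": 100.0 * spec}


@dataclass
class ClassificationReport:
    summary: pd.DataFrame        # model x condition x metric: mean, sd, n_seeds
    per_seed: pd.DataFrame
    cv_accuracy_range: tuple[float, float]
    feature_rankings: dict[str, list[str]]
    top5_intersection: list[str]
    excluded: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "summary": self.summary.to_dict(orient="records"),
            "per_seed": self.per_seed.to_dict(orient="records"),
            "cv_accuracy_range": list(self.cv_accuracy_range),
            "feature_rankings": self.feature_rankings,
            "top5_intersection": self.top5_intersection,
            "excluded": self.excluded,
        }, indent=1, sort_keys=True)


def train_evaluate(design: Design, seeds: list[int] | None = None,
                   grids: dict | None = None, cv_folds: int = 10,
                   models: tuple[str, ...] = ("rf", "svm", "ensemble"),
                   ) -> ClassificationReport:
    """Run the full repeated-seed protocol and assemble the report.

    Per seed: participant-level stratified 70/30 split; grid search with
    participant-grouped ``cv_folds``-fold CV on the 70 %; refit on the full
    training partition; per-condition evaluation on the 30 %.  The ensemble
    averages the two members' class probabilities (soft voting, threshold
    0.5).  Conditions whose test rows hold a single class are excluded from
    that seed's mean with a count.
    """
    seeds = list(range(10)) if seeds is None else list(seeds)
    grids = grids or default_grids()
    records = []
    cv_scores = []
    conds_present = [c for c in CONDITIONS if c in set(design.conditions)]

    for seed in seeds:
        train_m, test_m = _participant_split(design, seed)
        n_train_p = len(np.unique(design.participants[train_m]))
        if n_train_p < 4:
            raise ValueError("need at least 4 training participants")
        folds = min(cv_folds, n_train_p)  # grouped CV cannot exceed participants
        Xtr = design.X[train_m]
        ytr = design.y[train_m]
        gtr = design.participants[train_m]
        assert not set(np.unique(gtr)) & set(np.unique(design.participants[test_m]))

        fitted = {}
        for name in ("rf", "svm"):
            if name not in models and "ensemble" not in models:
                continue
            # SVM probabilities for soft voting come from cross-validated
            # Platt calibration fitted on the training partition only
            clf = (RandomForestClassifier(random_state=seed) if name == "rf"
                   else CalibratedClassifierCV(SVC(random_state=seed),
                                               ensemble=False))
            gkf = GroupKFold(n_splits=folds)
            gs = GridSearchCV(_make_pipe(clf), grids[name],
                              cv=list(gkf.split(Xtr, ytr, groups=gtr)),
                              scoring="accuracy", n_jobs=1, refit=True)
            gs.fit(Xtr, ytr)
            fitted[name] = gs.best_estimator_
            cv_scores.append(100.0 * gs.best_score_)

        def proba(model_name, X):
            if model_name == "ensemble":
                return (fitted["rf"].predict_proba(X)[:, 1]
                        + fitted["svm"].predict_proba(X)[:, 1]) / 2.0
            return fitted[model_name].predict_proba(X)[:, 1]

        for cond in conds_present:
            m = test_m & (design.conditions == cond)
            if not m.any():
                continue
            yte = design.y[m]
            for model_name in models:
                pr = proba(model_name, design.X[m])
                met = _confusion_metrics(yte, (pr >= 0.5).astype(int), pr)
                records.append({"seed": seed, "model": model_name,
                                "condition": cond, **met})
        # pooled over all conditions
        yte = design.y[test_m]
        for model_name in models:
            pr = proba(model_name, design.X[test_m])
            met = _confusion_metrics(yte, (pr >= 0.5).astype(int), pr)
            records.append({"seed": seed, "model": model_name,
                            "condition": "pooled", **met})

    per_seed = pd.DataFrame(records)
    summary = (per_seed.groupby(["model", "condition"])[METRICS]
               .agg(["mean", "std", "count"]).reset_index())
    summary.columns = ["model", "condition"] + [
        f"{m}_{s}" for m in METRICS for s in ("mean", "sd", "n_seeds")]

    rankings, top5 = rank_features(design, seeds[0])
    return ClassificationReport(
        summary=summary, per_seed=per_seed,
        cv_accuracy_range=(float(min(cv_scores)), float(max(cv_scores))),
        feature_rankings=rankings, top5_intersection=top5,
        excluded=design.excluded)


def rank_features(design: Design, seed: int,
                  ) -> tuple[dict[str, list[str]], list[str]]:
    """Feature orderings from RF impurity importance and RFE with a linear
    SVM (one feature eliminated per round), plus the top-5 intersection.
    Both are fitted on the seed's 70 % training partition."""
    train_m, _ = _participant_split(design, seed)
    Xtr, ytr = design.X[train_m], design.y[train_m]

    rf_pipe = _make_pipe(RandomForestClassifier(n_estimators=500, random_state=seed))
    rf_pipe.fit(Xtr, ytr)
    imp = rf_pipe.named_steps["clf"].feature_importances_
    rf_order = [CHARACTERISTICS[i] for i in np.argsort(imp)[::-1]]

    rfe_pipe = Pipeline([("impute", SimpleImputer(strategy="median")),
                         ("scale", StandardScaler()),
                         ("rfe", RFE(SVC(kernel="linear", random_state=seed),
                                     n_features_to_select=1, step=1))])
    rfe_pipe.fit(Xtr, ytr)
    ranking = rfe_pipe.named_steps["rfe"].ranking_
    svm_order = [CHARACTERISTICS[i] for i in np.argsort(ranking)]

    rankings = {"rf_importance": rf_order, "rfe_svm": svm_order}
    inter = sorted(set(rf_order[:5]) & set(svm_order[:5]))
    return rankings, inter
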