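"""Group statistics: normality screening, mixed ANOVA, group tests, AUC and
lab-vs-real-world correlations.

The mixed (split-plot) ANOVA has one between-participant factor (group) and
one within-participant factor (aggregation condition); it is computed from
explicit sums of squares with the classical degrees of freedom, and partial
eta squared is SS_effect / (SS_effect + SS_error-for-that-effect).  Group
comparisons use Welch's t-test when both groups pass a Shapiro-Wilk screen,
otherwise the Mann-Whitney U test; the discriminative AUC is the normalised
U statistic, oriented to be >= 0.5.  No multiple-comparison adjustment is
applied anywhere (exploratory battery, alpha = 0.05 throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .characteristics import CHARACTERISTICS

ALPHA = 0.05


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def normality_gate(values_by_group: dict[str, np.ndarray],
                   alpha: float = ALPHA) -> str:
    """'normal' unless Shapiro-Wilk rejects (p < alpha) in either group.

    Groups with fewer than 3 values cannot be screened and yield
    'non_normal' with a warning (the rank test is the safe default).
    """
    for g, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 3:
            warnings.warn(f"group {g!r} has n={len(vals)} < 3; treating as non-normal")
            return "non_normal"
        if np.ptp(vals) == 0:
            return "non_normal"
        if sps.shapiro(vals).pvalue < alpha:
            return "non_normal"
    return "normal"


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    F: float
    p: float
    partial_eta_sq: float
    df1: int
    df2: int
    p_gg: float = float("nan")  # Greenhouse-Geisser corrected, when requested


@dataclass
class MixedAnovaResult:
    group: EffectResult
    condition: EffectResult
    interaction: EffectResult
    n_dropped: int = 0  # participants removed for missing condition levels


def mixed_anova(table: pd.DataFrame, dv: str = "value",
                participant: str = "participant_id", between: str = "group",
                within: str = "condition",
                greenhouse_geisser: bool = False) -> MixedAnovaResult:
    """One-between, one-within repeated-measures ANOVA from explicit SS.

    Participants missing any within level are dropped (complete cases) and
    counted in ``n_dropped``.  Requires >= 2 within levels and >= 2
    participants per group after dropping.  ``greenhouse_geisser`` adds
    sphericity-corrected p-values for the within effects (classical,
    uncorrected p stays the primary value; both are reported).
    """
    df = table[[participant, between, within, dv]].dropna()
    levels = sorted(df[within].unique())
    b = len(levels)
    if b < 2:
        raise ValueError("need at least two within-factor levels")
    counts = df.groupby(participant)[within].nunique()
    complete = counts.index[counts == b]
    n_dropped = int((counts != b).sum())
    df = df[df[participant].isin(complete)]
    wide = df.pivot_table(index=[participant, between], columns=within,
                          values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("duplicate/missing cells after pivot")
    groups = wide.index.get_level_values(between)
    glabels = sorted(set(groups))
    if len(glabels) != 2 or min((groups == g).sum() for g in glabels) < 2:
        raise ValueError("need two groups with >= 2 complete participants each")

    X = wide.to_numpy()                       # subjects x conditions
    gidx = np.array([glabels.index(g) for g in groups])
    N = X.shape[0]
    grand = X.mean()
    subj_means = X.mean(axis=1)
    cond_means = X.mean(axis=0)

    ss_between_subj = b * np.sum((subj_means - grand) ** 2)
    ss_group = 0.0
    group_means = np.empty(2)
    ns = np.empty(2, dtype=int)
    for k in range(2):
        sel = gidx == k
        ns[k] = sel.sum()
        group_means[k] = X[sel].mean()
        ss_group += b * ns[k] * (group_means[k] - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group

    ss_total = np.sum((X - grand) ** 2)
    ss_within_subj = ss_total - ss_between_subj
    ss_cond = N * np.sum((cond_means - grand) ** 2)
    ss_inter = 0.0
    for k in range(2):
        cell = X[gidx == k].mean(axis=0)
        ss_inter += ns[k] * np.sum((cell - group_means[k] - cond_means + grand) ** 2)
    ss_err_within = ss_within_subj - ss_cond - ss_inter

    df_group, df_subj = 1, N - 2
    df_cond = b - 1
    df_inter = df_cond
    df_err_w = (N - 2) * (b - 1)

    def eff(ss, dfe, ss_err, df_err):
        ms, ms_err = ss / dfe, ss_err / df_err
        F = ms / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, dfe, df_err))
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return EffectResult(F=float(F), p=p, partial_eta_sq=float(eta),
                            df1=dfe, df2=df_err)

    res = MixedAnovaResult(
        group=eff(ss_group, df_group, ss_subj_within, df_subj),
        condition=eff(ss_cond, df_cond, ss_err_within, df_err_w),
        interaction=eff(ss_inter, df_inter, ss_err_within, df_err_w),
        n_dropped=n_dropped,
    )
    if greenhouse_geisser:
        # epsilon from the double-centred condition covariance (the
        # convention of the established repeated-measures implementations)
        C = np.cov(X, rowvar=False)
        C2 = (C - C.mean(axis=0, keepdims=True) - C.mean(axis=1, keepdims=True)
              + C.mean())
        eps = (np.trace(C2) ** 2) / ((b - 1) * np.sum(C2 * C2))
        eps = float(np.clip(eps, 1.0 / (b - 1), 1.0))
        for e in (res.condition, res.interaction):
            e.p_gg = float(sps.f.sf(e.F, eps * e.df1, eps * e.df2))
    return res


# ---------------------------------------------------------------------------
# group comparison + AUC
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    characteristic: str
    condition: str
    test_used: str       # "t" | "mann_whitney"
    statistic: float
    p: float
    auc: float           # oriented >= 0.5
    direction: str       # "PD_lower" | "PD_higher"
    n_pd: int
    n_hc: int


def auc_from_u(pd_vals: np.ndarray, hc_vals: np.ndarray) -> float:
    """P(PD value > HC value) + 0.5 P(tie): the normalised Mann-Whitney U."""
    u = sps.mannwhitneyu(pd_vals, hc_vals, alternative="two-sided").statistic
    return float(u) / (len(pd_vals) * len(hc_vals))


def compare_groups(table: pd.DataFrame, characteristic: str, condition: str,
                   welch: bool = True) -> GroupTestResult:
    """PD-vs-HC test for one characteristic under one aggregation condition.

    Welch's t-test when the Shapiro-Wilk screen passes in both groups,
    otherwise Mann-Whitney U.  The AUC is always the normalised U statistic,
    oriented above 0.5 with the direction of the PD shift recorded.
    """
    sub = table[table["condition"] == condition]
    x_pd = sub.loc[sub["group"] == "PD", characteristic].dropna().to_numpy()
    x_hc = sub.loc[sub["group"] == "HC", characteristic].dropna().to_numpy()
    if len(x_pd) == 0 or len(x_hc) == 0:
        raise ValueError("both groups must be non-empty")

    pooled = np.concatenate([x_pd, x_hc])
    if np.ptp(pooled) == 0:
        return GroupTestResult(characteristic, condition, "mann_whitney",
                               0.0, 1.0, 0.5, "PD_higher", len(x_pd), len(x_hc))

    gate = normality_gate({"PD": x_pd, "HC": x_hc})
    if gate == "normal":
        res = sps.ttest_ind(x_pd, x_hc, equal_var=not welch)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        res = sps.mannwhitneyu(x_pd, x_hc, alternative="two-sided")
        test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)

    auc_raw = auc_from_u(x_pd, x_hc)
    if auc_raw >= 0.5:
        auc, direction = auc_raw, "PD_higher"
    else:
        auc, direction = 1.0 - auc_raw, "PD_lower"
    return GroupTestResult(characteristic, condition, test, stat, p, auc,
                           direction, len(x_pd), len(x_hc))


def group_test_battery(table: pd.DataFrame,
                       conditions: list[str] | None = None,
                       characteristics: list[str] | None = None
                       ) -> pd.DataFrame:
    """Run compare_groups over the characteristic x condition grid."""
    conditions = conditions or sorted(table["condition"].unique().tolist())
    characteristics = characteristics or CHARACTERISTICS
    rows = []
    for cond in conditions:
        for ch in characteristics:
            try:
                r = compare_groups(table, ch, cond)
            except ValueError:
                continue
            rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lab vs real-world correlation
# ---------------------------------------------------------------------------

def lab_realworld_correlation(table: pd.DataFrame,
                              characteristics: list[str] | None = None
                              ) -> pd.DataFrame:
    """Pearson r between the lab value and each real-world condition value,
    per characteristic and group, pairwise-complete.  Pairs with fewer than
    3 observations or zero variance yield NaN."""
    characteristics = characteristics or CHARACTERISTICS
    lab = table[table["condition"] == "lab"]
    rows = []
    for grp in sorted(table["group"].unique()):
        lab_g = lab[lab["group"] == grp].set_index("participant_id")
        for cond in [c for c in table["condition"].unique() if c != "lab"]:
            rw = table[(table["condition"] == cond)
                       & (table["group"] == grp)].set_index("participant_id")
            common = lab_g.index.intersection(rw.index)
            for ch in characteristics:
                x = lab_g.loc[common, ch].to_numpy(dtype=float)
                y = rw.loc[common, ch].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                    r = np.nan
                else:
                    r = float(sps.pearsonr(x[ok], y[ok]).statistic)
                rows.append({"group": grp, "condition": cond,
                             "characteristic": ch, "r": r, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def anova_battery(table: pd.DataFrame, levels: list[str],
                  characteristics: list[str] | None = None) -> pd.DataFrame:
    """Mixed ANOVA per characteristic over the given within-factor levels.

    The level list is a parameter (the headline analysis uses lab, all-bout
    and the duration conditions of interest) rather than a fixed set.
    """
    characteristics = characteristics or CHARACTERISTICS
    rows = []
    for ch in characteristics:
        long = table[table["condition"].isin(levels)][
            ["participant_id", "group", "condition", ch]].rename(columns={ch: "value"})
        try:
            res = mixed_anova(long)
        except ValueError:
            continue
        for eff_name in ("group", "condition", "interaction"):
            e = getattr(res, eff_name)
            rows.append({"characteristic": ch, "effect": eff_name, "F": e.F,
                         "p": e.p, "partial_eta_sq": e.partial_eta_sq,
                         "df1": e.df1, "df2": e.df2,
                         "n_dropped": res.n_dropped})
    return pd.DataFrame(rows)
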