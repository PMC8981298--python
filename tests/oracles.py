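"""Independent brute-force oracles used to validate the statistics module.

These deliberately use plain nested loops and textbook definitional
formulas, sharing no code with the package implementation.
"""

import numpy as np
from scipy import stats as sps


def split_plot_anova_oracle(data: dict[str, dict[str, list[float]]]):
    """Split-plot ANOVA from first principles.

    ``data[group][subject] = [value per condition]`` (every subject has the
    same condition count).  Returns {effect: (F, p, partial_eta_sq)}.
    """
    groups = sorted(data)
    b = len(next(iter(data[groups[0]].values())))
    all_vals = []
    for g in groups:
        for s in data[g]:
            all_vals.extend(data[g][s])
    grand = sum(all_vals) / len(all_vals)
    N = sum(len(data[g]) for g in groups)

    ss_group = 0.0
    for g in groups:
        vals = [v for s in data[g] for v in data[g][s]]
        gm = sum(vals) / len(vals)
        ss_group += len(data[g]) * b * (gm - grand) ** 2

    ss_subj_within = 0.0
    for g in groups:
        vals = [v for s in data[g] for v in data[g][s]]
        gm = sum(vals) / len(vals)
        for s in data[g]:
            sm = sum(data[g][s]) / b
            ss_subj_within += b * (sm - gm) ** 2

    cond_means = []
    for c in range(b):
        vals = [data[g][s][c] for g in groups for s in data[g]]
        cond_means.append(sum(vals) / len(vals))
    ss_cond = N * sum((cm - grand) ** 2 for cm in cond_means)

    ss_inter = 0.0
    for g in groups:
        vals = [v for s in data[g] for v in data[g][s]]
        gm = sum(vals) / len(vals)
        for c in range(b):
            cell = [data[g][s][c] for s in data[g]]
            cellm = sum(cell) / len(cell)
            ss_inter += len(cell) * (cellm - gm - cond_means[c] + grand) ** 2

    ss_err_w = 0.0
    for g in groups:
        for s in data[g]:
            sm = sum(data[g][s]) / b
            for c in range(b):
                ss_err_w += (data[g][s][c] - sm) ** 2
    ss_err_w -= ss_cond + ss_inter

    df_g, df_s = len(groups) - 1, N - len(groups)
    df_c = b - 1
    df_i = df_g * df_c
    df_e = df_s * df_c

    def eff(ss, dfe, sse, dfee):
        F = (ss / dfe) / (sse / dfee)
        return F, float(sps.f.sf(F, dfe, dfee)), ss / (ss + sse)

    return {"group": eff(ss_group, df_g, ss_subj_within, df_s),
            "condition": eff(ss_cond, df_c, ss_err_w, df_e),
            "interaction": eff(ss_inter, df_i, ss_err_w, df_e)}


def auc_pair_oracle(pos: np.ndarray, neg: np.ndarray) -> float:
    """Proportion of cross-group pairs correctly ordered, plus half ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_anova_fixture(rng, max_subjects=6, max_conditions=4):
    n1 = int(rng.integers(2, max_subjects + 1))
    n2 = int(rng.integers(2, max_subjects + 1))
    b = int(rng.integers(2, max_conditions + 1))
    data = {}
    for g, n in (("A", n1), ("B", n2)):
        data[g] = {f"{g}{i}": list(rng.normal(0, 1, b)
                                   + rng.normal(0, 1)
                                   + (0.6 if g == "B" else 0) * np.arange(b))
                   for i in range(n)}
    return data


def fixture_to_long(data):
    import pandas as pd
    rows = []
    for g in data:
        for s in data[g]:
            for c, v in enumerate(data[g][s]):
                rows.append({"participant_id": s, "group": g,
                             "condition": f"c{c}", "value": float(v)})
    return pd.DataFrame(rows)
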