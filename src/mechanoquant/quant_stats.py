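"""Group statistics: two-sided t-test, two-way ANOVA with Tukey HSD post
hoc, relative expression by the delta-delta-Ct method, and an empirical
type-I-error self-check.

Defaults mirror common prism-style practice for cell-biology group data:
pooled-variance Student t-test (Welch available via a flag), type III sums
of squares with sum-to-zero contrasts for the two-way ANOVA, and Tukey
comparisons across all crossed cell means.  Normality is assumed, not
tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "StatResult",
    "two_sided_t_test",
    "two_way_anova_tukey",
    "ddct",
    "type_i_error_check",
    "significance_stars",
]


@dataclass
class StatResult:
    """Outcome of one statistical test.

    ``post_hoc`` (two-way ANOVA only) has one row per pair of compared
    groups with the mean difference and Tukey-adjusted p-value.
    """

    test: str
    statistic: dict
    df: dict
    p_value: dict
    alpha: float = 0.05
    post_hoc: pd.DataFrame | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.p_value.values():
            if np.isfinite(v) and not (0.0 <= v <= 1.0):
                raise ValueError("p-values must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "df": self.df,
             "p_value": self.p_value, "alpha": self.alpha,
             "degenerate": self.degenerate}
        if self.post_hoc is not None:
            d["post_hoc"] = self.post_hoc.to_dict(orient="records")
        d.update(self.extra)
        return d


def significance_stars(p: float) -> str:
    """Significance annotation: * p<0.05, ** p<0.01, *** p<0.001,
    **** p<0.0001, 'ns' otherwise."""
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                         (5e-2, "*")):
        if p < thresh:
            return mark
    return "ns"


def two_sided_t_test(group1, group2, welch: bool = False,
                     alpha: float = 0.05) -> StatResult:
    """Two-sample two-sided t-test (pooled variance by default).

    Degenerate inputs are handled explicitly: zero variance in both groups
    with equal means gives t = 0, p = 1; zero variance with unequal means
    is flagged degenerate (the difference is certain under the model, p
    reported as 0).
    """
    x = np.asarray(group1, float)
    y = np.asarray(group2, float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if v1 == 0 and v2 == 0:
        if diff == 0:
            return StatResult("t-test", {"t": 0.0},
                              {"df": float(n1 + n2 - 2)}, {"p": 1.0}, alpha)
        return StatResult("t-test", {"t": float(np.inf) * np.sign(diff)},
                          {"df": float(n1 + n2 - 2)}, {"p": 0.0}, alpha,
                          degenerate=True)
    if welch:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = np.sqrt(se2_1 + se2_2)
        df = (se2_1 + se2_2) ** 2 / (se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult("welch-t-test" if welch else "t-test",
                      {"t": float(t)}, {"df": float(df)}, {"p": float(p)},
                      alpha, extra={"mean_difference": float(diff)})


def _tukey_cell_means(df: pd.DataFrame, value: str, group_col: str,
                      mse: float, df_resid: float) -> pd.DataFrame:
    """Tukey(-Kramer) HSD over the levels of ``group_col`` using an
    externally supplied error variance."""
    groups = df.groupby(group_col, observed=True)[value]
    means = groups.mean()
    ns = groups.size()
    levels = list(means.index)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            d = means[b] - means[a]
            se = np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
            q = abs(d) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_resid)) if se > 0 else 0.0
            rows.append({"group1": a, "group2": b,
                         "mean_difference": float(d), "q": float(q),
                         "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def two_way_anova_tukey(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factorA",
    factor_b: str = "factorB",
    alpha: float = 0.05,
    tukey_mode: str = "cells",
) -> StatResult:
    """Two-way ANOVA (type III SS, sum-to-zero contrasts) with Tukey HSD.

    ``tukey_mode='cells'`` compares all crossed factor-cell means (the
    default, matching multiple-comparison plots over every condition);
    ``'main_a'``/``'main_b'`` compare the levels of one factor only.  The
    Tukey error term is the ANOVA residual mean square in either mode.
    Empty design cells raise with the offending cell named.
    """
    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"table lacks column {col!r}")
    df = table[[factor_a, factor_b, value]].copy()
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    la = df[factor_a].unique()
    lb = df[factor_b].unique()
    for a in la:
        for b in lb:
            if (a, b) not in counts.index:
                raise ValueError(f"empty design cell: ({a!r}, {b!r})")
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"design cell {bad!r} has fewer than 2 replicates")

    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}'), Sum) * C(Q('{factor_b}'), Sum)",
        data=df).fit()
    if model.ssr <= np.finfo(float).eps * max(1.0, float(model.centered_tss)):
        return StatResult("two-way-anova",
                          {"F_A": np.nan, "F_B": np.nan, "F_AB": np.nan},
                          {"df_resid": float(model.df_resid)},
                          {"p_A": np.nan, "p_B": np.nan, "p_AB": np.nan},
                          alpha, degenerate=True)
    aov = anova_lm(model, typ=3)
    row_a, row_b, row_ab = aov.index[1], aov.index[2], aov.index[3]
    stat = {"F_A": float(aov.loc[row_a, "F"]),
            "F_B": float(aov.loc[row_b, "F"]),
            "F_AB": float(aov.loc[row_ab, "F"])}
    pvals = {"p_A": float(aov.loc[row_a, "PR(>F)"]),
             "p_B": float(aov.loc[row_b, "PR(>F)"]),
             "p_AB": float(aov.loc[row_ab, "PR(>F)"])}
    dfs = {"df_A": float(aov.loc[row_a, "df"]),
           "df_B": float(aov.loc[row_b, "df"]),
           "df_AB": float(aov.loc[row_ab, "df"]),
           "df_resid": float(model.df_resid)}
    mse = float(model.ssr / model.df_resid)

    if tukey_mode == "cells":
        df["_cell"] = (df[factor_a].astype(str) + ":"
                       + df[factor_b].astype(str))
        post = _tukey_cell_means(df, value, "_cell", mse, model.df_resid)
    elif tukey_mode == "main_a":
        post = _tukey_cell_means(df, value, factor_a, mse, model.df_resid)
    elif tukey_mode == "main_b":
        post = _tukey_cell_means(df, value, factor_b, mse, model.df_resid)
    else:
        raise ValueError("tukey_mode must be 'cells', 'main_a' or 'main_b'")
    post["significance"] = post["p_adj"].map(significance_stars)
    return StatResult("two-way-anova", stat, dfs, pvals, alpha,
                      post_hoc=post, extra={"mse": mse})


def ddct(table: pd.DataFrame, reference_gene: str, calibrator: str,
         sample_col: str = "sample", condition_col: str = "condition",
         gene_col: str = "gene", ct_col: str = "ct") -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    Per sample and target gene: delta-Ct is the mean replicate Ct of the
    target minus the mean replicate Ct of the reference (housekeeping)
    gene; delta-delta-Ct subtracts the mean delta-Ct of the calibrator
    condition; fold change is 2^(-ddCt) (amplification efficiency 2, no
    efficiency correction).

    Returns one row per (sample, gene != reference) with columns
    ``delta_ct``, ``delta_delta_ct`` and ``fold_change``.
    """
    for col in (sample_col, condition_col, gene_col, ct_col):
        if col not in table.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    if not np.isfinite(table[ct_col]).all():
        raise ValueError("Ct values must be finite")
    if calibrator not in set(table[condition_col]):
        raise ValueError(f"calibrator condition {calibrator!r} not in table")
    mean_ct = (table.groupby([sample_col, condition_col, gene_col],
                             observed=True)[ct_col]
               .mean().reset_index())
    ref = mean_ct[mean_ct[gene_col] == reference_gene] \
        .set_index(sample_col)[ct_col]
    targets = mean_ct[mean_ct[gene_col] != reference_gene].copy()
    missing = set(targets[sample_col]) - set(ref.index)
    if missing:
        raise ValueError(
            f"reference gene {reference_gene!r} missing for sample(s): "
            f"{sorted(missing)}")
    targets["delta_ct"] = (targets[ct_col].to_numpy()
                           - ref.loc[targets[sample_col]].to_numpy())
    out = []
    for gene, sub in targets.groupby(gene_col, observed=True):
        cal = sub.loc[sub[condition_col] == calibrator, "delta_ct"]
        if cal.empty:
            raise ValueError(
                f"no calibrator ({calibrator!r}) samples for gene {gene!r}")
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - cal.mean()
        sub["fold_change"] = 2.0 ** (-sub["delta_delta_ct"])
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    return result[[sample_col, condition_col, gene_col, "delta_ct",
                   "delta_delta_ct", "fold_change"]]


def type_i_error_check(simulator, n_sims: int, alpha: float = 0.05,
                       seed: int = 0) -> float:
    """Empirical rejection rate of a test under a user-supplied null.

    ``simulator(rng)`` must draw one null dataset and return its p-value.
    Returns the fraction of simulations with p < alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = sum(simulator(rng) < alpha for _ in range(n_sims))
    return rejections / n_sims
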