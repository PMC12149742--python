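"""Group-comparison harness for per-cell feature tables.

The routing mirrors a standard electrophysiology statistics plan: each
group's values are first screened for normality (Shapiro-Wilk, alpha 0.05).
If every group passes, the comparison is parametric — Student's t-test for
two groups, one-way ANOVA with a Tukey HSD post hoc for more.  If any group
fails, the whole comparison goes non-parametric — Wilcoxon rank-sum
(Mann-Whitney) for two groups, Kruskal-Wallis for more.  Grouped
current-by-treatment designs (f-I curves, I/V families) use a two-way
mixed ANOVA (treatment between cells, current level within) with
Sidak-corrected per-level contrasts.

The individual tests are standard library implementations (scipy,
statsmodels, pingouin); the bespoke content is the routing and the
per-level contrast table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUP_LABELS",
    "ComparisonReport",
    "compare_groups",
    "compare_fi",
    "make_group_table",
    "ALPHA",
]

ALPHA = 0.05

#: treatment labels used throughout the synthetic experiments
GROUP_LABELS = (
    "control",
    "atropine-3h",
    "mecamylamine-3h",
    "atropine-0-10DIV",
    "mecamylamine-0-10DIV",
)


@dataclass
class ComparisonReport:
    feature: str
    test: str
    statistic: float
    p_value: float
    reject: bool
    parametric: bool
    normality_p: dict[str, float]
    groups: list[str]
    posthoc: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "feature": self.feature,
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p_value,
            "reject": self.reject,
            "parametric": self.parametric,
        }


def make_group_table(rows) -> pd.DataFrame:
    """Tidy per-cell feature table with columns
    (cell_id, culture_id, group, feature, value)."""
    df = pd.DataFrame(rows, columns=["cell_id", "culture_id", "group", "feature", "value"])
    dup = df.duplicated(subset=["cell_id", "feature"])
    if dup.any():
        raise ValueError("one value per (cell, feature) required")
    return df


def _group_values(table: pd.DataFrame, feature: str, aggregate: str | None):
    sub = table[table["feature"] == feature]
    if aggregate == "culture":
        sub = (
            sub.groupby(["group", "culture_id"], as_index=False)["value"].mean()
        )
    groups = [str(g) for g in sub["group"].unique()]
    values = {g: sub.loc[sub["group"] == g, "value"].to_numpy(float) for g in groups}
    small = [g for g, v in values.items() if v.size < 3]
    if len(groups) < 2 or small:
        raise ValueError(
            f"need >= 2 groups with >= 3 values each; undersized: {small}"
        )
    return groups, values


def compare_groups(
    table: pd.DataFrame,
    feature: str,
    design: str = "oneway",
    alpha: float = ALPHA,
    aggregate: str | None = None,
) -> ComparisonReport:
    """Normality-gated comparison of one feature across treatment groups.

    ``design``: 'oneway' (or 'pairwise' for exactly two groups).  The
    analysis unit is the cell; pass ``aggregate='culture'`` to average
    cells within cultures first.
    """
    if design not in ("oneway", "pairwise"):
        raise ValueError("design must be 'oneway' or 'pairwise' here; "
                         "use compare_fi for the grouped two-way design")
    groups, values = _group_values(table, feature, aggregate)
    if design == "pairwise" and len(groups) != 2:
        raise ValueError("pairwise design needs exactly two groups")

    norm_p = {}
    for g, v in values.items():
        if np.ptp(v) == 0:
            norm_p[g] = 0.0  # constant data: not plausibly Gaussian
        else:
            norm_p[g] = float(sps.shapiro(v).pvalue)
    parametric = all(p > alpha for p in norm_p.values())
    arrays = [values[g] for g in groups]

    posthoc = None
    if parametric:
        if len(groups) == 2:
            res = sps.ttest_ind(*arrays)
            test = "t-test (unpaired)"
        else:
            res = sps.f_oneway(*arrays)
            test = "one-way ANOVA"
            tk = sps.tukey_hsd(*arrays)
            rows = []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    rows.append(
                        {
                            "group_a": groups[i],
                            "group_b": groups[j],
                            "statistic": float(tk.statistic[i, j]),
                            "p": float(tk.pvalue[i, j]),
                            "reject": bool(tk.pvalue[i, j] < alpha),
                        }
                    )
            posthoc = pd.DataFrame(rows)
    else:
        if len(groups) == 2:
            res = sps.mannwhitneyu(*arrays, alternative="two-sided")
            test = "Wilcoxon rank-sum"
        else:
            res = sps.kruskal(*arrays)
            test = "Kruskal-Wallis"

    return ComparisonReport(
        feature=feature,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        reject=bool(res.pvalue < alpha),
        parametric=parametric,
        normality_p=norm_p,
        groups=groups,
        posthoc=posthoc,
    )


def compare_fi(
    fi_table: pd.DataFrame,
    alpha: float = ALPHA,
    dv: str = "rate",
    within: str = "current",
    between: str = "group",
    subject: str = "cell_id",
) -> ComparisonReport:
    """Two-way mixed ANOVA for grouped f-I (or I/V) data with Sidak
    per-level contrasts.

    ``fi_table``: long-format DataFrame with one row per (cell, current):
    columns cell_id, group, current, rate.  Treatment is the
    between-subject factor, current level the within-subject factor.  The
    per-current contrast table applies Sidak-corrected unpaired t-tests at
    each current level (two groups) or one-way ANOVA (more).
    """
    import pingouin as pg

    req = {subject, between, within, dv}
    if not req.issubset(fi_table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    groups = [str(g) for g in fi_table[between].unique()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    aov = pg.mixed_anova(
        data=fi_table, dv=dv, within=within, between=between, subject=subject
    )
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    inter = aov[aov["Source"] == "Interaction"]
    main = aov[aov["Source"] == between]
    stat = float(main["F"].iloc[0])
    p_main = float(main[pcol].iloc[0])

    levels = sorted(fi_table[within].unique())
    m = len(levels)
    alpha_sidak = 1.0 - (1.0 - alpha) ** (1.0 / m)
    rows = []
    for lev in levels:
        sub = fi_table[fi_table[within] == lev]
        arrays = [sub.loc[sub[between] == g, dv].to_numpy(float) for g in groups]
        if len(groups) == 2:
            r = sps.ttest_ind(*arrays)
        else:
            r = sps.f_oneway(*arrays)
        rows.append(
            {
                within: lev,
                "statistic": float(r.statistic),
                "p": float(r.pvalue),
                "reject_sidak": bool(r.pvalue < alpha_sidak),
            }
        )
    posthoc = pd.DataFrame(rows)

    return ComparisonReport(
        feature=dv,
        test="two-way mixed ANOVA + Sidak per-level contrasts",
        statistic=stat,
        p_value=p_main,
        reject=bool(p_main < alpha),
        parametric=True,
        normality_p={},
        groups=groups,
        posthoc=posthoc,
        extra={
            "anova": aov,
            "interaction_p": float(inter[pcol].iloc[0]) if len(inter) else float("nan"),
            "alpha_sidak": alpha_sidak,
        },
    )
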