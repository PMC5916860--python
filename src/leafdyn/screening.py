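"""One-way ANOVA screening of dynamic characteristics.

Each dynamic characteristic is tested for separation across the four
nitrogen treatments, separately per leaf position and period: classical
equal-variance one-way ANOVA, F = MS_between / MS_within with
(k - 1, N - k) degrees of freedom.  Features with p below the screening
level (default 0.05) are flagged significant; within each leaf position and
period features are ranked by F.  No multiple-testing correction is applied
by default (the screen is exploratory); Benjamini-Hochberg is available as
a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import DYNAMIC_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    feature: str
    leaf_position: str
    period: str
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict
    flags: str = ""


def f_significance_boundary(df_between: int, df_within: int, alpha: float = 0.05) -> float:
    """Critical F value: the (1 - alpha) quantile of F(df_between, df_within)."""
    return float(stats.f.ppf(1.0 - alpha, df_between, df_within))


def one_way_anova(
    groups, feature: str = "", leaf_position: str = "", period: str = ""
) -> AnovaResult:
    """Classical one-way ANOVA over a list of per-group value lists.

    Missing values are dropped per group; groups left with fewer than two
    values are excluded (logged, df adjusted).  Degenerate inputs are
    resolved by convention: all values identical everywhere -> F = 0,
    p = 1; zero within-group variance with real between-group spread ->
    p = 0 with a ``zero_within_variance`` flag.
    """
    cleaned, flags = [], []
    for i, g in enumerate(groups):
        vals = np.asarray(pd.Series(g).dropna(), dtype=float)
        if vals.size >= 2:
            cleaned.append(vals)
        else:
            flags.append(f"group{i}_excluded")
            log.info("ANOVA group %d excluded (n=%d) for %s/%s/%s",
                     i, vals.size, feature, leaf_position, period)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups with >= 2 values each")

    k = len(cleaned)
    n_total = sum(v.size for v in cleaned)
    df_b, df_w = k - 1, n_total - k
    means = {i: float(v.mean()) for i, v in enumerate(cleaned)}

    allv = np.concatenate(cleaned)
    if np.ptp(allv) == 0:
        f_stat, p = 0.0, 1.0
    else:
        within = sum(((v - v.mean()) ** 2).sum() for v in cleaned)
        if within == 0:
            f_stat, p = np.inf, 0.0
            flags.append("zero_within_variance")
        else:
            f_stat, p = stats.f_oneway(*cleaned)
            f_stat, p = float(f_stat), float(p)
    return AnovaResult(feature, leaf_position, period, f_stat, p, df_b, df_w,
                       means, ";".join(flags))


def screen_features(
    dyn: pd.DataFrame, alpha: float = 0.05, bh_correct: bool = False
) -> pd.DataFrame:
    """ANOVA of every dynamic characteristic per leaf position x period.

    Returns a tidy table with F, p, dfs, significance flag and the
    within-(position, period) rank by descending F.  With ``bh_correct``
    the significance flag uses Benjamini-Hochberg adjusted p-values.
    """
    rows = []
    for (position, period), grp in dyn.groupby(["leaf_position", "period"], sort=True):
        for feat in DYNAMIC_COLUMNS:
            if feat not in grp.columns:
                continue
            groups = [sub[feat] for _, sub in grp.groupby("treatment", sort=True)]
            try:
                res = one_way_anova(groups, feat, position, period)
            except ValueError:
                continue
            rows.append({
                "feature": feat, "leaf_position": position, "period": period,
                "F": res.f_stat, "p": res.p_value,
                "df_between": res.df_between, "df_within": res.df_within,
                "flags": res.flags,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    p_for_sig = out["p"]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        p_for_sig = pd.Series(
            multipletests(out["p"].values, method="fdr_bh")[1], index=out.index
        )
    out["significant"] = p_for_sig < alpha
    out["rank"] = out.groupby(["leaf_position", "period"])["F"].rank(
        ascending=False, method="min"
    ).astype(int)
    return out.sort_values(
        ["leaf_position", "period", "rank"], kind="mergesort"
    ).reset_index(drop=True)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_grid(screened: pd.DataFrame) -> pd.DataFrame:
    """Wide F-value grid (rows = period x feature, columns = leaf positions)
    with significance stars, the layout used for reporting."""
    df = screened.copy()
    df["cell"] = df.apply(lambda r: f"{r['F']:.2f}{_stars(r['p'])}", axis=1)
    return df.pivot_table(
        index=["period", "feature"], columns="leaf_position", values="cell",
        aggfunc="first",
    )
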