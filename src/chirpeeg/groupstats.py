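"""Band-power group comparisons: per-region two-way ANOVA (group x band)
with Bonferroni-adjusted per-band post hoc contrasts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .synthgen import ValidationError


@dataclass
class AnovaResult:
    region: str
    table: pd.DataFrame             # F, df, p for group, band, interaction
    posthoc: pd.DataFrame           # per-band contrasts, Bonferroni-adjusted


def two_way_anova(tbl: pd.DataFrame, region: str,
                  value_col: str = "ratio") -> AnovaResult:
    """Fixed-effects two-way ANOVA on the subject x band table of one region.

    ``tbl`` is the tidy band-power table (subject, group, region, band,
    value/ratio).  Post hoc contrasts are per-band two-group Welch-free
    (classical) t tests with Bonferroni m = number of bands.
    """
    df = tbl[tbl["region"] == region].copy()
    if df.empty:
        raise ValidationError(f"no rows for region {region}")
    groups = sorted(df["group"].unique())
    bands = list(dict.fromkeys(df["band"]))
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    counts = df.groupby(["group", "band"])["subject"].count()
    for g in groups:
        for b in bands:
            if counts.get((g, b), 0) < 2:
                raise ValidationError(f"cell group={g}, band={b} has <2 subjects")

    df = df.rename(columns={value_col: "y"})
    model = ols("y ~ C(group) * C(band)", data=df).fit()
    aov = anova_lm(model, typ=2)
    table = pd.DataFrame({
        "effect": ["group", "band", "interaction"],
        "F": [aov.loc["C(group)", "F"], aov.loc["C(band)", "F"],
              aov.loc["C(group):C(band)", "F"]],
        "df_num": [aov.loc["C(group)", "df"], aov.loc["C(band)", "df"],
                   aov.loc["C(group):C(band)", "df"]],
        "df_den": [aov.loc["Residual", "df"]] * 3,
        "p": [aov.loc["C(group)", "PR(>F)"], aov.loc["C(band)", "PR(>F)"],
              aov.loc["C(group):C(band)", "PR(>F)"]],
    })

    m = len(bands) * (len(groups) * (len(groups) - 1) // 2)
    rows = []
    for b in bands:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                xa = df[(df["band"] == b) & (df["group"] == ga)]["y"]
                xb = df[(df["band"] == b) & (df["group"] == gb)]["y"]
                t, p = stats.ttest_ind(xa, xb)
                rows.append({
                    "band": b, "group_a": ga, "group_b": gb,
                    "mean_a": xa.mean(), "mean_b": xb.mean(),
                    "t": t, "p_raw": p, "p_bonferroni": min(1.0, m * p),
                })
    return AnovaResult(region=region, table=table, posthoc=pd.DataFrame(rows))
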