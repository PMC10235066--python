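"""Preferential-placement check on the year-2000 baseline carbon map.

If protected areas had been preferentially sited on carbon-rich land, their
year-2000 baseline carbon density would already exceed their counterfactuals'.
This stage computes per-PA mean paired baseline differences, contrasts PAs
designated in or after 2000 ("recent", expected difference ~0 under the
additionality hypothesis) with older PAs (whose pre-2000 protection has had
time to accrue carbon), and regresses the baseline difference on PA age.

The ordinary least-squares fit is implemented from the normal equations so the
stage is self-contained; only the t distribution comes from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FOREST_KEYWORD = "forest"


@dataclass
class AgeRegression:
    slope: float
    intercept: float
    p_value: float
    r: float
    n: int


def baseline_differences(pairs: pd.DataFrame, cells: pd.DataFrame,
                         pas: pd.DataFrame) -> pd.DataFrame:
    """Per-PA mean paired year-2000 baseline AGCD difference (PA - control).

    Adds PA age relative to the 2000 baseline (2000 - status year; negative
    for post-2000 designations), a recent/older group label, and a forest flag
    derived from the PA's biome name.  PAs lacking baseline data are dropped.
    """
    base = cells.set_index("cell_id")["baseline_agcd_2000"]
    d = (base.reindex(pairs["pa_cell_id"]).to_numpy(float)
         - base.reindex(pairs["control_cell_id"]).to_numpy(float))
    df = pairs.reset_index(drop=True).copy()
    df["baseline_diff"] = d
    df = df.loc[np.isfinite(d)]
    per_pa = df.groupby("pa_id", observed=True).agg(
        baseline_diff=("baseline_diff", "mean"),
        n_pairs=("pa_cell_id", "size")).reset_index()
    meta = pas.set_index("pa_id")
    per_pa["status_year"] = meta["status_yr"].reindex(per_pa["pa_id"]).to_numpy()
    per_pa["pa_age_years"] = 2000 - per_pa["status_year"]
    per_pa["group"] = np.where(per_pa["status_year"] >= 2000, "recent", "older")
    per_pa["forest_flag"] = (meta["biome"].reindex(per_pa["pa_id"])
                             .str.contains(FOREST_KEYWORD).to_numpy())
    return per_pa


def age_regression(records: pd.DataFrame) -> AgeRegression:
    """OLS of baseline_diff on pa_age_years with a t-test on the slope."""
    x = records["pa_age_years"].to_numpy(float)
    yv = records["baseline_diff"].to_numpy(float)
    n = len(x)
    if n < 3 or len(np.unique(x)) < 2:
        raise ValueError("need >= 3 records with at least two distinct ages")
    xm, ym = x.mean(), yv.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (yv - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = yv - (intercept + slope * x)
    dof = n - 2
    s2 = (resid ** 2).sum() / dof if dof > 0 else math.nan
    se_slope = math.sqrt(s2 / sxx)
    if se_slope == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        tstat = slope / se_slope
        p = 2.0 * stats.t.sf(abs(tstat), dof)
    syy = ((yv - ym) ** 2).sum()
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 0.0
    return AgeRegression(slope=float(slope), intercept=float(intercept),
                         p_value=float(p), r=float(r), n=n)


def baseline_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Group means (recent vs older, and by forest flag) plus regressions."""
    rows = []
    for group, g in records.groupby("group", observed=True):
        rows.append({"stratum": group, "mean_baseline_diff":
                     float(g["baseline_diff"].mean()), "n_pas": len(g)})
    for flag, g in records.groupby("forest_flag", observed=True):
        name = "forest" if flag else "non_forest"
        row = {"stratum": name,
               "mean_baseline_diff": float(g["baseline_diff"].mean()),
               "n_pas": len(g)}
        try:
            reg = age_regression(g)
            row.update(slope=reg.slope, p_value=reg.p_value, r=reg.r)
        except ValueError:
            pass
        rows.append(row)
    try:
        reg = age_regression(records)
        rows.append({"stratum": "all", "mean_baseline_diff":
                     float(records["baseline_diff"].mean()),
                     "n_pas": len(records), "slope": reg.slope,
                     "p_value": reg.p_value, "r": reg.r})
    except ValueError:
        pass
    return pd.DataFrame(rows)
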