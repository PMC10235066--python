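"""Carbon effect estimation: paired differences, totals, extrapolation, scales.

Per matched pair the carbon-density difference is d_i = AGCD(protected cell) -
AGCD(counterfactual cell).  Stratum means and paired-difference standard errors
(sd(d)/sqrt(n)) are computed per PA and per country x biome, expanded to
additional carbon totals by multiplying by non-overlapping PA area, and
aggregated to country / continent / biome / globe assuming independence across
strata (variances add).  PAs without usable pairs inherit the country x biome
mean difference, falling back to continent x biome, with provenance recorded.

The mean carbon stock of a PA uses a hybrid variance: the sampling variance of
the 1-km cell means plus a configurable relative model-error term standing in
for footprint biomass-model parameter error.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HA_PER_KM2 = 100.0
MG_PER_GT = 1e9

PROV_MATCHED = "matched"
PROV_COUNTRY_BIOME = "extrapolated_country_biome"
PROV_CONTINENT_BIOME = "extrapolated_continent_biome"
PROV_NONE = "no_estimate"


def dissolve_pa_area(pa_cells: Mapping[int, Iterable[int]]) -> pd.DataFrame:
    """Non-overlapping area per PA from cell-id sets (1 km^2 per cell).

    Overlapping protected areas are counted once: each cell is attributed to
    the lowest pa_id that contains it (stable order), so summed per-PA areas
    equal the dissolved union area.
    """
    seen: set[int] = set()
    rows = []
    for pid in sorted(pa_cells):
        cells = set(pa_cells[pid])
        own = cells - seen
        seen |= cells
        rows.append({"pa_id": pid, "area_km2": float(len(cells)),
                     "dissolved_area_km2": float(len(own))})
    return pd.DataFrame(rows)


def hybrid_mean_se(cell_means: np.ndarray,
                   model_rel_se: float = 0.02) -> tuple[float, float]:
    """Mean carbon density over 1-km cell means with hybrid standard error.

    variance = s^2/n  (sampling design over cell means)
             + (model_rel_se * mean)^2  (biomass-model parameter error).
    With fewer than two cells the SE is undefined (NaN) and the estimate is
    low-confidence.
    """
    v = np.asarray(cell_means, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return math.nan, math.nan
    mean = float(v.mean())
    if len(v) < 2:
        return mean, math.nan
    sampling_var = v.var(ddof=1) / len(v)
    model_var = (model_rel_se * mean) ** 2
    return mean, float(math.sqrt(sampling_var + model_var))


def paired_differences(pairs: pd.DataFrame, cell_metrics: pd.DataFrame,
                       cells: pd.DataFrame,
                       carbon_factor: float = 0.49) -> pd.DataFrame:
    """Per-pair table with carbon and structure differences plus stratum labels.

    Differences are protected minus counterfactual.  Carbon densities are
    derived from the aggregated cell AGBD means with the configured factor;
    stratum labels (country, continent, biome) come from the protected cell.
    """
    met = cell_metrics.set_index("cell_id")
    lab = cells.set_index("cell_id")
    t = met.loc[pairs["pa_cell_id"]]
    c = met.loc[pairs["control_cell_id"]]
    out = pairs.reset_index(drop=True).copy()
    out["agbd_pa"] = t["mean_agbd"].to_numpy()
    out["agbd_control"] = c["mean_agbd"].to_numpy()
    out["d_agbd"] = out["agbd_pa"] - out["agbd_control"]
    out["agcd_pa"] = carbon_factor * out["agbd_pa"]
    out["agcd_control"] = carbon_factor * out["agbd_control"]
    out["d_agcd"] = out["agcd_pa"] - out["agcd_control"]
    for m in ("rh98", "canopy_cover", "pai"):
        out[f"d_{m}"] = (t[f"mean_{m}"].to_numpy()
                         - c[f"mean_{m}"].to_numpy())
    for lab_col in ("country", "continent", "biome"):
        out[lab_col] = lab.loc[pairs["pa_cell_id"], lab_col].to_numpy()
    return out


def _paired_se(g: pd.DataFrame, cluster: str | None) -> float:
    """Paired-difference SE, cluster-robust (CR1) when ``cluster`` groups
    several pairs.

    Pairs inside one protected area share fine-scale biomass anomalies, so
    the iid SE understates the uncertainty; the CR1 sandwich over clusters
    corrects for that and reduces exactly to sd(d)/sqrt(n) when every pair is
    its own cluster (or no cluster column is given).
    """
    d = g["d_agcd"].to_numpy(float)
    n = len(d)
    if n < 2:
        return math.nan
    if cluster is None or cluster not in g.columns:
        return float(d.std(ddof=1) / math.sqrt(n))
    grp = g.groupby(cluster, observed=True)["d_agcd"]
    n_clusters = grp.ngroups
    if n_clusters < 2:
        return float(d.std(ddof=1) / math.sqrt(n))
    resid = grp.sum().to_numpy(float) - grp.size().to_numpy(float) * d.mean()
    return float(math.sqrt(n_clusters / (n_clusters - 1) * (resid ** 2).sum()) / n)


def stratum_difference(pair_diffs: pd.DataFrame,
                       by: list[str] | str,
                       cluster: str | None = "pa_id") -> pd.DataFrame:
    """Mean paired carbon difference and SE per stratum.

    ``by`` is a grouping key, e.g. ``'pa_id'`` or ``['country', 'biome']``.
    SE is the paired-difference standard error (PA-cluster-robust when pairs
    carry a ``pa_id``; plain sd(d)/sqrt(n) otherwise); NaN when a stratum has
    a single pair (flagged by ``low_confidence``).  Structure-metric mean
    differences ride along.
    """
    keys = [by] if isinstance(by, str) else list(by)
    if cluster in keys:
        cluster = None
    rows = []
    for key, g in pair_diffs.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        d = g["d_agcd"].to_numpy(float)
        n = len(d)
        rows.append({
            **dict(zip(keys, key)),
            "n_pairs": n,
            "mean_agcd_pa": float(g["agcd_pa"].mean()),
            "mean_agcd_control": float(g["agcd_control"].mean()),
            "mean_diff": float(d.mean()),
            "se_diff": _paired_se(g, cluster),
            "mean_d_agbd": float(g["d_agbd"].mean()),
            "mean_d_rh98": float(g["d_rh98"].mean()),
            "mean_d_canopy_cover": float(g["d_canopy_cover"].mean()),
            "mean_d_pai": float(g["d_pai"].mean()),
            "low_confidence": n < 2,
        })
    return pd.DataFrame(rows)


def expand_to_total(mean: float, se: float,
                    area_km2: float) -> tuple[float, float]:
    """Density (Mg C/ha) x area -> stock in Gt; the SE scales identically."""
    if area_km2 < 0:
        raise ValueError("area must be non-negative")
    scale = area_km2 * HA_PER_KM2 / MG_PER_GT
    return mean * scale, se * scale


def extrapolate_unmatched(pa: pd.Series, country_biome: pd.DataFrame,
                          continent_biome: pd.DataFrame
                          ) -> tuple[float, float, str]:
    """Stratum mean difference applicable to a PA's area.

    Applies the country x biome pair-pooled mean difference and SE when that
    stratum has an estimate, else the continent x biome stratum, else flags
    no-estimate; this is also the extrapolation rule for PAs without any own
    matched pairs.  ``country_biome`` / ``continent_biome`` are stratum tables
    indexed by (country, biome) and (continent, biome).  Returns
    ``(mean_diff, se_diff, provenance)``.
    """
    key_cb = (pa["country"], pa["biome"])
    key_nb = (pa["continent"], pa["biome"])
    if len(country_biome) and key_cb in country_biome.index and \
            int(country_biome.loc[key_cb, "n_pairs"]) >= 2:
        s = country_biome.loc[key_cb]
        return float(s["mean_diff"]), float(s["se_diff"]), PROV_COUNTRY_BIOME
    if len(continent_biome) and key_nb in continent_biome.index and \
            int(continent_biome.loc[key_nb, "n_pairs"]) >= 2:
        s = continent_biome.loc[key_nb]
        return float(s["mean_diff"]), float(s["se_diff"]), PROV_CONTINENT_BIOME
    return math.nan, math.nan, PROV_NONE


def pa_estimates(pair_diffs: pd.DataFrame, pas: pd.DataFrame,
                 areas: pd.DataFrame, cell_metrics: pd.DataFrame,
                 cells: pd.DataFrame, carbon_factor: float = 0.49,
                 model_rel_se: float = 0.02) -> pd.DataFrame:
    """Per-PA estimates with matched/extrapolated provenance.

    The additional-carbon density applied to every PA's area is the
    pair-pooled country x biome stratum mean difference (falling back to
    continent x biome when the country stratum has no pairs); a PA whose own
    cells contributed pairs is flagged ``matched``, one relying purely on its
    stratum is flagged extrapolated, and one with neither stratum available
    is flagged ``no_estimate`` and contributes area but no carbon totals.
    The per-PA own-pair mean rides along as ``own_mean_diff`` (used by the
    loss-attribution classes).  The PA's total carbon stock uses the hybrid
    mean/SE over its qualified cell carbon means and its dissolved area.
    """
    by_pa = (stratum_difference(pair_diffs, "pa_id")
             if len(pair_diffs) else pd.DataFrame(columns=["pa_id"]))
    by_cb = (stratum_difference(pair_diffs, ["country", "biome"])
             if len(pair_diffs) else pd.DataFrame(columns=["country", "biome"]))
    by_nb = (stratum_difference(pair_diffs, ["continent", "biome"])
             if len(pair_diffs) else pd.DataFrame(columns=["continent", "biome"]))
    by_pa = by_pa.set_index("pa_id") if len(by_pa) else by_pa
    cb_idx = by_cb.set_index(["country", "biome"]) if len(by_cb) else by_cb
    nb_idx = by_nb.set_index(["continent", "biome"]) if len(by_nb) else by_nb

    met = cell_metrics.set_index("cell_id")
    cell_pa = cells.loc[cells["pa_id"].notna()]
    rows = []
    for _, pa in pas.iterrows():
        pid = pa["pa_id"]
        area = float(areas.set_index("pa_id").loc[pid, "dissolved_area_km2"])
        own_cells = cell_pa.loc[cell_pa["pa_id"] == pid, "cell_id"]
        agcd_cells = carbon_factor * met.loc[met.index.isin(own_cells),
                                             "mean_agbd"].dropna().to_numpy()
        stock_mean, stock_se = hybrid_mean_se(agcd_cells, model_rel_se)

        n_pairs = 0
        own_diff = math.nan
        if pid in getattr(by_pa, "index", []):
            est = by_pa.loc[pid]
            n_pairs = int(est["n_pairs"])
            own_diff = float(est["mean_diff"])
        # the additional-carbon density applied to the PA area is always the
        # pair-pooled stratum mean (matched pixels aggregated per country x
        # biome); a per-PA own mean over a handful of pairs would be noisy
        # and selection-prone
        mean_diff, se_diff, stratum_prov = extrapolate_unmatched(
            pa, cb_idx, nb_idx)
        if stratum_prov == PROV_NONE:
            provenance = PROV_NONE
            stratum_key = ""
        else:
            provenance = PROV_MATCHED if n_pairs >= 1 else stratum_prov
            stratum_key = (f"{pa['country']}|{pa['biome']}"
                           if stratum_prov == PROV_COUNTRY_BIOME
                           else f"{pa['continent']}|{pa['biome']}")

        if provenance == PROV_NONE or not math.isfinite(mean_diff):
            add_gt = se_add_gt = math.nan
        else:
            add_gt, se_add_gt = expand_to_total(mean_diff, se_diff, area)
        if math.isfinite(stock_mean) and math.isfinite(stock_se):
            tot_gt, se_tot_gt = expand_to_total(stock_mean, stock_se, area)
        else:
            tot_gt = se_tot_gt = math.nan
        rows.append({
            "pa_id": pid, "country": pa["country"],
            "continent": pa["continent"], "biome": pa["biome"],
            "n_pairs": n_pairs, "area_km2": area,
            "mean_diff": mean_diff, "se_diff": se_diff,
            "own_mean_diff": own_diff,
            "stratum_key": stratum_key,
            "additional_agc_gt": add_gt, "se_additional_agc_gt": se_add_gt,
            "total_agc_gt": tot_gt, "se_total_agc_gt": se_tot_gt,
            "provenance": provenance,
        })
    out = pd.DataFrame(rows)
    n_extrap = (out["provenance"].isin([PROV_COUNTRY_BIOME,
                                        PROV_CONTINENT_BIOME])).sum()
    logger.info("PA estimates: %d matched, %d extrapolated, %d without estimate",
                int((out["provenance"] == PROV_MATCHED).sum()), int(n_extrap),
                int((out["provenance"] == PROV_NONE).sum()))
    return out


def aggregate(pa_table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Aggregate per-PA estimates to country/continent/biome/globe.

    Totals are sums over PAs with an estimate; SEs combine in quadrature
    (independence across strata); areas are dissolved sums over all PAs.
    """
    if level not in ("country", "continent", "biome", "globe"):
        raise ValueError(f"unknown aggregation level {level!r}")
    t = pa_table.copy()
    key = "_globe" if level == "globe" else level
    if level == "globe":
        t[key] = "globe"
    rows = []
    for name, g in t.groupby(key, observed=True):
        ok = g.loc[g["additional_agc_gt"].notna()]
        # PAs sharing a stratum estimate are perfectly correlated: their SEs
        # add linearly within the stratum, then in quadrature across strata
        se_by_stratum = (ok.groupby("stratum_key", observed=True)
                         ["se_additional_agc_gt"].sum().to_numpy(float))
        stock_ok = g.loc[g["total_agc_gt"].notna()]
        stock_se = stock_ok["se_total_agc_gt"].fillna(0.0).to_numpy(float)
        rows.append({
            level if level != "globe" else "scope": name,
            "n_pas": len(g),
            "n_pas_estimated": len(ok),
            "area_km2": float(g["area_km2"].sum()),
            "additional_agc_gt": float(ok["additional_agc_gt"].sum()),
            "se_additional_agc_gt": float(np.sqrt(np.nansum(se_by_stratum ** 2))),
            "total_agc_gt": float(stock_ok["total_agc_gt"].sum()),
            "se_total_agc_gt": float(np.sqrt((stock_se ** 2).sum())),
        })
    return pd.DataFrame(rows)
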