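"""Forest-loss attribution: five effectiveness classes per protected area.

Each matched PA is classified from its biomass difference against the matched
counterfactual and the 2000-2019 forest-cover-loss fractions on both sides:

* diff > +5 Mg/ha and more loss outside      -> avoided_deforestation
* diff > +5 Mg/ha, no higher loss outside    -> enhanced_stocks
  (avoided degradation and/or enhanced growth; optical loss data saturate and
  miss subtle degradation)
* |diff| <= 2.5 Mg/ha                        -> no_additionality
* diff < -2.5 Mg/ha and more loss inside     -> encroachment
* diff < -2.5 Mg/ha otherwise                -> degradation

Differences in the open band (2.5, 5] Mg/ha take the positive branch with
``gap_band_flag`` set, keeping both thresholds explicit and configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASSES = ("avoided_deforestation", "enhanced_stocks", "no_additionality",
           "encroachment", "degradation")


@dataclass
class EffectivenessRecord:
    pa_id: int
    diff_agbd: float
    loss_pa: float
    loss_control: float
    effect_class: str
    gap_band_flag: bool


def loss_fractions(pairs: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Mean loss fraction over each PA's matched cells and their controls.

    Cells are equal-area (1 km^2) so the area-weighted mean is the plain mean.
    PAs whose cells lack loss data are excluded and logged.
    """
    loss = cells.set_index("cell_id")["loss_fraction"]
    t = loss.reindex(pairs["pa_cell_id"]).to_numpy(float)
    c = loss.reindex(pairs["control_cell_id"]).to_numpy(float)
    df = pairs.reset_index(drop=True).copy()
    df["loss_pa_cell"] = t
    df["loss_control_cell"] = c
    missing = df["loss_pa_cell"].isna() | df["loss_control_cell"].isna()
    if missing.any():
        bad = df.loc[missing, "pa_id"].unique()
        logger.warning("excluding %d pairs lacking loss data (PAs %s)",
                       int(missing.sum()), bad[:5])
        df = df.loc[~missing]
    out = df.groupby("pa_id", observed=True).agg(
        loss_pa=("loss_pa_cell", "mean"),
        loss_control=("loss_control_cell", "mean"),
        n_pairs=("pa_cell_id", "size")).reset_index()
    return out


def classify_pa(diff_agbd: float, loss_pa: float, loss_control: float,
                pos_threshold: float = 5.0,
                zero_halfwidth: float = 2.5) -> EffectivenessRecord:
    """Classify one PA; see the module docstring for the decision rule."""
    for v in (diff_agbd, loss_pa, loss_control):
        if not np.isfinite(v):
            raise ValueError("classification inputs must be finite")
    gap_band = False
    if abs(diff_agbd) <= zero_halfwidth:
        cls = "no_additionality"
    elif diff_agbd > zero_halfwidth:
        gap_band = diff_agbd <= pos_threshold
        cls = ("avoided_deforestation" if loss_control > loss_pa
               else "enhanced_stocks")
    else:
        cls = "encroachment" if loss_pa > loss_control else "degradation"
    return EffectivenessRecord(pa_id=-1, diff_agbd=float(diff_agbd),
                               loss_pa=float(loss_pa),
                               loss_control=float(loss_control),
                               effect_class=cls, gap_band_flag=gap_band)


def classify_all(pa_table: pd.DataFrame, losses: pd.DataFrame,
                 pos_threshold: float = 5.0,
                 zero_halfwidth: float = 2.5) -> pd.DataFrame:
    """Classification table over matched PAs with loss data.

    ``pa_table`` must carry per-PA ``mean_d_agbd``-style biomass differences
    (column ``mean_d_agbd``), as produced by the estimation stage for matched
    PAs; extrapolated PAs have no own pairs and are not classified.
    """
    merged = pa_table.merge(losses, on="pa_id", how="inner")
    rows = []
    for _, r in merged.iterrows():
        rec = classify_pa(r["mean_d_agbd"], r["loss_pa"], r["loss_control"],
                          pos_threshold, zero_halfwidth)
        rows.append({"pa_id": r["pa_id"], "continent": r.get("continent"),
                     "diff_agbd": rec.diff_agbd, "loss_pa": rec.loss_pa,
                     "loss_control": rec.loss_control,
                     "effect_class": rec.effect_class,
                     "gap_band_flag": rec.gap_band_flag})
    return pd.DataFrame(rows, columns=["pa_id", "continent", "diff_agbd",
                                       "loss_pa", "loss_control",
                                       "effect_class", "gap_band_flag"])


def class_shares(records: pd.DataFrame,
                 level: str | None = None) -> pd.DataFrame:
    """Fraction of classified PAs per effectiveness class (optionally per
    group, e.g. ``level='continent'``); shares sum to 1 within each group."""
    if records.empty:
        return pd.DataFrame(columns=["group", "effect_class", "share"])
    if level is None:
        counts = records["effect_class"].value_counts()
        total = counts.sum()
        return pd.DataFrame([{"group": "globe", "effect_class": c,
                              "share": counts.get(c, 0) / total}
                             for c in CLASSES])
    rows = []
    for name, g in records.groupby(level, observed=True):
        counts = g["effect_class"].value_counts()
        total = counts.sum()
        for c in CLASSES:
            rows.append({"group": name, "effect_class": c,
                         "share": counts.get(c, 0) / total})
    return pd.DataFrame(rows)
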