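"""Footprint quality filtering, biomass-to-carbon conversion, 1-km aggregation.

Shots are retained when the waveform quality flag is set and the sensitivity
metric (maximum canopy cover through which ground is detectable) is at least
the threshold.  Surviving shots are averaged per 1-km cell; cells with fewer
than ``min_shots`` passing shots are flagged unqualified and excluded from
matching so that every matched cell mean rests on a minimum sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CARBON_FACTOR = 0.49  # global average dry woody biomass -> carbon conversion

_REQUIRED_QUALITY_FIELDS = ("quality_flag", "sensitivity")
_METRICS = ("rh98", "canopy_cover", "pai", "agbd")


def filter_footprints(shots: pd.DataFrame,
                      sensitivity_threshold: float = 0.95) -> pd.DataFrame:
    """Return the shots passing quality_flag == 1 and sensitivity >= threshold.

    Order-preserving; the input frame is not modified.  The sensitivity bound
    is inclusive ("at least").
    """
    missing = [f for f in _REQUIRED_QUALITY_FIELDS if f not in shots.columns]
    if missing:
        raise ValueError(f"footprint table missing quality fields: {missing}")
    mask = (shots["quality_flag"] == 1) & (shots["sensitivity"] >= sensitivity_threshold)
    out = shots.loc[mask].copy()
    logger.info("quality filter kept %d / %d shots", len(out), len(shots))
    return out


def agbd_to_agcd(agbd, factor: float = CARBON_FACTOR):
    """Convert aboveground biomass density (Mg/ha) to carbon density (Mg C/ha).

    Linear with constant ratio ``factor`` (default 0.49); applies elementwise
    to arrays/Series.  Negative biomass is a domain error.
    """
    arr = np.asarray(agbd, dtype=float)
    if np.any(arr < 0):
        raise ValueError("AGBD must be non-negative")
    out = factor * arr
    if isinstance(agbd, pd.Series):
        return pd.Series(out, index=agbd.index, name="agcd")
    if np.isscalar(agbd):
        return float(out)
    return out


def aggregate_to_cells(shots: pd.DataFrame, cells: pd.DataFrame,
                       min_shots: int = 5,
                       carbon_factor: float = CARBON_FACTOR) -> pd.DataFrame:
    """Aggregate quality-filtered shots to per-cell means.

    Returns one row per cell of ``cells`` with mean structure metrics computed
    over passing shots, ``n_shots_pass`` counts, and a ``qualified`` flag true
    when the cell reaches ``min_shots``.  Means of unqualified cells are NaN.

    Raises
    ------
    ValueError
        If any shot references a cell_id absent from ``cells`` (offenders
        listed).
    """
    known = pd.Index(cells["cell_id"])
    unknown = shots.loc[~shots["cell_id"].isin(known), "cell_id"].unique()
    if len(unknown):
        raise ValueError(f"shots reference unknown cell_ids: {sorted(unknown)[:10]}")

    grouped = shots.groupby("cell_id")
    agg = grouped[list(_METRICS)].mean()
    agg.columns = [f"mean_{m}" for m in _METRICS]
    agg["n_shots_pass"] = grouped.size()
    agg = agg.reindex(known)
    agg["n_shots_pass"] = agg["n_shots_pass"].fillna(0).astype(int)
    agg["mean_agcd"] = agbd_to_agcd(agg["mean_agbd"].fillna(0.0),
                                    carbon_factor).where(agg["mean_agbd"].notna())
    agg["qualified"] = agg["n_shots_pass"] >= min_shots
    agg.loc[~agg["qualified"], [c for c in agg.columns
                                if c.startswith("mean_")]] = np.nan
    out = agg.reset_index().rename(columns={"index": "cell_id"})
    logger.info("aggregated %d shots into %d cells (%d qualified at >=%d shots)",
                len(shots), len(out), int(out["qualified"].sum()), min_shots)
    return out
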