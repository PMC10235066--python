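"""Derived shares and ranking arithmetic on carbon totals.

Percentages are printed at different precisions in different summary contexts;
both rounding modes are explicit functions rather than formatting side
effects: nearest-integer rounding (e.g. the share of terrestrial carbon held
in protected areas) and one-decimal truncation (e.g. a country's share of the
global additionality signal, where 36.68...% prints as 36.6%).
"""

from __future__ import annotations

import math

import pandas as pd


def percent_nearest_int(numerator: float, denominator: float) -> int:
    """100 * num/den rounded to the nearest integer."""
    if denominator == 0:
        raise ZeroDivisionError("share denominator is zero")
    return int(round(100.0 * numerator / denominator))


def percent_one_decimal_trunc(numerator: float, denominator: float) -> float:
    """100 * num/den truncated (floored toward zero) to one decimal place."""
    if denominator == 0:
        raise ZeroDivisionError("share denominator is zero")
    pct = 100.0 * numerator / denominator
    return math.trunc(pct * 10.0) / 10.0


def derived_shares(country_totals: pd.DataFrame,
                   pa_total_agc_gt: float,
                   terrestrial_agc_gt: float,
                   global_additional_gt: float | None = None,
                   top_n: int = 20) -> dict:
    """Share table from carbon totals (computed or hand-entered printed values).

    ``country_totals`` needs columns ``country``, ``additional_agc_gt`` and
    optionally ``total_agc_gt`` / ``national_agc_gt`` for protected-share
    columns.  Returns the protected share of total carbon (integer percent),
    each country's share of the global additionality signal (one-decimal
    truncation), and the top-``top_n`` ranking.
    """
    out: dict = {
        "pa_share_of_total_agc_pct": percent_nearest_int(
            pa_total_agc_gt, terrestrial_agc_gt),
    }
    t = country_totals.copy()
    global_add = (global_additional_gt if global_additional_gt is not None
                  else float(t["additional_agc_gt"].sum()))
    if global_add == 0:
        t["share_of_global_signal_pct"] = float("nan")
    else:
        t["share_of_global_signal_pct"] = [
            percent_one_decimal_trunc(v, global_add)
            for v in t["additional_agc_gt"]]
    if {"total_agc_gt", "national_agc_gt"} <= set(t.columns):
        t["protected_share_pct"] = [
            percent_nearest_int(p, n) if n else None
            for p, n in zip(t["total_agc_gt"], t["national_agc_gt"])]
    ranked = t.sort_values("additional_agc_gt", ascending=False)
    out["country_shares"] = t
    out["top_countries"] = ranked.head(top_n).reset_index(drop=True)
    out["global_additional_gt"] = global_add
    return out
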