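"""Counterfactual matching: control pool, propensity model, caliper, pairing.

Each protected 1-km cell is paired with one unprotected cell that (a) shares
its land-cover class, country, ecoregion and biome exactly, (b) lies outside a
buffer around every protected area (to avoid mixed pixels and spillover), and
(c) has the nearest propensity score within a caliper and the common-support
range.  Matching is 1:1 without replacement and fully deterministic: treated
cells are processed in descending score order and score-gap ties break on the
lowest control cell_id.

The propensity model is a maximum-likelihood logistic regression of the
protection indicator on z-scored quantitative covariates, fitted by iteratively
reweighted least squares (IRLS) with a ridge fallback under perfect separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import QUANT_COVARIATES, STRATUM_COVARIATES

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# control pool
# --------------------------------------------------------------------------- #

def distance_to_pa_boundary(cells: pd.DataFrame) -> np.ndarray:
    """Euclidean distance (km) from each cell centre to the nearest PA edge.

    Computed on the grid with a Euclidean distance transform of the protection
    mask; centre-to-centre distance minus half a cell approximates
    centre-to-boundary distance on the 1-km lattice.  Protected cells get 0.
    """
    nr = int(cells["row"].max()) + 1
    nc = int(cells["col"].max()) + 1
    mask = np.ones((nr, nc), dtype=bool)
    prot = cells.loc[cells["is_protected"]]
    mask[prot["row"].to_numpy(), prot["col"].to_numpy()] = False
    edt = ndimage.distance_transform_edt(mask)
    dist = np.clip(edt - 0.5, 0.0, None)
    return dist[cells["row"].to_numpy(), cells["col"].to_numpy()]


def build_control_pool(cells: pd.DataFrame, cell_metrics: pd.DataFrame,
                       buffer_km: float = 10.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split cells into the treated set and the eligible control pool.

    Treated: protected, entirely within one PA (true by construction on the
    cell-aligned grid), with a qualified cell mean.  Controls: unprotected,
    qualified, and farther than ``buffer_km`` from every PA boundary.  Returns
    ``(treated, controls)``, both joined with the cell metrics; the returned
    frames carry an ``in_buffer`` column on the control side of the split.
    """
    merged = cells.merge(cell_metrics, on="cell_id", how="left")
    merged["qualified"] = merged["qualified"].fillna(False).astype(bool)
    dist = distance_to_pa_boundary(cells)
    merged["in_buffer"] = (~merged["is_protected"]) & (dist <= buffer_km)

    treated = merged.loc[merged["is_protected"] & merged["qualified"]].copy()
    controls = merged.loc[(~merged["is_protected"]) & (~merged["in_buffer"])
                          & merged["qualified"]].copy()
    logger.info("control pool: %d treated, %d eligible controls "
                "(buffer %.1f km excluded %d unprotected cells)",
                len(treated), len(controls), buffer_km,
                int(merged["in_buffer"].sum()))
    return treated, controls


# --------------------------------------------------------------------------- #
# propensity model
# --------------------------------------------------------------------------- #

@dataclass
class PropensityModel:
    """Fitted logistic model of protection on standardised covariates.

    Exactly-matched categoricals enter as dummy terms (``categoricals`` with
    the reference levels in ``cat_levels``): they are balanced within pairs by
    construction, but leaving them out would distort the quantitative
    coefficients whenever protection priority differs by class.
    """

    covariates: list[str]
    coef: np.ndarray          # intercept first, then z-covariates, then dummies
    means: np.ndarray
    sds: np.ndarray
    converged: bool
    ridge_fallback: bool
    n_iter: int
    categoricals: list[str] = field(default_factory=list)
    cat_levels: dict = field(default_factory=dict)
    score_range_treated: tuple[float, float] = field(default=(0.0, 1.0))
    score_range_control: tuple[float, float] = field(default=(0.0, 1.0))

    def design(self, df: pd.DataFrame) -> np.ndarray:
        z = (df[self.covariates].to_numpy(dtype=float) - self.means) / self.sds
        cols = [np.ones(len(df)), z]
        for cat in self.categoricals:
            for lev in self.cat_levels[cat][1:]:  # first level is reference
                cols.append((df[cat].to_numpy() == lev).astype(float)[:, None])
        return np.column_stack(cols)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Propensity scores in (0, 1)."""
        eta = self.design(df) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def _irls(X: np.ndarray, yv: np.ndarray, ridge: float, tol: float,
          max_iter: int) -> tuple[np.ndarray, bool, int]:
    beta = np.zeros(X.shape[1])
    pen = ridge * np.eye(X.shape[1])
    pen[0, 0] = 0.0  # intercept unpenalised
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (yv - mu) - pen @ beta
        hess = (X * w[:, None]).T @ X + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True, it
    return beta, False, max_iter


def fit_propensity(treated: pd.DataFrame, controls: pd.DataFrame,
                   covariates: list[str] | None = None,
                   categoricals: list[str] | None = None,
                   tol: float = 1e-8, max_iter: int = 100,
                   ridge_on_separation: float = 1e-4) -> PropensityModel:
    """Fit the protection propensity model by IRLS.

    Quantitative covariates are z-scored on the pooled sample for numerical
    stability; the exactly-matched categoricals enter as dummies by default
    (pass ``categoricals=[]`` for a quantitative-only score).  If the
    unpenalised fit fails to converge or diverges (the perfect separation
    signature: unbounded coefficients), refits with a small ridge penalty and
    logs a warning.
    """
    if len(treated) == 0 or len(controls) == 0:
        raise ValueError("both treated and control groups must be non-empty")
    covariates = list(covariates or QUANT_COVARIATES)
    if categoricals is None:
        categoricals = [c for c in STRATUM_COVARIATES
                        if c in treated.columns and c in controls.columns]
    pooled = pd.concat([treated, controls], ignore_index=True)
    Xraw = pooled[covariates].to_numpy(dtype=float)
    if not np.all(np.isfinite(Xraw)):
        raise ValueError("quantitative covariates must be finite")
    means = Xraw.mean(axis=0)
    sds = Xraw.std(axis=0)
    sds[sds == 0] = 1.0
    cat_levels = {c: sorted(pooled[c].unique().tolist()) for c in categoricals}
    cols = [np.ones(len(pooled)), (Xraw - means) / sds]
    for cat in categoricals:
        for lev in cat_levels[cat][1:]:
            cols.append((pooled[cat].to_numpy() == lev).astype(float)[:, None])
    X = np.column_stack(cols)
    yv = np.concatenate([np.ones(len(treated)), np.zeros(len(controls))])

    ridge_used = False
    try:
        beta, converged, n_iter = _irls(X, yv, 0.0, tol, max_iter)
        if not converged or np.max(np.abs(beta)) > 1e3:
            raise np.linalg.LinAlgError("non-convergence / separation")
    except np.linalg.LinAlgError:
        logger.warning("propensity fit unstable (possible perfect separation); "
                       "refitting with ridge penalty %g", ridge_on_separation)
        beta, converged, n_iter = _irls(X, yv, ridge_on_separation, tol, max_iter)
        ridge_used = True

    model = PropensityModel(covariates=covariates, coef=beta, means=means,
                            sds=sds, converged=converged,
                            ridge_fallback=ridge_used, n_iter=n_iter,
                            categoricals=categoricals, cat_levels=cat_levels)
    st = model.predict(treated)
    sc = model.predict(controls)
    model.score_range_treated = (float(st.min()), float(st.max()))
    model.score_range_control = (float(sc.min()), float(sc.max()))
    return model


# --------------------------------------------------------------------------- #
# caliper and common support
# --------------------------------------------------------------------------- #

def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


@dataclass
class Caliper:
    """Common-support interval (probability scale) plus a score-distance
    caliper ``width`` on the logit scale, matching the 0.2-SD-of-logit rule."""

    support_lo: float
    support_hi: float
    width: float

    @property
    def empty_support(self) -> bool:
        return self.support_lo > self.support_hi

    def in_support(self, scores: np.ndarray) -> np.ndarray:
        return (scores >= self.support_lo) & (scores <= self.support_hi)


def set_caliper(model: PropensityModel, treated: pd.DataFrame,
                controls: pd.DataFrame, factor: float = 0.2) -> Caliper:
    """Common support = overlap of the treated and control score ranges;
    caliper width = ``factor`` x SD of the pooled logit scores (0.2 default).
    """
    lo = max(model.score_range_treated[0], model.score_range_control[0])
    hi = min(model.score_range_treated[1], model.score_range_control[1])
    scores = np.concatenate([model.predict(treated), model.predict(controls)])
    scores = np.clip(scores, 1e-12, 1 - 1e-12)
    width = factor * float(np.std(np.log(scores / (1 - scores))))
    cal = Caliper(support_lo=lo, support_hi=hi, width=width)
    if cal.empty_support:
        logger.warning("empty common support [%.3f, %.3f]: nothing can match",
                       lo, hi)
    return cal


# --------------------------------------------------------------------------- #
# greedy 1:1 matching without replacement
# --------------------------------------------------------------------------- #

def match(treated: pd.DataFrame, controls: pd.DataFrame,
          model: PropensityModel, caliper: Caliper,
          rule: str = "nearest") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair each treated cell with one control within its exact stratum.

    Within every stratum (land cover x country x ecoregion x biome), treated
    cells are visited in descending propensity order; each takes the eligible
    control with the smallest |score gap| within the caliper (``rule='nearest'``)
    or the eligible control with the highest score (``rule='max_score'``),
    and that control leaves the pool.  Score gaps are measured on the logit
    scale, the scale the default caliper width is defined on; ``abs_score_gap``
    in the returned pair table is that logit-scale gap.
    Returns ``(pairs, unmatched_treated)``.
    """
    if rule not in ("nearest", "max_score"):
        raise ValueError(f"unknown match rule {rule!r}")
    t = treated.copy()
    c = controls.copy()
    t["score"] = model.predict(t)
    c["score"] = model.predict(c)
    t["logit"] = _logit(t["score"].to_numpy())
    c["logit"] = _logit(c["score"].to_numpy())
    t_ok = t.loc[caliper.in_support(t["score"].to_numpy())]
    c_ok = c.loc[caliper.in_support(c["score"].to_numpy())]

    pair_rows, unmatched_ids = [], list(t.loc[~t["cell_id"].isin(t_ok["cell_id"]),
                                              "cell_id"])
    ctrl_groups = dict(tuple(c_ok.groupby(list(STRATUM_COVARIATES), observed=True)))
    for key, tgroup in t_ok.groupby(list(STRATUM_COVARIATES), observed=True):
        cgroup = ctrl_groups.get(key)
        if cgroup is None or cgroup.empty:
            unmatched_ids.extend(tgroup["cell_id"])
            continue
        # deterministic: sort controls by (cell_id) once; track availability
        c_ids = cgroup["cell_id"].to_numpy()
        c_scores = cgroup["score"].to_numpy()
        c_logits = cgroup["logit"].to_numpy()
        order = np.argsort(c_ids)
        c_ids, c_scores, c_logits = c_ids[order], c_scores[order], c_logits[order]
        free = np.ones(len(c_ids), dtype=bool)

        tsorted = tgroup.sort_values(["score", "cell_id"],
                                     ascending=[False, True])
        for _, trow in tsorted.iterrows():
            gaps = np.abs(c_logits - trow["logit"])
            elig = free & (gaps <= caliper.width)
            if not elig.any():
                unmatched_ids.append(trow["cell_id"])
                continue
            idx_e = np.flatnonzero(elig)
            if rule == "nearest":
                # min gap; ties resolved to lowest cell_id via stable ordering
                best = idx_e[np.argmin(gaps[idx_e])]
            else:  # max_score
                best = idx_e[np.argmax(c_scores[idx_e])]
            free[best] = False
            pair_rows.append({
                "pa_cell_id": int(trow["cell_id"]),
                "control_cell_id": int(c_ids[best]),
                "score_pa": float(trow["score"]),
                "score_control": float(c_scores[best]),
                "abs_score_gap": float(gaps[best]),
                "pa_id": trow.get("pa_id", np.nan),
            })
    pairs = pd.DataFrame(pair_rows, columns=["pa_cell_id", "control_cell_id",
                                             "score_pa", "score_control",
                                             "abs_score_gap", "pa_id"])
    unmatched = t.loc[t["cell_id"].isin(unmatched_ids)].copy()
    logger.info("matched %d / %d treated cells (%d unmatched)",
                len(pairs), len(t), len(unmatched))
    return pairs, unmatched


# --------------------------------------------------------------------------- #
# balance diagnostics
# --------------------------------------------------------------------------- #

def standardized_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """SMD = (mean_a - mean_b) / sqrt((var_a + var_b) / 2); 0 if both constant."""
    va, vb = np.var(a, ddof=1) if len(a) > 1 else 0.0, \
        np.var(b, ddof=1) if len(b) > 1 else 0.0
    denom = np.sqrt((va + vb) / 2.0)
    if denom == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / denom)


def balance_report(pairs: pd.DataFrame, treated: pd.DataFrame,
                   controls: pd.DataFrame,
                   covariates: list[str] | None = None) -> pd.DataFrame:
    """Covariate SMDs before (treated vs pool) and after (paired sets) matching,
    plus propensity-score summaries where a score column is present."""
    covariates = list(covariates or QUANT_COVARIATES)
    t_matched = treated.set_index("cell_id").loc[pairs["pa_cell_id"]]
    c_matched = controls.set_index("cell_id").loc[pairs["control_cell_id"]]
    rows = []
    for cov in covariates:
        rows.append({
            "covariate": cov,
            "smd_before": standardized_mean_difference(
                treated[cov].to_numpy(float), controls[cov].to_numpy(float)),
            "smd_after": standardized_mean_difference(
                t_matched[cov].to_numpy(float), c_matched[cov].to_numpy(float)),
        })
    return pd.DataFrame(rows)
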