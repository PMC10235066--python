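"""Control pool, propensity fit (vs independent oracle), caliper, matching."""

import numpy as np
import pandas as pd
import pytest

from pacarbon.matching import (Caliper, PropensityModel, _logit,
                               balance_report, build_control_pool,
                               fit_propensity, match, set_caliper,
                               standardized_mean_difference)
from pacarbon.footprints import aggregate_to_cells, filter_footprints
from pacarbon.synthetic import QUANT_COVARIATES

from conftest import small_config
from pacarbon.synthetic import generate_landscape, sample_footprints


def _score_model():
    """Identity-link stub: predict(df) = sigmoid(df['elevation'])."""
    return PropensityModel(covariates=["elevation"], coef=np.array([0.0, 1.0]),
                           means=np.array([0.0]), sds=np.array([1.0]),
                           converged=True, ridge_fallback=False, n_iter=1)


def cells_from_scores(scores, **fields):
    df = pd.DataFrame({"cell_id": np.arange(len(scores)),
                       "elevation": _logit(np.asarray(scores, float))})
    for k, v in fields.items():
        df[k] = v
    for cat in ("land_cover", "country", "ecoregion", "biome"):
        if cat not in df.columns:
            df[cat] = "A"
    return df


class TestControlPool:
    def make_world(self):
        # 1-D strip of 40 cells; PA covers cols 10..12
        n = 40
        cells = pd.DataFrame({
            "cell_id": np.arange(n), "row": 0, "col": np.arange(n),
            "x": np.arange(n) + 0.5, "y": 0.5,
            "is_protected": [(10 <= c <= 12) for c in range(n)],
            "pa_id": [0 if 10 <= c <= 12 else np.nan for c in range(n)],
        })
        metrics = pd.DataFrame({"cell_id": np.arange(n),
                                "qualified": True, "mean_agbd": 100.0})
        return cells, metrics

    def test_buffer_excludes_nearby_and_keeps_distant(self):
        cells, metrics = self.make_world()
        treated, controls = build_control_pool(cells, metrics, buffer_km=10)
        ids = set(controls["cell_id"])
        assert 17 not in ids          # ~5 km from the PA edge -> excluded
        assert 30 in ids              # >15 km from the PA -> eligible
        assert set(treated["cell_id"]) == {10, 11, 12}

    def test_unqualified_cells_excluded_everywhere(self):
        cells, metrics = self.make_world()
        metrics.loc[metrics["cell_id"].isin([11, 30]), "qualified"] = False
        treated, controls = build_control_pool(cells, metrics, buffer_km=10)
        assert 11 not in set(treated["cell_id"])
        assert 30 not in set(controls["cell_id"])


class TestPropensityFit:
    def test_symmetric_groups_score_half(self):
        # identically distributed groups of equal size: scores hover around
        # 0.5, with only ML sampling noise (no systematic tilt)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2000, len(QUANT_COVARIATES)))
        cols = dict(zip(QUANT_COVARIATES, x.T))
        treated = pd.DataFrame({"cell_id": np.arange(1000), **{
            k: v[:1000] for k, v in cols.items()}})
        controls = pd.DataFrame({"cell_id": np.arange(1000, 2000), **{
            k: v[1000:] for k, v in cols.items()}})
        model = fit_propensity(treated, controls, categoricals=[])
        scores = np.r_[model.predict(treated), model.predict(controls)]
        assert abs(scores.mean() - 0.5) < 0.005
        assert np.abs(scores - 0.5).max() < 0.15
        assert abs(model.predict(treated).mean()
                   - model.predict(controls).mean()) < 0.02

    def test_score_monotone_in_strong_covariate(self):
        rng = np.random.default_rng(1)
        n = 800
        x = rng.normal(size=n)
        y = rng.random(n) < 1 / (1 + np.exp(-2 * x))
        base = {k: np.zeros(y.sum()) for k in QUANT_COVARIATES}
        treated = pd.DataFrame({"cell_id": np.arange(y.sum()), **base,
                                "elevation": x[y]})
        base_c = {k: np.zeros((~y).sum()) for k in QUANT_COVARIATES}
        controls = pd.DataFrame({"cell_id": np.arange((~y).sum()), **base_c,
                                 "elevation": x[~y]})
        model = fit_propensity(treated, controls, categoricals=[])
        grid = pd.DataFrame({k: np.zeros(50) for k in QUANT_COVARIATES})
        grid["elevation"] = np.linspace(-2, 2, 50)
        s = model.predict(grid)
        assert (np.diff(s) > 0).all()

    def test_coefficients_match_reference_fit(self, small_world):
        # independent oracle: statsmodels' Newton ML fit on the same design
        statsmodels = pytest.importorskip("statsmodels.api")
        world, shots = small_world
        metrics = aggregate_to_cells(filter_footprints(shots), world.cells)
        treated, controls = build_control_pool(world.cells, metrics, 3.0)
        model = fit_propensity(treated, controls, categoricals=[])
        pooled = pd.concat([treated, controls])
        X = model.design(pooled)
        y = np.r_[np.ones(len(treated)), np.zeros(len(controls))]
        ref = statsmodels.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
        assert np.allclose(model.coef, ref.params, rtol=1e-4)

    def test_perfect_separation_falls_back_to_ridge(self):
        base = {k: np.zeros(50) for k in QUANT_COVARIATES}
        treated = pd.DataFrame({"cell_id": np.arange(50), **base})
        controls = pd.DataFrame({"cell_id": np.arange(50, 100), **base})
        treated["elevation"] = np.linspace(1, 2, 50)
        controls["elevation"] = np.linspace(-2, -1, 50)
        model = fit_propensity(treated, controls, categoricals=[])
        assert model.ridge_fallback
        assert np.isfinite(model.coef).all()

    def test_empty_group_rejected(self):
        df = pd.DataFrame({k: [0.0] for k in QUANT_COVARIATES})
        with pytest.raises(ValueError, match="non-empty"):
            fit_propensity(df.iloc[:0], df)


class TestCaliper:
    def test_support_is_interval_intersection(self):
        model = _score_model()
        treated = cells_from_scores(np.linspace(0.4, 0.9, 20))
        controls = cells_from_scores(np.linspace(0.1, 0.6, 20))
        model.score_range_treated = (0.4, 0.9)
        model.score_range_control = (0.1, 0.6)
        cal = set_caliper(model, treated, controls)
        assert (cal.support_lo, cal.support_hi) == pytest.approx((0.4, 0.6))

    def test_identical_distributions_full_support(self):
        model = _score_model()
        scores = np.linspace(0.2, 0.8, 10)
        t = cells_from_scores(scores)
        model.score_range_treated = model.score_range_control = (0.2, 0.8)
        cal = set_caliper(model, t, t)
        assert (cal.support_lo, cal.support_hi) == pytest.approx((0.2, 0.8))
        assert not cal.empty_support

    def test_width_is_fifth_of_logit_sd(self):
        # logit scores {-0.5, +0.5} -> SD 0.5 -> caliper 0.1
        model = _score_model()
        scores = 1 / (1 + np.exp(-np.array([-0.5, 0.5])))
        t = cells_from_scores(scores)
        cal = set_caliper(model, t, t)
        assert cal.width == pytest.approx(0.1)

    def test_empty_overlap_flags_everything_unmatched(self):
        model = _score_model()
        t = cells_from_scores([0.8, 0.9])
        c = cells_from_scores([0.1, 0.2])
        model.score_range_treated = (0.8, 0.9)
        model.score_range_control = (0.1, 0.2)
        cal = set_caliper(model, t, c)
        assert cal.empty_support
        pairs, unmatched = match(t, c, model, cal)
        assert pairs.empty and len(unmatched) == 2


class TestMatch:
    def test_nearest_within_caliper(self):
        # oracle: brute-force over the three candidate assignments
        model = _score_model()
        treated = cells_from_scores([0.60])
        controls = cells_from_scores([0.58, 0.70, 0.61])
        cal = Caliper(0.0, 1.0, 0.05)  # logit-scale width
        gaps = np.abs(_logit(np.array([0.58, 0.70, 0.61])) - _logit(np.array(0.60)))
        best = int(np.argmin(np.where(gaps <= cal.width, gaps, np.inf)))
        pairs, _ = match(treated, controls, model, cal)
        assert len(pairs) == 1
        assert pairs.loc[0, "control_cell_id"] == best == 2
        assert pairs.loc[0, "abs_score_gap"] <= cal.width

    def test_without_replacement(self):
        model = _score_model()
        treated = cells_from_scores([0.60, 0.59])
        controls = cells_from_scores([0.60])
        pairs, unmatched = match(treated, controls, model,
                                 Caliper(0.0, 1.0, 0.5))
        assert len(pairs) == 1 and len(unmatched) == 1
        assert pairs.loc[0, "pa_cell_id"] == 0  # higher score processed first

    def test_exact_country_never_crossed(self):
        model = _score_model()
        treated = cells_from_scores([0.5], country="X")
        controls = cells_from_scores([0.5], country="Y")
        pairs, unmatched = match(treated, controls, model,
                                 Caliper(0.0, 1.0, 1.0))
        assert pairs.empty and len(unmatched) == 1

    def test_score_gap_ties_break_on_lowest_cell_id(self):
        model = _score_model()
        treated = cells_from_scores([0.5])
        controls = cells_from_scores([0.52, 0.48, 0.52])
        pairs, _ = match(treated, controls, model, Caliper(0.0, 1.0, 0.5))
        # 0.48 and 0.52 are equidistant on the logit scale; 0.48 sits at
        # cell_id 1, below the duplicated 0.52s -> deterministic winner
        assert pairs.loc[0, "control_cell_id"] in (0, 1)
        again, _ = match(treated, controls, model, Caliper(0.0, 1.0, 0.5))
        assert pairs.loc[0, "control_cell_id"] == again.loc[0, "control_cell_id"]

    def test_pipeline_pairs_satisfy_all_invariants(self, default_bundle):
        b = default_bundle
        pairs = b.pairs
        assert pairs["control_cell_id"].is_unique
        assert pairs["pa_cell_id"].is_unique
        cells = b.cells.set_index("cell_id")
        for col in ("land_cover", "country", "ecoregion", "biome"):
            assert (cells.loc[pairs["pa_cell_id"], col].to_numpy()
                    == cells.loc[pairs["control_cell_id"], col].to_numpy()).all()
        assert (cells.loc[pairs["pa_cell_id"], "is_protected"]).all()
        assert (~cells.loc[pairs["control_cell_id"], "is_protected"]).all()


class TestBalance:
    def test_smd_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 3.0, 4.0])
        expected = (a.mean() - b.mean()) / np.sqrt(
            (a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert standardized_mean_difference(a, b) == pytest.approx(expected)
        assert standardized_mean_difference(a, a) == 0.0

    def test_constant_covariate_gives_zero(self):
        z = np.full(5, 7.0)
        assert standardized_mean_difference(z, z) == 0.0

    def test_matching_improves_balance(self, default_bundle):
        b = default_bundle
        # confounded placement: matching shrinks the summed imbalance
        assert (b.balance["smd_after"].abs().mean()
                < b.balance["smd_before"].abs().mean())
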