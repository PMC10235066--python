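"""Areas, hybrid variance, paired differences, totals, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from pacarbon.estimation import (aggregate, dissolve_pa_area, expand_to_total,
                                 extrapolate_unmatched, hybrid_mean_se,
                                 stratum_difference)


class TestDissolve:
    def test_overlap_counted_once(self):
        a = set(range(100))
        b = set(range(70, 170))  # 30 cells shared
        out = dissolve_pa_area({0: a, 1: b})
        assert out["dissolved_area_km2"].sum() == 170
        assert out.loc[out["pa_id"] == 1, "dissolved_area_km2"].item() == 70

    def test_disjoint_sums(self):
        out = dissolve_pa_area({0: range(10), 1: range(100, 140)})
        assert out["dissolved_area_km2"].tolist() == [10, 40]

    def test_nested_pa_adds_nothing(self):
        out = dissolve_pa_area({0: range(50), 1: range(10, 20)})
        assert out.loc[out["pa_id"] == 1, "dissolved_area_km2"].item() == 0
        assert out["dissolved_area_km2"].sum() == 50


class TestHybridVariance:
    def test_sampling_term_closed_form(self):
        mean, se = hybrid_mean_se(np.array([10.0, 20.0, 30.0]), 0.0)
        assert mean == pytest.approx(20.0)
        assert se == pytest.approx(10.0 / math.sqrt(3))

    def test_model_term_only(self):
        mean, se = hybrid_mean_se(np.full(8, 50.0), 0.1)
        assert (mean, se) == (pytest.approx(50.0), pytest.approx(5.0))

    def test_variance_additivity(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(10, 100, 20)
        _, se0 = hybrid_mean_se(v, 0.0)
        m, se = hybrid_mean_se(v, 0.05)
        assert se ** 2 == pytest.approx(se0 ** 2 + (0.05 * m) ** 2, rel=1e-12)

    def test_single_cell_low_confidence(self):
        mean, se = hybrid_mean_se(np.array([42.0]))
        assert mean == 42.0 and math.isnan(se)


def pair_frame(d, pa_id=None, **labels):
    n = len(d)
    base = 100.0 + np.arange(n)
    df = pd.DataFrame({
        "pa_cell_id": np.arange(n), "control_cell_id": np.arange(n) + 1000,
        "agcd_pa": base + np.asarray(d), "agcd_control": base,
        "d_agcd": np.asarray(d, float),
        "d_agbd": np.asarray(d, float) / 0.49,
        "d_rh98": 0.0, "d_canopy_cover": 0.0, "d_pai": 0.0,
        "pa_id": pa_id if pa_id is not None else np.arange(n),
    })
    for k, v in labels.items():
        df[k] = v
    return df


class TestStratumDifference:
    def test_closed_form_mean_and_se(self):
        out = stratum_difference(pair_frame([2.0, 4.0, 6.0], country="A"),
                                 "country")
        assert out.loc[0, "mean_diff"] == pytest.approx(4.0)
        # one pair per PA -> CR1 reduces exactly to sd/sqrt(n)
        assert out.loc[0, "se_diff"] == pytest.approx(2.0 / math.sqrt(3))

    def test_antisymmetry_under_label_swap(self):
        d = [1.0, -2.0, 5.0]
        fwd = stratum_difference(pair_frame(d, country="A"), "country")
        rev = stratum_difference(pair_frame([-x for x in d], country="A"),
                                 "country")
        assert fwd.loc[0, "mean_diff"] == pytest.approx(-rev.loc[0, "mean_diff"])
        assert fwd.loc[0, "se_diff"] == pytest.approx(rev.loc[0, "se_diff"])

    def test_single_pair_flagged(self):
        out = stratum_difference(pair_frame([3.0], country="A"), "country")
        assert bool(out.loc[0, "low_confidence"])
        assert math.isnan(out.loc[0, "se_diff"])

    def test_cluster_robust_se_grows_with_shared_pa_shift(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, 40)
        shift = np.repeat([2.0, -2.0, 1.0, -1.0], 10)
        clustered = pair_frame(noise + shift, pa_id=np.repeat(np.arange(4), 10),
                               country="A")
        independent = pair_frame(noise + shift, country="A")
        se_c = stratum_difference(clustered, "country").loc[0, "se_diff"]
        se_i = stratum_difference(independent, "country").loc[0, "se_diff"]
        assert se_c > se_i


class TestExpansion:
    def test_unit_algebra(self):
        total, se = expand_to_total(10.0, 1.0, 1000.0)
        assert total == pytest.approx(0.001)
        assert se == pytest.approx(0.0001)

    def test_zero_area(self):
        assert expand_to_total(10.0, 1.0, 0.0) == (0.0, 0.0)

    def test_linearity_in_area(self):
        t1, s1 = expand_to_total(7.0, 0.5, 500.0)
        t2, s2 = expand_to_total(7.0, 0.5, 1000.0)
        assert (t2, s2) == (pytest.approx(2 * t1), pytest.approx(2 * s1))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            expand_to_total(1.0, 0.1, -5.0)

    def test_round_trip_dimensional(self):
        rng = np.random.default_rng(4)
        for mean, area in zip(rng.uniform(1, 50, 10), rng.uniform(1, 5e4, 10)):
            total, _ = expand_to_total(mean, 0.0, area)
            assert total * 1e9 / (area * 100) == pytest.approx(mean)


class TestExtrapolation:
    def stratum_tables(self):
        cb = pd.DataFrame({"country": ["A"], "biome": ["forest"],
                           "n_pairs": [12], "mean_diff": [5.0],
                           "se_diff": [0.5]}).set_index(["country", "biome"])
        nb = pd.DataFrame({"continent": ["C0"], "biome": ["forest"],
                           "n_pairs": [30], "mean_diff": [3.0],
                           "se_diff": [0.4]}).set_index(["continent", "biome"])
        return cb, nb

    def test_country_biome_applies(self):
        cb, nb = self.stratum_tables()
        pa = pd.Series({"country": "A", "biome": "forest", "continent": "C0"})
        mean, se, prov = extrapolate_unmatched(pa, cb, nb)
        assert (mean, se, prov) == (5.0, 0.5, "extrapolated_country_biome")
        total, _ = expand_to_total(mean, se, 200.0)
        assert total == pytest.approx(1e-4)

    def test_fallback_to_continent_biome(self):
        cb, nb = self.stratum_tables()
        pa = pd.Series({"country": "B", "biome": "forest", "continent": "C0"})
        mean, se, prov = extrapolate_unmatched(pa, cb, nb)
        assert (mean, prov) == (3.0, "extrapolated_continent_biome")

    def test_both_missing_flagged(self):
        cb, nb = self.stratum_tables()
        pa = pd.Series({"country": "B", "biome": "tundra", "continent": "C9"})
        mean, se, prov = extrapolate_unmatched(pa, cb, nb)
        assert math.isnan(mean) and prov == "no_estimate"


def pa_rows(values, ses, continents, strata=None):
    n = len(values)
    return pd.DataFrame({
        "pa_id": np.arange(n), "country": [f"c{i}" for i in range(n)],
        "continent": continents, "biome": "forest",
        "n_pairs": 5, "area_km2": 100.0,
        "mean_diff": 1.0, "se_diff": 0.1,
        "stratum_key": strata if strata is not None
        else [f"s{i}" for i in range(n)],
        "additional_agc_gt": values, "se_additional_agc_gt": ses,
        "total_agc_gt": values, "se_total_agc_gt": ses,
        "provenance": "matched",
    })


class TestAggregate:
    def test_printed_continental_values_sum_to_globe(self):
        vals = [4.94, 1.38, 1.2, 0.86, 0.65, 0.61]
        t = pa_rows(vals, [0.1] * 6, [f"K{i}" for i in range(6)])
        out = aggregate(t, "globe")
        assert out.loc[0, "additional_agc_gt"] == pytest.approx(9.64)

    def test_single_stratum_identity(self):
        t = pa_rows([2.5], [0.3], ["K0"])
        out = aggregate(t, "continent")
        assert out.loc[0, "additional_agc_gt"] == pytest.approx(2.5)
        assert out.loc[0, "se_additional_agc_gt"] == pytest.approx(0.3)

    def test_independent_strata_ses_combine_in_quadrature(self):
        t = pa_rows([1.0, 1.0], [0.3, 0.4], ["K0", "K0"])
        out = aggregate(t, "continent")
        assert out.loc[0, "se_additional_agc_gt"] == pytest.approx(0.5)

    def test_shared_stratum_ses_add_linearly(self):
        t = pa_rows([1.0, 1.0], [0.3, 0.4], ["K0", "K0"],
                    strata=["same", "same"])
        out = aggregate(t, "continent")
        assert out.loc[0, "se_additional_agc_gt"] == pytest.approx(0.7)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pa_rows([1.0], [0.1], ["K0"]), "hemisphere")


class TestPipelineAdditivity:
    def test_global_total_equals_all_partitions(self, default_bundle):
        b = default_bundle
        g = b.globe.loc[0, "additional_agc_gt"]
        assert b.by_continent["additional_agc_gt"].sum() == pytest.approx(g, rel=1e-12)
        assert b.by_country["additional_agc_gt"].sum() == pytest.approx(g, rel=1e-12)
        assert b.by_biome["additional_agc_gt"].sum() == pytest.approx(g, rel=1e-12)
        per_pa = b.pa_table["additional_agc_gt"].dropna().sum()
        assert per_pa == pytest.approx(g, rel=1e-12)

    def test_paired_difference_sign_convention(self, default_bundle):
        pd_ = default_bundle.pair_diffs
        assert np.allclose(pd_["d_agcd"],
                           pd_["agcd_pa"] - pd_["agcd_control"])
        assert np.allclose(pd_["d_agcd"], 0.49 * pd_["d_agbd"])
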