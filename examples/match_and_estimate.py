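"""Full pipeline on one synthetic world: match, estimate, aggregate.

Runs quality filtering, 1-km aggregation, buffered control-pool construction,
propensity matching with exact strata, and carbon effect estimation, then
prints the global summary the way the study tabulates it.
"""

from pacarbon import RunConfig, LandscapeConfig, naive_difference, run_pipeline

config = RunConfig(seed=3, landscape=LandscapeConfig(seed=3))
bundle = run_pipeline(config)

c = bundle.manifest["counts"]
print(f"shots {c['shots_total']} -> {c['shots_pass_quality']} after quality "
      f"filter; {c['cells_qualified']} qualified 1-km cells")
print(f"treated cells {c['treated_cells']}, control pool {c['control_pool']}, "
      f"matched pairs {c['pairs']}")

true_c = 0.49 * bundle.manifest["true_delta"]
matched = bundle.pair_diffs["d_agcd"].mean()
naive = naive_difference(bundle.cells, bundle.cell_metrics)
print(f"\ntrue protection effect:   {true_c:6.2f} Mg C/ha")
print(f"matched paired estimate:  {matched:6.2f} Mg C/ha")
print(f"naive unmatched contrast: {naive:6.2f} Mg C/ha  (confounded)")

g = bundle.globe.iloc[0]
print(f"\nglobal additional carbon: {g['additional_agc_gt']:.5f} Gt "
      f"+/- {g['se_additional_agc_gt']:.5f} over {g['area_km2']:.0f} km^2 of PAs")
print("\nby continent:")
print(bundle.by_continent[["continent", "n_pas", "area_km2",
                           "additional_agc_gt", "se_additional_agc_gt"]]
      .round(5).to_string(index=False))
# The matched estimate recovers the true effect; the naive contrast inherits
# the siting bias of protected areas toward carbon-rich land.
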