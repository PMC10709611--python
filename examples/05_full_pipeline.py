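"""End-to-end pipeline run: simulate -> indices -> severity -> risk -> trends.

Writes all stage artifacts (stacks, dNBR grids, severity maps, risk map,
annual series, trend tables, report.json) under ./pipeline_demo_out.
"""

import fire_dynamics as fd

scene = fd.SceneConfig(
    seed=1, years=tuple(range(2001, 2023)),
    burn_events=(
        fd.BurnEvent(2005, 2, 2, 5, 5, "MLS", 0.30),
        fd.BurnEvent(2012, 9, 9, 5, 5, "MHS", 0.50),
        fd.BurnEvent(2020, 4, 9, 4, 4, "HS", 0.80),
    ),
    gpp_change_year=2008, gpp_step=3 * 0.002,
)
cfg = fd.PipelineConfig(out_dir="pipeline_demo_out", scene=scene)
report = fd.run_pipeline(cfg)

print("stages run:", ", ".join(s.stage for s in report.stages))
print("risk-level pixel counts:", report.risk_level_counts)
print("Pettitt change years:", report.pettitt_change_years)
print()
print("severe area (MLS+MHS+HS) by year with planted burns:")
for year in (2005, 2012, 2020):
    ha = report.class_areas_summary["severe_area_ha_by_year"][year]
    print(f"  {year}: {ha:.1f} ha")
print()
print("All outputs live under pipeline_demo_out/; report.json carries the")
print("machine-readable summary. Re-running with the same seed reproduces")
print("every CSV byte-for-byte.")
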