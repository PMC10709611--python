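"""Trend and change-point statistics on coupled annual series.

Generates a 22-year record with a planted GPP level shift in 2012, then
applies the Mann-Kendall trend test, the Pettitt change-point test, the
Pearson correlation matrix and a correlation-based PCA.
"""

import fire_dynamics as fd

cfg = fd.SceneConfig(seed=8, gpp_change_year=2012, gpp_step=3 * 0.002)
series = fd.generate_annual_series(cfg)

print("Mann-Kendall / Pettitt (alpha = 0.05):")
table = fd.trend_table(list(series.values()))
print(table.to_string(index=False))
print()

corr = fd.pearson_matrix(list(series.values()))
print("Pearson r(foci, precipitation) = "
      f"{corr.loc['foci', 'precipitation']:+.3f}  (negative coupling:")
print("wet years burn less)")
print(f"Pearson r(gpp, co2_flux)       = {corr.loc['gpp', 'co2_flux']:+.3f}")
print()

res = fd.pca(fd.align_series(list(series.values())))
print("PCA explained variance:",
      ", ".join(f"{v:.1%}" for v in res.explained_variance))
print()
print("The Pettitt test recovers the planted 3-sd GPP level shift as a")
print("significant change point within a year of the true 2012 onset")
print("(and drags co2_flux with it through the coupling), while the")
print("un-shifted precipitation and foci series show no change point.")
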