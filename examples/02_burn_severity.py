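"""Burn-severity mapping on a synthetic scene with a planted scar.

Generates pre/post-fire reflectance for one year with a high-severity
burn scar, computes dNBR, classifies it into the seven severity classes
and accounts per-class areas.
"""

import numpy as np

import fire_dynamics as fd

cfg = fd.SceneConfig(
    seed=42, years=(2019, 2020, 2021, 2022),
    burn_events=(fd.BurnEvent(2020, 4, 4, 6, 6, "HS", 0.75),),
)
pre, post, truth = fd.generate_scene(cfg)

dnbr = fd.delta_nbr(fd.nbr(pre[2020]), fd.nbr(post[2020]))
sev = fd.classify_severity(dnbr, cfg.scheme, year=2020)
areas = fd.class_areas([sev], cfg.pixel_area_ha)

scar = truth.burn_masks[2020]
print(f"planted scar: 6x6 pixels, target dNBR 0.75 (HS class)")
print(f"dNBR on scar : {dnbr.values[scar].mean():.4f} "
      f"(min {dnbr.values[scar].min():.4f}, max {dnbr.values[scar].max():.4f})")
print(f"dNBR off scar: |max| = {np.abs(dnbr.values[~scar]).max():.4f}")
print()
print("class areas for 2020 (pixel = %.1f ha):" % cfg.pixel_area_ha)
for _, row in areas[areas.pixels > 0].iterrows():
    print(f"  {row['class']:>12}: {row.pixels:4d} px  {row.area_ha:9.1f} ha")
print()
print("The scar classifies as HS (dNBR in [0.660, 1.300]); everything")
print("else stays UN because off-scar dNBR noise is well below 0.100.")
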