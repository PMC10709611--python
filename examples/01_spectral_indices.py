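"""Spectral indices on a uniform vegetated surface.

Builds a small reflectance stack with typical healthy-vegetation band
values and walks the index chain: PRI -> sPRI -> NDVI -> CO2-flux.
"""

import numpy as np

import fire_dynamics as fd
from fire_dynamics.rasters import BandStack

shape = (8, 8)
stack = BandStack(
    blue=np.full(shape, 0.05), green=np.full(shape, 0.10),
    red=np.full(shape, 0.06), nir=np.full(shape, 0.40),
    swir=np.full(shape, 0.18),
)

pri = fd.pri(stack)
spri = fd.spri(pri)
ndvi = fd.ndvi(stack)
flux = fd.co2_flux(ndvi, spri)
nbr = fd.nbr(stack)

print(f"PRI  = {pri.values[0, 0]:+.4f}   (blue-green contrast, [-1, 1])")
print(f"sPRI = {spri.values[0, 0]:.4f}   (PRI rescaled to [0, 1])")
print(f"NDVI = {ndvi.values[0, 0]:.4f}   (photosynthetic vigor)")
print(f"NBR  = {nbr.values[0, 0]:.4f}   (vegetation moisture/char)")
print(f"CO2 flux = {flux.values[0, 0]:+.3f} umol m-2 s-1")
print()
print("A dense healthy canopy gives a strongly negative CO2-flux index:")
print("the more negative, the higher the carbon-sequestration efficiency.")
print("Where the NDVI*sPRI product is zero the index sits at the model")
print(f"intercept, {fd.CO2_FLUX_INTERCEPT} umol m-2 s-1.")
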