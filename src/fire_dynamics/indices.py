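"""Per-pixel spectral indices and production models.

Implements the index chain used to monitor carbon dynamics and burn
severity in fire-prone savanna/wetland mosaics:

* PRI from blue/green reflectance and its rescaling sPRI = (PRI+1)/2,
* NDVI = (NIR − red)/(NIR + red),
* the empirical CO₂-flux index  13.63 − 66.207·(NDVI·sPRI)
  in µmol m⁻² s⁻¹ (more negative = stronger sequestration),
* the light-use-efficiency GPP model  GPP = ε·PAR·FPAR with
  ε = εmax·Tmin_scalar·VPD_scalar,
* digital-number scaling of composite GPP products to kg C m⁻² d⁻¹,
* NBR = (NIR − SWIR)/(NIR + SWIR) and the bi-temporal difference
  ΔNBR = NBR_pre − NBR_post used for burn-severity mapping.

All ratio indices return nodata (NaN + mask) where the denominator is
zero: an undefined ratio must not masquerade as a valid value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rasters import BandStack, IndexGrid

# CO2-flux index model constants (empirical regression on NDVI·sPRI).
CO2_FLUX_INTERCEPT = 13.63
CO2_FLUX_SLOPE = -66.207

#: Default digital-number scaling for 8-day composite GPP: 0.001 then /8.
GPP_SCALE_DEFAULT = 0.001 / 8.0
#: Alternative plain product-documentation scale factor.
GPP_SCALE_ALT = 0.0001


def _normalized_difference(a: np.ndarray, b: np.ndarray,
                           mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(a − b)/(a + b) with zero denominators masked as nodata."""
    denom = a + b
    bad = mask | (denom == 0) | ~np.isfinite(denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(bad, np.nan, (a - b) / np.where(bad, 1.0, denom))
    return values, bad


def pri(stack: BandStack) -> IndexGrid:
    """Photochemical reflectance index from blue (A) and green (Ve) bands.

    PRI = (A − Ve)/(A + Ve), in [−1, 1] for non-negative reflectance.
    """
    values, mask = _normalized_difference(stack.blue, stack.green, stack.mask)
    return IndexGrid(values, "pri", mask=mask, transform=stack.transform,
                     epoch=stack.epoch)


def spri(pri_grid: IndexGrid) -> IndexGrid:
    """Rescale PRI into [0, 1]: sPRI = (PRI + 1)/2. Affine, order-preserving."""
    values = (pri_grid.values + 1.0) / 2.0
    return IndexGrid(values, "spri", mask=pri_grid.mask,
                     transform=pri_grid.transform, epoch=pri_grid.epoch)


def ndvi(stack: BandStack) -> IndexGrid:
    """NDVI = (NIR − red)/(NIR + red); photosynthetic-vigor proxy."""
    values, mask = _normalized_difference(stack.nir, stack.red, stack.mask)
    return IndexGrid(values, "ndvi", mask=mask, transform=stack.transform,
                     epoch=stack.epoch)


def co2_flux(ndvi_grid: IndexGrid, spri_grid: IndexGrid) -> IndexGrid:
    """CO₂-flux index: 13.63 − 66.207·(NDVI·sPRI), µmol m⁻² s⁻¹.

    Strictly decreasing in the product NDVI·sPRI; equals the intercept
    13.63 wherever the product vanishes.
    """
    if ndvi_grid.shape != spri_grid.shape:
        raise ValueError(
            f"misaligned grids: {ndvi_grid.shape} vs {spri_grid.shape}")
    mask = ndvi_grid.mask | spri_grid.mask
    values = CO2_FLUX_INTERCEPT + CO2_FLUX_SLOPE * (
        ndvi_grid.values * spri_grid.values)
    return IndexGrid(values, "co2_flux", mask=mask,
                     transform=ndvi_grid.transform,
                     units="umol m-2 s-1", epoch=ndvi_grid.epoch)


@dataclass(frozen=True)
class GppLueInputs:
    """Inputs to the light-use-efficiency GPP model.

    epsilon_max : maximum light-use efficiency (kg C MJ⁻¹), ≥ 0
    t_min_scalar, vpd_scalar : environmental down-regulation scalars in [0, 1]
    par : absorbed photosynthetically active radiation term, ≥ 0
    fpar : fraction of PAR absorbed by the canopy, in [0, 1]
    """

    epsilon_max: float
    t_min_scalar: float
    vpd_scalar: float
    par: float
    fpar: float

    def __post_init__(self) -> None:
        for name in ("epsilon_max", "t_min_scalar", "vpd_scalar", "par", "fpar"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("t_min_scalar", "vpd_scalar", "fpar"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def gpp_lue(inputs: GppLueInputs) -> float:
    """GPP = ε·PAR·FPAR with ε = εmax·Tmin_scalar·VPD_scalar."""
    eps = inputs.epsilon_max * inputs.t_min_scalar * inputs.vpd_scalar
    return eps * inputs.par * inputs.fpar


def gpp_scale(raw_dn: np.ndarray, scale: float = GPP_SCALE_DEFAULT,
              mask: np.ndarray | None = None) -> IndexGrid:
    """Scale composite-GPP digital numbers to kg C m⁻² d⁻¹.

    Default ``scale`` is 0.001/8 (DN to kg C m⁻², then to an 8-day daily
    mean); pass :data:`GPP_SCALE_ALT` (0.0001) for products documented
    with the plain 10⁻⁴ conversion. Fill values must be masked first.
    """
    raw = np.asarray(raw_dn, dtype=np.float64)
    bad = ~np.isfinite(raw) | (raw < 0)
    if mask is not None:
        bad = bad | np.asarray(mask, dtype=bool)
    values = np.where(bad, np.nan, raw * scale)
    return IndexGrid(values, "gpp", mask=bad, units="kg C m-2 d-1")


def nbr(stack: BandStack) -> IndexGrid:
    """Normalized burn ratio: (NIR − SWIR)/(NIR + SWIR).

    Burned surfaces depress NIR and raise SWIR, so NBR drops after fire.
    """
    values, mask = _normalized_difference(stack.nir, stack.swir, stack.mask)
    return IndexGrid(values, "nbr", mask=mask, transform=stack.transform,
                     epoch=stack.epoch)


def delta_nbr(pre_fire: IndexGrid, post_fire: IndexGrid) -> IndexGrid:
    """ΔNBR = NBR_pre − NBR_post; positive = burn damage, negative = regrowth."""
    if pre_fire.shape != post_fire.shape:
        raise ValueError(
            f"misaligned grids: {pre_fire.shape} vs {post_fire.shape}")
    mask = pre_fire.mask | post_fire.mask
    values = pre_fire.values - post_fire.values
    return IndexGrid(values, "dnbr", mask=mask, transform=pre_fire.transform,
                     epoch=post_fire.epoch)
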