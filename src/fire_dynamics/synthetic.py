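"""Synthetic multi-year scene and annual-series generator.

Emulates the statistical structure of a fire-prone tropical wetland as
seen by a moderate-resolution optical sensor, with known ground truth,
so every downstream stage (indices → severity → risk → trends) can be
exercised and verified without external archives:

* reflectance stacks with a vegetated-surface band structure
  (NIR ≈ 0.40, SWIR ≈ 0.18, red ≈ 0.06, green ≈ 0.10, blue ≈ 0.05),
* burn scars that depress NIR and raise SWIR so that pre/post ΔNBR
  equals a planted target severity exactly (before clipping),
* annual precipitation with a multi-year wet/dry cycle,
* fire-foci counts negatively coupled to the precipitation anomaly
  (Poisson with a log-link),
* GPP positively coupled to precipitation, with an optional planted
  level shift, and a CO₂-flux series negatively coupled to GPP.

Reproducibility: one RNG stream per scene keyed by the seed, with
per-year substreams derived deterministically, so a fixed seed gives
bit-identical output and partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rasters import BandStack, DEFAULT_TRANSFORM, GeoTransform
from .severity import DEFAULT_SCHEME, SeverityScheme
from .trends import AnnualSeries

#: Mean reflectance of the unburned vegetated surface, per band.
BASE_REFLECTANCE = {"blue": 0.05, "green": 0.10, "red": 0.06,
                    "nir": 0.40, "swir": 0.18}
#: Static pixel-to-pixel surface variability (shared pre/post).
SURFACE_NOISE_SD = 0.01
#: Independent epoch-to-epoch noise; kept small so no-burn |ΔNBR| < 0.05.
EPOCH_NOISE_SD = 0.003


@dataclass(frozen=True)
class BurnEvent:
    """A planted rectangular burn scar in one year.

    ``severity_dnbr`` is the target ΔNBR of the scar and must lie inside
    the (unscaled) interval of ``target_class``.
    """

    year: int
    row0: int
    col0: int
    rows: int
    cols: int
    target_class: str
    severity_dnbr: float

    def footprint(self, shape: tuple[int, int]) -> np.ndarray:
        if (self.row0 < 0 or self.col0 < 0 or self.rows < 1 or self.cols < 1
                or self.row0 + self.rows > shape[0]
                or self.col0 + self.cols > shape[1]):
            raise ValueError(f"burn footprint out of bounds for grid {shape}")
        m = np.zeros(shape, dtype=bool)
        m[self.row0:self.row0 + self.rows, self.col0:self.col0 + self.cols] = True
        return m

    def validate(self, scheme: SeverityScheme) -> None:
        lo, hi = scheme.interval(self.target_class)
        inside = (lo <= self.severity_dnbr < hi
                  or (self.target_class == scheme.names[-1]
                      and self.severity_dnbr == hi))
        if not inside:
            raise ValueError(
                f"severity_dnbr={self.severity_dnbr} outside {self.target_class} "
                f"interval [{lo}, {hi})")


@dataclass(frozen=True)
class SceneConfig:
    """Study-condition parameters for one synthetic scene.

    Defaults mirror a 22-year moderate-resolution monitoring record of a
    seasonal wetland: ~1300 mm mean annual precipitation with ±300 mm
    spread on an 11-year wet/dry cycle, fire-foci counts around 10³ per
    year falling when rainfall is high (log-link coefficient −1.5), GPP
    near 0.018 kg C m⁻² d⁻¹ rising with rainfall, and a CO₂-flux index
    series moving opposite to GPP.
    """

    grid_rows: int = 16
    grid_cols: int = 16
    years: tuple[int, ...] = tuple(range(2001, 2023))
    pixel_area_ha: float = 21.4
    seed: int = 0
    burn_events: tuple[BurnEvent, ...] = ()
    precip_mean_mm: float = 1300.0
    precip_sd_mm: float = 300.0
    precip_cycle_years: float = 11.0
    foci_coupling: float = -1.5
    foci_log_mean: float = float(np.log(1000.0))
    gpp_mean: float = 0.018
    gpp_sd: float = 0.002
    gpp_precip_loading: float = 0.3
    gpp_change_year: int | None = None
    gpp_step: float = 0.0
    co2_mean: float = 10.0
    co2_gpp_loading: float = -0.8
    co2_noise_sd: float = 0.6
    transform: GeoTransform = DEFAULT_TRANSFORM
    scheme: SeverityScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ValueError("grid must be at least 8x8")
        years = np.asarray(self.years)
        if len(years) and not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing")
        if self.pixel_area_ha <= 0:
            raise ValueError("pixel_area_ha must be > 0")
        if self.precip_sd_mm < 0:
            raise ValueError("precip_sd_mm must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_rows, self.grid_cols)


@dataclass
class GroundTruth:
    """What the generator planted, for verification downstream."""

    burn_masks: dict[int, np.ndarray]          # year -> footprint mask
    burn_classes: dict[int, np.ndarray]        # year -> class-code grid (0=none)
    severity: dict[int, np.ndarray]            # year -> planted ΔNBR grid
    precipitation: dict[int, float]
    expected_foci: dict[int, float]            # Poisson mean per year
    change_year: int | None


def _year_rng(seed: int, year: int, tag: int) -> np.random.Generator:
    # Deterministic substream per (scene, year, purpose).
    return np.random.default_rng([seed & 0x7FFFFFFF, year, tag])


def _base_stack(config: SceneConfig, surface: dict[str, np.ndarray],
                rng: np.random.Generator, epoch: str) -> BandStack:
    bands = {}
    for name in BASE_REFLECTANCE:
        noise = rng.normal(0.0, EPOCH_NOISE_SD, size=config.shape)
        bands[name] = np.clip(surface[name] + noise, 0.0, 1.0)
    return BandStack(transform=config.transform, epoch=epoch, **bands)


def _apply_burns(pre: BandStack, post: BandStack,
                 events: list[BurnEvent]) -> tuple[np.ndarray, np.ndarray]:
    """Rewrite post-fire NIR/SWIR inside each footprint.

    Moving NIR down and SWIR up symmetrically preserves their sum s, so
    the post-fire values solve in closed form from the target NBR:
    NIR' = s(1+t)/2, SWIR' = s(1−t)/2 with t = NBR_pre − severity.
    Returns the achieved ΔNBR grid (0 off-scar) and the burned mask.
    """
    planted = np.zeros(pre.shape)
    covered = np.zeros(pre.shape, dtype=bool)
    for ev in events:
        fp = ev.footprint(pre.shape)
        if (fp & covered).any():
            raise ValueError(
                f"overlapping burn footprints in year {ev.year}")
        covered |= fp
        pre_nbr = ((pre.nir[fp] - pre.swir[fp])
                   / (pre.nir[fp] + pre.swir[fp]))
        target = pre_nbr - ev.severity_dnbr
        s = post.nir[fp] + post.swir[fp]
        post.nir[fp] = np.clip(s * (1.0 + target) / 2.0, 0.0, 1.0)
        post.swir[fp] = np.clip(s * (1.0 - target) / 2.0, 0.0, 1.0)
        # achieved ΔNBR equals severity exactly unless clipping engaged
        post_nbr = ((post.nir[fp] - post.swir[fp])
                    / (post.nir[fp] + post.swir[fp]))
        planted[fp] = pre_nbr - post_nbr
    return planted, covered


def generate_scene(config: SceneConfig
                   ) -> tuple[dict[int, BandStack], dict[int, BandStack],
                              GroundTruth]:
    """Generate per-year pre/post-fire stacks plus ground truth.

    Returns ``(pre_stacks, post_stacks, truth)`` keyed by year. Within a
    year, pre and post share the static surface field and differ by
    small independent epoch noise plus any planted burn scars, so ΔNBR
    off-scar stays near zero while on-scar ΔNBR equals each event's
    ``severity_dnbr`` (exactly, before reflectance clipping).
    """
    by_year: dict[int, list[BurnEvent]] = {}
    for ev in config.burn_events:
        ev.validate(config.scheme)
        ev.footprint(config.shape)  # bounds check
        if ev.year not in config.years:
            raise ValueError(f"burn event year {ev.year} not in scene years")
        by_year.setdefault(ev.year, []).append(ev)

    surface_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xA11CE])
    surface = {
        name: mean + surface_rng.normal(0.0, SURFACE_NOISE_SD,
                                        size=config.shape)
        for name, mean in BASE_REFLECTANCE.items()
    }

    pre_stacks: dict[int, BandStack] = {}
    post_stacks: dict[int, BandStack] = {}
    masks: dict[int, np.ndarray] = {}
    classes: dict[int, np.ndarray] = {}
    severity: dict[int, np.ndarray] = {}
    for year in config.years:
        pre = _base_stack(config, surface, _year_rng(config.seed, year, 1),
                          epoch=f"{year}")
        post = _base_stack(config, surface, _year_rng(config.seed, year, 2),
                           epoch=f"{year}")
        events = by_year.get(year, [])
        planted, mask = _apply_burns(pre, post, events)
        pre_stacks[year], post_stacks[year] = pre, post
        cls = np.zeros(config.shape, dtype=np.uint8)
        for ev in events:
            cls[ev.footprint(config.shape)] = config.scheme.code(
                ev.target_class)
        masks[year], classes[year], severity[year] = mask, cls, planted

    series = generate_annual_series(config)
    precip = dict(zip(config.years, series["precipitation"].values))
    lam = _foci_expectation(config, np.asarray(
        series["precipitation"].values))
    truth = GroundTruth(
        burn_masks=masks, burn_classes=classes, severity=severity,
        precipitation=precip,
        expected_foci=dict(zip(config.years, lam)),
        change_year=config.gpp_change_year,
    )
    return pre_stacks, post_stacks, truth


def _foci_expectation(config: SceneConfig, precip: np.ndarray) -> np.ndarray:
    sd = config.precip_sd_mm if config.precip_sd_mm > 0 else 1.0
    z = (precip - config.precip_mean_mm) / sd
    return np.exp(config.foci_log_mean + config.foci_coupling * z)


def generate_annual_series(config: SceneConfig) -> dict[str, AnnualSeries]:
    """Generate the four coupled annual series for one scene.

    precipitation : mm yr⁻¹; deterministic wet/dry cycle (amplitude
        0.5·sd, period ``precip_cycle_years``) plus Gaussian noise of sd
        √0.75·sd, so the total spread is ≈ the configured sd.
    foci : counts; Poisson with log-mean
        ``foci_log_mean + foci_coupling·z`` where z is the standardized
        precipitation anomaly (negative coupling = fewer fires in wet
        years).
    gpp : kg C m⁻² d⁻¹; loads positively on z, with an optional level
        shift of ``gpp_step`` from ``gpp_change_year`` onward.
    co2_flux : µmol m⁻² s⁻¹; loads negatively on the standardized GPP.
    """
    years = np.asarray(config.years, dtype=np.int64)
    n = len(years)
    if n < 4:
        raise ValueError("need at least 4 years for downstream trend tests")

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x5E21E5])
    idx = np.arange(n)
    cycle = 0.5 * np.sin(2 * np.pi * idx / config.precip_cycle_years)
    precip = (config.precip_mean_mm
              + config.precip_sd_mm * (cycle + np.sqrt(0.75)
                                       * rng.standard_normal(n)))
    precip = np.maximum(precip, 0.0)

    lam = _foci_expectation(config, precip)
    foci = rng.poisson(lam).astype(np.float64)

    sd = config.precip_sd_mm if config.precip_sd_mm > 0 else 1.0
    z = (precip - config.precip_mean_mm) / sd
    load = config.gpp_precip_loading
    eps = rng.standard_normal(n)
    gpp = (config.gpp_mean
           + config.gpp_sd * (load * z + np.sqrt(max(0.0, 1 - load ** 2)) * eps))
    if config.gpp_change_year is not None and config.gpp_step:
        gpp = gpp + np.where(years >= config.gpp_change_year,
                             config.gpp_step, 0.0)
    gpp = np.maximum(gpp, 0.0)

    z_gpp = (gpp - config.gpp_mean) / config.gpp_sd
    co2 = (config.co2_mean + config.co2_gpp_loading * z_gpp
           + config.co2_noise_sd * rng.standard_normal(n))

    return {
        "precipitation": AnnualSeries(years, precip, "precipitation", "mm"),
        "foci": AnnualSeries(years, foci, "foci", "count"),
        "gpp": AnnualSeries(years, gpp, "gpp", "kg C m-2 d-1"),
        "co2_flux": AnnualSeries(years, co2, "co2_flux", "umol m-2 s-1"),
    }
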