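"""ΔNBR burn-severity classification, class-area accounting, risk maps.

The seven-class severity scheme follows the conventional ΔNBR breaks
(×10³ scale): enhanced regrowth high/low (ERH, ERL), unburned (UN), and
low to high burn severity (LS, MLS, MHS, HS). Intervals are half-open,
lower bound inclusive, with the HS upper bound (1.300) closed; ΔNBR
outside [−0.500, 1.300] is explicitly unclassified rather than clamped.

Risk maps summarise multi-year severity: the per-pixel frequency of
membership in the severe classes (MLS ∪ MHS ∪ HS) across years with
valid data, binned into five qualitative levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rasters import GeoTransform, IndexGrid

log = logging.getLogger(__name__)

UNCLASSIFIED = 0
#: Class codes in increasing severity-rank order.
CLASS_CODES = {"ERH": 1, "ERL": 2, "UN": 3, "LS": 4, "MLS": 5, "MHS": 6, "HS": 7}
CLASS_LABELS = {
    "ERH": "enhanced regrowth, high",
    "ERL": "enhanced regrowth, low",
    "UN": "unburned",
    "LS": "low severity",
    "MLS": "moderate-low severity",
    "MHS": "moderate-high severity",
    "HS": "high severity",
}
SEVERE_CLASSES = ("MLS", "MHS", "HS")
RISK_LEVELS = ("low", "moderate", "elevated", "high", "very high")
DEFAULT_RISK_BREAKS = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class SeverityScheme:
    """Ordered ΔNBR class intervals.

    ``edges`` holds the n+1 breakpoints of the n contiguous classes;
    class i covers [edges[i], edges[i+1]) except the last, which is
    closed above.
    """

    names: tuple[str, ...] = tuple(CLASS_CODES)
    edges: tuple[float, ...] = (
        -0.500, -0.250, -0.100, 0.100, 0.270, 0.440, 0.660, 1.300)

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.names) + 1:
            raise ValueError("need len(names)+1 edges")
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def lower(self) -> float:
        return self.edges[0]

    @property
    def upper(self) -> float:
        return self.edges[-1]

    def interval(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return self.edges[i], self.edges[i + 1]

    def code(self, name: str) -> int:
        return self.names.index(name) + 1

    def legend(self) -> dict:
        return {str(self.code(n)): n for n in self.names} | {
            str(UNCLASSIFIED): "unclassified"}


DEFAULT_SCHEME = SeverityScheme()


@dataclass
class SeverityMap:
    """Per-pixel severity class codes for one epoch (0 = unclassified)."""

    codes: np.ndarray
    scheme: SeverityScheme
    year: int
    transform: GeoTransform | None = None
    valid: np.ndarray | None = None  # False where input ΔNBR was nodata

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.valid is None:
            self.valid = np.ones(self.codes.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def class_mask(self, name: str) -> np.ndarray:
        return self.codes == self.scheme.code(name)


def classify_severity(dnbr: IndexGrid,
                      scheme: SeverityScheme = DEFAULT_SCHEME,
                      year: int | None = None) -> SeverityMap:
    """Classify a ΔNBR grid by interval lookup.

    Lower-inclusive / upper-exclusive boundaries; the top class's upper
    bound is inclusive so the scheme's maximum value is classified.
    Non-finite or out-of-range values map to the unclassified code.
    """
    values = dnbr.values
    finite = np.isfinite(values) & ~dnbr.mask
    n_nonfinite = int(np.sum(~np.isfinite(values) & ~dnbr.mask))
    if n_nonfinite:
        log.warning("classify_severity: %d non-finite ΔNBR values "
                    "set to unclassified", n_nonfinite)

    edges = np.asarray(scheme.edges)
    # right=False: value in [edges[i-1], edges[i]) -> bin i (lower-inclusive)
    bins = np.digitize(np.where(finite, values, np.nan), edges, right=False)
    codes = np.where(finite & (bins >= 1) & (bins <= len(scheme.names)),
                     bins, UNCLASSIFIED)
    # closed upper bound of the top class
    codes = np.where(finite & (values == scheme.upper),
                     len(scheme.names), codes)
    if year is None:
        year = int(dnbr.epoch) if str(dnbr.epoch).isdigit() else 0
    return SeverityMap(codes.astype(np.uint8), scheme, year,
                       transform=dnbr.transform, valid=finite)


def class_areas(maps: list[SeverityMap], pixel_area_ha: float) -> pd.DataFrame:
    """Per-year, per-class pixel counts and areas (ha).

    Returns a tidy frame with columns ``year, class, pixels, area_ha``
    including an ``unclassified`` row and a ``severe_sum`` row
    (MLS + MHS + HS) per year. Pixel counts are exact; areas are
    counts × ``pixel_area_ha``.
    """
    if not maps:
        raise ValueError("no severity maps given")
    shape, scheme = maps[0].shape, maps[0].scheme
    for m in maps:
        if m.shape != shape or m.scheme.edges != scheme.edges:
            raise ValueError("severity maps mix grids or schemes")

    rows = []
    for m in maps:
        counts = np.bincount(m.codes.ravel(), minlength=len(scheme.names) + 1)
        for name in scheme.names:
            n = int(counts[scheme.code(name)])
            rows.append((m.year, name, n, n * pixel_area_ha))
        n_un = int(counts[UNCLASSIFIED])
        rows.append((m.year, "unclassified", n_un, n_un * pixel_area_ha))
        n_sev = int(sum(counts[scheme.code(c)] for c in SEVERE_CLASSES))
        rows.append((m.year, "severe_sum", n_sev, n_sev * pixel_area_ha))
    return pd.DataFrame(rows, columns=["year", "class", "pixels", "area_ha"])


@dataclass
class RiskMap:
    """Multi-year severe-burn frequency and binned risk level.

    ``frequency`` is the per-pixel mean of the severe indicator over
    years with valid data (NaN where no year was valid); ``level_codes``
    index into ``levels`` (255 = nodata).
    """

    frequency: np.ndarray
    level_codes: np.ndarray
    levels: tuple[str, ...]
    breaks: tuple[float, ...]
    transform: GeoTransform | None = None

    def level_mask(self, level: str) -> np.ndarray:
        return self.level_codes == self.levels.index(level)


def risk_map(maps: list[SeverityMap],
             breaks: tuple[float, ...] = DEFAULT_RISK_BREAKS) -> RiskMap:
    """Severe-burn frequency across years, binned into five risk levels.

    For each pixel, f = (#years classified MLS/MHS/HS) / (#years with a
    valid classification); the denominator excludes nodata epochs so a
    masked year does not dilute the frequency. Default equal-width bins:
    [0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1].
    """
    if len(maps) < 2:
        raise ValueError("risk_map needs at least 2 years of severity maps")
    shape = maps[0].shape
    scheme = maps[0].scheme
    for m in maps:
        if m.shape != shape:
            raise ValueError("severity maps mix grids")
    breaks = tuple(breaks)
    if len(breaks) != len(RISK_LEVELS) - 1 or not all(
            0 < b < 1 for b in breaks) or list(breaks) != sorted(set(breaks)):
        raise ValueError("breaks must be 4 strictly increasing values in (0,1)")

    severe = np.zeros(shape, dtype=np.int64)
    valid_years = np.zeros(shape, dtype=np.int64)
    severe_codes = [scheme.code(c) for c in SEVERE_CLASSES]
    for m in maps:
        severe += np.isin(m.codes, severe_codes) & m.valid
        valid_years += m.valid

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(valid_years > 0, severe / np.maximum(valid_years, 1),
                        np.nan)
    bins = np.digitize(np.where(valid_years > 0, freq, np.nan),
                       np.asarray(breaks), right=False)
    codes = np.where(valid_years > 0, bins, 255).astype(np.uint8)
    return RiskMap(freq, codes, RISK_LEVELS, breaks,
                   transform=maps[0].transform)
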