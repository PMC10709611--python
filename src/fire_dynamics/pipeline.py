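"""End-to-end orchestration: simulate → indices → severity → risk → trends.

A :class:`PipelineConfig` (loadable from YAML/JSON) fixes every knob:
scene parameters, severity-scheme override, risk-bin breaks, GPP scale
choice, significance level and seed. :func:`run_pipeline` writes all
stage artifacts under an output directory and returns a
:class:`RunReport`; identical config + seed gives identical outputs
(byte-stable CSVs, value-stable rasters).

Annual-series tables use the plain format ``year,variable,value`` — one
row per (year, variable) pair.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices
from .rasters import write_byte_grid, write_index, write_stack
from .severity import (DEFAULT_RISK_BREAKS, DEFAULT_SCHEME, SeverityScheme,
                       class_areas, classify_severity, risk_map)
from .synthetic import BurnEvent, SceneConfig, generate_scene
from .trends import AnnualSeries, pca, pearson_matrix, trend_table

log = logging.getLogger(__name__)

SERIES_HEADER = ["year", "variable", "value"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: Path
    scene: SceneConfig = field(default_factory=SceneConfig)
    risk_breaks: tuple[float, ...] = DEFAULT_RISK_BREAKS
    gpp_scale: float = indices.GPP_SCALE_DEFAULT
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def load_config(path, out_dir=None) -> PipelineConfig:
    """Load a YAML/JSON config document.

    Recognised top-level keys: ``out_dir``, ``scene`` (SceneConfig
    fields, with ``burn_events`` as a list of mappings), ``risk_breaks``,
    ``gpp_scale``, ``alpha``. Unknown keys are an error, so typos fail
    fast rather than silently running defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or {}
    known = {"out_dir", "scene", "risk_breaks", "gpp_scale", "alpha"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    scene_doc = dict(doc.get("scene", {}))
    scene_fields = {f.name for f in dataclasses.fields(SceneConfig)}
    bad = set(scene_doc) - scene_fields
    if bad:
        raise ValueError(f"unknown scene keys: {sorted(bad)}")
    events = tuple(BurnEvent(**ev) for ev in scene_doc.pop("burn_events", []))
    if "years" in scene_doc:
        scene_doc["years"] = tuple(scene_doc["years"])
    scene = SceneConfig(burn_events=events, **scene_doc)

    return PipelineConfig(
        out_dir=Path(out_dir or doc.get("out_dir", "fire_dynamics_out")),
        scene=scene,
        risk_breaks=tuple(doc.get("risk_breaks", DEFAULT_RISK_BREAKS)),
        gpp_scale=float(doc.get("gpp_scale", indices.GPP_SCALE_DEFAULT)),
        alpha=float(doc.get("alpha", 0.05)),
    )


def write_series_csv(path, series_set: dict[str, AnnualSeries] |
                     list[AnnualSeries]) -> None:
    """Write annual series in the tidy ``year,variable,value`` format."""
    if isinstance(series_set, dict):
        series_set = list(series_set.values())
    rows = [(int(y), s.name, float(v))
            for s in series_set for y, v in zip(s.years, s.values)]
    df = pd.DataFrame(rows, columns=SERIES_HEADER)
    df.to_csv(path, index=False, float_format="%.10g")


def read_series_csv(path) -> dict[str, AnnualSeries]:
    """Read a ``year,variable,value`` CSV into AnnualSeries per variable.

    Duplicate (year, variable) pairs and non-numeric values are errors
    naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"year": "Int64", "variable": str})
    if list(df.columns) != SERIES_HEADER:
        raise ValueError(
            f"{path}: expected header {','.join(SERIES_HEADER)}, "
            f"got {','.join(df.columns)}")
    if df.empty:
        return {}
    numeric = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[numeric.isna() & df["value"].notna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric value at row {bad[0] + 2}")
    if df["year"].isna().any():
        raise ValueError(f"{path}: missing/non-integer year")
    dup = df.duplicated(subset=["year", "variable"])
    if dup.any():
        row = df.index[dup][0]
        raise ValueError(
            f"{path}: duplicate (year, variable) at row {row + 2}: "
            f"{df.loc[row, 'year']},{df.loc[row, 'variable']}")
    out = {}
    for name, grp in df.groupby("variable", sort=True):
        grp = grp.sort_values("year")
        out[name] = AnnualSeries(grp["year"].to_numpy(dtype=np.int64),
                                 numeric[grp.index].to_numpy(), str(name))
    return out


@dataclass
class StageRecord:
    stage: str
    outputs: list[str]
    counts: dict
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    """Machine-readable record of a pipeline run."""

    config: dict
    stages: list[StageRecord]
    trend_table: list[dict]
    class_areas_summary: dict
    risk_level_counts: dict
    pettitt_change_years: dict

    def to_json(self) -> str:
        doc = {
            "config": self.config,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "trend_table": self.trend_table,
            "class_areas_summary": self.class_areas_summary,
            "risk_level_counts": self.risk_level_counts,
            "pettitt_change_years": self.pettitt_change_years,
        }
        return json.dumps(doc, indent=2, default=str)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(config.out_dir)
    d["scene"]["scheme"] = {"names": list(config.scene.scheme.names),
                            "edges": list(config.scene.scheme.edges)}
    return d


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage on a synthetic scene and write all artifacts.

    Layout under ``config.out_dir``::

        stacks/pre_<year>.tif, stacks/post_<year>.tif
        indices/dnbr_<year>.tif
        severity/severity_<year>.tif
        severity/class_areas.csv
        risk/risk_frequency.tif, risk/risk_level.tif
        series/annual_series.csv
        trends/trend_tests.csv, trends/correlation.csv,
        trends/pca_loadings.csv, trends/pca_scores.csv
        report.json
    """
    cfg_doc = _config_dict(config)
    for key, value in sorted(cfg_doc.items()):
        log.info("config %s = %s", key, value)
    out = config.out_dir
    stages: list[StageRecord] = []

    # simulate
    pre_stacks, post_stacks, truth = generate_scene(config.scene)
    stacks_dir = out / "stacks"
    stacks_dir.mkdir(parents=True, exist_ok=True)
    stack_files = []
    for year in config.scene.years:
        for tag, stack in (("pre", pre_stacks[year]), ("post", post_stacks[year])):
            p = stacks_dir / f"{tag}_{year}.tif"
            write_stack(p, stack)
            stack_files.append(str(p))
    stages.append(StageRecord("simulate", stack_files,
                              {"years": len(config.scene.years),
                               "pixels": int(np.prod(config.scene.shape)),
                               "burn_events": len(config.scene.burn_events)}))

    # indices (ΔNBR per year)
    idx_dir = out / "indices"
    idx_dir.mkdir(exist_ok=True)
    dnbr_by_year = {}
    idx_files = []
    for year in config.scene.years:
        d = indices.delta_nbr(indices.nbr(pre_stacks[year]),
                              indices.nbr(post_stacks[year]))
        dnbr_by_year[year] = d
        p = idx_dir / f"dnbr_{year}.tif"
        write_index(p, d)
        idx_files.append(str(p))
    stages.append(StageRecord("indices", idx_files,
                              {"grids": len(idx_files)}))

    # severity
    sev_dir = out / "severity"
    sev_dir.mkdir(exist_ok=True)
    sev_maps = []
    sev_files = []
    for year in config.scene.years:
        m = classify_severity(dnbr_by_year[year], config.scene.scheme,
                              year=year)
        sev_maps.append(m)
        p = sev_dir / f"severity_{year}.tif"
        write_byte_grid(p, m.codes, config.scene.transform,
                        config.scene.scheme.legend())
        sev_files.append(str(p))
    areas = class_areas(sev_maps, config.scene.pixel_area_ha)
    areas_path = sev_dir / "class_areas.csv"
    areas.to_csv(areas_path, index=False, float_format="%.6g")
    sev_files.append(str(areas_path))
    stages.append(StageRecord("severity", sev_files,
                              {"maps": len(sev_maps),
                               "rows": len(areas)}))

    # risk
    risk_dir = out / "risk"
    risk_dir.mkdir(exist_ok=True)
    risk = risk_map(sev_maps, breaks=config.risk_breaks)
    from .rasters import IndexGrid  # local import avoids cycle at top
    freq_path = risk_dir / "risk_frequency.tif"
    write_index(freq_path, IndexGrid(risk.frequency, "risk_frequency",
                                     transform=config.scene.transform))
    level_path = risk_dir / "risk_level.tif"
    write_byte_grid(level_path, risk.level_codes, config.scene.transform,
                    {str(i): lv for i, lv in enumerate(risk.levels)},
                    nodata_code=255)
    level_counts = {lv: int(np.sum(risk.level_codes == i))
                    for i, lv in enumerate(risk.levels)}
    stages.append(StageRecord("risk", [str(freq_path), str(level_path)],
                              {"levels": level_counts}))

    # series + trends
    series_dir = out / "series"
    series_dir.mkdir(exist_ok=True)
    from .synthetic import generate_annual_series
    series = generate_annual_series(config.scene)
    series_path = series_dir / "annual_series.csv"
    write_series_csv(series_path, series)

    trends_dir = out / "trends"
    trends_dir.mkdir(exist_ok=True)
    series_list = list(series.values())
    table = trend_table(series_list, alpha=config.alpha)
    table_path = trends_dir / "trend_tests.csv"
    table.to_csv(table_path, index=False, float_format="%.17g")
    corr = pearson_matrix(series_list)
    corr_path = trends_dir / "correlation.csv"
    corr.to_csv(corr_path, float_format="%.10g")
    from .trends import align_series
    pca_res = pca(align_series(series_list))
    loadings_path = trends_dir / "pca_loadings.csv"
    scores_path = trends_dir / "pca_scores.csv"
    pca_res.loadings.to_csv(loadings_path, float_format="%.10g")
    pca_res.scores.to_csv(scores_path, float_format="%.10g")
    stages.append(StageRecord(
        "trends",
        [str(series_path), str(table_path), str(corr_path),
         str(loadings_path), str(scores_path)],
        {"variables": len(series_list), "years": len(series_list[0])}))

    change_years = {
        r["variable"]: r["change_year"]
        for r in table.to_dict("records")
        if r["test"] == "pettitt" and r["change_year"] != ""
    }
    severe = areas[areas["class"] == "severe_sum"]
    report = RunReport(
        config=cfg_doc,
        stages=stages,
        trend_table=table.to_dict("records"),
        class_areas_summary={
            "classes": sorted(areas["class"].unique()),
            "severe_area_ha_by_year": {
                int(y): float(a) for y, a in zip(severe["year"],
                                                 severe["area_ha"])},
        },
        risk_level_counts=level_counts,
        pettitt_change_years=change_years,
    )
    (out / "report.json").write_text(report.to_json())
    return report
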