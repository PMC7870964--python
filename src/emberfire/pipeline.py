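"""End-to-end pipeline wiring and its serializable configuration.

A single config drives: simulate (synthetic world) -> featurize -> split ->
per-region greedy driver search -> metric reports -> mosaic of minimal
regional models -> temperature / vapour-pressure sensitivity. Every stage
writes artifacts under ``out_dir`` along with a manifest echoing the config
and seed; identical configs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from . import grid as gr
from . import metrics as mt
from . import selection as sel
from . import synth
from .model import TrainConfig, predict_field
from .features import FeatureSpec, assemble

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """Raised when the pipeline configuration is invalid; names the field."""


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    world: synth.WorldConfig = field(default_factory=synth.WorldConfig)
    niche: synth.NicheParams = field(default_factory=synth.NicheParams)
    candidates: tuple = ("ts", "pr", "gppl1", "cld", "vp", "pop")
    train: TrainConfig = field(default_factory=TrainConfig)
    weights: mt.MetricWeights = field(default_factory=mt.MetricWeights)
    burnable_threshold: float = 0.30
    area_weighting: bool = True
    delta_t: float = 1.0
    vp_factor: float = 1.01

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "out_dir" not in d:
            raise ConfigError("missing required config field: out_dir")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        try:
            if "world" in d:
                w = dict(d["world"])
                if "regions" in w:
                    w["regions"] = tuple(
                        (c, tuple(a), tuple(b)) for c, a, b in w["regions"])
                d["world"] = synth.WorldConfig(**w)
            if "niche" in d:
                d["niche"] = synth.NicheParams(**d["niche"])
            if "train" in d:
                t = dict(d["train"])
                if t.get("test_years") is not None:
                    t["test_years"] = tuple(t["test_years"])
                d["train"] = TrainConfig(**t)
            if "weights" in d:
                d["weights"] = mt.MetricWeights(**d["weights"])
            if "candidates" in d:
                d["candidates"] = tuple(d["candidates"])
        except TypeError as err:
            raise ConfigError(str(err)) from err
        cfg = cls(**d)
        bad = [c for c in cfg.candidates if c not in ft.KNOWN_DRIVERS]
        if bad:
            raise ConfigError(f"candidates: unknown driver codes {bad}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _effective_world(config: PipelineConfig) -> synth.WorldConfig:
    # the pipeline's global seed overrides the world's own
    return dataclasses.replace(config.world, seed=config.seed)


def simulate(config: PipelineConfig, out: Path) -> synth.World:
    """Generate the synthetic world and write its fields plus a manifest."""
    world = synth.generate_world(_effective_world(config), config.niche)
    out.mkdir(parents=True, exist_ok=True)
    gr.write_gridded(world.drivers, out / "drivers.nc")
    gr.write_gridded(world.ba, out / "ba.nc")
    veg_fields = {
        f"veg_frac_{t}": world.ba.like(
            np.repeat(world.veg.fractions[i][None], world.ba.n_time, axis=0),
            f"veg_frac_{t}")
        for i, t in enumerate(world.veg.types)}
    gr.write_gridded(veg_fields, out / "veg.nc")
    write_manifest(config, out, stage="simulate")
    return world


def featurize(config: PipelineConfig, world: synth.World) -> dict:
    """Assemble one feature matrix per region over the burnable mask."""
    spec = FeatureSpec(tuple(config.candidates))
    mask = gr.burnable_mask(world.veg, config.burnable_threshold)
    out = {}
    for code in world.regions.region_codes():
        rmask = mask & world.regions.mask(code)
        df = assemble(spec, world.drivers, world.veg, rmask, world.ba,
                      world.regions)
        out[code] = (df, rmask)
    return out


def _region_data(config: PipelineConfig, world: synth.World) -> list:
    out = []
    for code, (df, rmask) in featurize(config, world).items():
        if len(df) == 0:
            logger.warning("region %s: no usable samples", code)
            continue
        train_cfg = dataclasses.replace(config.train, seed=config.seed)
        from .model import split_samples
        split = split_samples(df, train_cfg)
        out.append(sel.RegionData(code, df, world.ba, rmask, split))
    return out


def write_manifest(config: PipelineConfig, out: Path, stage: str,
                   extra: dict | None = None) -> None:
    manifest = {"stage": stage, "seed": config.seed,
                "config_hash": config.config_hash(),
                "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Returns a dict with the per-region catalogs, chosen models, the global
    mosaic report, and the sensitivity tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = simulate(config, out)
    train_cfg = dataclasses.replace(config.train, seed=config.seed)

    catalogs = {}
    chosen = {}
    metric_rows = []
    regional_preds = []
    for data in _region_data(config, world):
        catalog = sel.search_models(data, config.candidates, train_cfg,
                                    config.weights, config.area_weighting)
        catalogs[data.region] = catalog
        best = catalog.best()
        minimal = sel.minimal_model(catalog)
        chosen[data.region] = {"best": best, "minimal": minimal, "data": data}
        for kind, entry in (("best", best), ("minimal", minimal)):
            metric_rows.append(_metric_row(data.region, kind, entry))
        pred = predict_field(minimal.model, data.df, world.grid,
                             world.ba.years, world.ba.months)
        regional_preds.append((data.mask, pred))
        catalog.to_frame().to_csv(out / f"catalog_{data.region}.csv",
                                  index=False, float_format=CSV_FLOAT_FORMAT)
        minimal.model.save(out / f"model_minimal_{data.region}.json")
        best.model.save(out / f"model_best_{data.region}.json")

    # global mosaic of the minimal regional models
    mosaic_field = sel.mosaic(regional_preds, world.grid, world.ba.years,
                              world.ba.months)
    gr.write_gridded(mosaic_field, out / "ba_mosaic.nc")
    global_mask = np.zeros((world.grid.n_lat, world.grid.n_lon), dtype=bool)
    for mask, _ in regional_preds:
        global_mask |= mask
    if regional_preds:
        g_report = mt.compute_metrics(mosaic_field, world.ba, global_mask,
                                      config.weights, config.area_weighting)
        metric_rows.append(_metric_row(
            "GLOBAL", "mosaic", sel.CatalogEntry(
                ("mosaic",), None, g_report,
                mt.aggregate_score(g_report, config.weights))))
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out / "metrics.csv", index=False,
                      float_format=CSV_FLOAT_FORMAT)

    # temperature and vapour-pressure sensitivity from per-region models
    sens_tables = {}
    for variable, runner in (("ts", "additive"), ("vp", "multiplicative")):
        smaps = []
        for region, info in chosen.items():
            entry = _model_with(catalogs[region], variable)
            if entry is None:
                logger.warning("region %s: no evaluated model uses %s; "
                               "skipped in sensitivity", region, variable)
                continue
            data = info["data"]
            if runner == "additive":
                smap = sel.temperature_sensitivity(entry.model, data.df,
                                                   world.grid, config.delta_t)
            else:
                smap = sel.multiplicative_sensitivity(entry.model, data.df,
                                                      world.grid, variable,
                                                      config.vp_factor)
            smaps.append((data.mask, smap))
        if not smaps:
            continue
        S = np.full((world.grid.n_lat, world.grid.n_lon), np.nan)
        S_pct = np.full_like(S, np.nan)
        baseline = np.full_like(S, np.nan)
        for mask, smap in smaps:
            S[mask] = smap.S[mask]
            S_pct[mask] = smap.S_pct[mask]
            baseline[mask] = smap.baseline[mask]
        combined = sel.SensitivityMap(world.grid, S, S_pct,
                                      np.full((1,) + S.shape, np.nan),
                                      baseline, variable,
                                      smaps[0][1].delta)
        table = sel.aggregate_sensitivity_by_vegtype(combined, world.veg)
        table.to_csv(out / f"sensitivity_{variable}.csv", index=False,
                     float_format=CSV_FLOAT_FORMAT)
        years1, months1 = world.ba.years[:1], world.ba.months[:1]
        gr.write_gridded(
            {f"S_{variable}": gr.MonthlyField(world.grid, S[None], years1,
                                              months1, f"S_{variable}"),
             f"S_pct_{variable}": gr.MonthlyField(world.grid, S_pct[None],
                                                  years1, months1,
                                                  f"S_pct_{variable}")},
            out / f"sensitivity_{variable}.nc")
        sens_tables[variable] = table

    write_manifest(config, out, stage="run",
                   extra={"regions": sorted(catalogs)})
    return {"world": world, "catalogs": catalogs, "chosen": chosen,
            "mosaic": mosaic_field, "metrics": metrics_df,
            "sensitivity": sens_tables}


def _model_with(catalog: sel.ModelCatalog, variable: str):
    """Best-scoring catalog entry whose drivers include ``variable``
    (the fallback rule when the chosen model dropped it)."""
    with_var = [e for e in catalog.entries if variable in e.drivers]
    if not with_var:
        return None
    return max(with_var, key=lambda e: (e.score, -len(e.drivers)))


def _metric_row(region: str, kind: str, entry) -> dict:
    r = entry.report
    return {"region": region, "model": kind, "r_T": r.r_T, "r_IA": r.r_IA,
            "r_S": r.r_S, "BA": r.BA_pred_total, "BA_obs": r.BA_obs_total,
            "LT": r.LT_pred, "LT_obs": r.LT_obs, "r_An": r.r_An,
            "r_BA": r.r_BA, "r_I": r.r_I, "P": entry.score,
            "variables": ", ".join(entry.drivers)}
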