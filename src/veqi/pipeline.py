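"""End-to-end orchestration: simulate -> functions -> veqi -> trends -> attribute.

Every stage reads its inputs from, and writes its outputs to, a single
working directory, so stages can be re-run individually or chained. A run
manifest records the configuration hash, per-stage output checksums and all
diagnostic warnings (water-balance floors, Mann-Kendall tie pixels,
driver-table gaps), making byte-level reproducibility checkable.

Internally VEQI is carried as a fraction in [0, 1]; reports render percent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .attribution import attribute_scene, regional_summary
from .ecofunctions import (
    casa_npp,
    habitat_quality,
    soil_retention,
    water_conservation,
    water_scalar_from_sm,
)
from .errors import ConfigurationError, DependencyError
from .index import compute_veqi, critic_weights, fvc_from_evi, integrate_functions, minmax_normalize
from .io import grids_to_dataset, read_raster_stack, write_raster_stack
from .synthetic import LANDUSE_CODES, SceneConfig, generate_scene, scene_from_config_dict
from .trends import trend_map

STAGES = ("simulate", "functions", "veqi", "trends", "attribute")

STAGE_OUTPUTS = {
    "simulate": ("scene.nc", "truth.nc"),
    "functions": ("functions.nc",),
    "veqi": ("veqi.nc", "weights.json"),
    "trends": ("trends.nc", "trend_summary.csv"),
    "attribute": ("attribution.nc", "climate_model.json", "regional_summary.csv"),
}


def _default_function_params() -> dict:
    return {
        "eps_max": 0.389,
        "vi_min": 0.05,
        "vi_max": 0.95,
        "k_factor": 0.03,
        "cell_size": 500.0,
        "slope_length": 100.0,
        "c_alpha": 2.0,
        "runoff_coef": {"water": 0.05, "forest": 0.1, "grass": 0.2, "crop": 0.3, "urban": 0.6},
        "hq": {
            "half_sat": 0.5,
            "z_exp": 2.5,
            "suitability": {"water": 0.6, "forest": 1.0, "grass": 0.8, "crop": 0.4, "urban": 0.05},
            "threats": {
                "crop": {"weight": 0.5, "max_dist": 4.0, "decay": "linear"},
                "urban": {"weight": 1.0, "max_dist": 8.0, "decay": "exponential"},
            },
            "sensitivity": {
                "forest": {"crop": 0.6, "urban": 0.8},
                "grass": {"crop": 0.5, "urban": 0.7},
                "crop": {"crop": 0.0, "urban": 0.4},
                "water": {"crop": 0.3, "urban": 0.5},
                "urban": {"crop": 0.0, "urban": 0.0},
            },
        },
    }


@dataclass
class PipelineConfig:
    """Everything one run needs: scene, stage toggles and parameter blocks."""

    workdir: str = "veqi_run"
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    function_params: dict = field(default_factory=_default_function_params)
    fvc_percentiles: tuple[float, float] = (0.5, 99.5)
    z_threshold: float = 1.96
    min_years_for_hurst: int = 10
    split_fraction: float = 0.5
    hyperparams: dict = field(default_factory=dict)
    mask_water: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = dataclasses.asdict(self.scene)
        d["scene"]["climate_params"] = {k: dataclasses.asdict(v) for k, v in self.scene.climate_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d and not isinstance(d["scene"], SceneConfig):
            d["scene"] = scene_from_config_dict(d["scene"])
        if "fvc_percentiles" in d:
            d["fvc_percentiles"] = tuple(d["fvc_percentiles"])
        fp = _default_function_params()
        _deep_update(fp, d.get("function_params", {}))
        d["function_params"] = fp
        stages = {s: True for s in STAGES}
        stages.update(d.get("stages", {}))
        d["stages"] = stages
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    def config_hash(self) -> str:
        d = _plain(self.to_dict())
        d.pop("workdir", None)  # output location is not part of the science
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class RunManifest:
    config_hash: str
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: dict[str, int] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    timestamp: str = ""

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _codes_by_name(mapping: dict) -> dict:
    """Translate class-name keys to integer land-use codes."""
    out = {}
    for key, val in mapping.items():
        code = LANDUSE_CODES[key] if isinstance(key, str) else int(key)
        out[code] = val
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, workdir: str) -> dict[str, int]:
    scene = generate_scene(config.scene)
    write_raster_stack(scene.to_dataset(), os.path.join(workdir, "scene.nc"))
    write_raster_stack(scene.truth.to_dataset(), os.path.join(workdir, "truth.nc"))
    return {}


def _load_scene(workdir: str):
    path = os.path.join(workdir, "scene.nc")
    if not os.path.exists(path):
        raise DependencyError("stage needs scene.nc; run the simulate stage first")
    return read_raster_stack(path, expected_dims=("time", "y", "x"))


def _valid_mask(config: PipelineConfig, scene) -> np.ndarray:
    landuse = scene["landuse"].values
    mask = np.ones(landuse.shape, dtype=bool)
    if config.mask_water:
        mask &= landuse != LANDUSE_CODES["water"]
    return mask


def stage_functions(config: PipelineConfig, workdir: str) -> dict[str, int]:
    scene = _load_scene(workdir)
    p = config.function_params
    mpy = int(scene.attrs.get("months_per_year", 12))
    evi = scene["evi"].values
    landuse = scene["landuse"].values
    dem = scene["dem"].values

    w = water_scalar_from_sm(scene["sm"].values)
    npp = casa_npp(evi, scene["tem"].values, scene["ssr"].values, w,
                   eps_max=p["eps_max"], vi_min=p["vi_min"], vi_max=p["vi_max"],
                   months_per_year=mpy)

    n_years = evi.shape[0] // mpy
    pre_y = scene["pre"].values.reshape(n_years, mpy, *evi.shape[1:]).sum(axis=1)
    et_y = scene["et"].values.reshape(n_years, mpy, *evi.shape[1:]).sum(axis=1)
    wc, floored = water_conservation(pre_y, et_y, landuse, _codes_by_name(p["runoff_coef"]))

    lo, hi = config.fvc_percentiles
    fvc = fvc_from_evi(evi, lo, hi, months_per_year=mpy)
    sr = soil_retention(scene["pre"].values, dem, fvc, p["k_factor"],
                        cell_size=p["cell_size"], slope_length=p["slope_length"],
                        c_alpha=p["c_alpha"], months_per_year=mpy)

    hq_cfg = p["hq"]
    hq2d = habitat_quality(
        landuse,
        threat_params=_codes_by_name(hq_cfg["threats"]),
        sensitivity={c: _codes_by_name(v) for c, v in _codes_by_name(hq_cfg["sensitivity"]).items()},
        suitability=_codes_by_name(hq_cfg["suitability"]),
        half_sat=hq_cfg["half_sat"], z_exp=hq_cfg["z_exp"],
    )
    hq = np.broadcast_to(hq2d, npp.shape).copy()

    ds = grids_to_dataset({"npp": npp, "wc": wc, "sr": sr, "hq": hq, "fvc": fvc,
                           "wc_floored": floored.astype("i1")})
    write_raster_stack(ds, os.path.join(workdir, "functions.nc"))
    return {"wc_floor_pixels": int(floored.sum())}


def stage_veqi(config: PipelineConfig, workdir: str) -> dict[str, int]:
    path = os.path.join(workdir, "functions.nc")
    if not os.path.exists(path):
        raise DependencyError("stage needs functions.nc; run the functions stage first")
    funcs = read_raster_stack(path, expected_dims=("year", "y", "x"))
    scene = _load_scene(workdir)
    valid = _valid_mask(config, scene)

    normalized = {name: minmax_normalize(np.where(valid[None], funcs[name].values, np.nan))
                  for name in ("npp", "wc", "sr", "hq")}
    rows = np.column_stack([normalized[n][:, valid].ravel() for n in ("npp", "wc", "sr", "hq")])
    w_func = critic_weights(rows, names=("npp", "wc", "sr", "hq"))
    efc = integrate_functions(normalized, w_func)
    fvc = funcs["fvc"].values
    veqi, w_couple = compute_veqi(np.where(valid[None], fvc, np.nan), efc, valid_mask=valid)

    ds = grids_to_dataset({"veqi": veqi / 100.0, "efc": efc, "fvc": fvc,
                           **{f"norm_{k}": v for k, v in normalized.items()},
                           "valid_mask": valid.astype("i1")})
    write_raster_stack(ds, os.path.join(workdir, "veqi.nc"))
    with open(os.path.join(workdir, "weights.json"), "w") as fh:
        json.dump({"functions": w_func.as_dict(), "coupling": w_couple.as_dict()}, fh, indent=2)
    return {}


def _load_veqi(workdir: str):
    path = os.path.join(workdir, "veqi.nc")
    if not os.path.exists(path):
        raise DependencyError("stage needs veqi.nc; run the veqi stage first")
    return read_raster_stack(path, expected_dims=("year", "y", "x"))


def stage_trends(config: PipelineConfig, workdir: str) -> dict[str, int]:
    ds = _load_veqi(workdir)
    valid = ds["valid_mask"].values.astype(bool)
    result = trend_map(ds["veqi"].values * 100.0, valid_mask=valid,
                       min_years_for_hurst=config.min_years_for_hurst,
                       z_threshold=config.z_threshold)
    out = grids_to_dataset({"sen_slope": result.sen_slope, "mk_s": result.mk_s,
                            "mk_z": result.mk_z, "hurst": result.hurst,
                            "future_code": result.future_code.astype("i1"),
                            "gap_flag": result.gap_flag.astype("i1")})
    write_raster_stack(out, os.path.join(workdir, "trends.nc"))
    result.summary.to_csv(os.path.join(workdir, "trend_summary.csv"), index=False)
    ties = int(np.sum((result.mk_z == 0) & valid))
    return {"future_code_gap_pixels": int(result.gap_flag.sum()), "mk_tie_pixels": ties}


def stage_attribute(config: PipelineConfig, workdir: str) -> dict[str, int]:
    ds = _load_veqi(workdir)
    scene = _load_scene(workdir)
    valid = ds["valid_mask"].values.astype(bool)
    reserve = scene["reserve_mask"].values.astype(bool) & valid
    result = attribute_scene(ds["veqi"].values, scene, reserve, valid_mask=valid,
                             seed=config.seed, split_fraction=config.split_fraction,
                             hyperparams=config.hyperparams or None)
    out = grids_to_dataset({
        "veqi_c": result.veqi_c, "veqi_h": result.veqi_h,
        "sen_total": result.sen_total, "sen_c": result.sen_c, "sen_h": result.sen_h,
        "z_total": result.z_total, "z_c": result.z_c, "z_h": result.z_h,
        "influence_climate": result.influence_climate.astype("i1"),
        "influence_human": result.influence_human.astype("i1"),
        "driver": result.driver.astype("i1"),
        "contrib_climate": result.contrib_climate,
        "contrib_human": result.contrib_human,
        "table_gap": result.table_gap.astype("i1"),
    })
    write_raster_stack(out, os.path.join(workdir, "attribution.nc"))
    with open(os.path.join(workdir, "climate_model.json"), "w") as fh:
        json.dump(result.report.as_dict(), fh, indent=2)
    regions = np.where(valid, "scene", "masked")
    summary = regional_summary(result, valid, regions)
    summary.to_csv(os.path.join(workdir, "regional_summary.csv"), index=False)
    return {"driver_table_gap_pixels": int(result.table_gap.sum())}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "functions": stage_functions,
    "veqi": stage_veqi,
    "trends": stage_trends,
    "attribute": stage_attribute,
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute enabled stages in dependency order and write the manifest.

    A disabled stage whose outputs already exist is skipped (its checksums
    are still recorded); a disabled stage with missing outputs raises a
    dependency error when a later stage needs them.
    """
    workdir = config.workdir
    os.makedirs(workdir, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    config.to_yaml(os.path.join(workdir, "config.yaml"))
    for stage in STAGES:
        outputs = [os.path.join(workdir, f) for f in STAGE_OUTPUTS[stage]]
        if not config.stages.get(stage, True):
            # a later stage that needs this stage's missing outputs raises
            # its own dependency error naming the input
            manifest.skipped.append(stage)
            for p in outputs:
                if os.path.exists(p):
                    manifest.checksums[os.path.basename(p)] = _sha256(p)
            continue
        t0 = time.perf_counter()
        warnings = _STAGE_FUNCS[stage](config, workdir)
        manifest.stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        manifest.warnings.update(warnings)
        for p in outputs:
            manifest.checksums[os.path.basename(p)] = _sha256(p)
    manifest.write(os.path.join(workdir, "manifest.json"))
    return manifest


def report_tables(workdir: str) -> dict:
    """Collect the headline numbers of a finished run into one dict."""
    out = {}
    veqi_path = os.path.join(workdir, "veqi.nc")
    if os.path.exists(veqi_path):
        ds = read_raster_stack(veqi_path)
        valid = ds["valid_mask"].values.astype(bool)
        series = ds["veqi"].values[:, valid].mean(axis=1) * 100.0
        out["mean_veqi_pct_by_year"] = [round(float(v), 3) for v in series]
    trends_path = os.path.join(workdir, "trends.nc")
    if os.path.exists(trends_path):
        import pandas as pd

        out["trend_summary"] = pd.read_csv(os.path.join(workdir, "trend_summary.csv")).to_dict("records")
        ds = read_raster_stack(trends_path)
        hurst = ds["hurst"].values
        out["mean_hurst"] = float(np.nanmean(hurst))
    model_path = os.path.join(workdir, "climate_model.json")
    if os.path.exists(model_path):
        with open(model_path) as fh:
            out["climate_model"] = json.load(fh)
    regional_path = os.path.join(workdir, "regional_summary.csv")
    if os.path.exists(regional_path):
        import pandas as pd

        out["regional_summary"] = pd.read_csv(regional_path).to_dict("records")
    return out
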