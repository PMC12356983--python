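"""End-to-end pipeline: scenes -> channel maps -> patches -> contrasts -> tests.

A validated configuration lists the input scenes (files or synthetic
generator specs with environment labels), the receptive-field sizes, the
window mode, the illuminant for reflectance data, and the statistical
transform. ``run_pipeline`` is deterministic for a fixed configuration and
emits tidy CSV tables plus a YAML run log; every output embeds the
configuration hash so any number in a report is regenerable.

Channel-to-field assignment follows the physiology: melanopsin and the two
ipRGC codifications are pooled by ipRGC-sized fields (parafoveal 1.37 deg,
with the peripheral 2.4 deg size computed alongside for melanopsin),
photopic luminance by 0.36-deg parasol fields, and local radiance by the
ipRGC field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import stats as mstats
from .contrast import between_patch_contrast, contrast_excitation_independence
from .errors import (
    ConfigError,
    DegenerateDataError,
    PatchLayoutError,
    TransformError,
)
from .excitation import compute_all_channels
from .receptive_field import (
    ReceptiveFieldSpec,
    local_excitation,
    local_radiance,
    tile_patches,
)
from .sceneio import read_scene
from .spectra import HyperspectralScene, apply_illuminant, parse_illuminant, resample_scene
from .synthetic import SceneGeneratorSpec, generate_scene


class SyntheticParams(BaseModel):
    """Generator parameters for a synthetic scene entry."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    height: int = 160
    width: int = 160
    mean_reflectance: float | None = None
    reflectance_sd: float | None = None
    spatial_correlation: Literal["white", "one_over_f"] = "one_over_f"


class SceneEntry(BaseModel):
    """One input scene: either a container path or a synthetic spec."""

    model_config = ConfigDict(extra="forbid")

    environment: Literal["natural", "human_made"]
    path: str | None = None
    quantity: Literal["radiance", "reflectance"] = "radiance"
    pixels_per_degree: float | None = None
    scene_id: str | None = None
    synthetic: SyntheticParams | None = None

    @field_validator("synthetic")
    @classmethod
    def _path_xor_synthetic(cls, v, info):
        if v is not None and info.data.get("path") is not None:
            raise ValueError("a scene entry is either a path or synthetic, not both")
        return v


class PipelineConfig(BaseModel):
    """Validated end-to-end run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    scenes: list[SceneEntry]
    pixels_per_degree: float = 28.0
    iprgc_field_deg: float = 1.37
    periphery_field_deg: float = 2.4
    luminance_field_deg: float = 0.36
    window: Literal["raised_cosine", "literal_cosine"] = "raised_cosine"
    tiling: str = "grid"  # "grid" or "jitter:<seed>"
    illuminant: str = "EES"
    nrd_illuminants: list[str] = ["D:25000", "D:6500", "D:4000", "EES"]
    transform: Literal["none", "log"] = "log"
    output_dir: str | None = None
    seed: int = 0

    @field_validator("scenes")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("config lists no scenes")
        return v

    @field_validator("tiling")
    @classmethod
    def _tiling_format(cls, v):
        if v != "grid" and not v.startswith("jitter:"):
            raise ValueError(f"tiling must be 'grid' or 'jitter:<seed>', got {v!r}")
        if v.startswith("jitter:"):
            int(v.split(":", 1)[1])
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
            return cls.model_validate(raw)
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def config_hash(self) -> str:
        # output_dir does not influence any computed number
        payload = self.model_dump()
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Tidy outputs of one run."""

    records: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    nrd_table: pd.DataFrame
    independence: pd.DataFrame
    log: dict = field(default_factory=dict)


def _materialize(entry: SceneEntry, config: PipelineConfig) -> HyperspectralScene:
    ppd = entry.pixels_per_degree or config.pixels_per_degree
    if entry.synthetic is not None:
        spec = SceneGeneratorSpec(
            environment=entry.environment,
            height=entry.synthetic.height,
            width=entry.synthetic.width,
            pixels_per_degree=ppd,
            mean_reflectance=entry.synthetic.mean_reflectance,
            reflectance_sd=entry.synthetic.reflectance_sd,
            spatial_correlation=entry.synthetic.spatial_correlation,
            seed=entry.synthetic.seed,
            scene_id=entry.scene_id or "",
        )
        return generate_scene(spec)
    if entry.path is None:
        raise ConfigError("scene entry has neither a path nor a synthetic spec")
    return read_scene(
        entry.path, entry.quantity, entry.environment, ppd, scene_id=entry.scene_id
    )


def _jitter_seed(config: PipelineConfig) -> int | None:
    if config.tiling.startswith("jitter:"):
        return int(config.tiling.split(":", 1)[1])
    return None


def _field_assignment(config: PipelineConfig) -> dict[str, list[float]]:
    return {
        "Mel": [config.iprgc_field_deg, config.periphery_field_deg],
        "ipRGC1": [config.iprgc_field_deg],
        "ipRGC2": [config.iprgc_field_deg],
        "Lum": [config.luminance_field_deg],
        "Rad": [config.iprgc_field_deg],
    }


def _safe_compare(a, b, transform, metric, **kw):
    """compare_groups with a fall-back to no transform when log is undefined."""
    try:
        return mstats.compare_groups(a, b, transform=transform, metric=metric, **kw), transform
    except TransformError:
        return mstats.compare_groups(a, b, transform="none", metric=metric, **kw), "none"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write CSV reports."""
    jitter = _jitter_seed(config)
    assignment = _field_assignment(config)
    illuminant = parse_illuminant(config.illuminant)

    reflectance_scenes: list[HyperspectralScene] = []
    rows: list[dict] = []
    skipped: list[dict] = []
    stage = "input"
    for entry in config.scenes:
        try:
            stage = "read/generate"
            scene = _materialize(entry, config)
            stage = "resample"
            scene = resample_scene(scene)
            if scene.quantity == "reflectance":
                reflectance_scenes.append(scene)
                stage = "apply_illuminant"
                radiance = apply_illuminant(scene, illuminant)
            else:
                radiance = scene
            stage = "excitation"
            maps = compute_all_channels(radiance)
            stage = "patches"
            for channel, diameters in assignment.items():
                for diam in diameters:
                    try:
                        layout = tile_patches(
                            radiance.shape,
                            ReceptiveFieldSpec(diam, config.window),
                            radiance.pixels_per_degree,
                            radiance.scene_id,
                            jitter_seed=jitter,
                        )
                    except PatchLayoutError:
                        layout = None
                    if layout is None or len(layout) < 2:
                        # scene too small for this field: between-patch
                        # contrast needs at least two patches
                        skipped.append(
                            {"scene_id": radiance.scene_id, "channel": channel,
                             "field_deg": diam}
                        )
                        continue
                    if channel == "Rad":
                        recs = local_radiance(radiance, layout)
                    else:
                        recs = local_excitation(maps[channel], layout)
                    cset = between_patch_contrast(recs)
                    for r in cset.records:
                        rows.append(
                            {
                                "scene_id": r.scene_id,
                                "environment": scene.environment,
                                "channel": r.channel,
                                "field_deg": r.field_diameter_deg,
                                "patch_index": r.patch_index,
                                "x0": r.center[1],
                                "y0": r.center[0],
                                "local_value": r.local_value,
                                "contrast": r.contrast,
                            }
                        )
        except Exception as exc:
            raise type(exc)(
                f"[stage={stage}, scene={entry.scene_id or entry.path or 'synthetic'}] {exc}"
            ) from exc

    records = pd.DataFrame(rows)

    # --- per-environment summaries (median / IQR), Table-style layout
    summary_rows = []
    for (env, channel, diam), grp in records.groupby(
        ["environment", "channel", "field_deg"], sort=True
    ):
        med_a, iqr_a = mstats.summarize(grp["local_value"].to_numpy())
        med_c, iqr_c = mstats.summarize(grp["contrast"].to_numpy())
        summary_rows.append(
            {
                "environment": env,
                "channel": channel,
                "field_deg": diam,
                "n_patches": len(grp),
                "absolute_median": med_a,
                "absolute_iqr": iqr_a,
                "contrast_median": med_c,
                "contrast_iqr": iqr_c,
            }
        )
    summary = pd.DataFrame(summary_rows)

    # --- between-environment and between-channel tests
    comp_rows: list[dict] = []

    def _add(comparisons, label, used_transform):
        for c in comparisons:
            comp_rows.append(
                {
                    "label": label if not c.label else f"{label}:{c.label}",
                    "metric": c.metric,
                    "kind": c.statistic_kind,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "df": "/".join(f"{d:g}" for d in c.df),
                    "transform": used_transform,
                }
            )

    envs = sorted(records["environment"].unique())
    both_envs = envs == ["human_made", "natural"]
    primary_fields = {ch: diams[0] for ch, diams in assignment.items()}
    if both_envs:
        for channel, diam in primary_fields.items():
            sel = records[(records.channel == channel) & (records.field_deg == diam)]
            nat = sel[sel.environment == "natural"]
            hm = sel[sel.environment == "human_made"]
            if len(nat) >= 3 and len(hm) >= 3:
                comps, used = _safe_compare(
                    nat["local_value"].to_numpy(),
                    hm["local_value"].to_numpy(),
                    config.transform,
                    channel,
                )
                _add(comps, f"{channel}_absolute_nat_vs_hm", used)
                comps, used = _safe_compare(
                    nat["contrast"].to_numpy(),
                    hm["contrast"].to_numpy(),
                    config.transform,
                    channel,
                )
                _add(comps, f"{channel}_contrast_nat_vs_hm", used)

    # ANOVA across Mel / ipRGC1 / Lum contrasts within each environment
    for env in envs:
        groups, labels = [], []
        for channel in ("Mel", "ipRGC1", "Lum"):
            sel = records[
                (records.channel == channel)
                & (records.field_deg == primary_fields[channel])
                & (records.environment == env)
            ]
            if len(sel) >= 2:
                groups.append(sel["contrast"].to_numpy())
                labels.append(channel)
        if len(groups) >= 2:
            try:
                comps = mstats.anova_tukey(
                    groups, transform="none", metric="contrast", labels=labels
                )
                _add(comps, f"contrast_anova_{env}", "none")
            except DegenerateDataError:
                pass

    # field-size effect: melanopsin at the peripheral vs parafoveal field,
    # paired per scene (scene-mean excitation and contrast)
    mel = records[records.channel == "Mel"]
    for env in envs:
        sub = mel[mel.environment == env]
        small = sub[sub.field_deg == config.iprgc_field_deg].groupby("scene_id")
        big = sub[sub.field_deg == config.periphery_field_deg].groupby("scene_id")
        common = sorted(set(small.groups) & set(big.groups))
        if len(common) >= 3:
            for var in ("local_value", "contrast"):
                a = np.array([small.get_group(s)[var].mean() for s in common])
                b = np.array([big.get_group(s)[var].mean() for s in common])
                try:
                    comps, used = _safe_compare(
                        a, b, config.transform, "Mel", paired=True
                    )
                    _add(comps, f"Mel_{var}_fieldsize_{env}", used)
                except DegenerateDataError:
                    pass

    comparisons = pd.DataFrame(comp_rows)

    # --- excitation/contrast independence (Pearson), per environment
    indep_rows = []
    for env in envs:
        for channel in ("Mel", "Lum"):
            sel = records[
                (records.channel == channel)
                & (records.field_deg == primary_fields[channel])
                & (records.environment == env)
            ]
            if len(sel) >= 3 and sel["local_value"].std() > 0 and sel["contrast"].std() > 0:
                from scipy import stats as sps

                r, p = sps.pearsonr(sel["local_value"], sel["contrast"])
                indep_rows.append(
                    {"environment": env, "channel": channel, "r": r, "p": p, "n": len(sel)}
                )
    independence = pd.DataFrame(indep_rows)

    # --- NRD across illuminants (needs reflectance scenes of both environments)
    nrd_rows = []
    refl_envs = {s.environment for s in reflectance_scenes}
    if {"natural", "human_made"} <= refl_envs:
        metric_means: dict[str, dict[str, tuple[float, float]]] = {
            "Mel": {}, "Lum": {}, "Rad": {}
        }
        for ill_name in config.nrd_illuminants:
            ill = parse_illuminant(ill_name)
            env_vals: dict[str, dict[str, list[float]]] = {
                "natural": {"Mel": [], "Lum": [], "Rad": []},
                "human_made": {"Mel": [], "Lum": [], "Rad": []},
            }
            for scene in reflectance_scenes:
                radiance = apply_illuminant(scene, ill)
                maps = compute_all_channels(radiance)
                for metric in ("Mel", "Lum", "Rad"):
                    diam = primary_fields[metric]
                    layout = tile_patches(
                        radiance.shape,
                        ReceptiveFieldSpec(diam, config.window),
                        radiance.pixels_per_degree,
                        radiance.scene_id,
                        jitter_seed=jitter,
                    )
                    recs = (
                        local_radiance(radiance, layout)
                        if metric == "Rad"
                        else local_excitation(maps[metric], layout)
                    )
                    env_vals[scene.environment][metric].extend(
                        r.local_value for r in recs
                    )
            for metric in ("Mel", "Lum", "Rad"):
                metric_means[metric][ill_name] = (
                    float(np.mean(env_vals["human_made"][metric])),
                    float(np.mean(env_vals["natural"][metric])),
                )
        for metric, by_ill in metric_means.items():
            try:
                table = mstats.nrd(by_ill)
            except DegenerateDataError:
                continue
            for ill_name, value in table.items():
                hm, nat = by_ill[ill_name]
                nrd_rows.append(
                    {
                        "metric": metric,
                        "illuminant": ill_name,
                        "hm_mean": hm,
                        "nat_mean": nat,
                        "nrd": value,
                    }
                )
    nrd_table = pd.DataFrame(nrd_rows)

    log = {
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "n_scenes": len(config.scenes),
        "n_records": len(records),
        "window": config.window,
        "transform": config.transform,
        "tiling": config.tiling,
        "seed": config.seed,
        "skipped_layouts": skipped,
    }
    result = PipelineResult(records, summary, comparisons, nrd_table, independence, log)
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={config.config_hash()}\n"
    for name, df in (
        ("patch_records.csv", result.records),
        ("summary.csv", result.summary),
        ("comparisons.csv", result.comparisons),
        ("nrd.csv", result.nrd_table),
        ("independence.csv", result.independence),
    ):
        path = outdir / name
        with path.open("w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(result.log, sort_keys=True))
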