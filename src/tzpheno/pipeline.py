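"""Configuration-driven orchestration: simulate/measure -> quantify ->
compare -> report, with seeds and provenance recorded in every output."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_stats import compare_groups
from .images import PlaneImage, Polyline, read_plane
from .synthetic import SceneGroundTruth, SimulatedScene, simulate_phasmid_scene
from .tz_quant import (
    asymmetry_index,
    extract_line_profile,
    fwhm_length,
    integrated_box_intensity,
)

logger = logging.getLogger("tzpheno")

KNOWN_METRICS = ("fwhm_length_um", "net_intensity", "asymmetry_index")

_PRESETS = {
    "widefield_wt": SceneGroundTruth.widefield,
    "widefield_g155s": SceneGroundTruth.widefield_g155s,
    "superres_wt": SceneGroundTruth.superres,
    "superres_g155s": SceneGroundTruth.superres_g155s,
}


@dataclass
class GenotypeSpec:
    name: str
    preset: str = "widefield_wt"
    n_scenes: int = 10
    truth_overrides: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    mode: str  # "simulate" | "measure"
    outdir: Path
    seed: int = 0
    metrics: list = field(default_factory=lambda: list(KNOWN_METRICS))
    genotypes: list = field(default_factory=list)  # GenotypeSpec (simulate mode)
    images: list = field(default_factory=list)  # dicts (measure mode)
    inner_box_px: int = 40
    alpha: float = 0.05
    force_test: Optional[str] = None
    reference_genotype: Optional[str] = None
    raw: dict = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        mode = raw.get("mode", "simulate")
        if mode not in ("simulate", "measure"):
            raise ValueError("mode must be 'simulate' or 'measure'")
        metrics = raw.get("metrics", list(KNOWN_METRICS))
        if not metrics:
            raise ValueError("metric list is empty")
        unknown = [m for m in metrics if m not in KNOWN_METRICS]
        if unknown:
            raise ValueError(f"unknown metrics: {unknown}")
        cfg = RunConfig(
            mode=mode,
            outdir=Path(raw.get("outdir", "tzpheno_run")),
            seed=int(raw.get("seed", 0)),
            metrics=list(metrics),
            inner_box_px=int(raw.get("inner_box_px", 40)),
            alpha=float(raw.get("alpha", 0.05)),
            force_test=raw.get("force_test"),
            reference_genotype=raw.get("reference_genotype"),
            raw=raw,
        )
        if mode == "simulate":
            genos = raw.get("genotypes") or []
            if not genos:
                raise ValueError("simulate mode needs a 'genotypes' list")
            for g in genos:
                preset = g.get("preset", "widefield_wt")
                if preset not in _PRESETS:
                    raise ValueError(f"unknown preset {preset!r}")
                cfg.genotypes.append(
                    GenotypeSpec(
                        name=g["name"],
                        preset=preset,
                        n_scenes=int(g.get("n_scenes", 10)),
                        truth_overrides=dict(g.get("truth", {})),
                    )
                )
        else:
            images = raw.get("images") or []
            if not images:
                raise ValueError("measure mode needs an 'images' list")
            for rec in images:
                p = Path(rec["path"])
                if not p.exists():
                    raise ValueError(f"referenced image does not exist: {p}")
            cfg.images = list(images)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def quantify_scene_channel(
    image: PlaneImage,
    profile_line: Polyline,
    box_center_px,
    metrics,
    inner_box_px: int = 40,
) -> dict:
    """Measure the requested TZ metrics on one annotated wide-field plane."""
    out = {}
    profile = None
    if "fwhm_length_um" in metrics or "asymmetry_index" in metrics:
        profile = extract_line_profile(image, profile_line)
    if "fwhm_length_um" in metrics:
        out["fwhm_length_um"] = fwhm_length(profile)
    if "asymmetry_index" in metrics:
        out["asymmetry_index"] = asymmetry_index(profile)
    if "net_intensity" in metrics:
        out["net_intensity"] = integrated_box_intensity(
            image, box_center_px, inner_box_px
        )
    return out


def _measure_simulated(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for gi, geno in enumerate(cfg.genotypes):
        factory = _PRESETS[geno.preset]
        for i in range(geno.n_scenes):
            seed = cfg.seed * 1_000_003 % (2 ** 31) + gi * 10_007 + i
            truth = factory(seed=seed, **geno.truth_overrides)
            scene: SimulatedScene = simulate_phasmid_scene(truth)
            image = scene.channels["tz"]
            vals = quantify_scene_channel(
                image,
                scene.info["profile_lines"][0],
                scene.info["box_center_px"],
                cfg.metrics,
                cfg.inner_box_px,
            )
            for metric, value in vals.items():
                rows.append(
                    {
                        "image_id": f"{geno.name}_{i:03d}",
                        "genotype": geno.name,
                        "metric": metric,
                        "value": value,
                        "units": "um" if metric == "fwhm_length_um" else "au",
                    }
                )
    return pd.DataFrame(rows)


def _measure_real(cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for rec in cfg.images:
        image = read_plane(rec["path"])
        line = Polyline(rec["tz_line"]) if "tz_line" in rec else None
        center = rec.get("box_center_px")
        metrics = [
            m
            for m in cfg.metrics
            if (m == "net_intensity" and center is not None)
            or (m in ("fwhm_length_um", "asymmetry_index") and line is not None)
        ]
        vals = quantify_scene_channel(image, line, center, metrics, cfg.inner_box_px)
        for metric, value in vals.items():
            rows.append(
                {
                    "image_id": rec.get("image_id", Path(rec["path"]).stem),
                    "genotype": rec["genotype"],
                    "metric": metric,
                    "value": value,
                    "units": "um" if metric == "fwhm_length_um" else "au",
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Emits ``measurements.csv`` (tidy per-image metric rows),
    ``comparisons.csv`` (pairwise post hoc table per metric), and
    ``summary.json`` (group means +/- s.d., test choices, seeds, config
    hash).  Deterministic given the same config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("tzpheno %s | config hash %s | seed %d",
                    __version__, config.config_hash(), config.seed)
        stage = "measure"
        try:
            table = (
                _measure_simulated(config)
                if config.mode == "simulate"
                else _measure_real(config)
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        table.to_csv(outdir / "measurements.csv", index=False)

        summary: dict = {
            "tzpheno_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "mode": config.mode,
            "metrics": {},
        }
        pairwise_frames = []
        for metric in config.metrics:
            sub = table[table["metric"] == metric]
            if sub.empty:
                continue
            groups = sub.groupby("genotype", sort=False)["value"]
            entry = {
                "group_mean": groups.mean().to_dict(),
                "group_sd": groups.std(ddof=1).to_dict(),
                "group_n": groups.size().to_dict(),
            }
            if sub["genotype"].nunique() >= 2 and groups.size().min() >= 3:
                stage = f"compare:{metric}"
                try:
                    res = compare_groups(
                        sub,
                        alpha=config.alpha,
                        force_test=config.force_test,
                        metric=metric,
                    )
                except Exception as exc:  # noqa: BLE001
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
                entry["comparison"] = res.to_dict()
                pw = res.pairwise.copy()
                pw.insert(0, "metric", metric)
                pairwise_frames.append(pw)
            summary["metrics"][metric] = entry
        if pairwise_frames:
            pd.concat(pairwise_frames, ignore_index=True).to_csv(
                outdir / "comparisons.csv", index=False
            )
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=_jsonify)
        )
        logger.info("wrote %s", outdir / "summary.json")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
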