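"""Config-driven runs tying the stages together.

A run is described by a single YAML config with per-stage blocks::

    seed: 1
    outdir: runs/demo
    imaging:
      conditions:
        - condition_id: rho2
          variable_name: enrichment_rho
          variable_value: 2.0
          enrichment_rho: 2.0
          n_images: 4
    gel:
      scenarios:
        - gel_id: g1
          bound_fraction_true: 0.5
    stages: [simulate, segment, coloc, gel, stats]

Stage seeds are derived from the master seed and the stage name, so stages
are reproducible independently and never share a stream.  Every produced
artifact is listed in the run report with its SHA-256 checksum, alongside
the hash of the canonicalized config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import imaging_io, segmentation
from .colocalization import colocalization_ratio
from .gel_quant import GelLane, bound_fraction_from_bands, integrate_band
from .imaging_io import load_condition, read_manifest, write_condition, write_manifest
from .stats import rank_sum_compare, trend_test
from .synthetic_data import GelScenario, ImagingScenario, generate_gel_image, generate_imaging_condition

ALL_STAGES = ("simulate", "segment", "coloc", "gel", "stats")

_IMAGING_KEYS = {f.name for f in ImagingScenario.__dataclass_fields__.values()}  # type: ignore[attr-defined]
_GEL_KEYS = {f.name for f in GelScenario.__dataclass_fields__.values()}  # type: ignore[attr-defined]


class ConfigError(ValueError):
    """Raised when a run config fails schema validation."""


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    stages: tuple[str, ...]
    imaging_conditions: list[dict]
    gel_scenarios: list[dict]
    stats_options: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunReport:
    config_hash: str
    artifacts: dict[str, str]  # path -> sha256
    stage_seconds: dict[str, float]
    log_path: str


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def load_config(path_or_dict: str | Path | Mapping[str, Any]) -> RunConfig:
    """Parse and validate a run config; all errors are raised before any stage."""
    if isinstance(path_or_dict, (str, Path)):
        p = Path(path_or_dict)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text())
    else:
        raw = dict(path_or_dict)
    _require(isinstance(raw, dict), "config must be a mapping")
    _require("outdir" in raw, "config requires 'outdir'")
    seed = raw.get("seed", 0)
    _require(isinstance(seed, int) and seed >= 0, "'seed' must be a non-negative integer")
    stages = tuple(raw.get("stages", ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    _require(not unknown, f"unknown stages {unknown}; valid: {ALL_STAGES}")

    imaging = raw.get("imaging", {}) or {}
    conds = imaging.get("conditions", []) or []
    seen_ids = set()
    for c in conds:
        _require(isinstance(c, dict) and "condition_id" in c, "each imaging condition needs condition_id")
        _require(c["condition_id"] not in seen_ids, f"duplicate condition_id {c['condition_id']!r}")
        seen_ids.add(c["condition_id"])
        bad = set(c) - _IMAGING_KEYS
        _require(not bad, f"condition {c['condition_id']!r}: unknown keys {sorted(bad)}")
    gel = raw.get("gel", {}) or {}
    gels = gel.get("scenarios", []) or []
    for g in gels:
        _require(isinstance(g, dict), "each gel scenario must be a mapping")
        bad = set(g) - _GEL_KEYS
        _require(not bad, f"gel scenario: unknown keys {sorted(bad)}")
    needs_images = {"segment", "coloc"} & set(stages)
    if needs_images and "simulate" not in stages:
        manifest = raw.get("manifest")
        _require(manifest is not None, "segment/coloc without simulate requires 'manifest'")
        _require(Path(manifest).exists(), f"manifest not found: {manifest}")
    _require(
        not ({"simulate", "segment", "coloc"} & set(stages)) or conds or "manifest" in raw,
        "imaging stages requested but no imaging conditions configured",
    )
    _require("gel" not in stages or gels, "gel stage requested but no gel scenarios configured")
    return RunConfig(
        seed=seed,
        outdir=Path(raw["outdir"]),
        stages=stages,
        imaging_conditions=conds,
        gel_scenarios=gels,
        stats_options=raw.get("stats", {}) or {},
        raw=raw,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig | str | Path | Mapping[str, Any]) -> RunReport:
    """Execute the configured stages; deterministic given the config seeds."""
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    times: dict[str, float] = {}
    log_lines: list[str] = [f"config_hash {cfg.config_hash}"]
    manifest_path = Path(cfg.raw.get("manifest", out / "manifest.csv"))

    def _stage(name):
        def deco(fn):
            if name in cfg.stages:
                t0 = time.perf_counter()
                try:
                    fn()
                except Exception as exc:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                times[name] = time.perf_counter() - t0
                log_lines.append(f"stage {name} ok {times[name]:.2f}s")
            return fn

        return deco

    @_stage("simulate")
    def _simulate():
        rows = []
        base = stage_seed(cfg.seed, "simulate")
        for i, block in enumerate(cfg.imaging_conditions):
            params = dict(block)
            params.setdefault("seed", (base + i) % (2**31))
            scenario = ImagingScenario(**params)
            cond, gt = generate_imaging_condition(scenario)
            sidecar = {
                "enrichment_rho": gt.enrichment_rho,
                "enrichment_per_image": gt.enrichment_per_image,
                "clip_fraction": gt.clip_fraction,
                "masks": gt.masks,
            }
            rows.append(write_condition(cond, out, ground_truth=sidecar))
            artifacts.append(out / f"{cond.condition_id}.tif")
            artifacts.append(out / f"{cond.condition_id}.groundtruth.json")
        write_manifest(rows, manifest_path)
        artifacts.append(manifest_path)

    @_stage("segment")
    def _segment():
        manifest = read_manifest(manifest_path)
        records = []
        for cid in manifest["condition_id"].unique():
            cond = load_condition(manifest, cid, root=manifest_path.parent)
            thr = segmentation.condition_threshold(cond)
            records.append(
                {
                    "condition_id": cid,
                    "threshold": thr.value,
                    "mean": thr.mean,
                    "sd": thr.sd,
                    "n_pixels": thr.n_pixels,
                }
            )
        pd.DataFrame(records).to_csv(out / "thresholds.csv", index=False)
        artifacts.append(out / "thresholds.csv")

    @_stage("coloc")
    def _coloc():
        manifest = read_manifest(manifest_path)
        detail = []
        for cid in manifest["condition_id"].unique():
            cond = load_condition(manifest, cid, root=manifest_path.parent)
            thr = segmentation.condition_threshold(cond)
            for img in cond.images:
                mask = segmentation.binarize(img, thr)
                r = colocalization_ratio(img, mask)
                detail.append(
                    {
                        "condition_id": r.condition_id,
                        "image_id": r.image_id,
                        "C_R": r.C_R,
                        "coverage": r.coverage,
                        "F_dna_lipid": r.F_dna_lipid,
                        "F_dna_background": r.F_dna_background,
                        "pearson_r": r.pearson_r,
                    }
                )
        imaging_io.write_results_table(detail, out / "results.csv", out / "summary.csv")
        artifacts.extend([out / "results.csv", out / "summary.csv"])

    @_stage("gel")
    def _gel():
        base = stage_seed(cfg.seed, "gel")
        records = []
        for i, block in enumerate(cfg.gel_scenarios):
            params = dict(block)
            params.setdefault("seed", (base + i) % (2**31))
            params.setdefault("gel_id", f"gel{i}")
            scenario = GelScenario(**params)
            img, gt = generate_gel_image(scenario)
            tifffile.imwrite(out / f"{scenario.gel_id}.tif", img.astype(np.float32))
            artifacts.append(out / f"{scenario.gel_id}.tif")
            by_pair: dict[str, dict[str, GelLane]] = {}
            for lane in gt.lanes:
                pair = lane.lane_id.rsplit(":", 1)[0]
                by_pair.setdefault(pair, {})[lane.role] = lane
            for pair, lanes in by_pair.items():
                sample = integrate_band(img, lanes["sample"])
                control = integrate_band(img, lanes["control"])
                records.append(
                    {
                        "gel_id": scenario.gel_id,
                        "pair": pair,
                        "B": sample.integrated_intensity,
                        "U": control.integrated_intensity,
                        "T_percent": bound_fraction_from_bands(sample, control),
                        "bound_fraction_true": gt.bound_fraction_true,
                    }
                )
        pd.DataFrame(records).to_csv(out / "gel_results.csv", index=False)
        artifacts.append(out / "gel_results.csv")

    @_stage("stats")
    def _stats():
        results_path = out / "results.csv"
        records = []
        if results_path.exists():
            df = pd.read_csv(results_path)
            manifest = read_manifest(manifest_path)
            var = manifest.set_index("condition_id")["variable_value"]
            df["variable_value"] = df["condition_id"].map(var)
            numeric = pd.to_numeric(df["variable_value"], errors="coerce")
            if numeric.notna().all() and numeric.nunique() >= 3:
                tr = trend_test(numeric.to_numpy(), df["C_R"].to_numpy(), variable="variable_value")
                records.append(
                    {
                        "test": "trend",
                        "groups": "all",
                        "estimate": tr.slope,
                        "ci_low": tr.ci95[0],
                        "ci_high": tr.ci95[1],
                        "p_value": float("nan"),
                        "decision": tr.decision,
                    }
                )
            cids = list(df["condition_id"].unique())
            for a, b in zip(cids, cids[1:]):
                va = df.loc[df["condition_id"] == a, "C_R"].to_numpy()
                vb = df.loc[df["condition_id"] == b, "C_R"].to_numpy()
                if va.size >= 3 and vb.size >= 3:
                    cmp_res = rank_sum_compare(va, vb, a, b)
                    records.append(
                        {
                            "test": "rank_sum",
                            "groups": f"{a} vs {b}",
                            "estimate": cmp_res.mean_difference,
                            "ci_low": float("nan"),
                            "ci_high": float("nan"),
                            "p_value": cmp_res.p_value,
                            "decision": "significant" if cmp_res.p_value < 0.05 else "ns",
                        }
                    )
        pd.DataFrame(
            records,
            columns=["test", "groups", "estimate", "ci_low", "ci_high", "p_value", "decision"],
        ).to_csv(out / "stats.csv", index=False)
        artifacts.append(out / "stats.csv")

    checksums = {str(p): _sha256(p) for p in artifacts if p.exists()}
    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    report = RunReport(
        config_hash=cfg.config_hash,
        artifacts=checksums,
        stage_seconds=times,
        log_path=str(log_path),
    )
    (out / "run_report.json").write_text(
        json.dumps(
            {
                "config_hash": report.config_hash,
                "artifacts": report.artifacts,
                "stage_seconds": report.stage_seconds,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return report
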