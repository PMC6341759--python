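"""Reproducible multi-stage runs: simulate -> segment -> metrics -> pfl ->
sweep -> cohort report.

A run is described by a single :class:`RunConfig` (YAML or JSON on disk)
with one block per stage; every stochastic stage derives its randomness
from the run seed, so re-running the same config reproduces outputs
bit-identically.  Each run writes a manifest recording the package
version, the seed, the effective config and a SHA-256 digest of every
output file.
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

from . import __version__
from .hydrodynamics import eddy_correction, flow_waveform, hydrodynamic_metrics, phase_to_velocity
from .io import (
    CohortTable,
    read_mask,
    read_series,
    write_cohort_table,
    write_mask,
    write_series,
)
from .latency import PFLConfig, compute_pfl, sensitivity_sweep
from .segmentation import segment_roi
from .stats import cohort_report
from .synthetic import CohortSpec, GroupSpec, generate_cohort

log = logging.getLogger("csfpulse")

STAGES = ("simulate", "segment", "metrics", "pfl", "sweep", "cohort")

__all__ = ["RunConfig", "run", "STAGES", "auto_static_mask"]


@dataclass
class RunConfig:
    """Ordered stage list plus per-stage config blocks."""

    stages: list
    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    segment: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    pfl: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid stages: {STAGES}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ValueError("stages must appear in pipeline order")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)

    def to_file(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2) + "\n")
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def auto_static_mask(shape, exclude=None, size: int = 6, margin: int = 1) -> np.ndarray:
    """Pick a static-tissue reference block (the "midbrain region" stand-in).

    Scans square blocks from the image corners inward and returns the
    first one fully disjoint from ``exclude`` (flow ROI, artery, ...).
    """
    excl = np.zeros(shape, dtype=bool) if exclude is None else np.asarray(exclude, dtype=bool)
    rows, cols = shape
    for r0 in range(margin, rows - size, size):
        for c0 in range(margin, cols - size, size):
            block = np.zeros(shape, dtype=bool)
            block[r0 : r0 + size, c0 : c0 + size] = True
            if not (block & excl).any():
                return block
    raise ValueError("no static region free of excluded voxels found")


def _default_groups() -> list:
    # demo cohort: latency distributions of the pre-treatment vs control
    # cistern groups; stroke volumes spread around the cohort medians
    return [
        {
            "name": "pre_shunt",
            "group": "pre_shunt",
            "n": 15,
            "site": "cistern",
            "distributions": {
                "latency": ("normal", 0.245, 0.063),
                "sv_ul": ("normal", 293.5, 110.0),
            },
        },
        {
            "name": "control",
            "group": "control",
            "n": 5,
            "site": "cistern",
            "distributions": {
                "latency": ("normal", 0.296, 0.132),
                "sv_ul": ("normal", 299.0, 120.0),
            },
        },
    ]


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest.

    Any stage failure halts the run with the stage name and offending
    input in the exception message.  Outputs land under
    ``config.out_dir`` in one directory per stage.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    state: dict = {"subjects": []}  # subject records threaded between stages

    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            outputs = _STAGE_FNS[stage](config, state, out / stage)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {k: str(p) for k, p in outputs.items()},
            "sha256": {k: _sha256(Path(p)) for k, p in outputs.items() if Path(p).is_file()},
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    log.info("manifest written to %s", manifest_path)
    return manifest


def _stage_simulate(config: RunConfig, state: dict, stage_dir: Path) -> dict:
    cfg = config.simulate
    groups = [GroupSpec(**g) if isinstance(g, dict) else g
              for g in cfg.get("groups", _default_groups())]
    spec = CohortSpec(groups=tuple(groups), seed=cfg.get("seed", config.seed),
                      n_frames=cfg.get("n_frames", 30))
    subjects, draw_log = generate_cohort(spec)
    outputs: dict = {}
    site_by_group = {g.name: g.site for g in groups}
    for i, (gname, series, truth) in enumerate(subjects):
        sid = f"sub{i:03d}"
        d = stage_dir / sid
        paths = write_series(series, d)
        write_mask(truth.mask.mask, d / "true_mask.nii.gz", series.pixel_spacing_mm)
        if truth.artery_mask is not None:
            write_mask(truth.artery_mask, d / "artery_mask.nii.gz", series.pixel_spacing_mm)
        (d / "truth.json").write_text(json.dumps({
            "true_pfl_pct": truth.true_pfl * 100.0,
            "metrics": truth.true_metrics.as_dict(),
        }, indent=2) + "\n")
        state["subjects"].append({
            "subject_id": sid, "group": gname, "site": site_by_group[gname],
            "dir": d, "series": series, "truth": truth,
        })
        outputs[f"{sid}/series"] = paths["sidecar"]
    p = stage_dir / "draw_log.csv"
    draw_log.to_csv(p, index=False)
    outputs["draw_log"] = p
    return outputs


def _stage_segment(config: RunConfig, state: dict, stage_dir: Path) -> dict:
    cfg = config.segment
    outputs: dict = {}
    for rec in state["subjects"]:
        series = rec.get("series") or read_series(rec["dir"])
        excl = rec["truth"].artery_mask if rec.get("truth") is not None else None
        roi = segment_roi(
            series,
            threshold=cfg.get("threshold", 0.6),
            exclusion_mask=excl,
            erode_iterations=cfg.get("erode_iterations", 0),
        )
        log.info("%s: %d voxels (%.1f mm^2)", rec["subject_id"], roi.n_voxels, roi.area_mm2)
        rec["roi"] = roi
        p = stage_dir / rec["subject_id"] / "mask.nii.gz"
        write_mask(roi.mask, p, series.pixel_spacing_mm)
        outputs[f"{rec['subject_id']}/mask"] = p
    return outputs


def _stage_metrics(config: RunConfig, state: dict, stage_dir: Path) -> dict:
    cfg = config.metrics
    outputs: dict = {}
    rows = []
    for rec in state["subjects"]:
        series = rec["series"]
        roi = rec["roi"]
        vel = phase_to_velocity(series)
        exclude = roi.mask.copy()
        truth = rec.get("truth")
        if truth is not None and truth.artery_mask is not None:
            exclude |= truth.artery_mask
        static = auto_static_mask(series.shape[:2], exclude=exclude,
                                  size=cfg.get("static_block", 6))
        vel = eddy_correction(vel, static, flow_roi=roi)
        rec["vel"] = vel
        q = flow_waveform(vel, roi)
        m = hydrodynamic_metrics(q, vel, roi,
                                 mean_flow_convention=cfg.get("mean_flow_convention", "conditional"))
        rec["metrics"] = m
        p = stage_dir / rec["subject_id"] / "metrics.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(m.as_dict(), indent=2) + "\n")
        outputs[f"{rec['subject_id']}/metrics"] = p
        rows.append({
            "subject_id": rec["subject_id"], "group": rec["group"], "site": rec["site"],
            "pair_id": None,
            "area[mm2]": m.area_mm2,
            "caudal_max_velocity[cm/s]": m.caudal_max_velocity_cm_s,
            "cranial_max_velocity[cm/s]": m.cranial_max_velocity_cm_s,
            "caudal_mean_flow[mL/s]": m.caudal_mean_flow_ml_s,
            "cranial_mean_flow[mL/s]": m.cranial_mean_flow_ml_s,
            "sv_bradley[uL]": m.sv_bradley_ul,
            "sv_bateman[uL]": m.sv_bateman_ul,
        })
    table = CohortTable(pd.DataFrame(rows))
    state["table"] = table
    p = stage_dir / "cohort_table.csv"
    write_cohort_table(table, p)
    outputs["cohort_table"] = p
    return outputs


def _stage_pfl(config: RunConfig, state: dict, stage_dir: Path) -> dict:
    cfg = config.pfl
    pcfg = PFLConfig(
        erosion_iterations=cfg.get("erosion_iterations", 1),
        keep_fraction=cfg.get("keep_fraction", 0.25),
        poly_degree=cfg.get("poly_degree", 6),
        dense_samples=cfg.get("dense_samples", 1000),
        fit_enabled=cfg.get("fit_enabled", True),
    )
    outputs: dict = {}
    for rec in state["subjects"]:
        res = compute_pfl(rec["vel"], rec["roi"], pcfg)
        rec["pfl"] = res
        p = stage_dir / rec["subject_id"] / "pfl.json"
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps({
            "pfl_percent": res.pfl_percent,
            "n_voxels_used": res.n_voxels_used,
            "flags": res.flags,
        }, indent=2) + "\n")
        outputs[f"{rec['subject_id']}/pfl"] = p
    if "table" in state:
        df = state["table"].df
        pfl_by_id = {rec["subject_id"]: rec["pfl"].pfl_percent for rec in state["subjects"]}
        df["pfl[%cycle]"] = df["subject_id"].map(pfl_by_id)
        state["table"] = CohortTable(df)
        p = stage_dir / "cohort_table.csv"
        write_cohort_table(state["table"], p)
        outputs["cohort_table"] = p
    return outputs


def _stage_sweep(config: RunConfig, state: dict, stage_dir: Path) -> dict:
    cfg = config.sweep
    name_a = cfg.get("cohort_a", state["subjects"][0]["group"])
    name_b = cfg.get("cohort_b", state["subjects"][-1]["group"])
    def pick(name):
        return [(r["vel"], r["roi"]) for r in state["subjects"] if r["group"] == name]
    grid, _ = sensitivity_sweep(
        pick(name_a), pick(name_b),
        degrees=cfg.get("degrees", (4, 5, 6, 7, 8, 9, 10)),
        removal_fractions=cfg.get("removal_fractions", (0.01, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)),
        include_no_fit=cfg.get("include_no_fit", True),
    )
    p = stage_dir / "pvalue_grid.csv"
    p.parent.mkdir(parents=True, exist_ok=True)
    grid.to_csv(p)
    return {"pvalue_grid": p}


def _stage_cohort(config: RunConfig, state: dict, stage_dir: Path) -> dict:
    cfg = config.cohort
    table = state["table"]
    plan = cfg.get("plan")
    if plan is None:
        sites = sorted(set(table.df["site"].dropna()))
        groups = list(dict.fromkeys(table.df["group"].dropna()))
        plan = []
        if len(groups) >= 2:
            for site in sites:
                for metric in table.metrics:
                    plan.append({"metric": metric, "site": site, "kind": "independent",
                                 "group_a": groups[0], "group_b": groups[1]})
        plan = [c for c in plan
                if len(table.values_for(c["metric"], c["group_a"], c["site"])) > 0
                and len(table.values_for(c["metric"], c["group_b"], c["site"])) > 0]
    report = cohort_report(table, plan, star_thresholds=cfg.get("star_thresholds"))
    stage_dir.mkdir(parents=True, exist_ok=True)
    p_csv = report.to_csv(stage_dir / "report.csv")
    p_md = stage_dir / "report.md"
    p_md.write_text(report.to_markdown() + "\n")
    return {"report_csv": p_csv, "report_md": p_md}


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "metrics": _stage_metrics,
    "pfl": _stage_pfl,
    "sweep": _stage_sweep,
    "cohort": _stage_cohort,
}
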