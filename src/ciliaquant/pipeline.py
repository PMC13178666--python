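"""Reproducible pipeline runs: configuration, stage dispatch, demo cohort.

A :class:`RunConfig` names one stage, its input files, acquisition
metadata and parameters; :func:`run_stage` dispatches it, writes the
stage's standard outputs (32-bit float TIFF maps, CSV tables, JSON
metrics) into the output directory and records a :class:`RunManifest`.
Identical config + seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cbf, clearance, morphometry, polarity, simulate, stats
from .io import VideoStack, read_labels, read_stack, read_video, write_stack

__all__ = ["RunConfig", "RunManifest", "run_stage", "demo_synthetic_cohort", "STAGES"]

_CSV_KW = dict(index=False, lineterminator="\n", float_format="%.9g")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    stage: str
    outdir: str
    inputs: dict = field(default_factory=dict)
    fps: float | None = None
    pixel_size_um: float | None = None
    pixel_size_nm: float | None = None
    voxel_size_um: tuple[float, float, float] | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["voxel_size_um"] is not None:
            d["voxel_size_um"] = list(d["voxel_size_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("voxel_size_um") is not None:
            d["voxel_size_um"] = tuple(d["voxel_size_um"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one completed run."""

    stage: str
    config_hash: str
    version: str
    inputs: list[str]
    outputs: list[str]
    started: float
    finished: float

    def save(self, path) -> None:
        lines = [
            f"stage: {self.stage}",
            f"config_hash: {self.config_hash}",
            f"version: {self.version}",
            f"started: {self.started:.3f}",
            f"finished: {self.finished:.3f}",
            "inputs:",
            *[f"  - {p}" for p in self.inputs],
            "outputs:",
            *[f"  - {p}" for p in self.outputs],
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _require(config: RunConfig, *names: str) -> None:
    missing = [n for n in names if getattr(config, n) is None]
    if missing:
        raise ValueError(f"stage {config.stage!r} requires metadata: {', '.join(missing)}")


def _stage_cbf(config: RunConfig, outdir: Path) -> list[str]:
    _require(config, "fps")
    video = read_video(config.inputs["video"], fps=config.fps,
                       pixel_size=config.pixel_size_um or 1.0)
    labels = read_labels(config.inputs["labels"])
    p = config.params
    fmap = cbf.dominant_frequency_map(
        video,
        band=tuple(p.get("band", (0.5, 30.0))),
        activity_threshold=p.get("activity_threshold", 0.2),
        floor_factor=p.get("floor_factor", 5.0),
    )
    cells = cbf.summarize_cell_cbf(fmap, labels)
    cbf.assign_beat_modes(cells, fmap, cbf.BeatModeThresholds(**p.get("beat_modes", {})))
    map_path = outdir / "frequency_map.tif"
    layers = np.stack([
        np.nan_to_num(fmap.dominant_freq, nan=0.0),
        fmap.peak_power,
        fmap.active.astype(np.float32),
    ]).astype(np.float32)
    write_stack(map_path, layers, dtype=np.float32)
    csv_path = outdir / "cell_cbf.csv"
    cbf.cells_to_frame(cells).to_csv(csv_path, **_CSV_KW)
    return [str(map_path), str(csv_path)]


def _stage_polarity(config: RunConfig, outdir: Path) -> list[str]:
    _require(config, "pixel_size_nm")
    image = read_stack(config.inputs["image"], axes=config.params.get("axes"))
    if image.ndim != 3 or image.shape[0] != 2:
        raise ValueError("polarity stage expects a 2-channel (2, Y, X) image")
    labels = read_labels(config.inputs["labels"])
    p = config.params
    kw = dict(
        pixel_size_nm=config.pixel_size_nm,
        sigma_nm=p.get("sigma_nm", 80.0),
        min_separation_nm=p.get("min_separation_nm", 300.0),
        rel_threshold=p.get("rel_threshold", 0.1),
    )
    bb = polarity.detect_spots(image[0], channel=0, **kw)
    feet = polarity.detect_spots(image[1], channel=1, **kw)
    pairs, _, _ = polarity.pair_spots(bb, feet, config.pixel_size_nm,
                                      max_dist_nm=p.get("max_dist_nm", 500.0))
    cells = polarity.cell_polarity(pairs, labels, min_pairs=p.get("min_pairs", 4))
    pairs_path = outdir / "pairs.csv"
    polarity.pairs_to_frame(pairs, labels).to_csv(pairs_path, **_CSV_KW)
    cells_path = outdir / "cell_polarity.csv"
    polarity.polarity_to_frame(cells).to_csv(cells_path, **_CSV_KW)
    return [str(pairs_path), str(cells_path)]


def _stage_ciliation(config: RunConfig, outdir: Path) -> list[str]:
    _require(config, "voxel_size_um")
    stack = read_stack(config.inputs["stack"], axes=config.params.get("axes"))
    if stack.ndim != 4 or stack.shape[0] != 2:
        raise ValueError("ciliation stage expects a 2-channel (2, Z, Y, X) stack")
    p = config.params
    result = morphometry.ciliation_result(
        stack[0], stack[1], config.voxel_size_um,
        cilia_min_length_um=p.get("min_length_um", 1.0),
        **({"cilia_threshold": p["threshold"]} if "threshold" in p else {}),
    )
    summ = morphometry.summarize_lengths(
        [morphometry.CiliumTrace(np.empty((0, 3)), np.empty((0, 3)), l) for l in result.lengths]
    )
    cell_path = outdir / "ciliation.csv"
    pd.DataFrame([
        {
            "label": result.label,
            "n_bb": result.n_basal_bodies,
            "n_cilia": result.n_cilia,
            "ciliation_level": result.ciliation_level,
            "mean_len": summ["mean"],
            "median_len": summ["median"],
        }
    ]).to_csv(cell_path, **_CSV_KW)
    len_path = outdir / "cilium_lengths.csv"
    pd.DataFrame({"length_um": sorted(result.lengths)}).to_csv(len_path, **_CSV_KW)
    return [str(cell_path), str(len_path)]


def _stage_beads(config: RunConfig, outdir: Path) -> list[str]:
    _require(config, "fps", "pixel_size_um")
    video = read_video(config.inputs["video"], fps=config.fps, pixel_size=config.pixel_size_um)
    p = config.params
    tracks = clearance.track_beads(
        video,
        sigma_um=p.get("sigma_um", 0.15),
        rel_threshold=p.get("rel_threshold", 0.2),
        max_step_um=p.get("max_step_um"),
    )
    metrics = clearance.compute_clearance_metrics(
        tracks, video.fps,
        coherence_threshold=p.get("coherence_threshold", 0.6),
        speed_floor=p.get("speed_floor", 0.5),
    )
    tracks_path = outdir / "tracks.csv"
    clearance.tracks_to_frame(tracks).to_csv(tracks_path, **_CSV_KW)
    metrics_path = outdir / "clearance.json"
    metrics_path.write_text(json.dumps(dataclasses.asdict(metrics), indent=2, sort_keys=True) + "\n")
    return [str(tracks_path), str(metrics_path)]


def _stage_stats(config: RunConfig, outdir: Path) -> list[str]:
    table = pd.read_csv(config.inputs["table"])
    rows = []
    if {"group", "variable", "value"}.issubset(table.columns):
        for var, sub in table.groupby("variable", sort=True):
            groups = [g for _, g in sub.groupby("group", sort=True)]
            if len(groups) != 2:
                continue
            res = stats.welch_t_test(groups[0]["value"], groups[1]["value"])
            rows.append({
                "test": "welch_t", "variable": var, "statistic": res.t,
                "df": res.df, "p": res.p, "flag": "degenerate" if res.degenerate else "",
            })
    elif {"group", "category", "count"}.issubset(table.columns):
        wide = table.pivot_table(index="group", columns="category", values="count",
                                 aggfunc="sum", fill_value=0).sort_index()
        p, odds = stats.fisher_exact(wide.to_numpy())
        rows.append({"test": "fisher_exact", "variable": "x".join(map(str, wide.shape)),
                     "statistic": odds, "df": float("nan"), "p": p, "flag": ""})
    else:
        raise ValueError(
            "stats stage needs columns (group, variable, value) or (group, category, count)"
        )
    out = outdir / "stats.csv"
    pd.DataFrame(rows, columns=["test", "variable", "statistic", "df", "p", "flag"]).to_csv(out, **_CSV_KW)
    return [str(out)]


def _stage_simulate(config: RunConfig, outdir: Path) -> list[str]:
    p = dict(config.params)
    kind = p.pop("kind", "cilia_video")
    p.setdefault("seed", config.seed)
    outputs = []
    if kind == "cilia_video":
        cells = [simulate.rect_motif(**c) for c in p.pop("cells")]
        video, labels, truth = simulate.generate_cilia_video(simulate.CiliaVideoSpec(cells=cells, **p))
        write_stack(outdir / "video.tif", video.data, dtype=np.uint16, scale=True)
        write_stack(outdir / "labels.tif", labels, dtype=None)
        truth.to_csv(outdir / "truth.csv", **_CSV_KW)
        outputs = ["video.tif", "labels.tif", "truth.csv"]
    elif kind == "spot_field":
        image, mask, truth = simulate.generate_spot_field(simulate.SpotFieldSpec(**p))
        write_stack(outdir / "spots.tif", image, dtype=np.float32)
        write_stack(outdir / "labels.tif", mask, dtype=None)
        truth.to_csv(outdir / "truth.csv", **_CSV_KW)
        outputs = ["spots.tif", "labels.tif", "truth.csv"]
    elif kind == "ciliation_stack":
        stack, truth = simulate.generate_ciliation_stack(simulate.CiliationStackSpec(**p))
        write_stack(outdir / "stack.tif", stack.astype(np.float32), dtype=np.float32)
        truth.to_csv(outdir / "truth.csv", **_CSV_KW)
        outputs = ["stack.tif", "truth.csv"]
    elif kind == "bead_video":
        video, truth = simulate.generate_bead_video(simulate.BeadVideoSpec(**p))
        write_stack(outdir / "beads.tif", video.data, dtype=np.uint16, scale=True)
        truth.to_csv(outdir / "truth.csv", **_CSV_KW)
        outputs = ["beads.tif", "truth.csv"]
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    return [str(outdir / name) for name in outputs]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cbf": _stage_cbf,
    "polarity": _stage_polarity,
    "ciliation": _stage_ciliation,
    "beads": _stage_beads,
    "stats": _stage_stats,
}
STAGES = tuple(_STAGE_FUNCS) + ("demo",)


def run_stage(config: RunConfig) -> RunManifest:
    """Run one configured stage and write its outputs + manifest."""
    started = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.stage == "demo":
        outputs = demo_synthetic_cohort(config.seed, outdir, **config.params)
    elif config.stage in _STAGE_FUNCS:
        outputs = _STAGE_FUNCS[config.stage](config, outdir)
    else:
        raise ValueError(f"unknown stage {config.stage!r}; choose from {', '.join(STAGES)}")
    manifest = RunManifest(
        stage=config.stage,
        config_hash=config.hash(),
        version=__version__,
        inputs=sorted(str(v) for v in config.inputs.values()),
        outputs=[str(p) for p in outputs],
        started=started,
        finished=time.time(),
    )
    manifest.save(outdir / "manifest.txt")
    config.save(outdir / "config.yaml")
    return manifest


# ---------------------------------------------------------------------------
# end-to-end synthetic demonstration
# ---------------------------------------------------------------------------

def _arm_params(arm: str) -> dict:
    """Generator settings of the two demo arms.

    The control arm emulates healthy multiciliated epithelium (beating
    cells, tight basal-foot polarity, high ciliation, directional bead
    transport); the KO arm emulates loss of cilia function (mostly
    static cells, dispersed polarity, low ciliation, diffusive beads).
    """
    if arm == "control":
        return dict(freqs=[6.0, 8.0, 10.0, 12.0, 14.0], amps=[400.0] * 5,
                    kappa=8.0, ciliated_fraction=0.75,
                    drift=(0.0, 2.0), diffusion=0.01)
    return dict(freqs=[0.0, 0.0, 0.0, 0.0, 6.0], amps=[400.0] * 4 + [40.0],
                kappa=0.3, ciliated_fraction=0.25,
                drift=(0.0, 0.0), diffusion=0.3)


def demo_synthetic_cohort(seed: int, outdir, scale: float = 1.0) -> list[str]:
    """Generate a control vs KO synthetic cohort and run every stage.

    Writes per-arm outputs under ``<outdir>/<arm>/<stage>/`` and a
    comparison report in which each metric separates the arms in the
    expected direction.  Returns the list of written report files.
    """
    outdir = Path(outdir)
    base = int(seed) % (2**31 - 1)
    report: dict[str, dict] = {}
    for ai, arm in enumerate(("control", "ko")):
        p = _arm_params(arm)
        arm_dir = outdir / arm
        arm_dir.mkdir(parents=True, exist_ok=True)
        arm_seed = (base * 7919 + ai * 104729) % (2**31 - 1)
        arm_report: dict = {}

        # --- beat-frequency stage
        cells = [
            simulate.rect_motif(i + 1, 4, 44, 4 + 44 * i, 44 + 44 * i,
                                beat_frequency=f, amplitude=a,
                                phase_gradient=(0.05, 0.05))
            for i, (f, a) in enumerate(zip(p["freqs"], p["amps"]))
        ]
        vspec = simulate.CiliaVideoSpec(
            n_frames=200, fps=100.0, height=48, width=224, cells=cells,
            noise_sd=60.0, seed=arm_seed,
        )
        video, labels, _ = simulate.generate_cilia_video(vspec)
        fmap = cbf.dominant_frequency_map(video)
        ccells = cbf.assign_beat_modes(cbf.summarize_cell_cbf(fmap, labels), fmap)
        stage_dir = arm_dir / "cbf"
        stage_dir.mkdir(exist_ok=True)
        cbf.cells_to_frame(ccells).to_csv(stage_dir / "cell_cbf.csv", **_CSV_KW)
        modes = [c.beat_mode for c in ccells]
        arm_report["cbf"] = {
            "motility_index": cbf.field_motility_index(fmap),
            "static_fraction": modes.count("static") / len(modes),
            "median_cbf": float(np.nanmedian([c.cbf_median for c in ccells])),
        }

        # --- polarity stage
        sspec = simulate.SpotFieldSpec(
            n_cells=4, spots_per_cell=25, kappa=p["kappa"],
            mu_per_cell=[0.3, 1.1, -0.8, 2.4], noise_sd=20.0, seed=arm_seed + 1,
        )
        image, mask, _ = simulate.generate_spot_field(sspec)
        kw = dict(pixel_size_nm=sspec.pixel_size, sigma_nm=sspec.psf_sigma)
        pairs, _, _ = polarity.pair_spots(
            polarity.detect_spots(image[0], channel=0, **kw),
            polarity.detect_spots(image[1], channel=1, **kw),
            sspec.pixel_size,
        )
        pcells = polarity.cell_polarity(pairs, mask)
        stage_dir = arm_dir / "polarity"
        stage_dir.mkdir(exist_ok=True)
        polarity.polarity_to_frame(pcells).to_csv(stage_dir / "cell_polarity.csv", **_CSV_KW)
        arm_report["polarity"] = {
            "median_R": float(np.median([c.resultant_length for c in pcells if c.scored])),
            "n_cells": len(pcells),
        }

        # --- ciliation stage
        cspec = simulate.CiliationStackSpec(
            ciliated_fraction=p["ciliated_fraction"], seed=arm_seed + 2,
        )
        stack, _ = simulate.generate_ciliation_stack(cspec)
        result = morphometry.ciliation_result(stack[0], stack[1], cspec.voxel_size)
        stage_dir = arm_dir / "ciliation"
        stage_dir.mkdir(exist_ok=True)
        pd.DataFrame([{
            "n_bb": result.n_basal_bodies, "n_cilia": result.n_cilia,
            "ciliation_level": result.ciliation_level,
        }]).to_csv(stage_dir / "ciliation.csv", **_CSV_KW)
        summ = morphometry.summarize_lengths(
            [morphometry.CiliumTrace(np.empty((0, 3)), np.empty((0, 3)), l) for l in result.lengths]
        )
        arm_report["ciliation"] = {
            "ciliation_level": result.ciliation_level,
            "mean_length_um": summ["mean"],
        }

        # --- clearance stage
        bspec = simulate.BeadVideoSpec(
            n_beads=12, drift_velocity=p["drift"], diffusion_coeff=p["diffusion"],
            n_frames=40, seed=arm_seed + 3,
        )
        bvideo, _ = simulate.generate_bead_video(bspec)
        tracks = clearance.track_beads(bvideo, max_step_um=1.2)
        metrics = clearance.compute_clearance_metrics(tracks, bvideo.fps)
        stage_dir = arm_dir / "beads"
        stage_dir.mkdir(exist_ok=True)
        clearance.tracks_to_frame(tracks).to_csv(stage_dir / "tracks.csv", **_CSV_KW)
        arm_report["clearance"] = {
            "coherence": metrics.directional_coherence,
            "mean_speed": metrics.mean_speed,
            "call": metrics.clearance_call,
        }
        report[arm] = arm_report

    checks = {
        "motility_control_gt_ko": report["control"]["cbf"]["motility_index"]
        > report["ko"]["cbf"]["motility_index"],
        "static_fraction_ko_gt_control": report["ko"]["cbf"]["static_fraction"]
        > report["control"]["cbf"]["static_fraction"],
        "polarity_R_control_gt_ko": report["control"]["polarity"]["median_R"]
        > report["ko"]["polarity"]["median_R"],
        "ciliation_control_gt_ko": report["control"]["ciliation"]["ciliation_level"]
        > report["ko"]["ciliation"]["ciliation_level"],
        "clearance_control_present": report["control"]["clearance"]["call"] == "present",
        "clearance_ko_absent": report["ko"]["clearance"]["call"] == "absent",
    }
    report["separation_checks"] = checks
    report_path = outdir / "comparison_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    rows = []
    for arm in ("control", "ko"):
        for stage, metrics_ in report[arm].items():
            for k, v in metrics_.items():
                rows.append({"arm": arm, "stage": stage, "metric": k, "value": v})
    csv_path = outdir / "comparison_report.csv"
    pd.DataFrame(rows, columns=["arm", "stage", "metric", "value"]).to_csv(csv_path, **_CSV_KW)
    return [str(report_path), str(csv_path)]
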