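"""Configuration, pipeline orchestration and fixture generation.

A :class:`PipelineConfig` collects every stage's parameters (each random
stage has an explicit seed derived from the top-level one) and round-trips
losslessly through YAML.  :func:`run_pipeline` executes
simulate -> univariate -> mvpa -> eye-control, writes all tables and a
manifest with per-file checksums and the config hash, and halts with a
stage-named error (after writing a partial manifest) if any stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bold, design, eye, mvpa, observer, univariate
from .bold import ROI_NAMES, SimulationParams
from .design import DesignParams
from .observer import ObserverModel
from .stimulus import StimulusParams

__all__ = [
    "AnalysisParams",
    "EyeParams",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "make_fixtures",
]

log = logging.getLogger("dsfm_attention")


@dataclass(frozen=True)
class AnalysisParams:
    highpass_cutoff: float | None = 100.0  # seconds; None disables filtering
    derivatives: bool = True
    drift: bool = True
    prewhiten: bool = False
    pool: str = "scan"
    k_voxels: int = 100
    C: float = 1.0
    folds: int = 5
    shift: int = 1            # volumes of hemodynamic label shift
    iterations: int = 50      # classification iterations in the pipeline
    n_perm: int = 200         # permutations in the pipeline (10^4 at full scale)
    alpha: float = 0.05
    n_areas: int = 7          # Bonferroni family size


@dataclass(frozen=True)
class EyeParams:
    rate: float = 500.0       # Hz
    duration: float = 4.0     # seconds per trial
    jitter_sd: float = 0.2    # degrees, stationary fixation jitter
    tau: float = 0.5          # seconds, jitter correlation time
    attend_offset: float = 0.0
    n_features: int = 50


@dataclass
class PipelineConfig:
    seed: int = 0
    n_scans: int = 6
    grid: tuple[int, int, int] = (20, 20, 10)
    roi_names: tuple[str, ...] = ROI_NAMES
    design: DesignParams = field(default_factory=DesignParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    observer: ObserverModel = field(default_factory=ObserverModel)
    sim: SimulationParams = field(default_factory=SimulationParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    eye: EyeParams = field(default_factory=EyeParams)
    mvpa_rois: tuple[tuple[str, str], ...] = (("V1", "left"),)
    comparisons: tuple[str, ...] = mvpa.COMPARISONS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["roi_names"] = list(self.roi_names)
        d["mvpa_rois"] = [list(r) for r in self.mvpa_rois]
        d["comparisons"] = list(self.comparisons)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("design", DesignParams), ("stimulus", StimulusParams),
                         ("observer", ObserverModel), ("sim", SimulationParams),
                         ("analysis", AnalysisParams), ("eye", EyeParams)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f in dataclasses.fields(typ):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                d[key] = typ(**sub)
        for key in ("grid", "roi_names", "comparisons"):
            if key in d:
                d[key] = tuple(d[key])
        if "mvpa_rois" in d:
            d["mvpa_rois"] = tuple(tuple(r) for r in d["mvpa_rois"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("design", "behavior", "bold", "mvpa", "eye")
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2 ** 31))
            for n, s in zip(names, ss)}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic pipeline and write a result bundle.

    Returns a dict with in-memory results and the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log.info("stage seeds: %s", seeds)
    if config.analysis.n_perm < 100:
        log.warning("n_perm=%d (<100): permutation null will be unstable",
                    config.analysis.n_perm)
    files: list[Path] = []
    results: dict = {"seeds": seeds}

    def _finish(status: str) -> None:
        manifest = {
            "status": status,
            "config_hash": config.hash(),
            "seeds": seeds,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    stage = "design"
    try:
        dsg = design.build_design(seeds["design"], config.n_scans,
                                  config.design)
        events = design.design_to_events(dsg)
        design.write_events(events, out / "events.tsv")
        files.append(out / "events.tsv")
        results["events"] = events

        stage = "behavior"
        behav = observer.simulate_trials(events, config.observer,
                                         seeds["behavior"])
        behav.to_csv(out / "behavior.tsv", sep="\t", index=False)
        files.append(out / "behavior.tsv")
        summary = observer.summarize(behav)
        (out / "behavior_summary.json").write_text(
            summary.to_json(orient="records", indent=2))
        files.append(out / "behavior_summary.json")
        results["behavior_summary"] = summary

        stage = "bold_simulation"
        rois = bold.make_rois(tuple(config.grid), tuple(config.roi_names))
        dataset = bold.simulate_dataset(dsg, rois, config.sim,
                                        seed=seeds["bold"])
        dataset.save(out / "bold")
        files += sorted((out / "bold").iterdir())
        results["dataset"] = dataset

        stage = "univariate"
        a = config.analysis
        table = univariate.condition_table(
            dataset, pool=a.pool, highpass_cutoff=a.highpass_cutoff,
            derivatives=a.derivatives, drift=a.drift, prewhiten=a.prewhiten)
        table.to_csv(out / "roi_responses.tsv", sep="\t", index=False)
        files.append(out / "roi_responses.tsv")
        results["roi_responses"] = table
        n_rep = table.groupby("roi").size().min()
        if n_rep >= 5:
            stats_table = univariate.roi_stats(table, alpha=a.alpha,
                                               n_areas=a.n_areas)
            stats_table.to_csv(out / "roi_stats.tsv", sep="\t", index=False)
            files.append(out / "roi_stats.tsv")
            results["roi_stats"] = stats_table
        else:
            log.warning("only %d replicate(s) per ROI; skipping ROI statistics"
                        " (need >= 5 paired replicates)", n_rep)

        stage = "mvpa"
        stat_map = mvpa.localizer_stats(dataset, shift=a.shift)
        mvpa_rows = []
        for roi_name, hemi in config.mvpa_rois:
            for comparison in config.comparisons:
                res, perm = mvpa.decode(
                    dataset, roi_name, hemi, comparison, k=a.k_voxels,
                    iterations=a.iterations, seed=seeds["mvpa"], C=a.C,
                    folds=a.folds, shift=a.shift, alpha=a.alpha,
                    n_areas=a.n_areas, stat_map=stat_map, n_perm=a.n_perm)
                mvpa_rows.append({
                    "roi": roi_name, "hemisphere": hemi,
                    "comparison": comparison,
                    "mean_accuracy": res.mean_accuracy,
                    "ci_low": res.ci[0], "ci_high": res.ci[1],
                    "null_mean": perm.null_mean,
                    "null_ci_low": perm.null_ci[0],
                    "null_ci_high": perm.null_ci[1],
                    "significant": perm.significant,
                })
        (out / "mvpa_results.json").write_text(
            json.dumps(mvpa_rows, indent=2))
        files.append(out / "mvpa_results.json")
        results["mvpa"] = mvpa_rows

        stage = "eye_control"
        e = config.eye
        traces, labels = bold.simulate_eye_traces(
            events, rate=e.rate, duration=e.duration, jitter_sd=e.jitter_sd,
            tau=e.tau, attend_offset=e.attend_offset, seed=seeds["eye"])
        pos = eye.mean_position_test(traces, labels)
        pos.to_csv(out / "eye_mean_position.tsv", sep="\t", index=False)
        files.append(out / "eye_mean_position.tsv")
        eye_rows = {}
        for comparison in ("side", "similarity"):
            r = eye.classify_eye_trials(
                traces, labels, comparison=comparison,
                n_features=e.n_features, n_perm=a.n_perm,
                seed=seeds["eye"], C=a.C, folds=a.folds,
                iterations=a.iterations, alpha=a.alpha)
            eye_rows[comparison] = {
                "observed_mean": r.observed_mean, "null_mean": r.null_mean,
                "null_ci": list(r.null_ci), "significant": r.significant,
            }
        (out / "eye_classification.json").write_text(
            json.dumps(eye_rows, indent=2))
        files.append(out / "eye_classification.json")
        feats = eye.trace_features(traces, n_features=e.n_features)
        feat_df = pd.DataFrame(feats)
        feat_df.insert(0, "trial", labels["trial"])
        feat_df.to_csv(out / "eye_traces_features.tsv", sep="\t", index=False)
        files.append(out / "eye_traces_features.tsv")
        results["eye"] = eye_rows
    except Exception as err:
        _finish(f"failed at {stage}")
        raise PipelineError(stage, err) from err

    _finish("complete")
    files.append(out / "manifest.json")
    results["files"] = [str(p) for p in files]
    return results


def tiny_config(seed: int = 0) -> PipelineConfig:
    """A desk-scale configuration: 2 ROIs, 1 scan, 500 permutations."""
    return PipelineConfig(
        seed=seed, n_scans=1, grid=(10, 8, 4), roi_names=("V1", "hMT+"),
        analysis=AnalysisParams(k_voxels=40, iterations=20, n_perm=500,
                                n_areas=2),
        mvpa_rois=(("V1", "left"),),
    )


def full_config(seed: int = 0) -> PipelineConfig:
    """The complete experimental geometry: 7 areas, 6 scans, 10^4 permutations."""
    return PipelineConfig(
        seed=seed, n_scans=6, grid=(20, 20, 10), roi_names=ROI_NAMES,
        analysis=AnalysisParams(k_voxels=100, iterations=10_000,
                                n_perm=10_000, n_areas=7),
        mvpa_rois=tuple((n, h) for n in ROI_NAMES for h in ("left", "right")),
    )


def make_fixtures(scale: str, out_dir) -> Path:
    """Write a self-contained fixture directory (config, events, data).

    scale="tiny" builds the desk-scale geometry in well under a minute;
    scale="full" builds the full 7-area, 6-scan, 1440-volume geometry.
    Eye traces are stored at feature resolution (50 samples/trial).
    """
    if scale == "tiny":
        config = tiny_config()
    elif scale == "full":
        config = full_config()
    else:
        raise ValueError(f"unknown scale {scale!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    config.to_yaml(out / "config.yaml")
    dsg = design.build_design(seeds["design"], config.n_scans, config.design)
    events = design.design_to_events(dsg)
    design.write_events(events, out / "events.tsv")
    rois = bold.make_rois(tuple(config.grid), tuple(config.roi_names))
    dataset = bold.simulate_dataset(dsg, rois, config.sim, seed=seeds["bold"])
    dataset.save(out / "bold")
    e = config.eye
    traces, labels = bold.simulate_eye_traces(
        events, rate=e.rate, duration=e.duration, jitter_sd=e.jitter_sd,
        tau=e.tau, seed=seeds["eye"])
    feats = eye.trace_features(traces, n_features=e.n_features)
    feat_df = pd.DataFrame(feats)
    feat_df.insert(0, "trial", labels["trial"])
    feat_df.to_csv(out / "eye_traces_features.tsv", sep="\t", index=False)
    all_files = sorted(p for p in out.rglob("*") if p.is_file()
                       and p.name != "manifest.json")
    manifest = {
        "scale": scale,
        "config_hash": config.hash(),
        "n_volumes": dataset.n_scans * dataset.volumes_per_scan,
        "files": {str(p.relative_to(out)): _sha256(p) for p in all_files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
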