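"""End-to-end orchestration: simulate/read -> detect -> colocalize ->
aggregate -> outlier screen -> group summary; and the behavioral arm:
simulate/read logs -> score. Every run serializes its config and seed next
to the outputs so any table is reproducible bit-identically."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aggregate as agg
from . import behavior as beh
from . import coloc, detect, simulate
from .io import StackMeta, read_stack, write_table

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("synaptopy")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full run (simulated cohort).

    The imaging cohort is ``groups x mice_per_group`` mice, each imaged in
    both ROIs with ``images_per_roi`` replicates (hemisphere x section). The
    behavioral cohort runs every mouse through the four test stages.
    """

    out_dir: str = "runs/demo"
    seed: int = 0
    log_level: str = "INFO"
    # imaging cohort
    groups: tuple[str, ...] = ("grp1", "grp2")
    mice_per_group: int = 8
    images_per_roi: int = 4
    stack_ny: int = 256
    stack_nx: int = 256
    stack_nz: int = 15
    n_pre: int = 150
    n_post: int = 150
    coloc_fraction: float = 0.5
    snr: float = 5.0
    group_coloc_delta: float = 0.0  # added to coloc_fraction for later groups
    # detection / colocalization / screening
    detection: detect.DetectionParams = field(default_factory=detect.DetectionParams)
    min_overlap_voxels: int = 1
    rout_q_percent: float = 1.0
    # behavior
    behavior_stages: tuple[str, ...] = beh.STAGES
    behavior_curve: simulate.LearningCurve = field(default_factory=simulate.LearningCurve)
    omission_prob: float = 0.01
    stack_paths: tuple[str, ...] = ()  # optional: analyse acquired stacks instead
    session_log: str = ""  # optional: score an existing session-log CSV

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "detection" in raw:
        raw["detection"] = detect.DetectionParams(**{
            k: tuple(v) if k == "log_sigmas" else v for k, v in raw["detection"].items()
        })
    if "behavior_curve" in raw:
        raw["behavior_curve"] = simulate.LearningCurve(**raw["behavior_curve"])
    for key in ("groups", "behavior_stages", "stack_paths"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _analyse_stack(stack, config: RunConfig):
    pre_set = detect.detect_puncta(
        stack.pre, config.detection, channel_label="pre", image_id=stack.meta.image_id
    )
    post_set = detect.detect_puncta(
        stack.post, config.detection, channel_label="post", image_id=stack.meta.image_id
    )
    pairs = coloc.match_puncta(pre_set, post_set, config.min_overlap_voxels)
    summary = coloc.summarize_image(pre_set, post_set, pairs)
    return pre_set, post_set, pairs, summary


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the written artifact paths.

    Stages run in order; any failure aborts with a stage-attributed message
    and partial outputs are retained. Reruns with the same config and seed
    reproduce all tables bit-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    run_log = out / "run.log"
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    artifacts: dict[str, Path] = {"run_log": run_log}
    try:
        provenance = {"config": asdict(config), "config_hash": config.config_hash(), "seed": config.seed}
        prov_path = out / "provenance.yaml"
        prov_path.write_text(yaml.safe_dump(provenance, sort_keys=True, default_flow_style=False))
        artifacts["provenance"] = prov_path

        artifacts.update(_imaging_arm(config, out))
        artifacts.update(_behavior_arm(config, out))
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts


def _imaging_arm(config: RunConfig, out: Path) -> dict[str, Path]:
    stage = "simulate/read stacks"
    summaries: list[coloc.ImageSummary] = []
    metas: list[StackMeta] = []
    try:
        stacks = []
        if config.stack_paths:
            for p in config.stack_paths:
                stacks.append(read_stack(p))
        else:
            image_seed = config.seed
            for g_idx, group in enumerate(config.groups):
                f = min(1.0, max(0.0, config.coloc_fraction + g_idx * config.group_coloc_delta))
                for m in range(config.mice_per_group):
                    mouse = f"{group}-m{m + 1}"
                    for roi in ("MO", "VO"):
                        for img in range(config.images_per_roi):
                            image_seed += 1
                            meta = StackMeta(
                                mouse=mouse,
                                group=group,
                                roi=roi,
                                hemisphere=("left", "right")[img % 2],
                                section=img // 2 + 1,
                                image_id=f"{mouse}-{roi}-{img + 1}",
                            )
                            stack, _truth = simulate.gen_stack(
                                n_pre=config.n_pre,
                                n_post=config.n_post,
                                coloc_fraction=f,
                                snr=config.snr,
                                geometry=simulate.StackGeometry(
                                    nz=config.stack_nz, ny=config.stack_ny, nx=config.stack_nx
                                ),
                                seed=image_seed,
                                meta=meta,
                            )
                            stacks.append(stack)
        log.info("imaging arm: %d stacks", len(stacks))

        stage = "detect/colocalize"
        for stack in stacks:
            _pre, _post, _pairs, summary = _analyse_stack(stack, config)
            summaries.append(summary)
            metas.append(stack.meta)
            log.info(
                "image %s: n_pre=%d n_post=%d n_coloc=%d",
                summary.image_id,
                summary.n_pre,
                summary.n_post,
                summary.n_coloc,
            )
        summary_path = write_table(coloc.summary_table(summaries), out / "image_summaries.csv")

        stage = "aggregate"
        keyed: dict[tuple[str, str], tuple[list, list]] = {}
        for s, m in zip(summaries, metas):
            keyed.setdefault((m.mouse, m.roi or ""), ([], []))
            keyed[(m.mouse, m.roi or "")][0].append(s)
            keyed[(m.mouse, m.roi or "")][1].append(m)
        records = [agg.aggregate_mouse_roi(ss, mm) for ss, mm in keyed.values()]
        records_path = write_table(agg.records_table(records), out / "mouse_roi_records.csv")

        stage = "outlier-flag/group-summary"
        tables = []
        for metric in ("n_pre", "n_post", "n_coloc", "mean_intensity_pre", "mean_intensity_post"):
            tables.append(agg.group_summary(records, metric, config.rout_q_percent))
        group_path = write_table(pd.concat(tables, ignore_index=True), out / "group_summary.csv")
        return {
            "image_summaries": summary_path,
            "mouse_roi_records": records_path,
            "group_summary": group_path,
        }
    except Exception as exc:
        raise RuntimeError(f"imaging arm failed at stage '{stage}': {exc}") from exc


def _behavior_arm(config: RunConfig, out: Path) -> dict[str, Path]:
    stage = "simulate/read logs"
    try:
        log_frames = []
        if config.session_log:
            from .io import read_table

            table = read_table(config.session_log)
            keyed = beh.trials_from_table(table)
        else:
            keyed = {}
            beh_seed = config.seed + 10_000
            for group in config.groups:
                for m in range(config.mice_per_group):
                    mouse = f"{group}-m{m + 1}"
                    for st in config.behavior_stages:
                        beh_seed += 1
                        trials, _truth = simulate.gen_behavior(
                            stage=st,
                            curve=config.behavior_curve,
                            omission_prob=config.omission_prob,
                            seed=beh_seed,
                            mouse=mouse,
                        )
                        keyed[(mouse, group, st)] = trials
            for (mouse, group, st), trials in keyed.items():
                log_frames.append(beh.trials_table(trials, mouse=mouse, group=group))
        artifacts = {}
        if log_frames:
            logs_path = write_table(pd.concat(log_frames, ignore_index=True), out / "session_logs.csv")
            artifacts["session_logs"] = logs_path

        stage = "score"
        rows = []
        for (mouse, group, st), trials in keyed.items():
            score = beh.score_stage(trials)
            rows.append(
                {
                    "mouse": mouse,
                    "group": group,
                    "stage": st,
                    "total_trials": score.total_trials,
                    "total_errors": score.total_errors,
                    "median_latency_s": score.median_latency_s,
                    "criterion_session": score.criterion_session if score.reached else "not reached",
                    "criterion_trial": score.criterion_trial if score.reached else "not reached",
                }
            )
        scores = pd.DataFrame(
            rows,
            columns=[
                "mouse",
                "group",
                "stage",
                "total_trials",
                "total_errors",
                "median_latency_s",
                "criterion_session",
                "criterion_trial",
            ],
        )
        scores_path = write_table(scores, out / "stage_scores.csv")
        artifacts["stage_scores"] = scores_path
        return artifacts
    except Exception as exc:
        raise RuntimeError(f"behavior arm failed at stage '{stage}': {exc}") from exc
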