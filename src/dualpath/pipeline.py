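"""End-to-end orchestration: synth -> qc -> preprocess -> train / evaluate ->
xai -> plsc, from one config with one master seed.

Each stage writes its artifacts plus a manifest under ``out_dir/<stage>/``
and records the seeds it used.  Per-stage seeds are derived from the master
seed with a hash splitter, so stages are reproducible independently and a
rerun with the same config is deterministic.
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

from . import behavior as bb
from . import xai
from .cohort import Cohort, CohortFormat, load_cohort, save_results
from .evaluate import (SearchSpace, encode_cohort_metadata, nested_cv,
                       prepare_inputs)
from .nn import ArchitectureConfig, TrainConfig, TrainedDualPath, fit_dualpath
from .preprocess import QcPolicy, SegmentSpec, apply_qc, condition_cohort
from .synth import BehaviorModel, EventSpec, SyntheticSpec, generate_cohort

log = logging.getLogger(__name__)

STAGE_ORDER = ["synth", "qc", "preprocess", "evaluate", "train", "xai", "plsc"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Counter-free splitter: hash master seed and stage name to < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class XaiSettings:
    fraction: float = 0.05
    alpha: float = 0.05
    min_len: int = 3
    n_steps: int = 32
    core_threshold: int = 2
    n_ensemble: int = 4   # independently seeded fits averaged for attribution


@dataclass
class BehaviorSettings:
    score_names: list[str] = field(default_factory=lambda: list(bb.DEFAULT_SCORES))
    n_perm: int = 1000
    n_boot: int = 1000


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    master_seed: int = 0
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    qc: QcPolicy = field(default_factory=QcPolicy)
    segment: SegmentSpec | None = None
    bandpass: tuple[float, float] | None = None
    delay_seconds: float | None = None
    scale: str = "none"
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    search: SearchSpace = field(default_factory=SearchSpace)
    training: TrainConfig = field(default_factory=TrainConfig)
    xai: XaiSettings = field(default_factory=XaiSettings)
    behavior: BehaviorSettings = field(default_factory=BehaviorSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "synthetic": SyntheticSpec, "qc": QcPolicy,
            "architecture": ArchitectureConfig, "search": SearchSpace,
            "training": TrainConfig, "xai": XaiSettings,
            "behavior": BehaviorSettings, "segment": SegmentSpec,
        }
        for key, val in raw.items():
            if key == "synthetic" and isinstance(val, dict):
                val = dict(val)
                if "events" in val:
                    val["events"] = tuple(
                        EventSpec(**{**e, "rois": tuple(e["rois"])})
                        if isinstance(e, dict) else e for e in val["events"])
                if "behavior" in val and isinstance(val["behavior"], dict):
                    b = dict(val["behavior"])
                    if "loadings" in b:
                        b["loadings"] = tuple(b["loadings"])
                    if "scores" in b:
                        b["scores"] = {k: tuple(v) for k, v in b["scores"].items()}
                    val["behavior"] = BehaviorModel(**b)
                for tup_key in ("trait_rois", "site_levels", "site_offsets", "p_male"):
                    if tup_key in val:
                        val[tup_key] = tuple(val[tup_key])
                kwargs[key] = SyntheticSpec(**val)
            elif key in nested and isinstance(val, dict):
                kwargs[key] = nested[key](**val)
            elif key in ("bandpass",) and isinstance(val, list):
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def echo(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [conv(v) for v in obj]
            return obj
        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


class PipelineError(RuntimeError):
    pass


def _write_cohort(cohort: Cohort, truth, out: Path) -> None:
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for ts in cohort.series:
        np.savetxt(ts_dir / f"{ts.subject_id}.tsv", ts.data, delimiter="\t", fmt="%.6f")
    rows = []
    for rec in cohort.records:
        row = {"subject_id": rec.subject_id, "diagnosis": rec.diagnosis,
               "age_years": rec.age_years, "sex": rec.sex, "site": rec.site,
               "mean_fd_mm": rec.mean_fd_mm,
               "pct_volumes_repaired": rec.pct_volumes_repaired}
        row.update(rec.behavior)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    if truth is not None:
        truth.amplitudes.to_csv(out / "true_amplitudes.tsv", sep="\t")
        (out / "ground_truth.json").write_text(json.dumps({
            "trait_rois": list(truth.trait_rois),
            "event_windows": [list(w) for w in truth.event_windows],
            "event_rois": [list(r) for r in truth.event_rois],
            "behavior_loadings": list(map(float, truth.behavior_loadings)),
        }, indent=2) + "\n")


def _load_cohort_from(out: Path, tr_seconds: float, n_regions: int) -> Cohort:
    fmt = CohortFormat(tr_seconds=tr_seconds, orientation="region_major",
                       n_regions=n_regions)
    return load_cohort(out / "timeseries", out / "phenotypes.tsv", fmt)


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; returns the manifest.

    Later stages reload upstream artifacts from disk when not run in the
    same call; a missing upstream artifact raises a PipelineError naming
    the stage to run first.
    """
    stages = list(STAGE_ORDER) if stages is None else \
        [s for s in STAGE_ORDER if s in set(stages)]
    unknown = set(stages or []) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.echo(), sort_keys=False))

    manifest: dict[str, list[str]] = {}
    state: dict = {}

    def need_cohort(stage: str) -> Cohort:
        if "cohort" in state:
            return state["cohort"]
        synth_dir = out / "synth"
        if not (synth_dir / "phenotypes.tsv").exists():
            raise PipelineError(f"stage '{stage}' needs a cohort; run 'synth' first")
        cohort = _load_cohort_from(synth_dir, config.synthetic.tr_seconds,
                                   config.synthetic.n_regions)
        state["cohort"] = cohort
        return cohort

    def finish(stage: str, stage_dir: Path, seeds: dict) -> None:
        files = sorted(p.name for p in stage_dir.iterdir() if p.is_file())
        (stage_dir / "log.json").write_text(json.dumps(
            {"stage": stage, "seeds": seeds, "files": files}, indent=2) + "\n")
        manifest[stage] = files + ["log.json"]

    for stage in stages:
        stage_dir = out / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        seed = derive_seed(config.master_seed, stage)
        log.info("stage %s (seed %d)", stage, seed)

        if stage == "synth":
            spec = dataclasses.replace(config.synthetic, seed=seed)
            cohort, truth = generate_cohort(spec)
            state["cohort"], state["truth"] = cohort, truth
            _write_cohort(cohort, truth, stage_dir)
            finish(stage, stage_dir, {"generator": seed})

        elif stage == "qc":
            cohort = need_cohort(stage)
            cohort, report = apply_qc(cohort, config.qc)
            state["cohort"] = cohort
            report.to_csv(stage_dir / "exclusions.tsv", sep="\t", index=False)
            finish(stage, stage_dir, {})

        elif stage == "preprocess":
            cohort = need_cohort(stage)
            cohort = condition_cohort(cohort, bandpass=config.bandpass,
                                      delay_seconds=config.delay_seconds,
                                      segment=config.segment,
                                      zscore=(config.scale == "zscore"))
            state["cohort"] = cohort
            (stage_dir / "settings.json").write_text(json.dumps({
                "bandpass": config.bandpass, "delay_seconds": config.delay_seconds,
                "segment": None if config.segment is None else config.segment.name,
                "scale": config.scale}, indent=2) + "\n")
            finish(stage, stage_dir, {})

        elif stage == "evaluate":
            cohort = need_cohort(stage)
            space = dataclasses.replace(config.search, seed=seed)
            report = nested_cv(cohort, space, config.architecture,
                               train_cfg=config.training, seed=seed)
            report.fold_metrics.to_csv(stage_dir / "fold_metrics.tsv",
                                       sep="\t", index=False)
            (stage_dir / "cv_report.json").write_text(json.dumps({
                "mean": report.mean, "sd": report.sd, "chosen": report.chosen,
                "seeds": report.seeds}, indent=2) + "\n")
            state["cv_report"] = report
            finish(stage, stage_dir, {"cv": seed})

        elif stage == "train":
            cohort = need_cohort(stage)
            X, y = prepare_inputs(cohort, scale=config.scale)
            meta = encode_cohort_metadata(cohort, np.arange(len(y)))
            cfg = dataclasses.replace(config.training, seed=seed)
            trained = fit_dualpath(X, meta, y, config.architecture, cfg)
            state["trained"] = trained
            np.savez(stage_dir / "checkpoint.npz", **trained.state)
            (stage_dir / "architecture.json").write_text(
                json.dumps(trained.architecture_json(), indent=2) + "\n")
            prov = {k: v for k, v in trained.provenance.items() if k != "history"}
            (stage_dir / "provenance.json").write_text(json.dumps(prov, indent=2) + "\n")
            finish(stage, stage_dir, {"train": seed})

        elif stage == "xai":
            cohort = need_cohort(stage)
            if "trained" not in state:
                ckpt = out / "train" / "checkpoint.npz"
                if not ckpt.exists():
                    raise PipelineError("stage 'xai' needs a model; run 'train' first")
                with np.load(ckpt) as z:
                    trained = TrainedDualPath(config.architecture,
                                              {k: z[k] for k in z.files})
                state["trained"] = trained
            trained = state["trained"]
            X, y = prepare_inputs(cohort, scale=config.scale)
            meta = encode_cohort_metadata(cohort, np.arange(len(y)))
            models = [trained]
            if config.xai.n_ensemble > 1:
                cfg_e = dataclasses.replace(config.training, seed=seed)
                from .nn.train import fit_ensemble
                models += fit_ensemble(X, meta, y, config.architecture, cfg_e,
                                       n_models=config.xai.n_ensemble - 1)
            bundles = xai.ensemble_bundles(models, X, meta, cohort.subject_ids,
                                           n_steps=config.xai.n_steps)
            state["bundles"] = bundles
            mask = y == 1
            attn = np.stack([b.attention for b in bundles])
            events = xai.detect_events(attn[mask], attn[~mask],
                                       alpha=config.xai.alpha,
                                       min_len=config.xai.min_len)
            state["events"] = events
            maps = xai.group_pooled_ig(bundles, mask)
            global_set = xai.top_k_rois(maps["case"], config.xai.fraction)
            case_bundles = [b for b, m in zip(bundles, mask) if m]
            event_sets = [xai.event_top_rois(case_bundles, w, config.xai.fraction)
                          for w in events]
            concord = xai.attention_ig_concordance(bundles, mask)
            indices = xai.saliency_indices(bundles, global_set, event_sets, events) \
                if events else []
            state["global_set"], state["event_sets"] = global_set, event_sets
            state["indices"] = indices

            xai.events_frame(events).to_csv(stage_dir / "events.tsv",
                                            sep="\t", index=False)
            pd.DataFrame({"region_id": cohort.region_ids,
                          "ig_case": maps["case"], "ig_control": maps["control"],
                          "ig_overall": maps["overall"]}).to_csv(
                stage_dir / "pooled_ig.tsv", sep="\t", index=False)
            pd.DataFrame({"region_index": global_set}).to_csv(
                stage_dir / "global_top_rois.tsv", sep="\t", index=False)
            if events:
                cpm = xai.core_presence([list(s) for s in event_sets],
                                        len(cohort.region_ids),
                                        min(config.xai.core_threshold, len(events)),
                                        cohort.region_ids)
                cpm.matrix.to_csv(stage_dir / "core_presence.tsv", sep="\t")
                xai.indices_frame(indices).to_csv(stage_dir / "saliency_indices.tsv",
                                                  sep="\t", index=False)
            (stage_dir / "concordance.json").write_text(json.dumps(
                {g: {"r": r, "p": p} for g, (r, p) in concord.items()},
                indent=2) + "\n")
            attn_df = pd.DataFrame(attn, index=cohort.subject_ids)
            attn_df.to_csv(stage_dir / "attention.tsv", sep="\t")
            finish(stage, stage_dir, {"xai": seed})

        elif stage == "plsc":
            cohort = need_cohort(stage)
            if "indices" not in state:
                idx_path = out / "xai" / "saliency_indices.tsv"
                if not idx_path.exists():
                    raise PipelineError("stage 'plsc' needs saliency indices; run 'xai' first")
                idx_df = pd.read_csv(idx_path, sep="\t")
            else:
                idx_df = xai.indices_frame(state["indices"])
            idx_df = idx_df.set_index("subject_id").loc[cohort.subject_ids]
            event_cols = [c for c in idx_df.columns if c.startswith("E")]
            scores, _ = bb.behavior_matrix(cohort, config.behavior.score_names)
            cov = bb.covariate_matrix(cohort)
            y = cohort.labels
            case = y == 1

            r, p = bb.partial_pearson(idx_df["global_index"].to_numpy()[case],
                                      scores[case, 0], cov[case])
            result = bb.plsc(idx_df[event_cols].to_numpy()[case], scores[case],
                             covariates=cov[case],
                             n_perm=config.behavior.n_perm,
                             n_boot=config.behavior.n_boot, seed=seed)
            state["plsc"] = result
            save_results(result, stage_dir, prefix="plsc_")
            (stage_dir / "global_partial_corr.json").write_text(json.dumps(
                {"score": config.behavior.score_names[0], "r": r, "p": p},
                indent=2) + "\n")
            finish(stage, stage_dir, {"plsc": seed})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"manifest": manifest, "state": state, "out_dir": str(out)}
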