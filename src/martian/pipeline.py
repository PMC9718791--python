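"""End-to-end orchestration: simulate -> align -> stage 1 -> post-process ->
stage 2 -> evaluate.

The stage order is fixed: once stage-1 artifacts (the refined synthetic kV
targets) are produced, stage 1 is no longer involved — stage 2 is the only
network applied at inference time. Study-level splits keep three pools
disjoint: stage-1 validation studies never feed stage-2 training, and a
held-out pool is touched only by the final evaluation.

Every stage writes its outputs under the working directory together with a
manifest carrying the config hash and seed; ``resume=True`` reuses a stage's
outputs when its recorded hash matches the current config.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import phantom_sim as sim
from .evaluation import (CATEGORY_ALL, EvalReport, build_report)
from .io_prep import (METAL_THRESHOLD_HU, AugmentationConfig, CTVolume,
                      NormalizationWindow, PairedSlice, augment, normalize)
from .losses import LossWeights
from .networks import (DiscriminatorSpec, GeneratorFunction, GeneratorSpec)
from .postprocess import (OverrideRule, build_stage2_pairs, intensity_override,
                          refine_monomodal)
from .registration import (MODE_MONOMODAL, MODE_MULTIMODAL,
                           RegistrationConfig, register)
from .training import TrainConfig, StageReport, infer_volume, train_stage


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "martian_run"
    seed: int = 0
    n_studies: int = 20
    holdout_fraction: float = 0.2
    stage1_val_fraction: float = 0.1
    dataset: sim.DatasetParams = sim.DatasetParams()
    gen_spec: GeneratorSpec = GeneratorSpec()
    disc_spec: DiscriminatorSpec = DiscriminatorSpec()
    weights: LossWeights = LossWeights()
    epochs: int = 100
    batch_size: int = 3
    learning_rate: float = 2e-4
    window: NormalizationWindow = NormalizationWindow()
    augmentation: AugmentationConfig = AugmentationConfig()
    registration_iterations: int = 50
    # control-point spacing (mm/level) of the mono-modal refinement; should
    # scale with the field of view so the DIR has comparable freedom
    refinement_grid: tuple[float, float, float] = (64.0, 32.0, 16.0)
    desk_scale: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def desk_scale_config(out_dir: str, seed: int = 0, n_studies: int = 48,
                      epochs: int = 10, image_size: int = 64,
                      n_slices: int = 3) -> PipelineConfig:
    """Reduced-size preset: 64 px slices, 16 base channels, short schedules."""
    return PipelineConfig(
        out_dir=out_dir, seed=seed, n_studies=n_studies,
        dataset=sim.DatasetParams(image_size=image_size, n_slices=n_slices,
                                  artifact=sim.ArtifactParams(
                                      n_projection_angles=90)),
        gen_spec=GeneratorSpec(base_channels=16),
        disc_spec=DiscriminatorSpec(n_down=4, base_channels=16),
        epochs=epochs,
        registration_iterations=20,
        # 64 mm phantom vs ~250 mm clinical head: scale control spacing down
        refinement_grid=(16.0, 8.0, 4.0),
        desk_scale=True)


def config_from_yaml(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    nested = {"dataset": sim.DatasetParams, "gen_spec": GeneratorSpec,
              "disc_spec": DiscriminatorSpec, "weights": LossWeights,
              "window": NormalizationWindow,
              "augmentation": AugmentationConfig}
    for key, cls in nested.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = dict(kwargs[key])
            if key == "dataset" and isinstance(sub.get("artifact"), dict):
                sub["artifact"] = sim.ArtifactParams(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in sub["artifact"].items()})
            kwargs[key] = cls(**sub)
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    report: EvalReport
    stage1_report: StageReport
    stage2_report: StageReport
    stage2_generator: GeneratorFunction
    splits: dict[str, list[str]]
    manifest_path: str


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _split_studies(studies: list[sim.PairedStudy], config: PipelineConfig,
                   ) -> dict[str, list[str]]:
    ids = [s.study_id for s in studies]
    rng = np.random.default_rng(config.seed)
    order = list(rng.permutation(ids))
    n_hold = max(1, int(round(len(order) * config.holdout_fraction)))
    n_val = max(1, int(round(len(order) * config.stage1_val_fraction)))
    holdout = order[:n_hold]
    stage1_val = order[n_hold:n_hold + n_val]
    train = order[n_hold + n_val:]
    # final evaluation needs artifact slices: make sure at least one
    # metal-containing study lands in the held-out pool
    has_metal = {s.study_id: s.has_metal for s in studies}
    if not any(has_metal[sid] for sid in holdout):
        for i, sid in enumerate(train):
            if has_metal[sid]:
                train[i], holdout[0] = holdout[0], sid
                break
    return {"train": sorted(train), "stage1_val": sorted(stage1_val),
            "holdout": sorted(holdout)}


def _align_mv(study: sim.PairedStudy,
              reg_config: RegistrationConfig) -> CTVolume:
    """Register each MV slice onto its kV slice (multimodal MI)."""
    kv = study.volume("kv_artifact", "kV")
    mv = study.volume("mv_like", "MV")
    out = np.empty_like(mv.voxels)
    for k in range(mv.n_slices):
        out[:, :, k] = register(kv.slice_at(k), mv.slice_at(k),
                                reg_config).warped
    return CTVolume(voxels=out, grid=mv.grid, modality="MV")


def _augmented(pairs: list[PairedSlice], config: PipelineConfig,
               copies: int) -> list[PairedSlice]:
    out = list(pairs)
    for c in range(copies):
        for i, p in enumerate(pairs):
            out.append(augment(p, config.augmentation,
                               draw_seed=c * len(pairs) + i))
    return out


def _normalized(pairs: list[PairedSlice],
                window: NormalizationWindow) -> list[PairedSlice]:
    return [PairedSlice(input=normalize(p.input, window),
                        target=normalize(p.target, window),
                        study_id=p.study_id, slice_index=p.slice_index,
                        kv_max_hu=p.kv_max_hu, normalized=True)
            for p in pairs]


def _stage1_pairs(study: sim.PairedStudy, aligned_mv: CTVolume,
                  threshold: float = METAL_THRESHOLD_HU) -> list[PairedSlice]:
    kv = study.volume("kv_artifact", "kV")
    pairs = []
    for k in range(kv.n_slices):
        kv_slice = kv.slice_at(k)
        if kv_slice.max() > threshold:
            continue  # metal slices are withheld from stage-1 training
        pairs.append(PairedSlice(input=aligned_mv.slice_at(k),
                                 target=kv_slice, study_id=study.study_id,
                                 slice_index=k,
                                 kv_max_hu=float(kv_slice.max())))
    return pairs


def _stage_dir(config: PipelineConfig, name: str) -> str:
    path = os.path.join(config.out_dir, name)
    os.makedirs(path, exist_ok=True)
    return path


def _stage_is_cached(stage_dir: str, config_hash: str) -> bool:
    marker = os.path.join(stage_dir, "stage_manifest.json")
    if not os.path.exists(marker):
        return False
    with open(marker) as fh:
        return json.load(fh).get("config_hash") == config_hash


def _mark_stage(stage_dir: str, config_hash: str, seed: int,
                extra: dict | None = None) -> None:
    payload = {"config_hash": config_hash, "seed": seed,
               "written": time.strftime("%Y-%m-%dT%H:%M:%S")}
    payload.update(extra or {})
    with open(os.path.join(stage_dir, "stage_manifest.json"), "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, resume: bool = False,
                 ) -> PipelineResult:
    os.makedirs(config.out_dir, exist_ok=True)
    chash = config.config_hash()

    # -- stage 0: synthetic cohort -------------------------------------
    studies = sim.generate_dataset(config.n_studies, config.dataset,
                                   seed=config.seed)
    sim_dir = _stage_dir(config, "simulate")
    if not (resume and _stage_is_cached(sim_dir, chash)):
        sim.save_dataset(studies, sim_dir, config.dataset, config.seed)
        _mark_stage(sim_dir, chash, config.seed)
    splits = _split_studies(studies, config)
    by_id = {s.study_id: s for s in studies}

    mm_config = RegistrationConfig(mode=MODE_MULTIMODAL,
                                   max_iterations=config.registration_iterations)
    mono_config = RegistrationConfig(
        mode=MODE_MONOMODAL, max_iterations=config.registration_iterations,
        bspline_grid_spacing=tuple(config.refinement_grid))

    # -- stage 1: multimodal alignment + MV->kV translation ------------
    aligned_mv = {sid: _align_mv(by_id[sid], mm_config) for sid in by_id}
    stage1_pool = splits["train"] + splits["stage1_val"]
    stage1_pairs = []
    for sid in stage1_pool:
        stage1_pairs.extend(_stage1_pairs(by_id[sid], aligned_mv[sid]))
    stage1_pairs = _augmented(stage1_pairs, config,
                              config.augmentation.copies_stage1)
    stage1_pairs = _normalized(stage1_pairs, config.window)

    stage1_dir = _stage_dir(config, "stage1")
    ckpt1 = os.path.join(stage1_dir, "stage1_best.npz")
    if resume and _stage_is_cached(stage1_dir, chash) and os.path.exists(ckpt1):
        gen1 = GeneratorFunction.load(ckpt1)
        report1 = StageReport(stage=1, checkpoint_path=ckpt1)
    else:
        gen1, report1 = train_stage(
            stage1_pairs,
            TrainConfig(learning_rate=config.learning_rate,
                        batch_size=config.batch_size, epochs=config.epochs,
                        seed=config.seed, stage=1),
            weights=config.weights, gen_spec=config.gen_spec,
            disc_spec=config.disc_spec, checkpoint_dir=stage1_dir,
            val_studies=set(splits["stage1_val"]))
        _mark_stage(stage1_dir, chash, config.seed,
                    {"best_epoch": report1.best_epoch})

    # -- stage-1 inference + post-processing ---------------------------
    # synthesize kV for every study (including slices excluded from
    # training), then override + mono-modal refinement
    synthetic, refined = {}, {}
    rule = OverrideRule()
    for sid in by_id:
        true_kv = by_id[sid].volume("kv_artifact", "kV")
        synth = infer_volume(gen1, aligned_mv[sid], config.window)
        synthetic[sid] = synth
        overridden = intensity_override(synth, true_kv, rule)
        refined[sid] = refine_monomodal(overridden, true_kv, mono_config, rule)

    # -- stage 2: artifact correction ----------------------------------
    stage2_train_ids = [sid for sid in splits["train"]
                        if by_id[sid].has_metal]
    if not stage2_train_ids:
        raise RuntimeError("no metal-containing studies available for stage 2")
    stage2_pairs = build_stage2_pairs(
        {sid: by_id[sid].volume("kv_artifact", "kV")
         for sid in stage2_train_ids},
        {sid: refined[sid] for sid in stage2_train_ids})
    stage2_pairs = _augmented(stage2_pairs, config,
                              config.augmentation.copies_stage2)
    stage2_pairs = _normalized(stage2_pairs, config.window)

    stage2_dir = _stage_dir(config, "stage2")
    ckpt2 = os.path.join(stage2_dir, "stage2_best.npz")
    if resume and _stage_is_cached(stage2_dir, chash) and os.path.exists(ckpt2):
        gen2 = GeneratorFunction.load(ckpt2)
        report2 = StageReport(stage=2, checkpoint_path=ckpt2)
    else:
        gen2, report2 = train_stage(
            stage2_pairs,
            TrainConfig(learning_rate=config.learning_rate,
                        batch_size=config.batch_size, epochs=config.epochs,
                        seed=config.seed + 1, stage=2),
            weights=config.weights, gen_spec=config.gen_spec,
            disc_spec=config.disc_spec, checkpoint_dir=stage2_dir)
        _mark_stage(stage2_dir, chash, config.seed,
                    {"best_epoch": report2.best_epoch})

    # -- final evaluation on held-out studies --------------------------
    hold = splits["holdout"]
    clean = {sid: by_id[sid].volume("kv_clean", "kV") for sid in hold}
    artifact = {sid: by_id[sid].volume("kv_artifact", "kV") for sid in hold}
    corrected = {sid: infer_volume(gen2, artifact[sid], config.window)
                 for sid in hold}
    no_severe = {"stage2_vs_kv": [m and not s for sid in hold
                                  for m, s in zip(by_id[sid].metal_flags,
                                                  by_id[sid].severe_flags)]}
    comparisons = {
        "mv_vs_kv": [(aligned_mv[sid], clean[sid]) for sid in hold],
        "stage1_vs_kv": [(synthetic[sid], clean[sid]) for sid in hold],
        "stage1_post_vs_kv": [(refined[sid], clean[sid]) for sid in hold],
        "artifact_vs_kv": [(artifact[sid], clean[sid]) for sid in hold],
        "stage2_vs_kv": [(corrected[sid], clean[sid]) for sid in hold],
    }
    report = build_report(comparisons, no_severe_flags=no_severe)

    eval_dir = _stage_dir(config, "evaluate")
    report.write_json(os.path.join(eval_dir, "report.json"))
    report.write_csv(os.path.join(eval_dir, "report.csv"))
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"config_hash": chash, "seed": config.seed,
                   "splits": splits,
                   "config": json.loads(json.dumps(asdict(config),
                                                   default=str))},
                  fh, indent=2)
    return PipelineResult(report=report, stage1_report=report1,
                          stage2_report=report2, stage2_generator=gen2,
                          splits=splits, manifest_path=manifest_path)
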