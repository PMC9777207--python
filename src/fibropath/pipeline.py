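"""Stage orchestration for ``run-all``: synth -> tile -> train-gan ->
generate -> train-cnn -> evaluate, with content-hash stage skipping.

Each stage writes its artifacts under the configured output directory and a
stamp recording a hash of (its own configuration + the stamps of its
inputs). On a re-run a stage is skipped when its stamp is unchanged and its
outputs still exist, so editing the training seed re-runs the GAN and CNN
stages while synthesis and tiling are reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import synthetic, tiling
from .classifier import (
    AugmentationPlan,
    build_classifier,
    finetune_on_real,
    label_index,
    pretrain_on_generated,
)
from .config import PipelineConfig
from .evaluation import run_experiment
from .gan import (
    build_stage_schedule,
    sample_images,
    save_generator_state,
    train_pggan,
)

logger = logging.getLogger(__name__)

STAGES = ("synth", "tile", "train-gan", "generate", "train-cnn", "evaluate")


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Stamps:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "stamps.json"
        self.data = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def fresh(self, stage: str, stamp: str, outputs: list[Path]) -> bool:
        return self.data.get(stage) == stamp and all(p.exists() for p in outputs)

    def record(self, stage: str, stamp: str) -> None:
        self.data[stage] = stamp
        self.path.write_text(json.dumps(self.data, indent=2))


def _spawn_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2 ** 31))


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns {stage: "ran" | "skipped"}."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stamps = _Stamps(out)
    exp = config.experiment
    status: dict[str, str] = {}

    # -- synth --------------------------------------------------------------
    synth_cfg = {
        "cohort": config.raw["cohort"],
        "spec": dataclasses.asdict(exp.slide_spec),
    }
    synth_stamp = _hash(synth_cfg)
    manifest_path = out / "slides" / "manifest.csv"
    if stamps.fresh("synth", synth_stamp, [manifest_path]):
        status["synth"] = "skipped"
    else:
        slides, manifest = synthetic.make_synthetic_cohort(
            exp.n_cases_per_class, exp.slides_per_case, exp.slide_spec,
            seed=config.data_seed,
        )
        synthetic.write_cohort(slides, manifest, out / "slides")
        stamps.record("synth", synth_stamp)
        status["synth"] = "ran"

    # -- tile ---------------------------------------------------------------
    tile_cfg = {
        "input": synth_stamp, "size": exp.patch_size, "min_tissue": exp.min_tissue,
    }
    tile_stamp = _hash(tile_cfg)
    patches_csv = out / "patches" / "patches.csv"
    if stamps.fresh("tile", tile_stamp, [patches_csv]):
        status["tile"] = "skipped"
    else:
        manifest = pd.read_csv(manifest_path)
        tiling.tile_manifest(
            manifest, out / "patches", patch_size=exp.patch_size,
            min_tissue=exp.min_tissue,
        )
        stamps.record("tile", tile_stamp)
        status["tile"] = "ran"

    # -- train-gan ----------------------------------------------------------
    gan_cfg = {
        "input": tile_stamp,
        "gan": dataclasses.asdict(exp.gan),
        "resolution": exp.gan_resolution,
        "seed": exp.seed,
    }
    gan_stamp = _hash(gan_cfg)
    ckpts = [out / f"gan_{cls}.npz" for cls in ("nonIPF", "IPF")]
    if stamps.fresh("train-gan", gan_stamp, ckpts):
        status["train-gan"] = "skipped"
    else:
        frame = pd.read_csv(patches_csv)
        schedule = build_stage_schedule(4, exp.gan_resolution)
        for cls_idx, (cls_name, ckpt) in enumerate(zip(("nonIPF", "IPF"), ckpts)):
            sel = frame[[label_index(l) == cls_idx for l in frame["label"]]]
            imgs = np.stack(
                [
                    tiling.resize_patch(tiling.read_slide(p), exp.gan_resolution)
                    for p in sel["patch_path"]
                ]
            )
            cfg = dataclasses.replace(exp.gan, seed=_spawn_seed(exp.seed, 2, cls_idx))
            state = train_pggan(imgs, cfg, schedule)
            save_generator_state(state, ckpt)
            (out / f"gan_{cls_name}_log.jsonl").write_text(
                "\n".join(json.dumps(e) for e in state.log)
            )
        stamps.record("train-gan", gan_stamp)
        status["train-gan"] = "ran"

    # -- generate -----------------------------------------------------------
    gen_cfg = {"input": gan_stamp, "n": exp.n_generated_per_class, "seed": exp.seed}
    gen_stamp = _hash(gen_cfg)
    gen_dirs = [out / "generated" / cls for cls in ("nonIPF", "IPF")]
    if stamps.fresh("generate", gen_stamp, gen_dirs):
        status["generate"] = "skipped"
    else:
        from .gan import load_generator_state

        for cls_idx, (ckpt, gdir) in enumerate(zip(ckpts, gen_dirs)):
            gdir.mkdir(parents=True, exist_ok=True)
            state = load_generator_state(ckpt)
            samples = sample_images(
                state, exp.n_generated_per_class, seed=_spawn_seed(exp.seed, 3, cls_idx)
            )
            for i, img in enumerate(samples):
                Image.fromarray(img).save(gdir / f"gen_{i:05d}.png")
        stamps.record("generate", gen_stamp)
        status["generate"] = "ran"

    # -- train-cnn (final model on all data; CV happens in evaluate) --------
    cnn_cfg = {
        "input": gen_stamp,
        "backbone": dataclasses.asdict(exp.backbone),
        "pretrain": dataclasses.asdict(exp.pretrain),
        "finetune": dataclasses.asdict(exp.finetune),
        "seed": exp.seed,
        "use_gan": exp.use_gan,
    }
    cnn_stamp = _hash(cnn_cfg)
    model_path = out / "classifier.npz"
    if stamps.fresh("train-cnn", cnn_stamp, [model_path]):
        status["train-cnn"] = "skipped"
    else:
        frame = pd.read_csv(patches_csv)
        model = build_classifier(
            exp.backbone, exp.head, input_edge=exp.input_edge,
            seed=_spawn_seed(exp.seed, 4),
        )
        if exp.use_gan:
            gen_images, gen_labels = [], []
            for cls_idx, gdir in enumerate(gen_dirs):
                for p in sorted(gdir.glob("*.png")):
                    gen_images.append(
                        tiling.resize_patch(tiling.read_slide(p), exp.input_edge)
                    )
                    gen_labels.append(cls_idx)
            pretrain_on_generated(
                model, np.stack(gen_images), np.array(gen_labels), exp.pretrain
            )
        images = np.stack(
            [
                tiling.resize_patch(tiling.read_slide(p), exp.input_edge)
                for p in frame["patch_path"]
            ]
        )
        labels = np.array([label_index(l) for l in frame["label"]])
        counts = {c: int((labels == c).sum()) for c in (0, 1)}
        balanced = AugmentationPlan.balanced(counts)
        plan = AugmentationPlan(
            factors={
                c: int(np.clip(exp.base_augmentation_factor * balanced.factor_for(c), 1, 8))
                for c in (0, 1)
            }
        )
        finetune_on_real(model, images, labels, plan, exp.finetune)
        np.savez_compressed(model_path, **model.state_arrays())
        stamps.record("train-cnn", cnn_stamp)
        status["train-cnn"] = "ran"

    # -- evaluate (case-grouped CV, retrains per fold) -----------------------
    eval_cfg = {"experiment": dataclasses.asdict(exp), "data_seed": config.data_seed}
    eval_stamp = _hash(eval_cfg)
    report_path = out / "eval_report.json"
    if stamps.fresh("evaluate", eval_stamp, [report_path]):
        status["evaluate"] = "skipped"
    else:
        report = run_experiment(exp)
        report.to_json(report_path)
        stamps.record("evaluate", eval_stamp)
        status["evaluate"] = "ran"

    for stage, st in status.items():
        logger.info("stage %s: %s", stage, st)
    return status
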