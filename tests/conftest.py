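"""Shared fixtures: synthetic patch sets and (session-scoped) heavy
end-to-end experiment runs reused across evaluation and acceptance tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fibropath import synthetic, tiling
from fibropath.evaluation import ExperimentConfig, run_experiment
from fibropath.synthetic import SlideSpec


def patch_images(label: str, n_slides: int, separation: float, res: int, seed0: int = 0):
    """Tissue-filtered patches of one class, resized to ``res``."""
    imgs = []
    for i in range(n_slides):
        spec = SlideSpec(
            width=256, height=256, class_label=label,
            tissue_coverage=0.7, texture_separation=separation,
            seed=seed0 + i,
        )
        slide = synthetic.make_synthetic_slide(spec)
        recs = tiling.filter_patches(
            tiling.tile_slide(slide.image, patch_size=64, label=label), 0.1
        )
        for r in recs:
            imgs.append(
                tiling.resize_patch(tiling.extract_patch(slide.image, r), res)
            )
    return np.stack(imgs)


@pytest.fixture(scope="session")
def fibrotic_patches16():
    return patch_images("IPF_like", 4, separation=3.0, res=16, seed0=1000)


@pytest.fixture(scope="session")
def inflammatory_patches16():
    return patch_images("nonIPF_like", 4, separation=3.0, res=16, seed0=2000)


@pytest.fixture(scope="session")
def desk_config() -> ExperimentConfig:
    """The desk-scale study conditions: 12 cases per class, high texture
    separation, tiny PGGAN at 16 px, tiny_cnn at 32 px, 5 folds."""
    return ExperimentConfig()


@pytest.fixture(scope="session")
def high_sep_report_gan(desk_config):
    """Full two-step pipeline (GAN pretraining + fine-tuning), high separation."""
    return run_experiment(desk_config)


@pytest.fixture(scope="session")
def high_sep_report_nogan(desk_config):
    """Ablation arm: fine-tuning only, no GAN pretraining."""
    return run_experiment(dataclasses.replace(desk_config, use_gan=False))


@pytest.fixture(scope="session")
def null_case_aucs(desk_config):
    """Case-based AUCs on zero-separation cohorts over three seeds."""
    aucs = []
    for seed in (11, 22, 33):
        cfg = dataclasses.replace(
            desk_config,
            slide_spec=dataclasses.replace(desk_config.slide_spec, texture_separation=0.0),
            use_gan=False,
            seed=seed,
        )
        report = run_experiment(cfg)
        aucs.append(report.per_repeat[0]["case_based"]["auc"])
    return aucs
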