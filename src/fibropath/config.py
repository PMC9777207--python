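"""Pipeline configuration: one YAML file, two scale presets.

The ``paper`` preset carries the reference experiment's parameters
(2240-px source patches resized to 224, latent dimension 128, Adam lr 1e-5
over 50 epochs, 10,000 generated images per class, 5-fold case-grouped CV).
The ``desk`` preset caps the geometry (patches <= 64 px, GAN <= 32 px,
tiny_cnn backbone) so the full pipeline runs in minutes on one CPU core.

Seeding: the cohort is controlled by ``data_seed`` and the training stages
by ``seed``; each stage derives its own stream via ``numpy SeedSequence``
spawning, so changing ``seed`` re-runs GAN/CNN stages while synthesis and
tiling artifacts stay valid.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .backbones import BackboneSpec
from .classifier import CnnTrainConfig, HeadSpec
from .evaluation import ExperimentConfig
from .gan import GanTrainConfig
from .synthetic import SlideSpec


class ConfigError(ValueError):
    pass


_PRESETS = {
    "paper": {
        "cohort": {
            "n_cases_per_class": 12,
            "slides_per_case": 1,
            "slide_width": 8960,
            "slide_height": 8960,
            "tissue_coverage": 0.6,
            "texture_separation": 3.0,
            "data_seed": 0,
        },
        "patch": {"size": 2240, "min_tissue": 0.10, "input_edge": 224},
        "gan": {
            "resolution": 256,
            "latent_dim": 128,
            "lr": 1e-5,
            "epochs": 50,
            "batch_size": 16,
            "gp_lambda": 10.0,
            "fade_in_fraction": 0.5,
            "base_channels": 128,
            "n_generated_per_class": 10000,
        },
        "cnn": {
            "backbone": "densenet121",
            "pretrained_imagenet": False,
            "hidden_units": 1024,
            "lr": 1e-5,
            "pretrain_epochs": 50,
            "finetune_epochs": 50,
            "batch_size": 32,
            "augmentation_factor": 1,
        },
        "evaluation": {"folds": 5, "repeats": 3, "cutoff": 0.5, "use_gan": True},
        "seed": 0,
        "out_dir": "runs/paper",
    },
    "desk": {
        "cohort": {
            "n_cases_per_class": 12,
            "slides_per_case": 1,
            "slide_width": 256,
            "slide_height": 256,
            "tissue_coverage": 0.6,
            "texture_separation": 3.0,
            "data_seed": 0,
        },
        "patch": {"size": 64, "min_tissue": 0.10, "input_edge": 32},
        "gan": {
            "resolution": 16,
            "latent_dim": 128,
            "lr": 1e-3,
            "epochs": 50,
            "batch_size": 8,
            "gp_lambda": 10.0,
            "fade_in_fraction": 0.5,
            "base_channels": 32,
            "n_generated_per_class": 200,
        },
        "cnn": {
            "backbone": "tiny_cnn",
            "pretrained_imagenet": False,
            "hidden_units": 1024,
            "lr": 2e-3,
            "pretrain_epochs": 3,
            "finetune_epochs": 4,
            "batch_size": 16,
            "augmentation_factor": 4,
        },
        "evaluation": {"folds": 5, "repeats": 1, "cutoff": 0.5, "use_gan": True},
        "seed": 0,
        "out_dir": "runs/desk",
    },
}

_DESK_CAPS = {"patch_size": 64, "gan_resolution": 32}


@dataclasses.dataclass
class PipelineConfig:
    scale: str
    raw: dict
    experiment: ExperimentConfig
    data_seed: int
    out_dir: Path

    @property
    def seed(self) -> int:
        return self.experiment.seed


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ConfigError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{path + key!r} must be a mapping")
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def validate_config(raw) -> PipelineConfig:
    """Parse YAML text (or a dict) into a validated :class:`PipelineConfig`.

    Defaults come from the chosen ``scale`` preset; unknown keys are
    rejected with the offending path named.
    """
    if isinstance(raw, (str, Path)):
        data = yaml.safe_load(str(raw)) or {}
    else:
        data = dict(raw or {})
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    scale = data.pop("scale", "desk")
    if scale not in _PRESETS:
        raise ConfigError(f"scale must be one of {tuple(_PRESETS)}")
    cfg = _merge(_PRESETS[scale], data)

    if scale == "desk":
        if cfg["patch"]["size"] > _DESK_CAPS["patch_size"]:
            raise ConfigError("desk preset caps patch size at 64")
        if cfg["gan"]["resolution"] > _DESK_CAPS["gan_resolution"]:
            raise ConfigError("desk preset caps GAN resolution at 32")

    if cfg["gan"]["lr"] <= 0 or cfg["cnn"]["lr"] <= 0:
        raise ConfigError("learning rates must be positive")
    if cfg["patch"]["size"] < 1:
        raise ConfigError("patch size must be >= 1")
    if not 0 <= cfg["patch"]["min_tissue"] <= 1:
        raise ConfigError("min_tissue must lie in [0, 1]")

    co, pa, ga, cn, ev = (
        cfg["cohort"], cfg["patch"], cfg["gan"], cfg["cnn"], cfg["evaluation"]
    )
    slide_spec = SlideSpec(
        width=co["slide_width"],
        height=co["slide_height"],
        tissue_coverage=co["tissue_coverage"],
        texture_separation=co["texture_separation"],
    ).validate()
    experiment = ExperimentConfig(
        n_cases_per_class=co["n_cases_per_class"],
        slides_per_case=co["slides_per_case"],
        slide_spec=slide_spec,
        patch_size=pa["size"],
        input_edge=pa["input_edge"],
        min_tissue=pa["min_tissue"],
        use_gan=ev["use_gan"],
        gan=GanTrainConfig(
            latent_dim=ga["latent_dim"],
            lr=ga["lr"],
            epochs=ga["epochs"],
            batch_size=ga["batch_size"],
            gp_lambda=ga["gp_lambda"],
            fade_in_fraction=ga["fade_in_fraction"],
            base_channels=ga["base_channels"],
        ).validate(),
        gan_resolution=ga["resolution"],
        n_generated_per_class=ga["n_generated_per_class"],
        backbone=BackboneSpec(
            name=cn["backbone"], pretrained_imagenet=cn["pretrained_imagenet"]
        ).validate(),
        head=HeadSpec(hidden_units=cn["hidden_units"]).validate(),
        pretrain=CnnTrainConfig(
            lr=cn["lr"], epochs=cn["pretrain_epochs"],
            batch_size=cn["batch_size"], input_edge=pa["input_edge"],
        ).validate(),
        finetune=CnnTrainConfig(
            lr=cn["lr"], epochs=cn["finetune_epochs"],
            batch_size=cn["batch_size"], input_edge=pa["input_edge"],
        ).validate(),
        folds=ev["folds"],
        repeats=ev["repeats"],
        cutoff=ev["cutoff"],
        seed=cfg["seed"],
        base_augmentation_factor=cn["augmentation_factor"],
    )
    return PipelineConfig(
        scale=scale,
        raw=cfg,
        experiment=experiment,
        data_seed=co["data_seed"],
        out_dir=Path(cfg["out_dir"]),
    )
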