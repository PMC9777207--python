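"""Two-step patch classifier: GAN pretraining then fine-tuning on real data.

Step (a) trains the CNN on GAN-generated patches only; step (b) fine-tunes
on real patches. The real set is class-imbalanced, so the minority class is
expanded by an integer factor of dihedral transforms (rotations by 90-degree
multiples and flips) chosen to balance the classes: with the reference
counts (23,142 IPF vs 7,817 non-IPF) the factor is 3, giving 23,451
non-IPF items. The two steps never mix generated and real images; each
training step is tagged in the model's log so step purity is auditable.

IPF is the positive class (index 1). Patch probabilities are the softmax
output for that class.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np

from .backbones import (
    IMAGENET_MEAN,
    IMAGENET_STD,
    BackboneSpec,
    build_backbone,
)
from .nn import layers as L
from .nn import tensor as T
from .nn.optim import Adam
from .nn.tensor import Tensor, no_grad

IPF_INDEX = 1
NONIPF_INDEX = 0

# fixed documented order: four rotations, then the four flipped rotations
DIHEDRAL_TRANSFORMS = ("r0", "r90", "r180", "r270", "f0", "f90", "f180", "f270")


def label_index(label: str) -> int:
    """Map a textual label to the class index; IPF is positive (1)."""
    return NONIPF_INDEX if str(label).lower().startswith("non") else IPF_INDEX


def apply_dihedral(image: np.ndarray, transform: str) -> np.ndarray:
    """Apply one of the 8 dihedral transforms to an (H, W, C) image."""
    if transform not in DIHEDRAL_TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    img = np.asarray(image)
    if transform.startswith("f"):
        img = np.fliplr(img)
    k = int(transform[1:]) // 90
    return np.ascontiguousarray(np.rot90(img, k))


@dataclasses.dataclass(frozen=True)
class HeadSpec:
    """The MLP replacing the backbone's fully connected layer."""

    hidden_units: int = 1024
    output_units: int = 2

    def validate(self) -> "HeadSpec":
        if self.output_units != 2:
            raise ValueError("the head is a two-class (IPF vs non-IPF) output")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        return self


@dataclasses.dataclass
class CnnTrainConfig:
    lr: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    input_edge: int = 224

    def validate(self) -> "CnnTrainConfig":
        if self.lr <= 0 or self.epochs < 1:
            raise ValueError("lr and epochs must be positive")
        return self


def balance_factor(n_majority: int, n_minority: int) -> int:
    """Minority-class expansion factor: round(n_major / n_minor) in [1, 8]."""
    if n_majority < 1 or n_minority < 1:
        raise ValueError("class counts must be >= 1")
    if n_majority < n_minority:
        raise ValueError("n_majority must be >= n_minority")
    factor = int(np.floor(n_majority / n_minority + 0.5))
    return int(np.clip(factor, 1, 8))


@dataclasses.dataclass(frozen=True)
class AugmentationPlan:
    """Per-class dihedral expansion factors (class index -> factor)."""

    factors: dict

    def __post_init__(self):
        for cls, f in self.factors.items():
            if not 1 <= int(f) <= 8:
                raise ValueError(f"factor {f} for class {cls} outside [1, 8]")

    def factor_for(self, class_index: int) -> int:
        return int(self.factors.get(class_index, 1))

    @classmethod
    def balanced(cls, class_counts: dict) -> "AugmentationPlan":
        """Expand only the minority class; the majority keeps factor 1."""
        if len(class_counts) != 2:
            raise ValueError("expected exactly two classes")
        (c0, n0), (c1, n1) = sorted(class_counts.items(), key=lambda kv: -kv[1])
        return cls(factors={c0: 1, c1: balance_factor(n0, n1)})


class AugmentedItem(NamedTuple):
    record: object
    transform: str


def expand_with_dihedral(records: Sequence, factor: int) -> list[AugmentedItem]:
    """Replicate each record under the first ``factor`` dihedral transforms."""
    if not 1 <= factor <= 8:
        raise ValueError("factor must be in [1, 8]")
    return [
        AugmentedItem(record=r, transform=t)
        for r in records
        for t in DIHEDRAL_TRANSFORMS[:factor]
    ]


class PatchClassifier(L.Module):
    """Backbone feature extractor + (hidden, 2) MLP head with softmax."""

    def __init__(
        self,
        backbone: BackboneSpec = BackboneSpec(),
        head: HeadSpec = HeadSpec(),
        input_edge: int = 224,
        seed: int = 0,
    ):
        backbone.validate()
        head.validate()
        rng = np.random.default_rng(seed)
        self.backbone_spec = backbone
        self.head_spec = head
        self.input_edge = input_edge
        self.features, feat_dim, self.weights_used = build_backbone(backbone, rng)
        self.head_hidden = L.Dense(feat_dim, head.hidden_units, rng=rng)
        self.head_out = L.Dense(head.hidden_units, head.output_units, rng=rng)
        self.train_log: list[dict] = []

    # -- data plumbing -----------------------------------------------------
    def preprocess(self, images: np.ndarray) -> Tensor:
        """uint8 (N, H, W, 3) -> normalised float tensor (N, 3, H, W)."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.input_edge or x.shape[2] != self.input_edge:
            raise ValueError(
                f"expected {self.input_edge}x{self.input_edge} input, got {x.shape[1:3]}"
            )
        x = x.astype(np.float64) / 255.0
        if self.backbone_spec.name != "tiny_cnn":
            x = (x - IMAGENET_MEAN) / IMAGENET_STD
        return Tensor(np.transpose(x, (0, 3, 1, 2)))

    def logits(self, x: Tensor) -> Tensor:
        h = self.features(x)
        return self.head_out(T.relu(self.head_hidden(h)))

    def forward(self, x: Tensor) -> Tensor:
        return L.softmax(self.logits(x))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        self.set_training(False)
        with no_grad():
            probs = self.forward(self.preprocess(images)).data
        return probs


def build_classifier(
    backbone: BackboneSpec = BackboneSpec(),
    head: HeadSpec = HeadSpec(),
    input_edge: int = 224,
    seed: int = 0,
) -> PatchClassifier:
    return PatchClassifier(backbone, head, input_edge=input_edge, seed=seed)


def _calibrate_batchnorm(
    model: PatchClassifier, images: np.ndarray, batch_size: int
) -> None:
    """Recompute BatchNorm running statistics as the cumulative average of
    batch statistics over one pass of the training set, so evaluation-mode
    behaviour matches what was trained (short runs leave the exponential
    moving average noisy)."""
    bns = [m for m in model.modules() if isinstance(m, L.BatchNorm2d)]
    if not bns:
        return
    saved = [(b.momentum,) for b in bns]
    for b in bns:
        b.running_mean[:] = 0.0
        b.running_var[:] = 0.0
    model.set_training(True)
    with no_grad():
        for k, start in enumerate(range(0, len(images), batch_size), start=1):
            for b in bns:
                b.momentum = 1.0 / k
            model.forward(model.preprocess(images[start : start + batch_size]))
    for b, (mom,) in zip(bns, saved):
        b.momentum = mom
    model.set_training(False)


def _train_phase(
    model: PatchClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    config: CnnTrainConfig,
    phase: str,
) -> PatchClassifier:
    config.validate()
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=int)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both classes present")
    rng = np.random.default_rng(config.seed)
    opt = Adam(
        model.parameters(), lr=config.lr, beta1=config.beta1, beta2=config.beta2
    )
    model.set_training(True)
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = model.preprocess(images[idx])
            loss = L.cross_entropy(model.logits(x), labels[idx])
            opt.zero_grad()
            T.backward(loss, opt.params)
            opt.step()
            model.train_log.append(
                {"phase": phase, "epoch": epoch, "loss": loss.item()}
            )
    _calibrate_batchnorm(model, images, config.batch_size)
    model.set_training(False)
    return model


def pretrain_on_generated(
    model: PatchClassifier,
    generated_images: np.ndarray,
    labels: np.ndarray,
    config: CnnTrainConfig,
) -> PatchClassifier:
    """Step (a): train on GAN-generated patches only."""
    return _train_phase(model, generated_images, labels, config, phase="pretrain")


def finetune_on_real(
    model: PatchClassifier,
    images: np.ndarray,
    labels: np.ndarray,
    plan: AugmentationPlan,
    config: CnnTrainConfig,
) -> PatchClassifier:
    """Step (b): fine-tune on real patches with class-balancing augmentation.

    Every image of class ``c`` appears under the first ``plan.factor_for(c)``
    dihedral transforms; all layers stay trainable.
    """
    images = np.asarray(images)
    labels = np.asarray(labels, dtype=int)
    aug_images, aug_labels = [], []
    for cls in sorted(set(labels.tolist())):
        cls_idx = np.flatnonzero(labels == cls)
        for item in expand_with_dihedral(cls_idx.tolist(), plan.factor_for(cls)):
            aug_images.append(apply_dihedral(images[item.record], item.transform))
            aug_labels.append(cls)
    return _train_phase(
        model,
        np.stack(aug_images),
        np.asarray(aug_labels),
        config,
        phase="finetune",
    )


def predict_patch_prob(model: PatchClassifier, patch: np.ndarray) -> float:
    """Probability that one patch (resized to the network edge) shows IPF."""
    patch = np.asarray(patch)
    if patch.shape[0] != model.input_edge or patch.shape[1] != model.input_edge:
        raise ValueError(
            f"patch must be {model.input_edge}x{model.input_edge}; got {patch.shape[:2]}"
        )
    return float(model.predict_proba(patch[None])[0, IPF_INDEX])
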