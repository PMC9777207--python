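"""Case-grouped evaluation: cross-validation, metrics, ROC, heatmaps.

Cases (patients) — not patches — are the unit of cross-validation: all
patches of a case stay in the same fold, so no patch of a test case is ever
seen in training. Folds are stratified by class and balanced to within one
case per class. Two views of performance are reported:

* image-based — patch-level IPF probabilities thresholded at 0.5;
* case-based — the mean patch probability per case, thresholded at 0.5.

IPF is the positive class. ROC curves sweep every unique score value (plus
the +/-inf endpoints) and the AUC is the trapezoidal area, which equals the
Mann-Whitney concordance probability when scores are tie-free.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import matplotlib
import numpy as np

from . import synthetic, tiling
from .classifier import (
    IPF_INDEX,
    AugmentationPlan,
    BackboneSpec,
    CnnTrainConfig,
    HeadSpec,
    PatchClassifier,
    build_classifier,
    finetune_on_real,
    label_index,
    pretrain_on_generated,
)
from .gan import GanTrainConfig, build_stage_schedule, sample_images, train_pggan
from .synthetic import SlideSpec

PROBABILITY_COLORMAP = "jet"   # red = high IPF probability
OVERLAY_ALPHA = 0.4


class UndefinedMetricError(ValueError):
    pass


# -- fold assignment ---------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: dict  # case_id -> fold index

    def test_cases(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.fold_of.items() if f == fold)

    def train_cases(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.fold_of.items() if f != fold)


def grouped_kfold(
    case_labels: dict, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Stratified grouped K-fold over cases.

    ``case_labels``: case_id -> label. Within each class, cases are shuffled
    deterministically and dealt into folds whose sizes differ by at most one.
    """
    by_class: dict = {}
    for case, label in case_labels.items():
        by_class.setdefault(label, []).append(case)
    rng = np.random.default_rng(seed)
    fold_of: dict = {}
    for label in sorted(by_class):
        cases = sorted(by_class[label])
        if len(cases) < k:
            raise ValueError(
                f"class {label!r} has {len(cases)} cases, fewer than K={k}"
            )
        rng.shuffle(cases)
        n = len(cases)
        sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
        pos = 0
        for fold, size in enumerate(sizes):
            for case in cases[pos : pos + size]:
                fold_of[case] = fold
            pos += size
    return FoldAssignment(k=k, fold_of=fold_of)


# -- scores and metrics ------------------------------------------------------

@dataclasses.dataclass
class CaseScore:
    case_id: str
    mean_patch_probability: float
    n_patches: int
    true_label: int


def case_probability(patch_probs) -> float:
    """Case score: the arithmetic mean of its patch IPF probabilities."""
    probs = np.asarray(list(patch_probs), dtype=float)
    if probs.size == 0:
        raise ValueError("a case needs at least one patch probability")
    return float(probs.mean())


@dataclasses.dataclass
class ConfusionMatrix:
    """Counts with IPF positive: TP/FN on IPF cases, TN/FP on non-IPF."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binary_metrics(cm: ConfusionMatrix) -> dict:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise UndefinedMetricError("metrics undefined with an empty class")
    return {
        "sensitivity": cm.tp / (cm.tp + cm.fn),
        "specificity": cm.tn / (cm.tn + cm.fp),
        "accuracy": (cm.tp + cm.tn) / cm.total,
    }


@dataclasses.dataclass
class RocCurve:
    points: list          # [(FPF, TPF), ...] from (0,0) to (1,1)
    auc: float
    thresholds: list


def roc_auc(scores, labels) -> RocCurve:
    """ROC by sweeping unique score cut-offs; trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    cuts = np.concatenate(([np.inf], np.unique(scores)[::-1], [-np.inf]))
    points = []
    for c in cuts:
        pred = scores >= c
        tpf = float(np.sum(pred & (labels == 1))) / n_pos
        fpf = float(np.sum(pred & (labels == 0))) / n_neg
        points.append((fpf, tpf))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points=points, auc=auc, thresholds=cuts.tolist())


# -- probability map ---------------------------------------------------------

def probability_to_color(prob: float, colormap: str = PROBABILITY_COLORMAP) -> np.ndarray:
    """RGB uint8 colour for one probability (red end = high IPF)."""
    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(float(prob))
    return np.array([int(round(255 * v)) for v in rgba[:3]], dtype=np.uint8)


@dataclasses.dataclass
class ProbabilityMap:
    grid: np.ndarray          # patch-raster grid of probabilities (NaN = no patch)
    overlay: np.ndarray       # RGB uint8 rendered slide


def render_probability_map(
    slide_image: np.ndarray,
    records: list,
    probs,
    colormap: str = PROBABILITY_COLORMAP,
    alpha: float = OVERLAY_ALPHA,
) -> ProbabilityMap:
    """Alpha-blend per-patch probability colours onto the slide.

    Unpatched regions are untouched; a record outside the slide is an error.
    """
    image = np.asarray(slide_image)
    h, w = image.shape[:2]
    probs = list(probs)
    if len(probs) != len(records):
        raise ValueError("one probability per patch record required")
    size = records[0].size if records else 1
    grid = np.full((h // size if size else 0, w // size if size else 0), np.nan)
    overlay = image.astype(np.float64).copy()
    for rec, p in zip(records, probs):
        if rec.x < 0 or rec.y < 0 or rec.x + rec.size > w or rec.y + rec.size > h:
            raise ValueError(f"patch at ({rec.x}, {rec.y}) lies outside the slide")
        color = probability_to_color(p, colormap).astype(np.float64)
        cell = overlay[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size]
        overlay[rec.y : rec.y + rec.size, rec.x : rec.x + rec.size] = (
            (1.0 - alpha) * cell + alpha * color
        )
        gy, gx = rec.y // rec.size, rec.x // rec.size
        if gy < grid.shape[0] and gx < grid.shape[1]:
            grid[gy, gx] = p
    return ProbabilityMap(grid=grid, overlay=np.clip(np.rint(overlay), 0, 255).astype(np.uint8))


# -- end-to-end experiment ---------------------------------------------------

@dataclasses.dataclass
class ExperimentConfig:
    """Desk-scale defaults; the reference experiment's geometry (2240-px
    patches, 256-px GAN, 224-px network input) is reached by overriding."""

    n_cases_per_class: int = 12
    slides_per_case: int = 1
    slide_spec: SlideSpec = dataclasses.field(
        default_factory=lambda: SlideSpec(width=256, height=256)
    )
    patch_size: int = 64
    input_edge: int = 32
    min_tissue: float = 0.10
    use_gan: bool = True
    gan: GanTrainConfig = dataclasses.field(
        default_factory=lambda: GanTrainConfig(
            epochs=50, batch_size=8, lr=1e-3, base_channels=32
        )
    )
    gan_resolution: int = 16
    n_generated_per_class: int = 200
    backbone: BackboneSpec = dataclasses.field(default_factory=BackboneSpec)
    head: HeadSpec = dataclasses.field(default_factory=HeadSpec)
    pretrain: CnnTrainConfig = dataclasses.field(
        default_factory=lambda: CnnTrainConfig(lr=2e-3, epochs=3, batch_size=16, input_edge=32)
    )
    finetune: CnnTrainConfig = dataclasses.field(
        default_factory=lambda: CnnTrainConfig(lr=2e-3, epochs=4, batch_size=16, input_edge=32)
    )
    # dihedral augmentation applied to every class during fine-tuning (the
    # balance factor multiplies this, clipped to the group size 8); rotation/
    # flip augmentation suppresses orientation-cluster overfitting, which at
    # desk scale otherwise anti-generalizes across held-out cases
    base_augmentation_factor: int = 4
    folds: int = 5
    repeats: int = 1
    cutoff: float = 0.5
    seed: int = 0


@dataclasses.dataclass
class EvalReport:
    """Per-repeat image- and case-based metrics with mean +- SD."""

    per_repeat: list
    summary: dict
    fold_audit: list          # per fold: train/test case ids (leakage check)
    case_scores: list         # CaseScore dicts of the last repeat
    config_used: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "per_repeat": self.per_repeat,
                "summary": self.summary,
                "fold_audit": self.fold_audit,
                "case_scores": self.case_scores,
                "config": self.config_used,
            },
            indent=2,
            default=str,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _spawn_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2 ** 31))


def _prepare_patches(config: ExperimentConfig):
    """Generate the cohort, tile, filter, and resize patches for both the
    network input and the GAN training resolution."""
    slides, manifest = synthetic.make_synthetic_cohort(
        config.n_cases_per_class,
        config.slides_per_case,
        config.slide_spec,
        seed=_spawn_seed(config.seed, 0),
    )
    patches = []
    for i, slide in enumerate(slides):
        recs = tiling.tile_slide(
            slide.image,
            patch_size=config.patch_size,
            case_id=slide.case_id,
            slide_id=f"{slide.case_id}_s{i}",
            label=slide.class_label,
        )
        recs = tiling.filter_patches(recs, config.min_tissue)
        for r in recs:
            raw = tiling.extract_patch(slide.image, r)
            patches.append(
                {
                    "case_id": r.case_id,
                    "label": label_index(r.label),
                    "net": tiling.resize_patch(raw, config.input_edge),
                    "gan": tiling.resize_patch(raw, config.gan_resolution),
                }
            )
    case_labels = {
        row.case_id: label_index(row.label) for row in manifest.itertuples()
    }
    return patches, case_labels


def _fit_and_score_fold(
    config: ExperimentConfig,
    patches: list,
    train_cases: set,
    test_cases: set,
    repeat_seed: int,
):
    train = [p for p in patches if p["case_id"] in train_cases]
    test = [p for p in patches if p["case_id"] in test_cases]

    model: PatchClassifier = build_classifier(
        config.backbone, config.head, input_edge=config.input_edge,
        seed=_spawn_seed(repeat_seed, 1),
    )

    if config.use_gan:
        schedule = build_stage_schedule(4, config.gan_resolution)
        gen_images, gen_labels = [], []
        for cls in (0, 1):
            cls_imgs = np.stack([p["gan"] for p in train if p["label"] == cls])
            gcfg = dataclasses.replace(
                config.gan, seed=_spawn_seed(repeat_seed, 2, cls)
            )
            state = train_pggan(cls_imgs, gcfg, schedule)
            samples = sample_images(
                state, config.n_generated_per_class, seed=_spawn_seed(repeat_seed, 3, cls)
            )
            gen_images.append(
                np.stack([tiling.resize_patch(s, config.input_edge) for s in samples])
            )
            gen_labels.append(np.full(len(samples), cls))
        pcfg = dataclasses.replace(
            config.pretrain, seed=_spawn_seed(repeat_seed, 4), input_edge=config.input_edge
        )
        pretrain_on_generated(
            model, np.concatenate(gen_images), np.concatenate(gen_labels), pcfg
        )

    labels = np.array([p["label"] for p in train])
    images = np.stack([p["net"] for p in train])
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    balanced = AugmentationPlan.balanced(counts)
    plan = AugmentationPlan(
        factors={
            c: int(np.clip(config.base_augmentation_factor * balanced.factor_for(c), 1, 8))
            for c in (0, 1)
        }
    )
    fcfg = dataclasses.replace(
        config.finetune, seed=_spawn_seed(repeat_seed, 5), input_edge=config.input_edge
    )
    finetune_on_real(model, images, labels, plan, fcfg)

    probs = []
    for start in range(0, len(test), 64):
        batch = np.stack([p["net"] for p in test[start : start + 64]])
        probs.extend(model.predict_proba(batch)[:, IPF_INDEX].tolist())
    return [
        {"case_id": p["case_id"], "label": p["label"], "prob": float(pr)}
        for p, pr in zip(test, probs)
    ]


def run_experiment(config: ExperimentConfig) -> EvalReport:
    """Full pipeline: synthesize -> tile -> (GAN -> pretrain) -> fine-tune ->
    case-grouped K-fold evaluation, repeated ``config.repeats`` times."""
    patches, case_labels = _prepare_patches(config)
    folds = grouped_kfold(case_labels, k=config.folds, seed=_spawn_seed(config.seed, 10))

    fold_audit = [
        {
            "fold": f,
            "train_cases": folds.train_cases(f),
            "test_cases": folds.test_cases(f),
        }
        for f in range(config.folds)
    ]

    per_repeat = []
    last_case_scores: list[dict] = []
    for rep in range(config.repeats):
        repeat_seed = _spawn_seed(config.seed, 100 + rep)
        patch_results = []
        for f in range(config.folds):
            patch_results.extend(
                _fit_and_score_fold(
                    config,
                    patches,
                    set(folds.train_cases(f)),
                    set(folds.test_cases(f)),
                    _spawn_seed(repeat_seed, f),
                )
            )
        img_labels = np.array([r["label"] for r in patch_results])
        img_probs = np.array([r["prob"] for r in patch_results])
        img_pred = (img_probs >= config.cutoff).astype(int)
        image_metrics = binary_metrics(
            ConfusionMatrix.from_predictions(img_labels, img_pred)
        )
        image_metrics["auc"] = roc_auc(img_probs, img_labels).auc

        by_case: dict = {}
        for r in patch_results:
            by_case.setdefault(r["case_id"], []).append(r["prob"])
        scores = [
            CaseScore(
                case_id=c,
                mean_patch_probability=case_probability(ps),
                n_patches=len(ps),
                true_label=case_labels[c],
            )
            for c, ps in sorted(by_case.items())
        ]
        case_labels_arr = np.array([s.true_label for s in scores])
        case_probs = np.array([s.mean_patch_probability for s in scores])
        case_pred = (case_probs >= config.cutoff).astype(int)
        case_metrics = binary_metrics(
            ConfusionMatrix.from_predictions(case_labels_arr, case_pred)
        )
        case_metrics["auc"] = roc_auc(case_probs, case_labels_arr).auc

        per_repeat.append({"image_based": image_metrics, "case_based": case_metrics})
        last_case_scores = [dataclasses.asdict(s) for s in scores]

    summary = {}
    for view in ("image_based", "case_based"):
        summary[view] = {}
        for metric in ("sensitivity", "specificity", "accuracy", "auc"):
            vals = np.array([r[view][metric] for r in per_repeat])
            summary[view][metric] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
            }
    return EvalReport(
        per_repeat=per_repeat,
        summary=summary,
        fold_audit=fold_audit,
        case_scores=last_case_scores,
        config_used=dataclasses.asdict(config),
    )
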