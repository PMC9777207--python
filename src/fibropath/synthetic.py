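"""Procedural whole-slide-like images with known tissue masks.

Real interstitial-pneumonia biopsy slides are private, so every downstream
stage (tiling, GAN augmentation, classification, evaluation) is exercised on
slides generated here. A slide emulates the features the pipeline actually
depends on: a bright near-white scanner background, darker H&E-coloured
tissue (eosin-pink matrix, hematoxylin-purple nuclei), and two texture
classes whose separability is a single knob:

* ``IPF_like`` — elongated eosinophilic band texture (fibrotic pattern) with
  sparse nuclei;
* ``nonIPF_like`` — weaker banding with dense small dark nuclei
  (inflammatory pattern).

``texture_separation`` is an effect size: at 0 the two classes are drawn
from the identical distribution (the no-signal null); large values push the
band amplitude and nucleus density of the classes apart monotonically.
All randomness flows through one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

IPF_LIKE = "IPF_like"
NONIPF_LIKE = "nonIPF_like"
CLASS_LABELS = (IPF_LIKE, NONIPF_LIKE)

# H&E-like palette (RGB, 8-bit): bright background, pink fibrous matrix,
# purple nuclei. Chosen so grayscale tissue sits well below background and
# Otsu thresholding behaves as on a real stain.
EOSIN_RGB = np.array([214.0, 158.0, 188.0])
HEMATOXYLIN_RGB = np.array([92.0, 58.0, 128.0])

# Base texture parameters shared by both classes at separation 0.
_BASE_BAND_AMP = 22.0          # intensity units of the oriented band texture
_BASE_NUCLEUS_DENSITY = 1.2e-3  # nuclei per tissue pixel
_NUCLEUS_RADIUS = 2.5          # px
_BAND_PERIOD = 14.0            # px


class InvalidSpecError(ValueError):
    """Raised for a malformed slide specification."""


@dataclasses.dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide."""

    width: int = 256
    height: int = 256
    class_label: str = IPF_LIKE
    tissue_coverage: float = 0.6
    texture_separation: float = 3.0
    background_gray: int = 235
    seed: int = 0

    def validate(self) -> "SlideSpec":
        if self.width <= 0 or self.height <= 0:
            raise InvalidSpecError("slide dimensions must be positive")
        if not 0.0 <= self.tissue_coverage <= 1.0:
            raise InvalidSpecError("tissue_coverage must be in [0, 1]")
        if self.texture_separation < 0:
            raise InvalidSpecError("texture_separation must be >= 0")
        if self.class_label not in CLASS_LABELS:
            raise InvalidSpecError(f"class_label must be one of {CLASS_LABELS}")
        if not 200 <= self.background_gray <= 255:
            raise InvalidSpecError("background_gray must be in [200, 255]")
        return self


@dataclasses.dataclass
class SyntheticSlide:
    image: np.ndarray            # (H, W, 3) uint8
    tissue_mask: np.ndarray      # (H, W) bool, ground truth
    case_id: str
    class_label: str

    def __post_init__(self):
        if self.image.shape[:2] != self.tissue_mask.shape:
            raise InvalidSpecError("image and mask dimensions differ")


def class_texture_params(class_label: str, separation: float) -> dict:
    """Band amplitude and nucleus density for a class at a given separation.

    The two classes coincide at separation 0 and diverge monotonically; the
    mapping is bounded so extreme separations stay inside a renderable range.
    """
    u = float(np.tanh(separation / 2.0))
    if class_label == IPF_LIKE:
        return {
            "band_amp": _BASE_BAND_AMP * (1.0 + u),
            "nucleus_density": _BASE_NUCLEUS_DENSITY * (1.0 - 0.85 * u),
        }
    return {
        "band_amp": _BASE_BAND_AMP * (1.0 - 0.85 * u),
        "nucleus_density": _BASE_NUCLEUS_DENSITY * (1.0 + 1.5 * u),
    }


def _tissue_mask(rng: np.random.Generator, h: int, w: int, coverage: float) -> np.ndarray:
    if coverage <= 0.0:
        return np.zeros((h, w), dtype=bool)
    if coverage >= 1.0:
        return np.ones((h, w), dtype=bool)
    field = gaussian_filter(rng.normal(size=(h, w)), sigma=max(4.0, min(h, w) / 10.0))
    thresh = np.quantile(field, 1.0 - coverage)
    return field > thresh


def _poisson_disc(
    rng: np.random.Generator,
    mask: np.ndarray,
    n_target: int,
    min_dist: float,
) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling restricted to the tissue mask."""
    if n_target <= 0 or not mask.any():
        return np.empty((0, 2))
    h, w = mask.shape
    cell = min_dist / np.sqrt(2.0)
    grid: dict[tuple[int, int], tuple[float, float]] = {}
    pts: list[tuple[float, float]] = []
    for _ in range(n_target * 12):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        if not mask[int(y), int(x)]:
            continue
        cy, cx = int(y / cell), int(x / cell)
        ok = True
        for dy in (-2, -1, 0, 1, 2):
            for dx in (-2, -1, 0, 1, 2):
                p = grid.get((cy + dy, cx + dx))
                if p is not None and (p[0] - y) ** 2 + (p[1] - x) ** 2 < min_dist ** 2:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            grid[(cy, cx)] = (y, x)
            pts.append((y, x))
            if len(pts) >= n_target:
                break
    return np.array(pts) if pts else np.empty((0, 2))


def make_synthetic_slide(spec: SlideSpec, case_id: str = "") -> SyntheticSlide:
    """Render one slide. Identical spec + seed gives a bit-identical result."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = _tissue_mask(rng, h, w, spec.tissue_coverage)
    params = class_texture_params(spec.class_label, spec.texture_separation)

    img = np.empty((h, w, 3))
    img[:] = spec.background_gray
    img += rng.normal(0.0, 2.0, size=(h, w, 3))

    if mask.any():
        yy, xx = np.mgrid[0:h, 0:w]
        theta = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        coord = xx * np.cos(theta) + yy * np.sin(theta)
        ripple = gaussian_filter(rng.normal(size=(h, w)), sigma=3.0)
        bands = np.sin(2 * np.pi * coord / _BAND_PERIOD + phase + 2.0 * ripple)
        # darken along the bands: elongated eosinophilic fibre texture
        shade = params["band_amp"] * 0.5 * (bands + 1.0)
        tissue = EOSIN_RGB[None, None, :] - shade[:, :, None]
        tissue += rng.normal(0.0, 4.0, size=(h, w, 3))
        img[mask] = tissue[mask]

        n_nuclei = int(round(params["nucleus_density"] * mask.sum()))
        pts = _poisson_disc(rng, mask, n_nuclei, min_dist=3.0 * _NUCLEUS_RADIUS)
        for y, x in pts:
            r = _NUCLEUS_RADIUS * rng.uniform(0.8, 1.2)
            y0, y1 = max(0, int(y - r - 1)), min(h, int(y + r + 2))
            x0, x1 = max(0, int(x - r - 1)), min(w, int(x + r + 2))
            sy, sx = np.mgrid[y0:y1, x0:x1]
            blob = (sy - y) ** 2 + (sx - x) ** 2 <= r ** 2
            region = img[y0:y1, x0:x1]
            region[blob] = HEMATOXYLIN_RGB + rng.normal(0.0, 5.0, size=3)
            img[y0:y1, x0:x1] = region

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSlide(
        image=image, tissue_mask=mask, case_id=case_id, class_label=spec.class_label
    )


def make_synthetic_cohort(
    n_cases_per_class: int,
    slides_per_case: int,
    base_spec: SlideSpec,
    seed: int,
) -> tuple[list[SyntheticSlide], pd.DataFrame]:
    """A labelled cohort: ``n_cases_per_class`` cases per class, each with
    ``slides_per_case`` slides sharing one case_id and label.

    Returns the slides plus a manifest (case_id, slide_path, label); paths
    are filled by :func:`write_cohort` when the cohort is saved.
    """
    if n_cases_per_class < 1:
        raise InvalidSpecError("n_cases_per_class must be >= 1")
    if slides_per_case < 1:
        raise InvalidSpecError("slides_per_case must be >= 1")
    base_spec.validate()

    slides: list[SyntheticSlide] = []
    rows = []
    for ci, label in enumerate(CLASS_LABELS):
        short = "ipf" if label == IPF_LIKE else "nonipf"
        for k in range(n_cases_per_class):
            case_id = f"{short}_{k:03d}"
            for s in range(slides_per_case):
                slide_seed = int(
                    np.random.SeedSequence([seed, ci, k, s]).generate_state(1)[0]
                    % (2 ** 31)
                )
                spec = dataclasses.replace(base_spec, class_label=label, seed=slide_seed)
                slides.append(make_synthetic_slide(spec, case_id=case_id))
                rows.append(
                    {
                        "case_id": case_id,
                        "slide_path": f"{case_id}_s{s}.png",
                        "label": label,
                    }
                )
    return slides, pd.DataFrame(rows)


def write_cohort(
    slides: list[SyntheticSlide], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write slides as PNG, masks as single-channel PNG, manifest as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for slide, path in zip(slides, manifest["slide_path"]):
        Image.fromarray(slide.image).save(out / path)
        mask_png = (slide.tissue_mask.astype(np.uint8)) * 255
        Image.fromarray(mask_png).save(out / (Path(path).stem + "_mask.png"))
    manifest = manifest.copy()
    manifest["slide_path"] = [str(out / p) for p in manifest["slide_path"]]
    manifest.to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def nucleus_pixel_fraction(patch: np.ndarray) -> float:
    """Fraction of dark (nucleus-like) pixels in an RGB patch.

    The simple texture statistic used by sanity oracles: nonIPF-like patches
    carry more hematoxylin-dark pixels per unit area than IPF-like ones.
    """
    gray = patch.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    return float((gray < 120.0).mean())
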