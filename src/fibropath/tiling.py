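"""Slide tiling and tissue filtering.

A whole-slide image is divided into fixed-size patches on a non-overlapping
raster grid (default source size 2240 px, later resized to 224 for the CNN).
Patches are binarized with Otsu's method — tissue is dark on a bright H&E
background, so foreground means "at or below threshold" — and patches whose
tissue fraction falls below 10% are excluded. A fraction of exactly 0.10 is
kept: the exclusion rule is *less than* 10%.

The Otsu threshold is computed once per slide rather than per patch, so a
near-empty patch cannot produce a degenerate threshold. Coordinates are
0-based with a top-left origin; a patch occupies the half-open square
``[x, x+size) x [y, y+size)``. Partial edge patches are dropped, never
padded. When a region-of-interest mask is supplied (the pathologist's
designated pneumonia area), a patch is kept if its centre lies inside the
ROI; the tissue-fraction rule is applied after ROI selection.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 2240
DEFAULT_MIN_TISSUE = 0.10
DEFAULT_NETWORK_EDGE = 224

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = [
    "case_id", "slide_id", "x", "y", "size", "tissue_fraction", "label", "patch_path",
]


class FormatError(ValueError):
    """Raised for images with an unexpected layout."""


@dataclasses.dataclass
class PatchRecord:
    """Provenance and tissue content of one extracted patch."""

    case_id: str
    slide_id: str
    x: int
    y: int
    size: int
    tissue_fraction: float
    label: str = "unknown"
    patch_path: str = ""


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance (0.299/0.587/0.114), rounded to 8-bit."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    gray = image.astype(np.float64) @ GRAY_WEIGHTS
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin count histogram.

    Returns the level ``t`` maximizing the between-class variance of
    ``{<=t, >t}``; ties broken toward the smallest ``t``. Comparisons use
    exact integer arithmetic, so tie-breaking is not at the mercy of
    floating-point rounding. A histogram with all mass in a single bin is
    degenerate — that bin's index is returned.
    """
    h = np.asarray(histogram)
    if h.ndim != 1 or len(h) != 256:
        raise FormatError("histogram must be a 256-bin vector")
    if (h < 0).any():
        raise ValueError("histogram counts must be non-negative")
    counts = [int(c) for c in np.rint(h)]
    total = sum(counts)
    if total == 0:
        raise ValueError("histogram has no mass")
    nonzero = [i for i, c in enumerate(counts) if c > 0]
    if len(nonzero) == 1:
        return nonzero[0]

    grand = sum(i * c for i, c in enumerate(counts))
    best_t, best_num, best_den = 0, -1, 1
    w0 = 0
    s0 = 0
    for t in range(256):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            num, den = 0, 1
        else:
            # between-class variance ~ (s0*N - S*w0)^2 / (w0*w1), exact ints
            num = (s0 * total - grand * w0) ** 2
            den = w0 * w1
        if num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    return best_t


def gray_histogram(gray: np.ndarray) -> np.ndarray:
    return np.bincount(np.asarray(gray, dtype=np.uint8).ravel(), minlength=256)


def tissue_mask(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground (tissue) = pixels at or below the threshold."""
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise FormatError("gray image must be single-channel")
    return gray <= threshold


def tissue_fraction(mask: np.ndarray) -> float:
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(mask.mean())


def tile_slide(
    slide_image: np.ndarray,
    roi: np.ndarray | None = None,
    patch_size: int = DEFAULT_PATCH_SIZE,
    *,
    case_id: str = "",
    slide_id: str = "",
    label: str = "unknown",
) -> list[PatchRecord]:
    """Non-overlapping grid tiling with per-patch tissue fractions.

    The Otsu threshold is estimated from the whole slide's grayscale
    histogram and reused for every patch. With an ROI mask (same dimensions
    as the slide), only patches whose centre pixel is inside the ROI are
    returned.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    image = np.asarray(slide_image)
    h, w = image.shape[:2]
    if roi is not None:
        roi = np.asarray(roi).astype(bool)
        if roi.shape != (h, w):
            raise FormatError("ROI mask dimensions must equal slide dimensions")
    if patch_size > h or patch_size > w:
        logger.warning(
            "patch_size %d exceeds slide dimensions (%d x %d); no patches",
            patch_size, w, h,
        )
        return []

    gray = rgb_to_gray(image) if image.ndim == 3 else np.asarray(image, dtype=np.uint8)
    threshold = otsu_threshold(gray_histogram(gray))
    fg = tissue_mask(gray, threshold)

    records = []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            if roi is not None:
                cy, cx = y + patch_size // 2, x + patch_size // 2
                if not roi[cy, cx]:
                    continue
            frac = tissue_fraction(fg[y : y + patch_size, x : x + patch_size])
            records.append(
                PatchRecord(
                    case_id=case_id, slide_id=slide_id, x=x, y=y,
                    size=patch_size, tissue_fraction=frac, label=label,
                )
            )
    return records


def filter_patches(
    records: list[PatchRecord], min_fraction: float = DEFAULT_MIN_TISSUE
) -> list[PatchRecord]:
    """Keep patches with tissue_fraction >= min_fraction, order preserved."""
    return [r for r in records if r.tissue_fraction >= min_fraction]


def extract_patch(slide_image: np.ndarray, record: PatchRecord) -> np.ndarray:
    return np.asarray(slide_image)[
        record.y : record.y + record.size, record.x : record.x + record.size
    ]


def resize_patch(patch: np.ndarray, target: int = DEFAULT_NETWORK_EDGE) -> np.ndarray:
    """Bilinear resize of a square patch to ``target`` x ``target``."""
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise FormatError("resize_patch requires a square input")
    if patch.shape[0] == target:
        return patch.copy()
    img = Image.fromarray(patch)
    out = img.resize((target, target), resample=Image.BILINEAR)
    return np.asarray(out)


# -- I/O ---------------------------------------------------------------------

def read_slide(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return np.asarray(Image.open(path).convert("RGB"))


def records_to_frame(records: list[PatchRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=MANIFEST_COLUMNS
    )


def frame_to_records(df: pd.DataFrame) -> list[PatchRecord]:
    return [
        PatchRecord(
            case_id=str(row.case_id), slide_id=str(row.slide_id),
            x=int(row.x), y=int(row.y), size=int(row.size),
            tissue_fraction=float(row.tissue_fraction),
            label=str(row.label), patch_path=str(row.patch_path),
        )
        for row in df.itertuples()
    ]


def tile_manifest(
    slide_manifest: pd.DataFrame,
    out_dir: str | Path,
    patch_size: int = DEFAULT_PATCH_SIZE,
    min_tissue: float = DEFAULT_MIN_TISSUE,
    roi_paths: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tile every slide in a cohort manifest; write patch PNGs and a patch
    manifest CSV to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_records: list[PatchRecord] = []
    for row in slide_manifest.itertuples():
        image = read_slide(row.slide_path)
        slide_id = Path(row.slide_path).stem
        roi = None
        if roi_paths and slide_id in roi_paths:
            roi = np.asarray(Image.open(roi_paths[slide_id]).convert("L")) > 0
        recs = tile_slide(
            image, roi=roi, patch_size=patch_size,
            case_id=str(row.case_id), slide_id=slide_id, label=str(row.label),
        )
        recs = filter_patches(recs, min_tissue)
        for r in recs:
            name = f"{slide_id}_x{r.x}_y{r.y}.png"
            Image.fromarray(extract_patch(image, r)).save(out / name)
            r.patch_path = str(out / name)
        all_records.extend(recs)
    frame = records_to_frame(all_records)
    frame.to_csv(out / "patches.csv", index=False)
    return frame
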