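"""Texture-enhanced training-image composition.

A composed scene shows the R-LBP-encoded fruit on a grayscaled background:
the fruit region (mask = 1) carries the code image of the grayscale
conversion, the background keeps the plain grayscale.  The encoding at
fruit-border pixels reads its neighbor intensities from the full grayscale
image regardless of the mask — the fruit is encoded in place, not on a
zero-filled cut-out, so no spurious edges are fabricated at the boundary.

``build_training_set`` batch-composes a directory of images with same-stem
masks and carries optional plain-text detection label files through
unchanged (composition never moves objects).
"""

from __future__ import annotations

import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_core import as_binary_mask, read_image, to_grayscale, write_image
from .rlbp_encoder import RLBPParams, rlbp_transform

__all__ = ["ComposedScene", "BuildReport", "compose_scene", "build_training_set"]

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class ComposedScene:
    """A composed grayscale scene plus the provenance of its inputs."""

    image: np.ndarray
    source: str | None = None
    mask_source: str | None = None
    params: RLBPParams = RLBPParams()


@dataclass
class BuildReport:
    """Outcome of a batch composition: scenes written and inputs skipped."""

    written: int = 0
    skipped: list[str] = field(default_factory=list)


def compose_scene(
    img: np.ndarray,
    mask: np.ndarray,
    params: RLBPParams = RLBPParams(),
    *,
    source: str | None = None,
    mask_source: str | None = None,
) -> ComposedScene:
    """Compose one scene: R-LBP codes where mask = 1, grayscale elsewhere.

    ``img`` may be RGB or already grayscale; the mask must match its
    spatial shape.
    """
    arr = np.asarray(img)
    m = as_binary_mask(mask, arr.shape[:2])
    gray = to_grayscale(arr)
    codes = rlbp_transform(gray, params)
    out = np.where(m == 1, codes, gray).astype(np.uint8)
    return ComposedScene(image=out, source=source, mask_source=mask_source, params=params)


def _find_same_stem(directory: Path, stem: str, suffixes) -> Path | None:
    for suffix in suffixes:
        candidate = directory / f"{stem}{suffix}"
        if candidate.exists():
            return candidate
    return None


def build_training_set(
    images_dir: str | os.PathLike,
    masks_dir: str | os.PathLike,
    labels_dir: str | os.PathLike | None,
    out_dir: str | os.PathLike,
    params: RLBPParams = RLBPParams(),
) -> BuildReport:
    """Compose every image in ``images_dir`` with its same-stem mask.

    Composed scenes are written to ``out_dir`` as ``<stem>_rlbp.png``.
    When ``labels_dir`` is given, a same-stem ``.txt`` label file (one
    detection box per line) is copied byte-identically to
    ``<stem>_rlbp.txt``.  Images without a mask are skipped and listed in
    the returned report, never fatal.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels_dir = Path(labels_dir) if labels_dir is not None else None
    report = BuildReport()
    for img_path in sorted(images_dir.iterdir()):
        if img_path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        stem = img_path.stem
        mask_path = _find_same_stem(masks_dir, stem, IMAGE_SUFFIXES)
        if mask_path is None:
            report.skipped.append(stem)
            continue
        img = read_image(img_path)
        mask = (read_image(mask_path) > 0).astype(np.uint8)
        if mask.ndim == 3:
            mask = mask.any(axis=2).astype(np.uint8)
        scene = compose_scene(
            img, mask, params, source=str(img_path), mask_source=str(mask_path)
        )
        write_image(scene.image, out_dir / f"{stem}_rlbp.png")
        if labels_dir is not None:
            label_path = labels_dir / f"{stem}.txt"
            if label_path.exists():
                shutil.copyfile(label_path, out_dir / f"{stem}_rlbp.txt")
        report.written += 1
    return report
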