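"""Seeded synthetic fruit scenes with controlled surface roughness.

The generator emulates close-range fruit photographs: a disc-shaped fruit
on a leaf-like background.  The fruit surface carries an additive Gaussian
noise field (one shared field across the RGB channels, so grayscale
conversion preserves its amplitude); the background carries a spatially
smoothed noise field, i.e. low-frequency leaf-like texture distinct from
the fruit's high-frequency surface grain.

Ripening is modelled along two coupled axes, mirroring how epicuticular
wax deposition changes the peel: the surface noise *amplitude* decreases
stage A (least ripe) to D (ripest), and the surface becomes spatially
*smoother* (the noise field is low-pass filtered with an increasing
width, then renormalised to the stage amplitude).  Amplitude alone would
leave LBP-family code images nearly unchanged — their dispersion ratios
and rank comparisons are insensitive to a pure intensity rescaling — so
the smoothing axis is what lets code-space methods see the stage
structure, exactly as surface micro-texture does on real peel.  Fruit
color interpolates green (unripe) to orange (ripe).

Everything is seeded and integer-valued, so outputs are bit-reproducible
across runs and platforms.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_core import write_image

__all__ = [
    "SceneSpec",
    "StageSeries",
    "STAGE_LABELS",
    "STAGE_SIGMAS",
    "STAGE_COLORS",
    "STAGE_SMOOTHING",
    "generate_fruit_scene",
    "generate_stage_series",
    "generate_group_set",
    "write_group_set",
]

STAGE_LABELS = ("A", "B", "C", "D")

#: Per-stage fruit surface noise std, strictly decreasing A -> D.
STAGE_SIGMAS = (30.0, 20.0, 12.0, 5.0)

#: Per-stage fruit base color, green (unripe) -> orange (ripe).
STAGE_COLORS = ((70, 132, 58), (126, 140, 52), (190, 148, 45), (240, 152, 38))

#: Per-stage smoothing width (px) of the surface noise field, increasing
#: A -> D: wax deposition low-passes the peel micro-texture.
STAGE_SMOOTHING = (0.0, 0.7, 1.4, 2.1)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic fruit scene.

    The disc must fit inside the frame with at least a 6-pixel margin.
    ``fruit_blur_sigma`` is the low-pass width of the surface noise field
    (0 leaves the noise i.i.d.); after smoothing the field is renormalised
    so its sample std equals ``noise_sigma``.
    """

    height: int = 256
    width: int = 256
    disc_center: tuple[int, int] = (128, 128)
    disc_radius: int = 60
    fruit_rgb: tuple[int, int, int] = (70, 132, 58)
    noise_sigma: float = 20.0
    fruit_blur_sigma: float = 0.0
    bg_rgb: tuple[int, int, int] = (64, 96, 48)
    bg_noise_sigma: float = 28.0
    bg_blur_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self):
        cr, cc = self.disc_center
        r = self.disc_radius
        if (
            cr - r < 6
            or cc - r < 6
            or cr + r > self.height - 1 - 6
            or cc + r > self.width - 1 - 6
        ):
            raise ValueError("disc must fit inside the frame with a >= 6-pixel margin")
        if self.noise_sigma < 0 or self.bg_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class StageSeries:
    """Four aligned scenes of one fruit at ripeness stages A..D.

    All four share the disc geometry (hence an identical mask); they
    differ in surface noise amplitude/smoothness and base color.
    """

    scenes: tuple[np.ndarray, ...]  # four (H, W, 3) uint8 images
    mask: np.ndarray  # shared (H, W) uint8 {0, 1}
    specs: tuple[SceneSpec, ...] | None = None  # None for scenes loaded from disk

    def __post_init__(self):
        if len(self.scenes) != 4 or (self.specs is not None and len(self.specs) != 4):
            raise ValueError("a stage series holds exactly four scenes")


def _normalised_field(rng: np.random.Generator, shape, sigma: float, blur: float) -> np.ndarray:
    """Gaussian noise field with sample std ``sigma``, optionally low-pass
    filtered with width ``blur`` before renormalisation."""
    field = rng.standard_normal(shape)
    if blur > 0:
        field = gaussian_filter(field, blur, mode="reflect")
    sd = field.std()
    if sd > 0 and sigma > 0:
        field *= sigma / sd
    else:
        field = np.zeros(shape)
    return field


def generate_fruit_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic scene: an (H, W, 3) uint8 image and its fruit mask.

    The mask is exactly the disc inequality (no anti-aliased fringe).  The
    same spec always yields bit-identical output: noise is drawn in a
    fixed order from ``default_rng(spec.seed)``, applied in float, then
    rounded half-up and clamped to [0, 255] once.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    fruit_field = _normalised_field(rng, (h, w), spec.noise_sigma, spec.fruit_blur_sigma)
    bg_field = _normalised_field(rng, (h, w), spec.bg_noise_sigma, spec.bg_blur_sigma)

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    cr, cc = spec.disc_center
    mask = ((rows - cr) ** 2 + (cols - cc) ** 2 <= spec.disc_radius**2).astype(np.uint8)

    img = np.empty((h, w, 3), dtype=np.float64)
    for ch in range(3):
        img[..., ch] = np.where(
            mask == 1,
            spec.fruit_rgb[ch] + fruit_field,
            spec.bg_rgb[ch] + bg_field,
        )
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return img, mask


def generate_stage_series(
    base: SceneSpec,
    sigmas: tuple[float, ...] = STAGE_SIGMAS,
    colors: tuple[tuple[int, int, int], ...] = STAGE_COLORS,
    smoothing: tuple[float, ...] = STAGE_SMOOTHING,
) -> StageSeries:
    """Four-stage series sharing ``base``'s geometry and seed.

    ``sigmas`` must be strictly decreasing (the roughness trend of
    ripening); stage scene seeds are ``base.seed * 4 + stage`` so series
    generated from consecutive base seeds stay independent.
    """
    if len(sigmas) != 4 or len(colors) != 4 or len(smoothing) != 4:
        raise ValueError("need exactly four sigmas, colors and smoothing widths")
    if not all(a > b for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError(f"stage sigmas must be strictly decreasing, got {sigmas}")
    specs = tuple(
        replace(
            base,
            noise_sigma=float(sigmas[i]),
            fruit_rgb=tuple(colors[i]),
            fruit_blur_sigma=float(smoothing[i]),
            seed=base.seed * 4 + i,
        )
        for i in range(4)
    )
    scenes, masks = zip(*(generate_fruit_scene(s) for s in specs))
    return StageSeries(scenes=tuple(scenes), mask=masks[0], specs=specs)


def generate_group_set(n_groups: int, base: SceneSpec) -> list[StageSeries]:
    """``n_groups`` independent stage series with base seeds
    ``base.seed + group_index`` (deterministic, pairwise distinct)."""
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    return [generate_stage_series(replace(base, seed=base.seed + g)) for g in range(n_groups)]


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def write_group_set(
    out_dir: str | os.PathLike, n_groups: int, base: SceneSpec
) -> dict:
    """Write a group set to disk as PNGs plus a JSON manifest.

    Layout: ``group_<g>_stage_<L>.png`` and one shared mask per group,
    ``group_<g>_mask.png``.  The manifest records specs and SHA-256
    checksums of the pixel arrays; it is returned and also written to
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"n_groups": n_groups, "base_seed": base.seed, "groups": []}
    for g, series in enumerate(generate_group_set(n_groups, base)):
        mask_name = f"group_{g:03d}_mask.png"
        write_image(series.mask * 255, out_dir / mask_name)
        entry = {"mask": mask_name, "mask_sha256": _sha256(series.mask), "stages": []}
        for label, scene, spec in zip(STAGE_LABELS, series.scenes, series.specs):
            name = f"group_{g:03d}_stage_{label}.png"
            write_image(scene, out_dir / name)
            entry["stages"].append(
                {
                    "label": label,
                    "file": name,
                    "sha256": _sha256(scene),
                    "noise_sigma": spec.noise_sigma,
                    "fruit_blur_sigma": spec.fruit_blur_sigma,
                    "fruit_rgb": list(spec.fruit_rgb),
                    "seed": spec.seed,
                }
            )
        manifest["groups"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
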