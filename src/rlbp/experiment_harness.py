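"""Adjacent-stage roughness-difference experiment.

For a four-stage series the harness grayscales each stage's fruit
bounding-rectangle crop, optionally applies a texture transform (classic
LBP or R-LBP; the grayscale arm applies none), measures peel roughness on
the crop, and records the mean absolute roughness difference between
adjacent stages.  Over many groups these per-group averages are
summarised as median, quartiles and IQR, one distribution per
preprocessing arm.  A texture transform that *amplifies* the stage
structure yields larger adjacent-stage differences than grayscale alone.

The three arms differ only in the transform step, so any difference in
the summary statistics is attributable to the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .image_core import to_grayscale
from .rlbp_encoder import RLBPParams, lbp_transform, rlbp_transform
from .roughness import mask_bounding_rect, peel_roughness
from .synthetic_scenes import StageSeries

__all__ = [
    "PreprocessMethod",
    "DistributionStats",
    "stage_roughness",
    "group_difference",
    "run_experiment1",
]


class PreprocessMethod(str, Enum):
    """The three preprocessing arms of the roughness experiment."""

    GRAYSCALE = "grayscale"
    LBP = "lbp"
    RLBP = "rlbp"


@dataclass(frozen=True)
class DistributionStats:
    """Five-number-style summary of per-group roughness differences.

    Quartiles use linear interpolation between closest order statistics.
    """

    median: float
    q1: float
    q3: float
    iqr: float
    n: int
    values: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "iqr": self.iqr,
            "values": list(self.values),
        }


def _apply_method(crop: np.ndarray, method: PreprocessMethod, params: RLBPParams) -> np.ndarray:
    if method == PreprocessMethod.GRAYSCALE:
        return crop
    if method == PreprocessMethod.LBP:
        return lbp_transform(crop)
    if method == PreprocessMethod.RLBP:
        return rlbp_transform(crop, params)
    raise ValueError(f"unknown preprocessing method {method!r}")


def stage_roughness(
    scene: np.ndarray,
    mask: np.ndarray,
    method: PreprocessMethod,
    params: RLBPParams = RLBPParams(),
) -> float:
    """Overall peel roughness of one scene's fruit crop under one arm.

    The crop is the bounding rectangle of the mask's nonzero pixels on the
    grayscaled scene; the transform (if any) is applied to the crop and
    roughness is measured on the result.
    """
    gray = to_grayscale(scene)
    top, left, bottom, right = mask_bounding_rect(mask)
    crop = gray[top:bottom, left:right]
    return peel_roughness(_apply_method(crop, PreprocessMethod(method), params)).overall


def group_difference(
    series: StageSeries,
    method: PreprocessMethod,
    params: RLBPParams = RLBPParams(),
) -> float:
    """Mean absolute roughness difference between adjacent stages of one
    four-stage group: ``mean(|P_A - P_B|, |P_B - P_C|, |P_C - P_D|)``."""
    rough = [stage_roughness(scene, series.mask, method, params) for scene in series.scenes]
    diffs = [abs(a - b) for a, b in zip(rough, rough[1:])]
    return float(np.mean(diffs))


def run_experiment1(
    groups: list[StageSeries],
    method: PreprocessMethod,
    params: RLBPParams = RLBPParams(),
) -> DistributionStats:
    """Per-group adjacent-stage differences under one arm, summarised.

    Requires at least one group.  Order of the groups does not affect the
    statistics.
    """
    if len(groups) == 0:
        raise ValueError("need at least one group")
    values = [group_difference(series, method, params) for series in groups]
    q1, med, q3 = (float(q) for q in np.percentile(values, (25, 50, 75), method="linear"))
    return DistributionStats(
        median=med, q1=q1, q3=q3, iqr=q3 - q1, n=len(values), values=tuple(values)
    )
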