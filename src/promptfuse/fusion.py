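"""Weighted late fusion of two continuous score masks.

The conventional segmentator's logit mask and the promptable segmentator's
logit mask are combined per pixel as a weighted average,

    fused = (w_seg * s_seg + w_zs * s_zs) / (w_seg + w_zs),

after both have been normalized to the canonical foreground-high polarity
(a promptable segmentator following the opposite convention is inverted
first).  Dividing by the weight sum keeps the fused scores on the 0-255
scale, so a single fixed margin (default 128) remains meaningful for any
weights.  The default weights are 2 for the conventional segmentator and 1
for the promptable one, which down-weights the noisier zero-shot mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .masks import (
    BinaryMask,
    MaskValidationError,
    Polarity,
    ScoreMask,
    binarize,
    read_mask,
    write_mask,
)

__all__ = ["FusionConfig", "fuse", "fuse_files"]


@dataclass(frozen=True)
class FusionConfig:
    """Weights and binarization threshold of the fusion rule."""

    seg_weight: float = 2.0
    zs_weight: float = 1.0
    threshold: int = 128

    def __post_init__(self) -> None:
        if self.seg_weight < 0 or self.zs_weight < 0 or self.seg_weight + self.zs_weight <= 0:
            raise MaskValidationError("weights must be nonnegative with a positive sum")
        if not 0 <= self.threshold <= 255:
            raise MaskValidationError("threshold must be in [0, 255]")


def fuse(seg: ScoreMask, zs: ScoreMask, config: FusionConfig = FusionConfig()) -> tuple[ScoreMask, BinaryMask]:
    """Fuse two score masks and binarize the result.

    Returns the continuous fused mask (foreground-high, rounded half away
    from zero) and its binarization at ``config.threshold`` (foreground wins
    ties).  The fused score is a convex combination, so it is bounded by the
    per-pixel min and max of the inputs.
    """
    if seg.shape != zs.shape:
        raise MaskValidationError(f"shape mismatch: {seg.shape} vs {zs.shape}")
    a = seg.to_foreground_high().scores.astype(np.float64)
    b = zs.to_foreground_high().scores.astype(np.float64)
    w1, w2 = config.seg_weight, config.zs_weight
    avg = (w1 * a + w2 * b) / (w1 + w2)
    fused = ScoreMask(np.floor(avg + 0.5).astype(np.uint8), Polarity.FOREGROUND_HIGH)
    return fused, binarize(fused, config.threshold)


def fuse_files(
    seg_path: Union[str, Path],
    zs_path: Union[str, Path],
    config: FusionConfig,
    out_prefix: Union[str, Path],
    seg_polarity: Polarity = Polarity.FOREGROUND_LOW,
    zs_polarity: Polarity = Polarity.FOREGROUND_HIGH,
) -> dict[str, Path]:
    """Fuse two on-disk score masks; write fused score + binary PNGs.

    A JSON provenance sidecar records weights, threshold, and the declared
    polarities so the run is reproducible from the artifacts alone.
    Nothing is written if the inputs are unreadable or shape-mismatched.
    """
    seg = read_mask(seg_path, seg_polarity)
    zs = read_mask(zs_path, zs_polarity)
    fused, binary = fuse(seg, zs, config)
    out_prefix = Path(out_prefix)
    paths = {
        "fused": out_prefix.with_name(out_prefix.name + "_fused.png"),
        "binary": out_prefix.with_name(out_prefix.name + "_binary.png"),
        "sidecar": out_prefix.with_name(out_prefix.name + "_fusion.json"),
    }
    write_mask(fused, paths["fused"])
    write_mask(binary, paths["binary"])
    sidecar = {
        "seg_path": str(seg_path),
        "zs_path": str(zs_path),
        "seg_weight": config.seg_weight,
        "zs_weight": config.zs_weight,
        "threshold": config.threshold,
        "seg_polarity": seg_polarity.value,
        "zs_polarity": zs_polarity.value,
    }
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return paths
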