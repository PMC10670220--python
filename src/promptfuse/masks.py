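"""Score and binary mask containers with explicit foreground polarity.

Continuous segmentator outputs ("logit masks") are exchanged on the 0-255
byte scale.  Conventions differ between models: some emit high values for
foreground (``foreground_high``), others the opposite.  Every
:class:`ScoreMask` therefore carries an explicit polarity tag and no
operation in this package ever assumes a default.  The internal canonical
polarity is ``foreground_high``; adapters normalize at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

__all__ = [
    "Polarity",
    "ScoreMask",
    "BinaryMask",
    "MaskValidationError",
    "read_mask",
    "write_mask",
    "rescale_to_byte",
    "invert",
    "binarize",
]


class MaskValidationError(ValueError):
    """Raised when a mask or parameter violates its contract."""


class Polarity(str, enum.Enum):
    """Which end of the byte scale denotes foreground."""

    FOREGROUND_HIGH = "foreground_high"
    FOREGROUND_LOW = "foreground_low"


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (unlike numpy's banker's rounding)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class ScoreMask:
    """Per-pixel continuous scores on the 0-255 byte scale.

    Parameters
    ----------
    scores
        ``(H, W)`` uint8 array.
    polarity
        Whether high bytes mean foreground.
    """

    scores: np.ndarray
    polarity: Polarity

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise MaskValidationError(f"scores must be a non-empty 2-D array, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise MaskValidationError("scores must be integers in [0, 255]")
        object.__setattr__(self, "scores", arr)
        object.__setattr__(self, "polarity", Polarity(self.polarity))

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape  # type: ignore[return-value]

    def to_foreground_high(self) -> "ScoreMask":
        """Return an equivalent mask in the canonical polarity."""
        if self.polarity is Polarity.FOREGROUND_HIGH:
            return self
        return invert(self)


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel {0, 1} foreground labels."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise MaskValidationError(f"labels must be a non-empty 2-D array, got shape {arr.shape}")
        if arr.dtype == np.bool_:
            arr = arr.astype(np.uint8)
        if not np.isin(arr, (0, 1)).all():
            raise MaskValidationError("labels must be 0 or 1")
        object.__setattr__(self, "labels", arr.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


def read_mask(path: Union[str, Path], polarity: Polarity) -> ScoreMask:
    """Read a grayscale score mask from disk.

    Multi-channel images are collapsed to gray by ITU-R 601 luma weighting;
    16-bit rasters are linearly rescaled to [0, 255].  The caller must
    declare the polarity of the stored values.

    PNG is the canonical (lossless) format; JPG is accepted read-only for
    compatibility with pipelines that stored logit masks as JPEGs.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            if img.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(img, dtype=np.float64)
                arr = _round_half_away(arr * (255.0 / 65535.0)).astype(np.uint8)
            else:
                arr = np.asarray(img.convert("L"))
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode mask file {path}: {exc}") from exc
    if arr.size == 0:
        raise MaskValidationError(f"{path} decodes to a zero-sized raster")
    return ScoreMask(arr, Polarity(polarity))


def write_mask(mask: Union[ScoreMask, BinaryMask], path: Union[str, Path]) -> None:
    """Write a mask as an 8-bit grayscale PNG.

    Binary masks are stored with the on-disk convention {0, 255}.  The write
    is bit-exact round-trippable with :func:`read_mask`.
    """
    path = Path(path)
    if isinstance(mask, BinaryMask):
        arr = mask.labels * np.uint8(255)
    else:
        arr = mask.scores
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def rescale_to_byte(raw: np.ndarray, polarity: Polarity = Polarity.FOREGROUND_HIGH) -> ScoreMask:
    """Linearly map real-valued scores onto [0, 255].

    ``min(raw)`` maps to 0 and ``max(raw)`` to 255 (per-image min-max),
    rounding half away from zero.  A constant input maps to all zeros: an
    uninformative mask makes no foreground claim.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise MaskValidationError("raw scores must be a non-empty 2-D array")
    if not np.isfinite(arr).all():
        raise MaskValidationError("raw scores contain NaN or Inf")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        scaled = np.zeros_like(arr)
    else:
        scaled = _round_half_away((arr - lo) * (255.0 / (hi - lo)))
    return ScoreMask(scaled.astype(np.uint8), Polarity(polarity))


def invert(mask: ScoreMask) -> ScoreMask:
    """Map each score s to 255 - s and flip the polarity tag.

    This is the reconciliation step used when a promptable segmentator and a
    conventional segmentator follow opposite byte conventions; it is an
    involution.
    """
    flipped = (
        Polarity.FOREGROUND_LOW
        if mask.polarity is Polarity.FOREGROUND_HIGH
        else Polarity.FOREGROUND_HIGH
    )
    return ScoreMask(np.uint8(255) - mask.scores, flipped)


def binarize(mask: ScoreMask, threshold: int) -> BinaryMask:
    """Threshold a score mask into a binary mask.

    The threshold is interpreted in the mask's *native* convention and the
    mask is first normalized to ``foreground_high``:

    - ``foreground_high``: pixel is foreground iff ``score >= threshold``.
    - ``foreground_low`` with margin ``t``: foreground iff the score is below
      the margin, realized as ``(255 - score) >= 256 - t``.  The complement
      256 - t (not 255 - t) makes the two rules classify identical byte
      values, so e.g. the strict margin 32 keeps scores 0..31 as foreground.
    """
    t = int(threshold)
    if not 0 <= t <= 255:
        raise MaskValidationError(f"threshold must be in [0, 255], got {threshold}")
    if mask.polarity is Polarity.FOREGROUND_LOW:
        norm = invert(mask)
        eff = 256 - t
    else:
        norm = mask
        eff = t
    return BinaryMask((norm.scores.astype(np.int16) >= eff).astype(np.uint8))
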