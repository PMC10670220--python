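"""Connected-component ("blob") extraction and border-mode erosion.

A source mask may cover several disconnected regions of the same class;
prompt generation operates per blob.  Border mode shrinks the mask with a
morphological erosion (default: a 10x10 discrete elliptical structuring
element) so that prompts stay away from object boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import BinaryMask, MaskValidationError

__all__ = ["Blob", "label_blobs", "erode", "elliptical_kernel", "DEFAULT_KERNEL_SIZE"]

#: Kernel size of the border-mode erosion: a 10x10 elliptical element.
DEFAULT_KERNEL_SIZE: tuple[int, int] = (10, 10)

# 8-connectivity: diagonal neighbours belong to the same blob.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Blob:
    """One connected foreground component of a binary mask.

    ``pixels`` is stored as an ``(n, 2)`` array of (row, col) coordinates in
    lexicographic order; ``bbox`` is inclusive ``(row_min, col_min, row_max,
    col_max)``; ``centroid`` is the arithmetic mean of the pixel coordinates
    and may fall outside the pixel set for concave blobs.
    """

    id: int
    pixels: np.ndarray
    bbox: tuple[int, int, int, int] = field(init=False)
    centroid: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if px.shape[0] < 1:
            raise MaskValidationError("a blob must contain at least one pixel")
        order = np.lexsort((px[:, 1], px[:, 0]))
        px = px[order]
        object.__setattr__(self, "pixels", px)
        object.__setattr__(
            self,
            "bbox",
            (int(px[:, 0].min()), int(px[:, 1].min()), int(px[:, 0].max()), int(px[:, 1].max())),
        )
        object.__setattr__(self, "centroid", (float(px[:, 0].mean()), float(px[:, 1].mean())))

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    def contains(self, row: int, col: int) -> bool:
        return bool(np.any((self.pixels[:, 0] == row) & (self.pixels[:, 1] == col)))

    def to_mask(self, shape: tuple[int, int]) -> BinaryMask:
        arr = np.zeros(shape, dtype=np.uint8)
        arr[self.pixels[:, 0], self.pixels[:, 1]] = 1
        return BinaryMask(arr)


def label_blobs(mask: BinaryMask) -> list[Blob]:
    """Extract the 8-connected foreground components of a binary mask.

    Blobs are returned ordered by (row_min, col_min, area) and numbered from
    0 in that order, so the labelling is deterministic.  An empty mask yields
    an empty list.
    """
    labelled, n = ndimage.label(mask.as_bool(), structure=_STRUCTURE_8)
    raw: list[np.ndarray] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labelled == lab)
        raw.append(np.column_stack([rows, cols]))
    raw.sort(key=lambda px: (int(px[:, 0].min()), int(px[:, 1].min()), px.shape[0]))
    return [Blob(i, px) for i, px in enumerate(raw)]


def elliptical_kernel(size: tuple[int, int] = DEFAULT_KERNEL_SIZE) -> np.ndarray:
    """Discrete filled ellipse inscribed in a ``size`` box.

    A pixel (i, j) belongs to the element iff its center lies inside the
    ellipse with semi-axes h/2, w/2 centered at the box center
    ((h-1)/2, (w-1)/2).  The construction is symmetric under flips of either
    axis; for the default 10x10 box the extreme rows/columns keep their four
    central pixels.
    """
    h, w = int(size[0]), int(size[1])
    if h < 1 or w < 1:
        raise MaskValidationError("kernel size must be positive")
    ci, cj = (h - 1) / 2.0, (w - 1) / 2.0
    ri, rj = h / 2.0, w / 2.0
    ii, jj = np.mgrid[0:h, 0:w]
    kernel = ((ii - ci) / ri) ** 2 + ((jj - cj) / rj) ** 2 <= 1.0
    if not kernel.any():  # degenerate 1x1 etc. always contain the center
        kernel[h // 2, w // 2] = True
    return kernel


def erode(mask: BinaryMask, kernel: np.ndarray | None = None) -> BinaryMask:
    """Morphological erosion with out-of-image pixels treated as background.

    An output pixel is foreground iff the kernel, anchored at
    (ceil(h/2)-1, ceil(w/2)-1), fits entirely inside the input foreground.
    For even kernels (which have no center pixel) this anchor is the common
    upper-left-of-center convention.  A kernel larger than the image erodes
    everything away; that is a valid (all-background) result, not an error.
    """
    if kernel is None:
        kernel = elliptical_kernel()
    kernel = np.asarray(kernel, dtype=bool)
    if kernel.ndim != 2 or not kernel.any():
        raise MaskValidationError("kernel must be a non-empty 2-D boolean array")
    h, w = kernel.shape
    anchor = (-(-h // 2) - 1, -(-w // 2) - 1)
    # scipy centers a size-k structure at index k // 2; shift to our anchor.
    origin = (anchor[0] - h // 2, anchor[1] - w // 2)
    out = ndimage.binary_erosion(
        mask.as_bool(), structure=kernel, origin=origin, border_value=0
    )
    return BinaryMask(out.astype(np.uint8))
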