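"""Checkpoint (point-prompt) generation from a source mask.

A promptable segmentator takes an image plus point prompts and returns an
object mask.  The prompts ("checkpoints") are derived from a *source mask*
-- either a conventional segmentator's binarized output or, in the oracle
protocol, the ground truth.  Four methods are provided:

- ``A``: bounding-box center of each blob (an average of the coordinate
  extremes; may fall outside a concave blob -- a documented failure mode).
- ``B``: pixel centroid of each blob, snapped to the nearest blob pixel when
  the rounded centroid lands outside the blob.
- ``C``: a uniformly random pixel of each blob (seeded, reproducible).
- ``D``: all points of a period-``b`` lattice falling inside a blob, with a
  shift fallback guaranteeing every blob at least one checkpoint, and an
  optional *border mode* that erodes the mask first so prompts avoid object
  boundaries.

Checkpoint coordinates are (row, col), 0-based; serialization exports them
as (x=col, y=row), the convention of point-prompt segmentators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

import numpy as np

from .blobs import DEFAULT_KERNEL_SIZE, Blob, elliptical_kernel, erode, label_blobs
from .masks import BinaryMask, MaskValidationError

__all__ = [
    "Checkpoint",
    "PromptConfig",
    "PromptSet",
    "method_a",
    "method_b",
    "method_c",
    "method_d",
    "extract_prompts",
    "load_prompts",
]

_METHODS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class Checkpoint:
    """A single point prompt with its originating blob and method."""

    row: int
    col: int
    blob_id: int
    method: str

    def to_xy(self) -> dict:
        return {"x": self.col, "y": self.row, "blob_id": self.blob_id, "method": self.method}


@dataclass(frozen=True)
class PromptConfig:
    """Parameters of checkpoint extraction.

    ``b`` is the lattice step of method D in pixels; ``border_mode`` erodes
    the source mask with ``erosion_kernel_size`` before extraction;
    ``rescue_on_empty_erosion`` restores a blob's un-eroded pixel set when
    erosion removes it entirely (so small blobs still receive prompts);
    ``rng_seed`` drives method C.
    """

    method: str = "D"
    b: int = 50
    border_mode: bool = False
    rng_seed: int = 0
    erosion_kernel_size: tuple[int, int] = DEFAULT_KERNEL_SIZE
    rescue_on_empty_erosion: bool = True

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise MaskValidationError(f"unknown prompt method {self.method!r}; expected one of {_METHODS}")
        if self.method == "D" and self.b < 1:
            raise MaskValidationError("lattice step b must be >= 1")


@dataclass(frozen=True)
class PromptSet:
    """Ordered checkpoints plus the configuration that produced them."""

    checkpoints: tuple[Checkpoint, ...]
    config: PromptConfig

    def __len__(self) -> int:
        return len(self.checkpoints)

    def __iter__(self) -> Iterator[Checkpoint]:
        return iter(self.checkpoints)

    def to_json(self) -> str:
        payload = {
            "method": self.config.method,
            "b": self.config.b,
            "border_mode": self.config.border_mode,
            "rng_seed": self.config.rng_seed,
            "checkpoints": [c.to_xy() for c in self.checkpoints],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def method_a(blob: Blob) -> Checkpoint:
    """Bounding-box center of the blob, rounded half away from zero.

    No blob-membership guarantee: for concave or ring-shaped blobs the box
    center can land on background.
    """
    r0, c0, r1, c1 = blob.bbox
    return Checkpoint(_round_half_away((r0 + r1) / 2), _round_half_away((c0 + c1) / 2), blob.id, "A")


def method_b(blob: Blob) -> Checkpoint:
    """Center of mass of the blob, snapped into the blob if necessary.

    The pixel centroid is rounded to integer coordinates; if that point is
    not a blob pixel, the blob pixel nearest (Euclidean) to the real-valued
    centroid is returned, ties broken by (row, col) order.  The returned
    checkpoint therefore always lies inside the blob.
    """
    cr, cc = blob.centroid
    r, c = _round_half_away(cr), _round_half_away(cc)
    if blob.contains(r, c):
        return Checkpoint(r, c, blob.id, "B")
    d2 = (blob.pixels[:, 0] - cr) ** 2 + (blob.pixels[:, 1] - cc) ** 2
    best = blob.pixels[int(np.argmin(d2))]  # pixels are (row, col)-sorted: argmin is the tie-break
    return Checkpoint(int(best[0]), int(best[1]), blob.id, "B")


def method_c(blob: Blob, rng_seed: int) -> Checkpoint:
    """A pixel drawn uniformly from the blob, reproducible from the seed."""
    rng = np.random.default_rng([int(rng_seed), int(blob.id)])
    idx = int(rng.integers(blob.area))
    r, c = blob.pixels[idx]
    return Checkpoint(int(r), int(c), blob.id, "C")


def _lattice_points_in(pixel_set: frozenset, shape: tuple[int, int], b: int, dy: int, dx: int) -> list[tuple[int, int]]:
    h, w = shape
    pts = []
    for r in range(dy, h, b):
        for c in range(dx, w, b):
            if (r, c) in pixel_set:
                pts.append((r, c))
    return pts


def method_d(mask: BinaryMask, config: PromptConfig) -> list[Checkpoint]:
    """Lattice sampling with per-blob shift fallback (and optional erosion).

    A global lattice {(i*b, j*b)} anchored at the image origin is laid over
    the mask and every lattice point inside a blob becomes a checkpoint.  A
    blob missed by the lattice triggers the fallback: the lattice is shifted
    by one pixel at a time, horizontally first (dx = 1..b-1 at dy = 0) and
    then vertically (dy = 1..b-1, each with dx = 0..b-1), stopping at the
    first shift that intersects the blob; the intersecting points are
    emitted.  Since the shifts enumerate every residue class of the period-b
    lattice, the fallback always terminates and every nonempty blob
    contributes at least one checkpoint.

    With ``border_mode`` the mask is eroded first and blobs are re-labelled
    on the eroded mask; a blob erased entirely by erosion falls back to its
    un-eroded pixel set when ``rescue_on_empty_erosion`` is set.
    """
    b = config.b
    pixel_sets: list[np.ndarray] = []
    if config.border_mode:
        eroded = erode(mask, elliptical_kernel(config.erosion_kernel_size))
        pixel_sets = [bl.pixels for bl in label_blobs(eroded)]
        if config.rescue_on_empty_erosion:
            er = eroded.as_bool()
            for blob in label_blobs(mask):
                if not er[blob.pixels[:, 0], blob.pixels[:, 1]].any():
                    pixel_sets.append(blob.pixels)
        pixel_sets.sort(key=lambda px: (int(px[:, 0].min()), int(px[:, 1].min()), px.shape[0]))
        blobs = [Blob(i, px) for i, px in enumerate(pixel_sets)]
    else:
        blobs = label_blobs(mask)

    out: list[Checkpoint] = []
    for blob in blobs:
        pset = frozenset((int(r), int(c)) for r, c in blob.pixels)
        pts = _lattice_points_in(pset, mask.shape, b, 0, 0)
        if not pts:
            for dy, dx in _fallback_offsets(b):
                pts = _lattice_points_in(pset, mask.shape, b, dy, dx)
                if pts:
                    break
        out.extend(Checkpoint(r, c, blob.id, "D") for r, c in pts)
    out.sort(key=lambda cp: (cp.row, cp.col))
    return out


def _fallback_offsets(b: int) -> Iterator[tuple[int, int]]:
    """Shift order: horizontal first, then vertical-major sweep."""
    for dx in range(1, b):
        yield 0, dx
    for dy in range(1, b):
        for dx in range(0, b):
            yield dy, dx


def extract_prompts(mask: BinaryMask, config: PromptConfig) -> PromptSet:
    """Dispatch checkpoint extraction over methods A-D.

    Methods A, B, and C yield one checkpoint per blob; method D delegates to
    :func:`method_d`.  Applying this to a ground-truth mask realizes the
    oracle prompting protocol with no code change -- only the source mask
    differs.
    """
    if config.method == "D":
        cps = method_d(mask, config)
    else:
        blobs = label_blobs(mask)
        if config.method == "A":
            cps = [method_a(bl) for bl in blobs]
        elif config.method == "B":
            cps = [method_b(bl) for bl in blobs]
        else:
            cps = [method_c(bl, config.rng_seed) for bl in blobs]
    return PromptSet(tuple(cps), config)


def load_prompts(path: Union[str, Path]) -> PromptSet:
    """Read a prompt JSON file written by :meth:`PromptSet.save`."""
    payload = json.loads(Path(path).read_text())
    config = PromptConfig(
        method=payload["method"],
        b=payload["b"],
        border_mode=payload["border_mode"],
        rng_seed=payload["rng_seed"],
    )
    cps = tuple(
        Checkpoint(row=int(c["y"]), col=int(c["x"]), blob_id=int(c["blob_id"]), method=c["method"])
        for c in payload["checkpoints"]
    )
    return PromptSet(cps, config)
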