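"""Synthetic masks and a mock promptable backend.

Real evaluations of prompt engineering need a trained conventional
segmentator, a promptable zero-shot segmentator, and annotated datasets.
This module replaces all three with controllable stand-ins so every
pipeline stage runs at desk scale:

- :func:`generate_ground_truth` draws multi-blob binary masks (ellipses or
  blobby polygons) with a guaranteed blob count and pairwise separation;
- :func:`degrade` turns a ground truth into an imperfect "segmentator"
  score mask, with independently tunable failure modes observed in real
  segmentators: boundary jitter, missed blobs, spurious blobs, score noise;
- :func:`mock_backend` emulates a point-promptable segmentator: a prompt
  "selects" the whole ground-truth blob it lands on, prompts on background
  select nothing, and the rendered mask degrades as fidelity drops below 1.
  At fidelity 1 with every blob prompted it reproduces the ground truth
  exactly, which makes the oracle prompting protocol testable end to end.

Everything is seed-deterministic: identical specs and seeds yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .blobs import label_blobs
from .masks import BinaryMask, MaskValidationError, Polarity, ScoreMask, write_mask
from .prompts import PromptConfig, PromptSet, extract_prompts

__all__ = [
    "SyntheticSpec",
    "DegradationSpec",
    "MockPromptableBackend",
    "generate_ground_truth",
    "degrade",
    "mock_backend",
    "write_fixture_tree",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry of a synthetic multi-blob ground truth.

    Defaults describe the desk-scale study condition used throughout the
    test suite: three blobs of radius 8-15 px in a 128x128 frame, at least
    two background pixels apart so the blob count is verifiable by
    8-connected labelling.
    """

    height: int = 128
    width: int = 128
    n_blobs: int = 3
    blob_radius_range: tuple[float, float] = (8.0, 15.0)
    min_separation: float = 2.0
    shape_family: str = "ellipse"  # or "blobby-polygon"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1 or self.n_blobs < 0:
            raise MaskValidationError("invalid synthetic geometry")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi):
            raise MaskValidationError("blob_radius_range must be positive and ordered")
        if self.shape_family not in ("ellipse", "blobby-polygon"):
            raise MaskValidationError(f"unknown shape family {self.shape_family!r}")


@dataclass(frozen=True)
class DegradationSpec:
    """Controls of the synthetic segmentator-error model.

    ``score_noise_sd`` is additive clipped Gaussian noise in gray levels;
    ``boundary_jitter`` dilates/erodes each blob by a random amount up to
    the given number of pixels; ``drop_blob_prob`` removes whole blobs;
    ``false_blob_rate`` is the Poisson mean of spurious small blobs.
    """

    score_noise_sd: float = 0.0
    boundary_jitter: int = 0
    false_blob_rate: float = 0.0
    drop_blob_prob: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_blob_prob <= 1.0:
            raise MaskValidationError("drop_blob_prob must be in [0, 1]")
        if self.score_noise_sd < 0 or self.boundary_jitter < 0 or self.false_blob_rate < 0:
            raise MaskValidationError("degradation magnitudes must be nonnegative")


def _draw_shape(rng: np.random.Generator, spec: SyntheticSpec, center: tuple[float, float], radius: float) -> tuple[np.ndarray, np.ndarray]:
    if spec.shape_family == "ellipse":
        ecc = rng.uniform(0.6, 1.0)
        rot = rng.uniform(0.0, np.pi)
        return skdraw.ellipse(
            center[0], center[1], radius, radius * ecc, shape=(spec.height, spec.width), rotation=rot
        )
    # blobby polygon: radial perturbation of a circle, up to +-30 % of radius
    n_vert = int(rng.integers(7, 13))
    angles = np.sort(rng.uniform(0.0, 2 * np.pi, n_vert))
    radii = radius * rng.uniform(0.7, 1.3, n_vert)
    rows = center[0] + radii * np.sin(angles)
    cols = center[1] + radii * np.cos(angles)
    return skdraw.polygon(rows, cols, shape=(spec.height, spec.width))


def generate_ground_truth(spec: SyntheticSpec) -> BinaryMask:
    """Draw a binary mask whose 8-connected component count is ``n_blobs``.

    Blob centers are rejection-sampled so bounding circles stay
    ``min_separation`` apart and fully inside the frame.  Raises when the
    placement budget is exhausted (too many/too large blobs for the frame).
    """
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = spec.blob_radius_range
    sep = max(spec.min_separation, 2.0)  # 8-connectivity needs a >=2 px gap
    for _attempt in range(32):
        arr = np.zeros((spec.height, spec.width), dtype=np.uint8)
        placed: list[tuple[float, float, float]] = []
        budget = 2000
        while len(placed) < spec.n_blobs and budget > 0:
            budget -= 1
            radius = rng.uniform(lo, hi)
            # +-30 % polygon perturbation can exceed the nominal radius
            outer = radius * (1.3 if spec.shape_family == "blobby-polygon" else 1.0)
            r = rng.uniform(outer, spec.height - 1 - outer) if spec.height - 1 > 2 * outer else None
            c = rng.uniform(outer, spec.width - 1 - outer) if spec.width - 1 > 2 * outer else None
            if r is None or c is None:
                continue
            if any(
                np.hypot(r - pr, c - pc) < outer + po + sep for pr, pc, po in placed
            ):
                continue
            rows, cols = _draw_shape(rng, spec, (r, c), radius)
            if rows.size == 0:
                continue
            arr[rows, cols] = 1
            placed.append((r, c, outer))
        if len(placed) == spec.n_blobs:
            mask = BinaryMask(arr)
            if len(label_blobs(mask)) == spec.n_blobs:
                return mask
    raise MaskValidationError(
        "could not place blobs; reduce n_blobs, the radii, or min_separation"
    )


def _jitter_blob(blob_arr: np.ndarray, k: int) -> np.ndarray:
    if k > 0:
        return ndimage.binary_dilation(blob_arr, iterations=k)
    if k < 0:
        return ndimage.binary_erosion(blob_arr, iterations=-k, border_value=0)
    return blob_arr.astype(bool)


def degrade(gt: BinaryMask, spec: DegradationSpec) -> ScoreMask:
    """Derive an imperfect continuous score mask from a ground truth.

    Per blob: dilate or erode by a random amount up to ``boundary_jitter``
    and drop the blob with ``drop_blob_prob``.  Globally: add
    Poisson(``false_blob_rate``) spurious elliptical blobs (radius 3-8 px),
    render to {0, 255}, and add clipped Gaussian score noise.  With an
    all-zero spec the output binarizes back to ``gt`` exactly.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = gt.shape
    out = np.zeros((h, w), dtype=bool)
    for blob in label_blobs(gt):
        if spec.drop_blob_prob > 0 and rng.random() < spec.drop_blob_prob:
            continue
        blob_arr = blob.to_mask((h, w)).as_bool()
        if spec.boundary_jitter > 0:
            k = int(rng.integers(-spec.boundary_jitter, spec.boundary_jitter + 1))
            blob_arr = _jitter_blob(blob_arr, k)
        out |= blob_arr
    if spec.false_blob_rate > 0:
        for _ in range(int(rng.poisson(spec.false_blob_rate))):
            radius = rng.uniform(3.0, 8.0)
            r = rng.uniform(0, h - 1)
            c = rng.uniform(0, w - 1)
            rows, cols = skdraw.ellipse(r, c, radius, radius * rng.uniform(0.6, 1.0), shape=(h, w))
            out[rows, cols] = True
    scores = out.astype(np.float64) * 255.0
    if spec.score_noise_sd > 0:
        scores += rng.normal(0.0, spec.score_noise_sd, size=scores.shape)
    scores = np.clip(np.floor(scores + 0.5), 0, 255)
    return ScoreMask(scores.astype(np.uint8), Polarity.FOREGROUND_HIGH)


class MockPromptableBackend:
    """A deterministic stand-in for a point-promptable segmentator.

    The backend holds a reference ground truth.  When prompted it returns
    the union of ground-truth blobs containing at least one checkpoint,
    rendered to {0, 255}; checkpoints on background contribute nothing,
    mirroring how promptable segmentators expand a point into the object
    under it and ignore pointless prompts.  ``fidelity`` in [0, 1] scales
    additive Gaussian score noise with sd = 255 * (1 - fidelity): fidelity 1
    is a perfect oracle.  Identical calls return identical masks.
    """

    polarity = Polarity.FOREGROUND_HIGH

    def __init__(self, gt: BinaryMask, fidelity: float = 1.0, rng_seed: int = 0) -> None:
        if not 0.0 <= fidelity <= 1.0:
            raise MaskValidationError("fidelity must be in [0, 1]")
        self.gt = gt
        self.fidelity = float(fidelity)
        self.rng_seed = int(rng_seed)
        self._blobs = label_blobs(gt)

    def predict(self, image: Optional[np.ndarray], prompts: PromptSet) -> ScoreMask:
        """Return a score mask for the prompted objects; ``image`` is a
        pass-through payload and is ignored by the mock."""
        h, w = self.gt.shape
        selected = np.zeros((h, w), dtype=bool)
        gt_arr = self.gt.as_bool()
        hit_pts = [
            (cp.row, cp.col)
            for cp in prompts
            if 0 <= cp.row < h and 0 <= cp.col < w and gt_arr[cp.row, cp.col]
        ]
        if hit_pts:
            for blob in self._blobs:
                blob_arr = blob.to_mask((h, w)).as_bool()
                if any(blob_arr[r, c] for r, c in hit_pts):
                    selected |= blob_arr
        scores = selected.astype(np.float64) * 255.0
        sd = 255.0 * (1.0 - self.fidelity)
        if sd > 0:
            rng = np.random.default_rng(self.rng_seed)  # fresh per call: purity
            scores += rng.normal(0.0, sd, size=scores.shape)
        scores = np.clip(np.floor(scores + 0.5), 0, 255)
        return ScoreMask(scores.astype(np.uint8), self.polarity)


def mock_backend(gt: BinaryMask, fidelity: float = 1.0, rng_seed: int = 0) -> MockPromptableBackend:
    """Construct a :class:`MockPromptableBackend` (see class docs)."""
    return MockPromptableBackend(gt, fidelity=fidelity, rng_seed=rng_seed)


def write_fixture_tree(
    out_dir: Union[str, Path],
    n_images: int,
    syn_spec: SyntheticSpec = SyntheticSpec(),
    deg_spec: DegradationSpec = DegradationSpec(score_noise_sd=40.0, boundary_jitter=2),
    prompt_config: PromptConfig = PromptConfig(method="D", b=8),
    rng_seed: int = 0,
) -> Path:
    """Dump a directory tree of (ground truth, degraded source, prompts).

    Per image ``img_NNN``: ``gt_NNN.png``, ``src_NNN.png`` and
    ``prompts_NNN.json`` (prompts extracted from the binarized source), plus
    a ``manifest.csv`` consumable by the evaluation pipeline.  Returns the
    manifest path.
    """
    from .masks import binarize  # local import to avoid cycle noise

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        gt = generate_ground_truth(
            SyntheticSpec(**{**syn_spec.__dict__, "rng_seed": rng_seed + 2 * i})
        )
        src = degrade(gt, DegradationSpec(**{**deg_spec.__dict__, "rng_seed": rng_seed + 2 * i + 1}))
        gt_path = out_dir / f"gt_{i:03d}.png"
        src_path = out_dir / f"src_{i:03d}.png"
        write_mask(gt, gt_path)
        write_mask(src, src_path)
        prompts = extract_prompts(binarize(src, 128), prompt_config)
        prompts.save(out_dir / f"prompts_{i:03d}.json")
        rows.append(f"img_{i:03d},{src_path.name},{gt_path.name}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("image_id,source_mask,ground_truth\n" + "\n".join(rows) + "\n")
    return manifest
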