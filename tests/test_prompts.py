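"""Checkpoint generation: methods A-D, border mode, fallback, determinism."""

import numpy as np
import pytest

from promptfuse import (
    BinaryMask,
    MaskValidationError,
    PromptConfig,
    extract_prompts,
    label_blobs,
    load_prompts,
    method_a,
    method_b,
    method_c,
    method_d,
)

from oracles import method_d_reference


def _mask(arr):
    return BinaryMask(np.asarray(arr, dtype=np.uint8))


def _single_blob(arr):
    (blob,) = label_blobs(_mask(arr))
    return blob


class TestMethodA:
    def test_symmetric_square_center(self):
        arr = np.zeros((5, 5), dtype=np.uint8)
        arr[0:3, 0:3] = 1
        cp = method_a(_single_blob(arr))
        assert (cp.row, cp.col) == (1, 1)

    def test_ring_center_may_leave_blob(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[0:10, 0:10] = 1
        arr[2:8, 2:8] = 0  # hollow center
        blob = _single_blob(arr)
        cp = method_a(blob)
        assert (cp.row, cp.col) == (5, 5)  # bbox midpoint, rounded half-away
        assert not blob.contains(cp.row, cp.col)

    def test_single_pixel(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[7, 3] = 1
        cp = method_a(_single_blob(arr))
        assert (cp.row, cp.col) == (7, 3)


class TestMethodB:
    def test_plus_shape_centroid(self):
        arr = np.zeros((3, 3), dtype=np.uint8)
        arr[0, 1] = arr[1, 0] = arr[1, 1] = arr[1, 2] = arr[2, 1] = 1
        cp = method_b(_single_blob(arr))
        assert (cp.row, cp.col) == (1, 1)

    def test_ring_snaps_to_nearest_blob_pixel(self):
        arr = np.zeros((11, 11), dtype=np.uint8)
        arr[0:11, 0:11] = 1
        arr[2:9, 2:9] = 0
        blob = _single_blob(arr)
        cp = method_b(blob)
        assert blob.contains(cp.row, cp.col)
        cr, cc = blob.centroid
        d_cp = (cp.row - cr) ** 2 + (cp.col - cc) ** 2
        dists = (blob.pixels[:, 0] - cr) ** 2 + (blob.pixels[:, 1] - cc) ** 2
        assert d_cp == pytest.approx(float(dists.min()))

    def test_always_inside_blob_on_random_masks(self, rng):
        for _ in range(20):
            arr = (rng.random((20, 20)) < 0.3).astype(np.uint8)
            for blob in label_blobs(BinaryMask(arr)):
                cp = method_b(blob)
                assert blob.contains(cp.row, cp.col)


class TestMethodC:
    def test_single_pixel_support(self):
        arr = np.zeros((10, 10), dtype=np.uint8)
        arr[7, 3] = 1
        for seed in (0, 1, 99):
            cp = method_c(_single_blob(arr), seed)
            assert (cp.row, cp.col) == (7, 3)

    def test_checkpoint_always_in_blob_and_deterministic(self, rng):
        arr = (rng.random((15, 15)) < 0.4).astype(np.uint8)
        for blob in label_blobs(BinaryMask(arr)):
            a, b = method_c(blob, 42), method_c(blob, 42)
            assert (a.row, a.col) == (b.row, b.col)
            assert blob.contains(a.row, a.col)

    def test_uniformity_on_two_pixel_blob(self):
        arr = np.zeros((4, 4), dtype=np.uint8)
        arr[1, 1] = arr[1, 2] = 1
        blob = _single_blob(arr)
        hits = sum(method_c(blob, seed).col == 1 for seed in range(10_000))
        # binomial(10^4, 0.5): 5 sigma = 250
        assert abs(hits - 5000) < 250


class TestMethodD:
    def test_filled_rectangle_b50(self):
        cps = method_d(BinaryMask(np.ones((100, 100), dtype=np.uint8)), PromptConfig(b=50))
        assert [(c.row, c.col) for c in cps] == [(0, 0), (0, 50), (50, 0), (50, 50)]

    def test_fallback_finds_single_pixel(self):
        arr = np.zeros((100, 100), dtype=np.uint8)
        arr[7, 7] = 1
        cps = method_d(BinaryMask(arr), PromptConfig(b=50))
        assert [(c.row, c.col) for c in cps] == [(7, 7)]

    def test_b1_emits_every_foreground_pixel(self, rng):
        arr = (rng.random((12, 12)) < 0.4).astype(np.uint8)
        cps = method_d(BinaryMask(arr), PromptConfig(b=1))
        assert sorted((c.row, c.col) for c in cps) == sorted(
            map(tuple, np.argwhere(arr))
        )

    @pytest.mark.parametrize("b", [1, 2, 3, 5, 7])
    def test_matches_exhaustive_oracle(self, b, rng):
        for _ in range(15):
            arr = (rng.random((40, 40)) < 0.2).astype(np.uint8)
            cps = method_d(BinaryMask(arr), PromptConfig(b=b))
            assert sorted((c.row, c.col) for c in cps) == method_d_reference(arr, b)

    def test_every_blob_contributes(self, rng):
        for _ in range(10):
            arr = (rng.random((40, 40)) < 0.1).astype(np.uint8)
            cps = method_d(BinaryMask(arr), PromptConfig(b=6))
            covered = {c.blob_id for c in cps}
            assert covered == set(range(len(label_blobs(BinaryMask(arr)))))


class TestBorderMode:
    def test_checkpoints_avoid_boundary_when_erosion_survives(self):
        arr = np.zeros((40, 40), dtype=np.uint8)
        arr[5:35, 5:35] = 1
        cps = method_d(BinaryMask(arr), PromptConfig(b=4, border_mode=True))
        assert cps
        interior = {tuple(p) for p in np.argwhere(arr)}
        boundary = {
            (r, c)
            for (r, c) in interior
            if any(
                (r + dr, c + dc) not in interior
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
            )
        }
        for cp in cps:
            assert (cp.row, cp.col) in interior and (cp.row, cp.col) not in boundary

    def test_small_blob_rescued_when_erosion_erases_it(self):
        arr = np.zeros((40, 40), dtype=np.uint8)
        arr[10:13, 10:13] = 1  # 3x3: vanishes under the 10x10 kernel
        cps = method_d(BinaryMask(arr), PromptConfig(b=4, border_mode=True))
        assert len(cps) >= 1
        assert all(arr[c.row, c.col] for c in cps)

    def test_rescue_can_be_disabled(self):
        arr = np.zeros((40, 40), dtype=np.uint8)
        arr[10:13, 10:13] = 1
        cps = method_d(
            BinaryMask(arr),
            PromptConfig(b=4, border_mode=True, rescue_on_empty_erosion=False),
        )
        assert cps == []


class TestExtractPrompts:
    def test_empty_mask_any_method(self):
        empty = BinaryMask(np.zeros((8, 8), dtype=np.uint8))
        for method in "ABCD":
            assert len(extract_prompts(empty, PromptConfig(method=method, b=3))) == 0

    def test_one_checkpoint_per_blob_for_abc(self, rng):
        arr = np.zeros((30, 30), dtype=np.uint8)
        arr[1:4, 1:4] = arr[10:14, 10:14] = arr[20:25, 20:26] = 1
        for method in "ABC":
            ps = extract_prompts(BinaryMask(arr), PromptConfig(method=method))
            assert len(ps) == 3
            assert sorted(c.blob_id for c in ps) == [0, 1, 2]

    def test_unknown_method_rejected(self):
        with pytest.raises(MaskValidationError):
            PromptConfig(method="E")

    def test_serialization_round_trip_and_determinism(self, tmp_path, rng):
        arr = (rng.random((30, 30)) < 0.3).astype(np.uint8)
        config = PromptConfig(method="D", b=5, rng_seed=7)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        extract_prompts(BinaryMask(arr), config).save(p1)
        extract_prompts(BinaryMask(arr), config).save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        loaded = load_prompts(p1)
        assert loaded.checkpoints == extract_prompts(BinaryMask(arr), config).checkpoints
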