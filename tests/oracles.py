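"""Independent brute-force reference implementations used by the tests.

Everything here is written from the definitions, with naive mechanisms
(flood fill, pixel scans, distance matrices, explicit shift-and-add
convolution) deliberately different from the library's vectorized /
scipy-backed code paths.
"""

from __future__ import annotations

import math

import numpy as np

GAUSS_KSIZE = 7
GAUSS_SIGMA = 5.0


# ---------------------------------------------------------------- blobs


def flood_fill_components(arr: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit stack-based flood fill."""
    h, w = arr.shape
    seen = np.zeros_like(arr, dtype=bool)
    comps = []
    for r0 in range(h):
        for c0 in range(w):
            if arr[r0, c0] and not seen[r0, c0]:
                comp = set()
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and arr[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def erode_scan(arr: np.ndarray, kernel: np.ndarray, anchor: tuple[int, int]) -> np.ndarray:
    """Erosion as a literal 'does the kernel fit here' scan (zero-padded)."""
    h, w = arr.shape
    kh, kw = kernel.shape
    padded = np.zeros((h + kh, w + kw), dtype=bool)
    padded[anchor[0] : anchor[0] + h, anchor[1] : anchor[1] + w] = arr.astype(bool)
    out = np.zeros((h, w), dtype=np.uint8)
    kmask = kernel.astype(bool)
    for r in range(h):
        for c in range(w):
            if padded[r : r + kh, c : c + kw][kmask].all():
                out[r, c] = 1
    return out


# -------------------------------------------------------------- prompts


def method_d_reference(arr: np.ndarray, b: int) -> list[tuple[int, int]]:
    """Exhaustive lattice-and-offset enumeration of method D (no erosion)."""
    h, w = arr.shape
    out: list[tuple[int, int]] = []
    for comp in flood_fill_components(arr):
        pts = [(r, c) for (r, c) in comp if r % b == 0 and c % b == 0]
        if not pts:
            offsets = [(0, dx) for dx in range(1, b)] + [
                (dy, dx) for dy in range(1, b) for dx in range(0, b)
            ]
            for dy, dx in offsets:
                pts = [(r, c) for (r, c) in comp if (r - dy) % b == 0 and (c - dx) % b == 0]
                if pts:
                    break
        out.extend(pts)
    return sorted(out)


# --------------------------------------------------------------- fusion


def fuse_reference(a: np.ndarray, b: np.ndarray, w1: float, w2: float) -> np.ndarray:
    """Per-pixel scalar evaluation of the weighted-average rule."""
    h, w = a.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            v = (w1 * float(a[r, c]) + w2 * float(b[r, c])) / (w1 + w2)
            out[r, c] = int(math.floor(v + 0.5))
    return out


# -------------------------------------------------------------- metrics


def iou_sets(p: np.ndarray, t: np.ndarray) -> float:
    P = {(r, c) for r, c in zip(*np.nonzero(p))}
    T = {(r, c) for r, c in zip(*np.nonzero(t))}
    if not P and not T:
        return 1.0
    return len(P & T) / len(P | T)


def dice_sets(p: np.ndarray, t: np.ndarray) -> float:
    P = {(r, c) for r, c in zip(*np.nonzero(p))}
    T = {(r, c) for r, c in zip(*np.nonzero(t))}
    if not P and not T:
        return 1.0
    return 2 * len(P & T) / (len(P) + len(T))


def mae_pixels(p: np.ndarray, t: np.ndarray) -> float:
    h, w = p.shape
    return sum(
        abs(int(p[r, c]) - int(t[r, c])) for r in range(h) for c in range(w)
    ) / (h * w)


def _gauss_kernel() -> np.ndarray:
    half = (GAUSS_KSIZE - 1) / 2.0
    k = np.array(
        [
            [
                math.exp(-((i - half) ** 2 + (j - half) ** 2) / (2 * GAUSS_SIGMA**2))
                for j in range(GAUSS_KSIZE)
            ]
            for i in range(GAUSS_KSIZE)
        ]
    )
    return k / k.sum()


def _conv_zero_padded(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlation via explicit shift-and-add over the kernel support."""
    kh, kw = kernel.shape
    oh, ow = (kh - 1) // 2, (kw - 1) // 2
    padded = np.zeros((img.shape[0] + kh - 1, img.shape[1] + kw - 1))
    padded[oh : oh + img.shape[0], ow : ow + img.shape[1]] = img
    out = np.zeros_like(img, dtype=float)
    for ki in range(kh):
        for kj in range(kw):
            out += kernel[ki, kj] * padded[ki : ki + img.shape[0], kj : kj + img.shape[1]]
    return out


def wfm_reference(p: np.ndarray, t: np.ndarray) -> float:
    """Weighted F-measure from the definition, using a full distance matrix
    for the nearest-foreground map (mean over all tied nearest pixels)."""
    pf, tf = p.astype(float), t.astype(bool)
    if not tf.any():
        return 1.0 if not pf.any() else 0.0
    E = np.abs(pf - tf.astype(float))
    fg = np.argwhere(tf)  # row-major
    Et = E.copy()
    dist = np.zeros_like(E)
    for r, c in np.argwhere(~tf):
        d2 = (fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2
        d2min = d2.min()  # exact: integer distances squared
        tied = fg[d2 == d2min]
        Et[r, c] = E[tied[:, 0], tied[:, 1]].mean()
        dist[r, c] = math.sqrt(float(d2min))
    EA = _conv_zero_padded(Et, _gauss_kernel())
    min_e_ea = E.copy()
    sel = tf & (EA < E)
    min_e_ea[sel] = EA[sel]
    B = np.where(tf, 1.0, 2.0 - np.exp(math.log(0.5) / 5.0 * dist))
    Ew = min_e_ea * B
    n_fg = tf.sum()
    TPw = n_fg - Ew[tf].sum()
    FPw = Ew[~tf].sum()
    R = 1.0 - Ew[tf].mean()
    Pw = TPw / (TPw + FPw) if TPw + FPw > 0 else 0.0
    if R + Pw <= 0:
        return 0.0
    return min(max(2.0 * R * Pw / (R + Pw), 0.0), 1.0)


def emeasure_reference(p: np.ndarray, t: np.ndarray) -> float:
    """Enhanced-alignment measure evaluated pixel by pixel."""
    h, w = t.shape
    pf, tf = p.astype(float), t.astype(float)
    n_fg = tf.sum()
    if n_fg == 0:
        vals = [1.0 - pf[r, c] for r in range(h) for c in range(w)]
    elif n_fg == h * w:
        vals = [pf[r, c] for r in range(h) for c in range(w)]
    else:
        mp, mt = pf.mean(), tf.mean()
        vals = []
        for r in range(h):
            for c in range(w):
                dp, dt = pf[r, c] - mp, tf[r, c] - mt
                align = 2.0 * dp * dt / (dp * dp + dt * dt)
                vals.append((align + 1.0) ** 2 / 4.0)
    return min(max(sum(vals) / (h * w), 0.0), 1.0)
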