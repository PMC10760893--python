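"""Gray-level co-occurrence features of the quantized heatmap.

For each of four pixel offsets (distance 1 at 0, 45, 90 and 135 degrees) the
co-occurrence matrix counts ordered pairs ``(g1, g2)`` of gray levels at a
pixel and its offset neighbour.  Counts are raw — unnormalized and
asymmetric.  The four 100 x 100 matrices are stacked and flattened into the
40000-dimensional global feature vector.

Offset convention, frozen here: ``(a, b) = (dx, dy)`` with y increasing
downward; 0 deg -> (1, 0), 45 deg -> (1, -1), 90 deg -> (0, 1),
135 deg -> (-1, -1).  Any fixed convention yields equivalent features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heatmap import Heatmap, QuantizedHeatmap, quantize_heatmap

ANGLE_OFFSETS: tuple = (
    ("0", (1, 0)),
    ("45", (1, -1)),
    ("90", (0, 1)),
    ("135", (-1, -1)),
)


@dataclass(frozen=True)
class GlcmConfig:
    distance: int = 1
    offsets: tuple = ANGLE_OFFSETS
    gray_levels: int = 100

    def __post_init__(self):
        if self.gray_levels < 2:
            raise ValueError("need at least 2 gray levels")
        for _, (a, b) in self.offsets:
            if a == 0 and b == 0:
                raise ValueError("offsets must be nonzero")


@dataclass
class GlcmFeature:
    """Stacked per-angle co-occurrence counts and their flattened vector."""

    stack: np.ndarray  # (g, g, n_angles)
    flat: np.ndarray   # (g * g * n_angles,), fixed angle order


def glcm(q: QuantizedHeatmap | np.ndarray, offset: tuple[int, int], g: int = 100) -> np.ndarray:
    """Raw co-occurrence counts of gray pairs at one ``(dx, dy)`` offset.

    For every pixel whose offset neighbour is in bounds, the count at
    ``[level(pixel), level(neighbour)]`` is incremented.
    """
    lv = q.levels if isinstance(q, QuantizedHeatmap) else np.asarray(q)
    if lv.min() < 0 or lv.max() >= g:
        raise ValueError(f"gray levels must lie in [0, {g})")
    a, b = offset  # dx, dy
    H, W = lv.shape
    ys = slice(max(0, -b), min(H, H - b))
    xs = slice(max(0, -a), min(W, W - a))
    g1 = lv[ys, xs]
    g2 = lv[ys.start + b : ys.stop + b, xs.start + a : xs.stop + a]
    pairs = g1.ravel() * g + g2.ravel()
    return np.bincount(pairs, minlength=g * g).reshape(g, g)


def glcm_stack(h: Heatmap | np.ndarray, cfg: GlcmConfig = GlcmConfig()) -> GlcmFeature:
    """Quantize a heatmap and compute one GLCM per angle in fixed order."""
    q = quantize_heatmap(h, cfg.gray_levels)
    g = cfg.gray_levels
    mats = [glcm(q, off, g) for _, off in cfg.offsets]
    stack = np.stack(mats, axis=-1)
    return GlcmFeature(stack=stack, flat=stack.reshape(-1, order="C").astype(float))


def feature_table(heatmaps, labels=None, cfg: GlcmConfig = GlcmConfig()):
    """Row-per-heatmap feature matrix (n, g*g*n_angles) plus optional labels."""
    X = np.stack([glcm_stack(h, cfg).flat for h in heatmaps])
    if labels is None:
        return X
    return X, np.asarray(labels, dtype=int)
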