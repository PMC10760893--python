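"""Sliding-window geometry over the inscribed circle of a CT slice.

The useful content of an axial CT slice lies inside the circle tangent to the
square frame, so window centers are generated only where the full window fits
inside the image and the center lies within that circle.  Row ordinates are
``img_size/2 + i*stride``; within a row at height offset ``h`` from the image
center, the admissible half-width is ``w = floor(sqrt((ct/2)^2 - h^2))`` and
abscissas run ``ct/2 +- j*stride`` for ``j <= (w - img_size/2)/stride``.

Coordinates are 0-based ``(row=y, col=x)`` with y increasing downward;
windows are half-open ``[c - size/2, c + size/2)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridConfig:
    """Sliding-window grid: image side, window side and stride, in pixels."""

    ct_size: int = 512
    img_size: int = 32
    stride: int = 4

    def __post_init__(self):
        if self.img_size > self.ct_size:
            raise ValueError("img_size must not exceed ct_size")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.img_size % 2 != 0:
            raise ValueError("img_size must be even")

    @property
    def lattice_len(self) -> int:
        """Cells per axis of the full stride lattice: floor((ct-img)/s) + 1."""
        return (self.ct_size - self.img_size) // self.stride + 1


def row_centers(cfg: GridConfig) -> list[int]:
    """Ordinates of all window rows: img_size/2 + i*stride, windows in-bounds."""
    half = cfg.img_size // 2
    i_max = (cfg.ct_size - cfg.img_size) // cfg.stride
    return [half + i * cfg.stride for i in range(i_max + 1)]


def col_centers(cfg: GridConfig, y: int) -> list[int]:
    """Abscissas admissible in the row at ordinate ``y``.

    Mirrored around the vertical midline: x = ct/2 - j*s is included along
    with x = ct/2 + j*s, deduplicated at j = 0.  Empty when the chord
    half-width is below half a window.
    """
    if y not in set(row_centers(cfg)):
        raise ValueError(f"y={y} is not a row-center ordinate for {cfg}")
    half = cfg.img_size // 2
    c = cfg.ct_size // 2
    h = abs(y - c)
    sq = (cfg.ct_size / 2) ** 2 - h**2
    if sq < 0:
        return []
    w = math.floor(math.sqrt(sq))
    if w < half:
        return []
    j_max = (w - half) // cfg.stride
    xs = {c + j * cfg.stride for j in range(j_max + 1)}
    xs |= {c - j * cfg.stride for j in range(j_max + 1)}
    return sorted(xs)


@dataclass(frozen=True)
class WindowGrid:
    """All circle-constrained window centers of a grid config, row-major."""

    cfg: GridConfig
    centers: tuple  # of (y, x) pairs

    def __len__(self) -> int:
        return len(self.centers)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.centers, dtype=int).reshape(-1, 2)


def window_grid(cfg: GridConfig) -> WindowGrid:
    """Enumerate every admissible window center in row-major order."""
    centers = []
    for y in row_centers(cfg):
        for x in col_centers(cfg, y):
            centers.append((y, x))
    return WindowGrid(cfg=cfg, centers=tuple(centers))


def crop_patch(pixels: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """Copy the half-open ``size x size`` window centered at ``(y, x)``."""
    arr = np.asarray(pixels)
    y, x = center
    half = size // 2
    y0, x0 = y - half, x - half
    if y0 < 0 or x0 < 0 or y0 + size > arr.shape[0] or x0 + size > arr.shape[1]:
        raise ValueError(f"window at {center} size {size} exceeds image bounds {arr.shape}")
    return arr[y0 : y0 + size, x0 : x0 + size].copy()


def crop_patches(pixels: np.ndarray, centers, size: int) -> np.ndarray:
    """Stack of patches for many centers (order preserved)."""
    return np.stack([crop_patch(pixels, c, size) for c in centers])


@dataclass(frozen=True)
class AugConfig:
    """Patch-augmentation scheme around tamper centers.

    Positives: every integer shift within Chebyshev distance ``pos_halfwidth``
    of the tamper center (default 2, i.e. the 5x5 grid of 25 centers).
    Negatives: the 2x5 lattice of near offsets ``neg_near_rect`` (default
    (-2,-2)..(-1,2), 10 centers) plus ``neg_random_count`` distinct centers
    sampled from the window grid.
    """

    pos_halfwidth: int = 2
    neg_near_rect: tuple = ((-2, -2), (-1, 2))
    neg_random_count: int = 20
    neg_per_pos: int = 10
    seed: int = 0

    def __post_init__(self):
        (y0, x0), (y1, x1) = self.neg_near_rect
        if y1 < y0 or x1 < x0:
            raise ValueError("neg_near_rect must be well-ordered")
        if self.pos_halfwidth < 0 or self.neg_random_count < 0 or self.neg_per_pos < 0:
            raise ValueError("augmentation counts must be non-negative")


def _fits(center, cfg: GridConfig) -> bool:
    y, x = center
    half = cfg.img_size // 2
    return half <= y <= cfg.ct_size - half and half <= x <= cfg.ct_size - half


def positive_aug_centers(tamper_center, aug: AugConfig, cfg: GridConfig | None = None):
    """All shifts of the tamper center within the positive Chebyshev radius."""
    y, x = tamper_center
    r = aug.pos_halfwidth
    centers = [(y + dy, x + dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
    if cfg is not None:
        kept = [c for c in centers if _fits(c, cfg)]
        if len(kept) < len(centers):
            log.warning("dropped %d positive centers whose window exits the image", len(centers) - len(kept))
        centers = kept
    return centers


def negative_aug_centers(ref_center, grid: WindowGrid, aug: AugConfig):
    """Near-offset negatives around a reference center plus random grid centers.

    Deterministic for a fixed ``aug.seed``; random centers are drawn from the
    window grid without replacement.
    """
    if len(grid) == 0:
        raise ValueError("window grid is empty")
    if aug.neg_random_count > len(grid):
        raise ValueError("neg_random_count exceeds grid size")
    y, x = ref_center
    (dy0, dx0), (dy1, dx1) = aug.neg_near_rect
    near = [(y + dy, x + dx) for dy in range(dy0, dy1 + 1) for dx in range(dx0, dx1 + 1)]
    kept = [c for c in near if _fits(c, grid.cfg)]
    if len(kept) < len(near):
        log.warning("dropped %d near-negative centers whose window exits the image", len(near) - len(kept))
    rng = np.random.default_rng(aug.seed)
    idx = rng.choice(len(grid), size=aug.neg_random_count, replace=False)
    return kept + [grid.centers[i] for i in idx]
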