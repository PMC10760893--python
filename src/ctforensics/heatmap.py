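"""Assemble per-window tamper probabilities into a slice heatmap.

The heatmap lives on the stride lattice: one cell per window position, so it
is smaller than the slice by a factor of the stride.  Lattice cells whose
window was never evaluated (outside the inscribed circle) default to tamper
probability 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .imageio import NormalizedSlice
from .windows import GridConfig, crop_patches, window_grid


@dataclass
class Heatmap:
    """Tamper probabilities on the full rectangular stride lattice."""

    values: np.ndarray  # (L, L) floats in [0, 1]
    mask: np.ndarray    # True where a window was actually evaluated
    cfg: GridConfig
    source_id: str = ""

    def __post_init__(self):
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError("unevaluated lattice cells must be exactly 0")


@dataclass
class QuantizedHeatmap:
    """Integer gray levels in [0, g_max] obtained by rounding levels * p."""

    levels: np.ndarray
    g_max: int


def _lattice_index(coord: int, cfg: GridConfig) -> int:
    off = coord - cfg.img_size // 2
    idx, rem = divmod(off, cfg.stride)
    if rem != 0:
        raise ValueError(
            "window center does not sit on the stride lattice; "
            "(ct_size - img_size)/2 must be a multiple of the stride"
        )
    return idx


def detect_slice(model, slc: NormalizedSlice, cfg: GridConfig) -> Heatmap:
    """Score every circle-constrained window of a slice with the detector.

    ``model`` is anything exposing ``predict(patches) -> probabilities``.
    """
    if slc.pixels.shape != (cfg.ct_size, cfg.ct_size):
        raise ValueError(
            f"slice shape {slc.pixels.shape} does not match grid ct_size {cfg.ct_size}"
        )
    grid = window_grid(cfg)
    L = cfg.lattice_len
    values = np.zeros((L, L))
    mask = np.zeros((L, L), dtype=bool)
    if len(grid):
        patches = crop_patches(slc.pixels, grid.centers, cfg.img_size)
        probs = np.asarray(model.predict(patches), dtype=float)
        for (y, x), p in zip(grid.centers, probs):
            values[_lattice_index(y, cfg), _lattice_index(x, cfg)] = p
            mask[_lattice_index(y, cfg), _lattice_index(x, cfg)] = True
    return Heatmap(values=values, mask=mask, cfg=cfg, source_id=slc.source_id)


def quantize_heatmap(h: Heatmap | np.ndarray, levels: int = 100) -> QuantizedHeatmap:
    """Round probabilities to gray levels: g = min(round_half_up(levels*p), levels-1).

    Rounding is half-up (0.5 rounds to 1) for cross-platform stability; the
    top probability 1.0 is clipped into the highest level rather than opening
    an extra level.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    p = h.values if isinstance(h, Heatmap) else np.asarray(h)
    g = np.floor(levels * p + 0.5).astype(int)
    g = np.minimum(g, levels - 1)
    return QuantizedHeatmap(levels=g, g_max=levels - 1)


# ---- persistence and visualization ------------------------------------------

def save_heatmap(h: Heatmap, path) -> Path:
    """Raw array + JSON sidecar (grid config, slice id)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), h.values)
    sidecar = {
        "source_id": h.source_id,
        "grid": {"ct_size": h.cfg.ct_size, "img_size": h.cfg.img_size, "stride": h.cfg.stride},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    np.save(path.with_suffix(".mask.npy"), h.mask)
    return path.with_suffix(".npy")


def load_heatmap(path) -> Heatmap:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    mask = np.load(path.with_suffix(".mask.npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = GridConfig(**meta["grid"])
    return Heatmap(values=values, mask=mask, cfg=cfg, source_id=meta.get("source_id", ""))


def overlay_png(h: Heatmap, slc: NormalizedSlice, path) -> Path:
    """Nearest-neighbor upsampled red overlay of the heatmap on the slice."""
    from PIL import Image

    size = h.cfg.ct_size
    scale = max(1, size // h.values.shape[0])
    up = np.kron(h.values, np.ones((scale, scale)))[:size, :size]
    canvas = np.zeros((size, size))
    canvas[: up.shape[0], : up.shape[1]] = up
    gray = (slc.pixels * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1).astype(float)
    rgb[..., 0] = np.minimum(255, rgb[..., 0] + 255 * canvas)
    Image.fromarray(rgb.astype(np.uint8)).save(path)
    return Path(path)
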