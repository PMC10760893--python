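"""Synthetic chest-CT phantoms with planted small-region forgeries.

Real CT training data for the cascade is not redistributable, so this module
generates phantom slices with the statistical structure the detector relies
on: a mid-intensity body ellipse over a dark background, two low-intensity
lung fields, spatially correlated noise texture and bright vessel-like
blobs, with intensities in the stored-value range [0, 4095].

The forgery operator emulates the two artifacts that generative in-painting
leaves in a small region — over-smoothness and a deficit of high-frequency
spectral energy — by replacing the texture inside a square box (at most
32 x 32 pixels) with its smoothed version plus re-sampled low-pass noise.
It does not re-implement any generative attack; outside the box the image
is bit-identical to its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imageio import NormalizedSlice, ScanVolume, SliceImage
from .windows import AugConfig, WindowGrid, crop_patch, negative_aug_centers, positive_aug_centers

log = logging.getLogger(__name__)

INTENSITY_MAX = 4095.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and texture of the synthetic chest phantom.

    Fractions are relative to the image side.  Intensities are stored units
    in [0, 4095]: dark exterior, mid-intensity body ring, low-intensity lung
    fields.
    """

    size: int = 512
    body_axes: tuple = (0.46, 0.40)
    body_intensity: float = 1150.0
    lung_centers: tuple = ((0.50, 0.31), (0.50, 0.69))
    lung_axes: tuple = (0.24, 0.13)  # (y, x) semi-axes as fraction of the side
    lung_intensity: float = 220.0
    background_intensity: float = 30.0
    noise_std: float = 60.0
    noise_corr_px: float = 1.5
    n_blobs: int = 8
    blob_amp: tuple = (250.0, 900.0)
    blob_sigma: tuple = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.size < 64:
            raise ValueError("phantom size must be at least 64 (4x the largest tamper box)")


@dataclass(frozen=True)
class ForgeryConfig:
    """Small-region forgery stand-in: box size, smoothing and spectral deficit."""

    box_min: int = 16
    box_max: int = 32
    smoothing_sigma: float = 1.5
    noise_corr_px: float = 2.0  # smoother than native texture: spectral deficit
    noise_gain: float = 0.5
    lung_threshold: float = 600.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.box_min <= self.box_max <= 32):
            raise ValueError("tamper box sides must satisfy 1 <= min <= max <= 32")


@dataclass(frozen=True)
class TamperRecord:
    """Ground truth for one planted forgery."""

    center: tuple        # (y, x) box center
    box_size: int
    slice_span: tuple | None = None  # (first, last) inclusive slice indices
    label: int = 1


def _ellipse_mask(size: int, center_frac, axes_frac) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = center_frac[0] * size, center_frac[1] * size
    ay, ax = axes_frac[0] * size, axes_frac[1] * size
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def lung_mask(cfg: PhantomConfig) -> np.ndarray:
    m = np.zeros((cfg.size, cfg.size), dtype=bool)
    for c in cfg.lung_centers:
        m |= _ellipse_mask(cfg.size, c, cfg.lung_axes)
    return m


def sample_blobs(cfg: PhantomConfig, rng: np.random.Generator) -> list[tuple]:
    """Bright vessel/nodule-like bumps: (y, x, amplitude, sigma) inside the lungs."""
    lungs = lung_mask(cfg)
    ys, xs = np.nonzero(lungs)
    blobs = []
    for _ in range(cfg.n_blobs):
        i = rng.integers(len(ys))
        blobs.append((int(ys[i]), int(xs[i]),
                      float(rng.uniform(*cfg.blob_amp)), float(rng.uniform(*cfg.blob_sigma))))
    return blobs


def make_phantom_slice(cfg: PhantomConfig, seed: int | None = None,
                       blobs: list[tuple] | None = None) -> SliceImage:
    """One phantom slice, a pure function of (config, seed[, fixed blobs]).

    ``blobs`` lets a scan share one anatomy across slices; by default they
    are sampled from the slice's own seed.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    size = cfg.size
    img = np.full((size, size), cfg.background_intensity)
    body = _ellipse_mask(size, (0.5, 0.5), cfg.body_axes)
    img[body] = cfg.body_intensity
    lungs = lung_mask(cfg)
    img[lungs] = cfg.lung_intensity

    noise = rng.normal(size=(size, size))
    noise = ndimage.gaussian_filter(noise, cfg.noise_corr_px)
    noise *= cfg.noise_std / max(noise.std(), 1e-12)
    img = img + noise

    if blobs is None:
        blobs = sample_blobs(cfg, rng)
    yy, xx = np.mgrid[0:size, 0:size]
    for by, bx, amp, sig in blobs:
        img += amp * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sig**2)))

    img = np.clip(img, 0.0, INTENSITY_MAX)
    return SliceImage(img, source_id=f"phantom-{cfg.size}-{cfg.seed if seed is None else seed}")


def _placement_mask(pixels: np.ndarray, box: int, threshold: float) -> np.ndarray:
    """Centers where a box x box window fits entirely in a low-intensity lung field."""
    low = pixels < threshold
    # remove the dark exterior: keep low regions not connected to the border
    labeled, _ = ndimage.label(low)
    border_labels = np.unique(np.concatenate([
        labeled[0], labeled[-1], labeled[:, 0], labeled[:, -1]]))
    interior_low = low & ~np.isin(labeled, border_labels[border_labels > 0])
    half = box // 2
    eroded = ndimage.binary_erosion(interior_low, structure=np.ones((box, box)))
    ok = np.zeros_like(eroded)
    ok[half:-half or None, half:-half or None] = eroded[half:-half or None, half:-half or None]
    return ok


def apply_forgery(
    slc: SliceImage,
    f: ForgeryConfig,
    seed: int | None = None,
    center: tuple | None = None,
    box: int | None = None,
    noise_field: np.ndarray | None = None,
) -> tuple[SliceImage, TamperRecord]:
    """Plant one smoothed, spectrally attenuated square region inside a lung field.

    Outside the box the output is bit-identical to the input.
    """
    rng = np.random.default_rng(f.seed if seed is None else seed)
    if box is None:
        box = int(rng.integers(f.box_min, f.box_max + 1))
    pixels = slc.pixels.astype(float).copy()
    if center is None:
        ok = _placement_mask(pixels, box, f.lung_threshold)
        ys, xs = np.nonzero(ok)
        if len(ys) == 0:
            raise ValueError("no valid lung-field placement for the tamper box")
        i = rng.integers(len(ys))
        center = (int(ys[i]), int(xs[i]))
    y, x = center
    half = box // 2
    y0, x0 = y - half, x - half
    if y0 < 0 or x0 < 0 or y0 + box > pixels.shape[0] or x0 + box > pixels.shape[1]:
        raise ValueError("tamper box must lie fully inside the image")
    region = pixels[y0 : y0 + box, x0 : x0 + box]
    smooth = ndimage.gaussian_filter(region, f.smoothing_sigma)
    resid_std = (region - smooth).std()
    if noise_field is None:
        noise = ndimage.gaussian_filter(rng.normal(size=region.shape), f.noise_corr_px)
    else:
        noise = np.array(noise_field, dtype=float)
    noise -= noise.mean()
    noise *= f.noise_gain * resid_std / max(noise.std(), 1e-12)
    forged = np.clip(smooth + noise, 0.0, INTENSITY_MAX)
    pixels[y0 : y0 + box, x0 : x0 + box] = forged
    out = SliceImage(pixels, spacing_mm=slc.spacing_mm, z_position=slc.z_position,
                     source_id=slc.source_id + "+forged")
    return out, TamperRecord(center=(y, x), box_size=box)


def make_scan(
    cfg: PhantomConfig,
    f: ForgeryConfig | None,
    n_slices: int,
    tamper_span: int = 10,
    ann_span: int | None = None,
    seed: int = 0,
) -> tuple[ScanVolume, list[TamperRecord]]:
    """A z-stack of phantoms, optionally with one forgery spanning consecutive slices.

    Anatomy varies smoothly with z (lung fields shrink towards the stack
    ends); for tampered scans the forgery is applied at a fixed (y, x) on
    ``tamper_span`` consecutive slices around the stack center.  The
    annotated region is the ``ann_span`` consecutive slices centered in the
    tampered span (default: the whole span): a 3-D in-painting attack
    involves many more slices than the window a region-level evaluation
    marks around the central slice, so the annotated slices are a subset of
    the physically tampered ones.
    """
    if f is not None and tamper_span > n_slices:
        raise ValueError("tamper_span cannot exceed n_slices")
    ann_span = tamper_span if ann_span is None else ann_span
    if f is not None and not (1 <= ann_span <= tamper_span):
        raise ValueError("ann_span must be within the tampered span")
    slices = []
    records: list[TamperRecord] = []
    z0 = (n_slices - tamper_span) // 2
    tampered_z = set(range(z0, z0 + tamper_span)) if f is not None else set()
    center = None
    rng = np.random.default_rng(seed)
    # anatomy (blobs) persists through the stack; noise is per-slice
    blobs = sample_blobs(cfg, rng)
    # fix the tamper center from the central slice's geometry
    if f is not None:
        mid_cfg = _scaled_cfg(cfg, n_slices, n_slices // 2)
        mid = make_phantom_slice(mid_cfg, seed=seed * 1000 + n_slices // 2, blobs=blobs)
        box = int(rng.integers(f.box_min, f.box_max + 1))
        ok = _placement_mask(mid.pixels, box, f.lung_threshold)
        ys, xs = np.nonzero(ok)
        if len(ys) == 0:
            raise ValueError("no valid lung-field placement for the tamper box")
        i = rng.integers(len(ys))
        center = (int(ys[i]), int(xs[i]))
        # the 3-D in-painter writes z-coherent generated texture: the box
        # noise interpolates smoothly between two draws across the span
        # (variance-preserving), while the smoothing blends with each
        # slice's local context
        nrng = np.random.default_rng(seed * 1000 + 999)
        eta_a = ndimage.gaussian_filter(nrng.normal(size=(box, box)), f.noise_corr_px)
        eta_b = ndimage.gaussian_filter(nrng.normal(size=(box, box)), f.noise_corr_px)
    for z in range(n_slices):
        scfg = _scaled_cfg(cfg, n_slices, z)
        slc = make_phantom_slice(scfg, seed=seed * 1000 + z, blobs=blobs)
        slc = SliceImage(slc.pixels, z_position=float(z), source_id=f"scan{seed}-z{z}")
        if z in tampered_z:
            t = (z - z0) / max(1, tamper_span - 1)
            eta = np.cos(t * np.pi / 2) * eta_a + np.sin(t * np.pi / 2) * eta_b
            slc, _ = apply_forgery(slc, f, seed=seed * 1000 + 999, center=center,
                                   box=box, noise_field=eta)
        slices.append(slc)
    if f is not None:
        a0 = z0 + (tamper_span - ann_span) // 2
        records.append(TamperRecord(center=center, box_size=box,
                                    slice_span=(a0, a0 + ann_span - 1)))
    return ScanVolume(slices=slices, slice_spacing_mm=1.0), records


def _scaled_cfg(cfg: PhantomConfig, n_slices: int, z: int) -> PhantomConfig:
    # lungs taper smoothly towards the ends of the stack
    t = np.sin(np.pi * (z + 0.5) / n_slices)
    scale = 0.85 + 0.15 * t
    return replace(cfg, lung_axes=(cfg.lung_axes[0] * scale, cfg.lung_axes[1] * scale))


def make_patch_dataset(
    slice_pairs,
    clean_arrays,
    grid: WindowGrid,
    aug: AugConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled patches for detector training.

    ``slice_pairs`` are (clean_array, tampered_array, TamperRecord) triples in
    the detector's normalized input space; positives are the shift grid
    around each tamper center cropped from the tampered slice, negatives are
    the near-offset + random-grid centers cropped from the pre-tamper slice,
    plus 25 random-grid crops from each of ``neg_per_pos`` standalone clean
    slices per pair (``clean_arrays``).
    """
    size = grid.cfg.img_size
    patches, labels = [], []
    for i, (clean, tampered, record) in enumerate(slice_pairs):
        for c in positive_aug_centers(record.center, aug, grid.cfg):
            patches.append(crop_patch(tampered, c, size))
            labels.append(1)
        pair_aug = replace(aug, seed=aug.seed + 7919 * (i + 1))
        for c in negative_aug_centers(record.center, grid, pair_aug):
            patches.append(crop_patch(clean, c, size))
            labels.append(0)
    needed = aug.neg_per_pos * len(slice_pairs)
    if len(clean_arrays) < needed:
        log.warning("only %d clean slices supplied for %d requested pairings",
                    len(clean_arrays), needed)
    rng = np.random.default_rng(aug.seed)
    for arr in list(clean_arrays)[:needed]:
        idx = rng.choice(len(grid), size=min(25, len(grid)), replace=False)
        for i in idx:
            patches.append(crop_patch(arr, grid.centers[i], size))
            labels.append(0)
    return np.stack(patches), np.asarray(labels, dtype=int)


def normalize_phantom(slc: SliceImage) -> NormalizedSlice:
    """Phantoms are stored-unit images; normalize over the full [0, 4095] range."""
    from .imageio import normalize_intensity

    return normalize_intensity(slc, 0.0, INTENSITY_MAX)
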