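"""End-to-end synthetic benchmark for the two-stage cascade.

Runs the whole pipeline on phantom data at reduced scale — 128 x 128 slices
with 16 x 16 tampers, preserving the tamper-to-image area regime of real
512 x 512 scans with sub-32 x 32 forgeries — so the cascade is trainable and
measurable on one CPU in minutes.  All stages consume the package's public
interfaces; nothing here is test-only shortcutting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .classifier import (GlobalModel, GlobalModelConfig, ScanRule, classify_slice,
                         classify_scan, fit_global)
from .detector import DetectorConfig, DetectorModel, TrainConfig, build_detector, train_detector
from .evaluation import ConfusionCounts, RegionAnnotation, confusion_metrics, region_eval, slice_confusion
from .glcm import GlcmConfig, feature_table
from .heatmap import detect_slice
from .imageio import NormalizedSlice
from .synthetic import (ForgeryConfig, PhantomConfig, apply_forgery, make_patch_dataset,
                        make_phantom_slice, make_scan, normalize_phantom)
from .windows import AugConfig, GridConfig, window_grid

log = logging.getLogger(__name__)


@dataclass
class BenchmarkConfig:
    """Problem sizes of the reduced-scale synthetic study.

    Everything scales down together from the full-size configuration: 128 px
    slices with 16 px tampers keep the full-scale tamper-to-image regime,
    the window shrinks with the tamper so the forgery still fills it, the
    co-occurrence quantization (25 levels on the 29 x 29 lattice) keeps the
    pairs-per-coordinate density of 100 levels on a 121 x 121 lattice, and
    the PCA dimension (16 for 300 training heatmaps) keeps the full-scale
    reduction ratio (256 components for thousands of samples).
    """

    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(size=128))
    forgery: ForgeryConfig = field(default_factory=lambda: ForgeryConfig(box_min=16, box_max=16))
    grid: GridConfig = field(default_factory=lambda: GridConfig(ct_size=128, img_size=16, stride=4))
    detector: DetectorConfig = field(default_factory=DetectorConfig.small)
    # patience is stated in epochs, but a benchmark epoch is ~100x fewer
    # optimizer steps than a full-scale epoch; 10 epochs here is still far
    # below the full-scale rule's step budget
    train: TrainConfig = field(default_factory=lambda: TrainConfig(early_stop_patience=10))
    aug: AugConfig = field(default_factory=lambda: AugConfig(neg_per_pos=2))
    glcm: GlcmConfig = field(default_factory=lambda: GlcmConfig(gray_levels=25))
    global_cfg: GlobalModelConfig = field(default_factory=lambda: GlobalModelConfig(reduced_dim=16))
    rule: ScanRule = field(default_factory=ScanRule)
    n_train_pairs: int = 75
    n_val_pairs: int = 10
    n_global_per_class: int = 120
    n_test_per_class: int = 20
    n_scans: int = 3
    scan_slices: int = 24
    scan_tamper_span: int = 16  # physically tampered slices per region
    tamper_span: int = 10       # annotated window around the central slice


def _tampered_pair(cfg: BenchmarkConfig, seed: int):
    clean = make_phantom_slice(cfg.phantom, seed=seed)
    tampered, record = apply_forgery(clean, cfg.forgery, seed=seed)
    return (normalize_phantom(clean).pixels, normalize_phantom(tampered).pixels, record)


def _norm_slice(arr: np.ndarray, source_id: str) -> NormalizedSlice:
    return NormalizedSlice(pixels=arr, lo=0.0, hi=4095.0, source_id=source_id)


@dataclass
class BenchmarkResult:
    detector: DetectorModel
    global_model: GlobalModel
    patch_val_auc: float
    slice_counts: ConfusionCounts
    slice_metrics: dict
    region_counts: ConfusionCounts
    n_regions: int
    scan_verdicts: list
    clean_scan_verdict: bool


def _patch_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, probs))


def run_benchmark(seed: int = 0, cfg: BenchmarkConfig | None = None) -> BenchmarkResult:
    """Train the cascade on synthetic data and evaluate held-out slices and scans."""
    cfg = cfg or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    base = int(rng.integers(0, 2**20)) * 1000
    grid = window_grid(cfg.grid)

    # ---- stage 1: patch detector -------------------------------------------
    train_pairs = [_tampered_pair(cfg, base + i) for i in range(cfg.n_train_pairs)]
    val_pairs = [_tampered_pair(cfg, base + 100 + i) for i in range(cfg.n_val_pairs)]
    n_clean_train = cfg.aug.neg_per_pos * cfg.n_train_pairs
    n_clean_val = cfg.aug.neg_per_pos * cfg.n_val_pairs
    clean_train = [normalize_phantom(make_phantom_slice(cfg.phantom, seed=base + 200 + i)).pixels
                   for i in range(n_clean_train)]
    clean_val = [normalize_phantom(make_phantom_slice(cfg.phantom, seed=base + 400 + i)).pixels
                 for i in range(n_clean_val)]
    aug = replace(cfg.aug, seed=seed)
    Xtr, ytr = make_patch_dataset(train_pairs, clean_train, grid, aug)
    Xva, yva = make_patch_dataset(val_pairs, clean_val, grid, replace(aug, seed=seed + 1))
    log.info("patch dataset: %d train (%d pos), %d val", len(ytr), ytr.sum(), len(yva))

    detector = build_detector(cfg.detector, seed=seed)
    tc = replace(cfg.train, seed=seed)
    train_detector(detector, Xtr, ytr, Xva, yva, tc)
    val_auc = _patch_auc(detector.predict(Xva), yva)
    log.info("patch val AUC %.4f", val_auc)

    # ---- stage 2: global classifier ----------------------------------------
    def heatmaps_for(arrs, tag):
        return [detect_slice(detector, _norm_slice(a, f"{tag}{i}"), cfg.grid)
                for i, a in enumerate(arrs)]

    g_tampered = [_tampered_pair(cfg, base + 600 + i)[1] for i in range(cfg.n_global_per_class)]
    g_clean = [normalize_phantom(make_phantom_slice(cfg.phantom, seed=base + 800 + i)).pixels
               for i in range(cfg.n_global_per_class)]
    feats, labels = feature_table(
        heatmaps_for(g_tampered, "gt") + heatmaps_for(g_clean, "gc"),
        [1] * len(g_tampered) + [0] * len(g_clean),
        cfg.glcm,
    )
    gcfg = replace(cfg.global_cfg, seed=seed)
    gmodel = fit_global(feats, labels, gcfg)
    log.info("global CV accuracy %.4f with %s", gmodel.cv_score, gmodel.best_params)

    # ---- held-out slice evaluation -----------------------------------------
    t_test = [_tampered_pair(cfg, base + 1200 + i)[1] for i in range(cfg.n_test_per_class)]
    c_test = [normalize_phantom(make_phantom_slice(cfg.phantom, seed=base + 1400 + i)).pixels
              for i in range(cfg.n_test_per_class)]
    preds = []
    for i, a in enumerate(t_test + c_test):
        label, _ = classify_slice(gmodel, detector, _norm_slice(a, f"test{i}"), cfg.grid, cfg.glcm)
        preds.append(label)
    truths = [1] * len(t_test) + [0] * len(c_test)
    counts = slice_confusion(preds, truths)
    metrics = confusion_metrics(counts)
    log.info("held-out slice metrics: %s", metrics)

    # ---- 3-D region evaluation on scans ------------------------------------
    region_tp = region_fp = region_fn = 0
    verdicts = []
    n_regions = 0
    for s in range(cfg.n_scans):
        volume, records = make_scan(cfg.phantom, cfg.forgery, cfg.scan_slices,
                                    tamper_span=cfg.scan_tamper_span,
                                    ann_span=cfg.tamper_span, seed=base // 1000 + 30 + s)
        slice_preds = []
        for slc in volume.slices:
            label, _ = classify_slice(gmodel, detector, normalize_phantom(slc), cfg.grid, cfg.glcm)
            slice_preds.append(label)
        anns = [RegionAnnotation(scan_id=f"scan{s}", center_index=(r.slice_span[0] + r.slice_span[1]) // 2,
                                 span=r.slice_span) for r in records]
        n_regions += len(anns)
        rc = region_eval(slice_preds, anns, cfg.rule)
        region_tp += rc.tp
        region_fp += rc.fp
        region_fn += rc.fn
        verdicts.append(classify_scan(slice_preds, cfg.rule)[0])
    clean_volume, _ = make_scan(cfg.phantom, None, cfg.scan_slices, seed=base // 1000 + 60)
    clean_preds = [classify_slice(gmodel, detector, normalize_phantom(s), cfg.grid, cfg.glcm)[0]
                   for s in clean_volume.slices]
    clean_verdict = classify_scan(clean_preds, cfg.rule)[0]

    return BenchmarkResult(
        detector=detector,
        global_model=gmodel,
        patch_val_auc=val_auc,
        slice_counts=counts,
        slice_metrics=metrics,
        region_counts=ConfusionCounts(tp=region_tp, tn=0, fp=region_fp, fn=region_fn),
        n_regions=n_regions,
        scan_verdicts=verdicts,
        clean_scan_verdict=clean_verdict,
    )
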