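"""Global classification stage: PCA-reduced GLCM features into a kernel SVM.

The 40000-dimensional co-occurrence feature of a slice heatmap is reduced to
256 principal components (mean-centered, no whitening) and classified by a
maximum-margin classifier whose hyper-parameters are chosen by seeded
stratified cross-validated grid search.  Slice decisions are aggregated to a
scan verdict with an n-of-m consecutive-slice rule (default 9 of 10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .glcm import GlcmConfig, glcm_stack
from .heatmap import detect_slice
from .imageio import NormalizedSlice
from .windows import GridConfig

log = logging.getLogger(__name__)


def default_param_grid() -> list[dict]:
    """Small standard SVM grid: RBF and linear kernels, a few soft margins.

    The RBF kernel widths 'scale' and 'auto' are 1/(d*var) and 1/d
    respectively, alongside two fixed values.
    """
    return [
        {"kernel": ["rbf"], "C": [0.1, 1.0, 10.0, 100.0],
         "gamma": ["scale", "auto", 0.01, 0.001]},
        {"kernel": ["linear"], "C": [0.1, 1.0, 10.0, 100.0]},
    ]


@dataclass
class GlobalModelConfig:
    reduced_dim: int = 256
    param_grid: list = field(default_factory=default_param_grid)
    cv_folds: int = 5
    decision_threshold: float = 0.5
    seed: int = 0


@dataclass
class GlobalModel:
    """Fitted reduction + classifier with the chosen grid point and CV score."""

    pca: PCA
    clf: SVC
    cfg: GlobalModelConfig
    best_params: dict
    cv_score: float

    def score_features(self, X: np.ndarray) -> np.ndarray:
        """Probability-like tamper score per feature row."""
        return self.clf.predict_proba(self.pca.transform(X))[:, 1]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "GlobalModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ValueError(f"{path} does not contain a GlobalModel")
        return model


def fit_global(features: np.ndarray, labels, cfg: GlobalModelConfig | None = None) -> GlobalModel:
    """Fit PCA on the training features, then grid-search the classifier.

    ``reduced_dim`` is lowered (with a warning) when there are fewer samples
    than requested components.
    """
    cfg = cfg or GlobalModelConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) aligned with labels")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the global model")
    if not cfg.param_grid:
        raise ValueError("hyper-parameter grid is empty")

    n_comp = min(cfg.reduced_dim, X.shape[0], X.shape[1])
    if n_comp < cfg.reduced_dim:
        log.warning("reduced_dim lowered from %d to %d (n=%d samples, d=%d features)",
                    cfg.reduced_dim, n_comp, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, whiten=False, random_state=cfg.seed)
    Z = pca.fit_transform(X)

    folds = min(cfg.cv_folds, int(np.bincount(y).min()))
    if folds < cfg.cv_folds:
        log.warning("cv folds lowered from %d to %d for class balance", cfg.cv_folds, folds)
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=cfg.seed)
    search = GridSearchCV(
        SVC(probability=True, random_state=cfg.seed),
        cfg.param_grid,
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(Z, y)
    return GlobalModel(
        pca=pca,
        clf=search.best_estimator_,
        cfg=cfg,
        best_params=dict(search.best_params_),
        cv_score=float(search.best_score_),
    )


def classify_slice(
    gmodel: GlobalModel,
    detector,
    slc: NormalizedSlice,
    grid_cfg: GridConfig,
    glcm_cfg: GlcmConfig = GlcmConfig(),
) -> tuple[int, float]:
    """Run the full cascade on one slice: heatmap -> GLCM -> PCA -> classifier."""
    h = detect_slice(detector, slc, grid_cfg)
    feat = glcm_stack(h, glcm_cfg).flat[None, :]
    score = float(gmodel.score_features(feat)[0])
    label = int(score > gmodel.cfg.decision_threshold)
    return label, score


@dataclass(frozen=True)
class ScanRule:
    """Scan verdict rule: tampered iff some m consecutive slices hold >= n positives."""

    m: int = 10
    n: int = 9

    def __post_init__(self):
        if not (1 <= self.n <= self.m):
            raise ValueError("require 1 <= n <= m")


def classify_scan(slice_labels, rule: ScanRule = ScanRule()) -> tuple[bool, list[int]]:
    """Apply the n-of-m rule to an ordered sequence of slice decisions.

    Returns the verdict and the start indices of every triggering window.
    Sequences shorter than ``m`` are evaluated on the whole sequence, with a
    warning.
    """
    labels = np.asarray(slice_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("slice label sequence is empty")
    if labels.size < rule.m:
        log.warning("sequence of %d slices shorter than rule window m=%d; evaluating whole sequence",
                    labels.size, rule.m)
        return bool(labels.sum() >= rule.n), ([0] if labels.sum() >= rule.n else [])
    cums = np.concatenate([[0], np.cumsum(labels)])
    window_counts = cums[rule.m:] - cums[:-rule.m]
    starts = np.nonzero(window_counts >= rule.n)[0].tolist()
    return bool(starts), starts
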