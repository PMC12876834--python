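"""Tile-level foamy/not-foamy classification with case-level CV.

The classifier operates on fixed colour/texture summary features of each
512x512 tile (per-channel histograms, channel moments, gray-level
percentiles) and a logistic model trained by mini-batch SGD, which keeps
the epochs / batch-size / learning-rate / seed semantics of conventional
deep training while running in seconds on one CPU. Cross-validation is
*case-level*: every tile of a patient stays in one fold, so performance
estimates are free of patient leakage.

Predictions are aggregated upward: tile -> glomerulus (any-positive by
default, matching the screening intent) and glomerulus -> case (a case
is positive iff any of its glomeruli is).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb, rgb2hsv

from .evaluate import ClassificationMetrics, confusion_metrics
from .tiling import Tile

log = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "TilePrediction",
    "make_case_folds",
    "augment_tile",
    "apply_augment",
    "tile_features",
    "TileClassifier",
    "train_classifier",
    "predict_tiles",
    "aggregate_glomerulus",
    "aggregate_case",
    "save_model_bundle",
    "load_model_bundle",
]

LABELS = ("not_foamy", "foamy")


def _balanced_weights(y: np.ndarray) -> dict[int, float]:
    """Inverse-frequency class weights computed on the full training
    labels (partial_fit cannot infer them per batch)."""
    y = np.asarray(y)
    n = y.size
    return {
        c: n / (2 * max(int((y == c).sum()), 1)) for c in (0, 1)
    }


@dataclass
class FoldSplit:
    """Case-level fold assignment: all tiles of a case share its fold."""

    k: int
    assignment: dict[str, int]

    def fold_of(self, case_id: str) -> int:
        return self.assignment[case_id]

    def cases_in(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f == fold)


@dataclass
class TrainConfig:
    model: str = "sgd_logistic"
    augment: bool = False
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 0.05
    seed: int = 0
    n_augment: int = 1  # augmented copies per training tile

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TilePrediction:
    case_id: str
    slide_id: str
    region_id: str
    origin: tuple[int, int]
    p_foamy: float
    predicted_label: str  # thresholded at 0.5
    true_label: str = "unknown"


def make_case_folds(
    case_ids: list[str], k: int = 5, seed: int = 0
) -> FoldSplit:
    """Shuffle cases with the seed and deal them round-robin into k
    folds; fold sizes differ by at most one case."""
    cases = sorted(set(case_ids))
    if len(cases) < k:
        raise ValueError(f"need at least {k} cases, got {len(cases)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    assignment = {cases[j]: i % k for i, j in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment)


# ---------------------------------------------------------------------------
# augmentation


def apply_augment(
    pixels: np.ndarray,
    flip_h: bool = False,
    flip_v: bool = False,
    rot90: int = 0,
    brightness: float = 1.0,
    contrast: float = 1.0,
    hue_shift: float = 0.0,
) -> np.ndarray:
    """Deterministic label-preserving tile transform.

    With all factors at their identity values the input is returned
    bit-identically (no float round trip).
    """
    out = pixels
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    if rot90 % 4:
        out = np.rot90(out, k=rot90 % 4)
    if brightness != 1.0 or contrast != 1.0:
        f = out.astype(np.float32)
        mean = f.mean()
        f = (f - mean) * contrast + mean * brightness
        out = np.clip(f, 0, 255).astype(np.uint8)
    if hue_shift != 0.0:
        hsv = rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + hue_shift) % 1.0
        out = np.clip(hsv2rgb(hsv) * 255, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(out)


def augment_tile(
    pixels: np.ndarray,
    rng: np.random.Generator,
    brightness_jitter: float = 0.10,
    contrast_jitter: float = 0.10,
    hue_jitter: float = 0.05,
    allow_flip: bool = True,
) -> np.ndarray:
    """Random flip / 90-degree rotation / +-10% brightness-contrast /
    +-5% hue jitter, drawn from ``rng`` (deterministic per state)."""
    flip_h = allow_flip and bool(rng.integers(2))
    flip_v = allow_flip and bool(rng.integers(2))
    rot = int(rng.integers(4)) if allow_flip else 0
    b = 1.0 + (rng.uniform(-brightness_jitter, brightness_jitter)
               if brightness_jitter else 0.0)
    c = 1.0 + (rng.uniform(-contrast_jitter, contrast_jitter)
               if contrast_jitter else 0.0)
    h = rng.uniform(-hue_jitter, hue_jitter) if hue_jitter else 0.0
    return apply_augment(pixels, flip_h, flip_v, rot, b, c, h)


# ---------------------------------------------------------------------------
# features + model

_HIST_BINS = 8


def tile_features(pixels: np.ndarray) -> np.ndarray:
    """Fixed 35-dim colour/texture summary of one RGB tile."""
    f = pixels.reshape(-1, 3).astype(np.float32)
    feats = []
    for ch in range(3):
        hist, _ = np.histogram(f[:, ch], bins=_HIST_BINS, range=(0, 256))
        feats.append(hist / f.shape[0])
    means = f.mean(axis=0) / 255.0
    stds = f.std(axis=0) / 255.0
    gray = f.mean(axis=1)
    pct = np.percentile(gray, [5, 25, 50, 75, 95]) / 255.0
    return np.concatenate(feats + [means, stds, pct]).astype(np.float64)


class TileClassifier:
    """Logistic tile classifier trained by mini-batch SGD on summary
    features, with feature standardisation fitted on the training set."""

    def __init__(self, cfg: TrainConfig):
        if cfg.model != "sgd_logistic":
            raise ValueError(f"unknown model {cfg.model!r}")
        self.cfg = cfg
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self._clf = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TileClassifier":
        from sklearn.linear_model import SGDClassifier

        cfg = self.cfg
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_

        # inverse-frequency weighting guards against class imbalance
        clf = SGDClassifier(
            loss="log_loss", learning_rate="constant", eta0=cfg.learning_rate,
            alpha=1e-4, random_state=cfg.seed,
            class_weight=_balanced_weights(y),
        )
        rng = np.random.default_rng(cfg.seed)
        classes = np.array([0, 1])
        n = Xs.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                clf.partial_fit(Xs[idx], y[idx], classes=classes)
        self._clf = clf
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("classifier is not fitted")
        Xs = (X - self.mean_) / self.scale_
        return self._clf.predict_proba(Xs)[:, 1]


def _featurize(tiles: list[Tile]) -> np.ndarray:
    return np.stack([tile_features(t.pixels) for t in tiles])


def train_classifier(
    tiles: list[Tile],
    folds: FoldSplit,
    cfg: TrainConfig,
) -> dict:
    """Case-level cross-validated training.

    Tiles must carry labels ("foamy"/"not_foamy") and case ids present
    in ``folds``. For each fold a classifier is fitted on the other k-1
    folds (optionally with augmented copies) and evaluated on the
    held-out fold. Returns per-fold models and metrics plus the pooled
    out-of-fold predictions.
    """
    y = np.array([1 if t.label == "foamy" else 0 for t in tiles])
    tile_folds = np.array([folds.fold_of(t.case_id) for t in tiles])
    X = _featurize(tiles)

    models: dict[int, TileClassifier] = {}
    metrics: dict[int, ClassificationMetrics] = {}
    oof: list[TilePrediction] = []
    for f in range(folds.k):
        train_idx = np.nonzero(tile_folds != f)[0]
        val_idx = np.nonzero(tile_folds == f)[0]
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"training split for fold {f} has a single class")
        Xtr, ytr = X[train_idx], y[train_idx]
        if cfg.augment:
            rng = np.random.default_rng((cfg.seed, f))
            extra_X, extra_y = [], []
            for i in train_idx:
                for _ in range(cfg.n_augment):
                    extra_X.append(tile_features(
                        augment_tile(tiles[i].pixels, rng)
                    ))
                    extra_y.append(y[i])
            Xtr = np.vstack([Xtr, np.stack(extra_X)])
            ytr = np.concatenate([ytr, extra_y])
        model = TileClassifier(cfg).fit(Xtr, ytr)
        models[f] = model
        if len(val_idx):
            p = model.predict_proba(X[val_idx])
            pred = (p >= 0.5).astype(int)
            metrics[f] = confusion_metrics(
                pred, y[val_idx], level="tile", scores=p
                if len(np.unique(y[val_idx])) == 2 else None,
            )
            for i, pi in zip(val_idx, p):
                t = tiles[i]
                oof.append(TilePrediction(
                    case_id=t.case_id, slide_id=t.slide_id,
                    region_id=t.region_id, origin=t.origin,
                    p_foamy=float(pi),
                    predicted_label=LABELS[int(pi >= 0.5)],
                    true_label=t.label,
                ))
    return {"models": models, "metrics": metrics, "oof": oof}


def predict_tiles(
    model: TileClassifier, tiles: list[Tile]
) -> list[TilePrediction]:
    """One prediction per tile; independent of batch composition."""
    if not tiles:
        return []
    p = model.predict_proba(_featurize(tiles))
    return [
        TilePrediction(
            case_id=t.case_id, slide_id=t.slide_id, region_id=t.region_id,
            origin=t.origin, p_foamy=float(pi),
            predicted_label=LABELS[int(pi >= 0.5)], true_label=t.label,
        )
        for t, pi in zip(tiles, p)
    ]


# ---------------------------------------------------------------------------
# aggregation


def aggregate_glomerulus(
    preds: list[TilePrediction], rule: str = "any_positive"
) -> tuple[str, float]:
    """Pool one region's tile predictions into a label and a score.

    any_positive: foamy iff any tile is predicted foamy; score = max p.
    majority: foamy iff more than half the tiles are; score = mean p.
    mean_prob: foamy iff mean p >= 0.5; score = mean p.
    """
    if not preds:
        raise ValueError("no predictions for region")
    ps = np.array([p.p_foamy for p in preds])
    pos = np.array([p.predicted_label == "foamy" for p in preds])
    if rule == "any_positive":
        return LABELS[int(pos.any())], float(ps.max())
    if rule == "majority":
        return LABELS[int(pos.sum() > len(pos) / 2)], float(ps.mean())
    if rule == "mean_prob":
        return LABELS[int(ps.mean() >= 0.5)], float(ps.mean())
    raise ValueError(f"unknown aggregation rule {rule!r}")


def aggregate_case(region_labels: list[str]) -> str:
    """A case is positive iff any of its glomeruli is positive."""
    if not region_labels:
        raise ValueError("no region labels for case")
    return LABELS[int(any(l == "foamy" for l in region_labels))]


# ---------------------------------------------------------------------------
# model bundle (patch-inference-runtime-compatible metadata)


def save_model_bundle(
    model: TileClassifier, outdir: str | Path,
    tile_px: int = 512, target_mpp: float = 0.5,
) -> Path:
    """Write weights + a metadata JSON whose fields mirror the WSInfer
    model-card convention (spacing, patch size, classes, transform)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clf = model._clf
    if clf is None:
        raise ValueError("model is not fitted")
    np.savez(
        outdir / "weights.npz",
        coef=clf.coef_, intercept=clf.intercept_,
        mean=model.mean_, scale=model.scale_,
    )
    meta = {
        "spec_version": "1.0",
        "architecture": model.cfg.model,
        "num_classes": 2,
        "class_names": list(LABELS),
        "patch_size_pixels": tile_px,
        "spacing_um_px": target_mpp,
        "transform": {
            "resize_size": tile_px,
            "features": "color_histogram_v1",
            "mean": model.mean_.tolist(),
            "std": model.scale_.tolist(),
        },
    }
    (outdir / "config.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_model_bundle(outdir: str | Path) -> TileClassifier:
    from sklearn.linear_model import SGDClassifier

    outdir = Path(outdir)
    meta = json.loads((outdir / "config.json").read_text())
    data = np.load(outdir / "weights.npz")
    model = TileClassifier(TrainConfig(model=meta["architecture"]))
    clf = SGDClassifier(loss="log_loss")
    clf.coef_ = data["coef"]
    clf.intercept_ = data["intercept"]
    clf.classes_ = np.array([0, 1])
    model._clf = clf
    model.mean_ = data["mean"]
    model.scale_ = data["scale"]
    return model
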