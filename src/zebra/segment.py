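"""Pixel-level segmentation of foamy podocytes and the glomerulus.

The segmenter is a per-pixel logistic model over multi-scale colour and
edge features (raw RGB, Gaussian-smoothed RGB at two scales, gradient
magnitude, large-scale context) — the trainable-segmentation idiom of
ilastik / scikit-image — trained on pixels sampled from the training
tiles under the same case-level fold machinery as the classifier.
Dice and IoU are reported both as global pixel pools and as per-tile
means (an empty-vs-empty tile counts as a perfect 1.0 in the latter).

The derived tile-positivity rule — a tile is positive when at least one
pixel is predicted as foamy podocyte — turns the segmenter into a
screening detector with its own sensitivity/PPV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .classify import FoldSplit, _balanced_weights, augment_tile
from .tiling import Tile

log = logging.getLogger(__name__)

__all__ = [
    "SegMetrics",
    "SegTrainConfig",
    "dice",
    "iou",
    "pixel_features",
    "PixelSegmenter",
    "train_segmenter",
    "predict_mask",
    "tile_positive",
    "seg_screen_metrics",
    "compute_seg_metrics",
]


@dataclass
class SegMetrics:
    dice: float
    iou: float
    n_tiles: int
    aggregation: str  # "global_pixel" | "per_tile_mean"

    def as_dict(self) -> dict:
        return {"dice": self.dice, "iou": self.iou,
                "n_tiles": self.n_tiles, "aggregation": self.aggregation}


@dataclass
class SegTrainConfig:
    model: str = "sgd_logistic"
    target: str = "podocyte"  # "podocyte" | "glomerulus"
    augment: bool = False
    epochs: int = 3
    batch_size: int = 256
    learning_rate: float = 0.05
    seed: int = 0
    n_sample_px: int = 2000  # training pixels sampled per tile
    threshold: float = 0.5
    min_object_px: int = 0  # optional post-hoc small-object filter

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.target not in ("podocyte", "glomerulus"):
            raise ValueError("target must be 'podocyte' or 'glomerulus'")


# ---------------------------------------------------------------------------
# overlap metrics


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    return a, b


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """2|A^B| / (|A|+|B|); both masks empty -> 1 by convention."""
    a, b = _check_pair(mask_a, mask_b)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2 * (a & b).sum() / denom)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """|A^B| / |AvB|; both masks empty -> 1 by convention."""
    a, b = _check_pair(mask_a, mask_b)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def compute_seg_metrics(
    pred_masks: list[np.ndarray],
    true_masks: list[np.ndarray],
    aggregation: str = "global_pixel",
) -> SegMetrics:
    """Dice/IoU over a tile set, pooled globally or averaged per tile."""
    if len(pred_masks) != len(true_masks):
        raise ValueError("mask list lengths differ")
    if aggregation == "global_pixel":
        inter = sum_p = sum_t = 0
        for p, t in zip(pred_masks, true_masks):
            p, t = _check_pair(p, t)
            inter += int((p & t).sum())
            sum_p += int(p.sum())
            sum_t += int(t.sum())
        denom = sum_p + sum_t
        d = 2 * inter / denom if denom else 1.0
        union = denom - inter
        i = inter / union if union else 1.0
        return SegMetrics(float(d), float(i), len(pred_masks), aggregation)
    if aggregation == "per_tile_mean":
        ds = [dice(p, t) for p, t in zip(pred_masks, true_masks)]
        is_ = [iou(p, t) for p, t in zip(pred_masks, true_masks)]
        return SegMetrics(
            float(np.mean(ds)), float(np.mean(is_)),
            len(pred_masks), aggregation,
        )
    raise ValueError(f"unknown aggregation {aggregation!r}")


# ---------------------------------------------------------------------------
# features + model

_SIGMAS = (2.0, 8.0)
_CONTEXT_SIGMA = 24.0
N_FEATURES = 3 + 3 * len(_SIGMAS) + 1 + 1


def pixel_features(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack (H, W, 11), float32.

    RGB, RGB smoothed at sigma 2 and 8 px, Sobel gradient magnitude of
    the gray image, and a sigma-24 gray context channel that lets the
    model tell pale lesions inside the dark tuft from the equally pale
    background outside it.
    """
    f = pixels.astype(np.float32) / 255.0
    chans = [f[..., c] for c in range(3)]
    for s in _SIGMAS:
        for c in range(3):
            chans.append(ndimage.gaussian_filter(f[..., c], s))
    gray = f.mean(axis=2)
    gx = ndimage.sobel(gray, axis=0)
    gy = ndimage.sobel(gray, axis=1)
    chans.append(np.hypot(gx, gy))
    chans.append(ndimage.gaussian_filter(gray, _CONTEXT_SIGMA))
    return np.stack(chans, axis=-1)


class PixelSegmenter:
    """Logistic per-pixel segmenter trained by SGD on sampled pixels."""

    def __init__(self, cfg: SegTrainConfig):
        if cfg.model != "sgd_logistic":
            raise ValueError(f"unknown model {cfg.model!r}")
        self.cfg = cfg
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None
        self._clf = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PixelSegmenter":
        from sklearn.linear_model import SGDClassifier

        cfg = self.cfg
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Xs = (X - self.mean_) / self.scale_
        clf = SGDClassifier(
            loss="log_loss", learning_rate="constant", eta0=cfg.learning_rate,
            alpha=1e-4, random_state=cfg.seed,
            class_weight=_balanced_weights(y),
        )
        rng = np.random.default_rng(cfg.seed)
        n = Xs.shape[0]
        classes = np.array([0, 1])
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                clf.partial_fit(Xs[idx], y[idx], classes=classes)
        self._clf = clf
        return self

    def probability_map(self, tile_pixels: np.ndarray) -> np.ndarray:
        return self.probability_from_features(pixel_features(tile_pixels))

    def probability_from_features(self, feats: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("segmenter is not fitted")
        h, w, nf = feats.shape
        Xs = (feats.reshape(-1, nf) - self.mean_) / self.scale_
        p = self._clf.predict_proba(Xs)[:, 1]
        return p.reshape(h, w)


def _sample_pixels(
    tiles: list[Tile], feats_of: list[np.ndarray], target: str,
    cfg: SegTrainConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced pixel sample across tiles (half foreground where
    the tile has any)."""
    Xs, ys = [], []
    for t, feats in zip(tiles, feats_of):
        mask = t.masks[target].astype(bool)
        feats = feats.reshape(-1, N_FEATURES)
        flat = mask.ravel()
        pos = np.nonzero(flat)[0]
        neg = np.nonzero(~flat)[0]
        n = cfg.n_sample_px
        if len(pos):
            take_pos = pos[rng.integers(0, len(pos), size=n // 2)]
            take_neg = neg[rng.integers(0, len(neg), size=n - n // 2)]
            take = np.concatenate([take_pos, take_neg])
        else:
            take = neg[rng.integers(0, len(neg), size=n)]
        Xs.append(feats[take])
        ys.append(flat[take].astype(int))
    return np.vstack(Xs), np.concatenate(ys)


def train_segmenter(
    tiles: list[Tile],
    folds: FoldSplit,
    cfg: SegTrainConfig,
) -> dict:
    """Case-level cross-validated segmenter training.

    Tiles must carry a ground-truth mask under ``masks[cfg.target]``.
    Returns per-fold models, held-out Dice/IoU under both aggregation
    modes, and the pooled out-of-fold predicted masks (ordered like the
    input tiles, only held-out entries present).
    """
    tile_folds = np.array([folds.fold_of(t.case_id) for t in tiles])
    if cfg.target == "podocyte" and not any(
        t.masks[cfg.target].any() for t in tiles
    ):
        raise ValueError("all podocyte masks are empty; nothing to learn")

    # feature maps are fold-independent: compute once per tile
    feats_of = [pixel_features(t.pixels) for t in tiles]

    models: dict[int, PixelSegmenter] = {}
    metrics: dict[int, dict[str, SegMetrics]] = {}
    oof_masks: dict[int, np.ndarray] = {}
    for f in range(folds.k):
        train_sel = [i for i, tf in enumerate(tile_folds) if tf != f]
        train_tiles = [tiles[i] for i in train_sel]
        train_feats = [feats_of[i] for i in train_sel]
        val_idx = np.nonzero(tile_folds == f)[0]
        if cfg.target == "podocyte" and not any(
            t.masks[cfg.target].any() for t in train_tiles
        ):
            raise ValueError(
                f"training split for fold {f} has no podocyte pixels"
            )
        rng = np.random.default_rng((cfg.seed, f))
        if cfg.augment:
            aug = [
                Tile(
                    pixels=augment_tile(t.pixels, rng, allow_flip=False),
                    origin=t.origin, region_id=t.region_id, label=t.label,
                    case_id=t.case_id, slide_id=t.slide_id, masks=t.masks,
                )
                for t in train_tiles
            ]
            train_tiles = train_tiles + aug
            train_feats = train_feats + [
                pixel_features(t.pixels) for t in aug
            ]
        X, y = _sample_pixels(train_tiles, train_feats, cfg.target, cfg, rng)
        model = PixelSegmenter(cfg).fit(X, y)
        models[f] = model
        preds, trues = [], []
        for i in val_idx:
            prob = model.probability_from_features(feats_of[i])
            m = _threshold_mask(prob, cfg.threshold, cfg.min_object_px)
            oof_masks[int(i)] = m
            preds.append(m)
            trues.append(tiles[i].masks[cfg.target].astype(bool))
        if preds:
            metrics[f] = {
                agg: compute_seg_metrics(preds, trues, agg)
                for agg in ("global_pixel", "per_tile_mean")
            }
    return {"models": models, "metrics": metrics, "oof_masks": oof_masks}


def predict_mask(
    model: PixelSegmenter,
    tile_pixels: np.ndarray,
    threshold: float = 0.5,
    min_object_px: int = 0,
) -> np.ndarray:
    """Threshold the per-pixel probability map into a binary mask.

    Masks are nested in the threshold (higher threshold -> subset).
    ``min_object_px`` optionally drops connected components smaller
    than that size (off by default).
    """
    prob = model.probability_map(tile_pixels)
    return _threshold_mask(prob, threshold, min_object_px)


def _threshold_mask(
    prob: np.ndarray, threshold: float, min_object_px: int
) -> np.ndarray:
    mask = prob >= threshold
    if min_object_px > 0 and mask.any():
        labeled, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        small = np.nonzero(sizes < min_object_px)[0] + 1
        mask[np.isin(labeled, small)] = False
    return mask


def tile_positive(podocyte_mask: np.ndarray) -> bool:
    """A tile is positive when at least one pixel is predicted foamy."""
    return bool(np.asarray(podocyte_mask).any())


def seg_screen_metrics(
    tile_positives: list[bool] | np.ndarray,
    tile_labels: list[bool] | np.ndarray,
) -> tuple[float | None, float | None]:
    """Sensitivity and PPV of the segmentation-derived tile detector.

    Ratios with zero denominators are returned as None (e.g. PPV with
    no predicted positives, sensitivity with no positive labels).
    """
    pred = np.asarray(tile_positives).astype(bool)
    true = np.asarray(tile_labels).astype(bool)
    if pred.shape != true.shape:
        raise ValueError("vectors must be aligned")
    tp = int((pred & true).sum())
    fn = int((~pred & true).sum())
    fp = int((pred & ~true).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    ppv = tp / (tp + fp) if (tp + fp) else None
    return sens, ppv
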