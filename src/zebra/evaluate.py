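"""Statistical evaluation protocol for the screening pipeline.

Implements the metric suite used to assess the foamy-podocyte classifier,
the segmenters and the ZEBRA score: confusion-table metrics at tile /
glomerulus / case level, AUC-ROC, percentile bootstrap confidence
intervals (1,000 resamples by default), Youden's-J cutoff selection on the
case-mean score, Spearman rank correlation against the manual podocyte
vacuolization score, Mann-Whitney group comparison and the chi-square
test for categorical tables.

Undefined ratios (zero denominators) are reported as ``None`` / NaN,
never silently as 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

log = logging.getLogger(__name__)

__all__ = [
    "ClassificationMetrics",
    "BootstrapCI",
    "RocResult",
    "CorrelationResult",
    "confusion_metrics",
    "auc_roc",
    "bootstrap_ci",
    "youden_cutoff",
    "spearman",
    "mann_whitney",
    "chi_square",
    "evaluate_run",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class ClassificationMetrics:
    """Binary classification metrics from a 2x2 table.

    Any ratio with a zero denominator is ``None`` (missing), not 0.
    ``level`` records the evaluation unit: tile, glomerulus or case.
    """

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    auc_roc: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    level: str = "tile"
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "accuracy", "precision", "recall", "f1", "auc_roc",
                "sensitivity", "specificity", "ppv", "npv",
                "level", "tp", "fp", "tn", "fn",
            )
        }


@dataclass
class BootstrapCI:
    metric: str
    point: float
    lo95: float
    hi95: float
    n_resamples: int
    seed: int
    n_undefined: int = 0

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "point": self.point,
            "lo95": self.lo95,
            "hi95": self.hi95,
            "n_resamples": self.n_resamples,
            "n_undefined": self.n_undefined,
        }


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    youden_cutoff: float
    youden_sens: float
    youden_spec: float
    J: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_cutoff": self.youden_cutoff,
            "youden_sens": self.youden_sens,
            "youden_spec": self.youden_spec,
            "J": self.J,
        }


@dataclass
class CorrelationResult:
    r_s: float | None
    n: int
    stratum: str = ""

    def as_dict(self) -> dict:
        return {"r_s": self.r_s, "n": self.n, "stratum": self.stratum}


# ---------------------------------------------------------------------------
# metric primitives


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(
    predicted: Sequence[int] | np.ndarray,
    truth: Sequence[int] | np.ndarray,
    level: str = "tile",
    scores: Sequence[float] | None = None,
) -> ClassificationMetrics:
    """Metrics from predicted and true binary labels (1 = positive).

    ``scores`` (optional continuous scores) enable the AUC-ROC entry; it
    is left missing when scores are absent or only one class occurs.
    """
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have the same length")
    if predicted.size == 0:
        raise ValueError("empty label vectors")

    tp = int(np.sum((predicted == 1) & (truth == 1)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)

    auc = None
    if scores is not None and len(np.unique(truth)) == 2:
        auc = auc_roc(scores, truth)

    return ClassificationMetrics(
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        precision=precision,
        recall=recall,
        f1=f1,
        auc_roc=auc,
        sensitivity=recall,
        specificity=_ratio(tn, tn + fp),
        ppv=precision,
        npv=_ratio(tn, tn + fn),
        level=level,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def metrics_from_counts(
    tp: int, fp: int, tn: int, fn: int, level: str = "case"
) -> ClassificationMetrics:
    """Build the metric set from raw confusion counts (e.g. a published
    confusion table) by expanding them into label vectors."""
    pred = np.concatenate([
        np.ones(tp + fp, dtype=int), np.zeros(tn + fn, dtype=int)
    ])
    true = np.concatenate([
        np.ones(tp, dtype=int), np.zeros(fp, dtype=int),
        np.zeros(tn, dtype=int), np.ones(fn, dtype=int),
    ])
    return confusion_metrics(pred, true, level=level)


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve.

    Equals the probability that a random positive outranks a random
    negative, ties counted 1/2 (the Mann-Whitney identity).
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("auc_roc requires both classes present")
    return float(roc_auc_score(labels, scores))


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], float | None],
    predictions: Sequence[float],
    labels: Sequence[int],
    n_resamples: int = 1000,
    seed: int = 0,
    metric_name: str = "metric",
) -> BootstrapCI:
    """Percentile bootstrap CI for a metric of (predictions, labels).

    Resamples (prediction, label) pairs with replacement, recomputes the
    metric each time and returns the empirical 2.5/97.5 percentiles.
    Resamples where the metric is undefined (``None``/NaN) are skipped
    and counted; more than 50% undefined is an error.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("empty sample")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")

    rng = np.random.default_rng(seed)
    n = predictions.size
    point = metric_fn(predictions, labels)
    if point is None:
        raise ValueError("metric undefined on the observed sample")

    idx = rng.integers(0, n, size=(n_resamples, n))
    values = np.empty(n_resamples)
    n_undef = 0
    for i in range(n_resamples):
        v = metric_fn(predictions[idx[i]], labels[idx[i]])
        if v is None or (isinstance(v, float) and math.isnan(v)):
            values[i] = np.nan
            n_undef += 1
        else:
            values[i] = v
    if n_undef > n_resamples / 2:
        raise ValueError(
            f"metric undefined in {n_undef}/{n_resamples} resamples"
        )
    lo, hi = np.nanpercentile(values, [2.5, 97.5])
    return BootstrapCI(
        metric=metric_name, point=float(point), lo95=float(lo),
        hi95=float(hi), n_resamples=n_resamples, seed=seed,
        n_undefined=n_undef,
    )


def youden_cutoff(
    scores: Sequence[float], labels: Sequence[int]
) -> RocResult:
    """ROC analysis with the Youden's-J optimal cutoff.

    The decision rule is *positive iff score >= cutoff*. J = sens + spec
    - 1 is evaluated at every midpoint between adjacent sorted unique
    scores (plus sentinels below the minimum and above the maximum);
    ties in J are broken toward the lower cutoff, favouring sensitivity
    as befits a screening score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("youden_cutoff requires both classes present")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))

    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    sens = np.empty(candidates.size)
    spec = np.empty(candidates.size)
    for i, c in enumerate(candidates):
        pred = scores >= c
        sens[i] = np.sum(pred & (labels == 1)) / n_pos
        spec[i] = np.sum(~pred & (labels == 0)) / n_neg
    J = sens + spec - 1
    # candidates ascend; argmax takes the first (lowest) maximizer
    best = int(np.argmax(J))
    return RocResult(
        auc=auc_roc(scores, labels),
        thresholds=candidates,
        sens=sens,
        spec=spec,
        youden_cutoff=float(candidates[best]),
        youden_sens=float(sens[best]),
        youden_spec=float(spec[best]),
        J=float(J[best]),
    )


def spearman(
    x: Sequence[float], y: Sequence[float], stratum: str = ""
) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        log.warning("spearman: zero rank variance in stratum %r", stratum)
        return CorrelationResult(r_s=None, n=int(x.size), stratum=stratum)
    r = stats.spearmanr(x, y).statistic
    return CorrelationResult(r_s=float(r), n=int(x.size), stratum=stratum)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    U is the rank-sum statistic for ``group_a`` (ties share mid-ranks).
    For pooled n <= 12 the p-value is exact by enumerating every
    assignment of the pooled values to the two groups (correct under
    ties); otherwise the tie-corrected normal approximation is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size

    u_obs = _u_statistic(a, b)
    if n_a + n_b <= 12:
        pooled = np.concatenate([a, b])
        center = n_a * n_b / 2
        total = 0
        extreme = 0
        for comb in itertools.combinations(range(n_a + n_b), n_a):
            mask = np.zeros(n_a + n_b, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )
        p = float(res.pvalue)
    return float(u_obs), float(min(p, 1.0))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via mid-rank sums."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction
    by default (flag in :func:`chi_square_corrected`)."""
    return _chi_square(table, correction=False)


def chi_square_corrected(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Chi-square with Yates continuity correction."""
    return _chi_square(table, correction=True)


def _chi_square(table, correction: bool) -> tuple[float, float]:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("chi_square expects a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# full report

_CI_METRICS: dict[str, Callable] = {
    "accuracy": lambda p, t: _ratio(np.sum(p == t), p.size),
    "sensitivity": lambda p, t: _ratio(
        np.sum((p == 1) & (t == 1)), np.sum(t == 1)
    ),
    "specificity": lambda p, t: _ratio(
        np.sum((p == 0) & (t == 0)), np.sum(t == 0)
    ),
    "ppv": lambda p, t: _ratio(np.sum((p == 1) & (t == 1)), np.sum(p == 1)),
    "npv": lambda p, t: _ratio(np.sum((p == 0) & (t == 0)), np.sum(p == 0)),
}


def metrics_with_cis(
    predicted, truth, level: str, n_resamples: int = 1000, seed: int = 0,
    scores=None,
) -> dict:
    """Confusion metrics plus percentile bootstrap CIs per metric."""
    m = confusion_metrics(predicted, truth, level=level, scores=scores)
    out = m.as_dict()
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    cis = {}
    for name, fn in _CI_METRICS.items():
        if out.get(name) is None:
            continue
        try:
            ci = bootstrap_ci(
                fn, predicted, truth, n_resamples=n_resamples,
                seed=seed, metric_name=name,
            )
        except ValueError:
            continue
        cis[name] = ci.as_dict()
    out["bootstrap_cis"] = cis
    return out


def evaluate_run(
    tile_preds: pd.DataFrame | None,
    glom_preds: pd.DataFrame | None,
    case_preds: pd.DataFrame | None,
    case_scores: pd.DataFrame | None,
    case_records: pd.DataFrame | None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict:
    """Assemble the full evaluation report.

    Expected frames (missing levels are skipped with a note):

    - ``tile_preds`` / ``glom_preds`` / ``case_preds``: columns
      ``predicted`` and ``truth`` (0/1), optional ``p_foamy`` score.
    - ``case_scores``: columns ``case_id``, ``mean_zs``.
    - ``case_records``: columns ``case_id``, ``disease`` ("FN"/"control"),
      optional ``mpvs``, ``stain``, ``sex``.
    """
    report: dict = {"notes": [], "seed": seed, "n_resamples": n_resamples}

    for level, frame in (
        ("tile", tile_preds), ("glomerulus", glom_preds), ("case", case_preds)
    ):
        if frame is None or len(frame) == 0:
            report["notes"].append(f"no predictions at {level} level")
            continue
        scores = frame["p_foamy"].to_numpy() if "p_foamy" in frame else None
        report[f"{level}_metrics"] = metrics_with_cis(
            frame["predicted"].to_numpy(), frame["truth"].to_numpy(),
            level=level, n_resamples=n_resamples, seed=seed, scores=scores,
        )

    if case_scores is not None and case_records is not None and len(case_scores):
        merged = case_scores.merge(case_records, on="case_id")
        zs = merged["mean_zs"].to_numpy(dtype=float)
        is_fn = (merged["disease"] == "FN").to_numpy()
        if is_fn.any() and (~is_fn).any():
            roc = youden_cutoff(zs, is_fn.astype(int))
            report["zs_roc"] = roc.as_dict()
            u, p = mann_whitney(zs[is_fn], zs[~is_fn])
            report["zs_group_comparison"] = {
                "mean_zs_fn": float(zs[is_fn].mean()),
                "mean_zs_control": float(zs[~is_fn].mean()),
                "U": u, "p": p, "significant": p < 0.05,
            }
        else:
            report["notes"].append(
                "ROC/group comparison skipped: only one disease group present"
            )
        if "mpvs" in merged:
            report["zs_vs_mpvs"] = _mpvs_correlations(merged)

    return report


def _mpvs_correlations(merged: pd.DataFrame) -> list[dict]:
    """Spearman r_s of mean ZS vs manual MPVS, overall and stratified by
    stain and sex where the metadata columns are present."""
    out = []
    sub = merged.dropna(subset=["mpvs"])

    def corr(frame: pd.DataFrame, name: str):
        if len(frame) < 3:
            return
        try:
            out.append(spearman(frame["mean_zs"], frame["mpvs"], name).as_dict())
        except ValueError:
            pass

    corr(sub, "all")
    for col in ("stain", "sex"):
        if col in sub:
            for value, frame in sub.groupby(col):
                corr(frame, str(value))
    return out
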