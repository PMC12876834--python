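"""The ZEBRA score: foamy-podocyte area fraction of the glomerulus.

For each glomerulus, fpA is the foamy-podocyte pixel area *inside* the
glomerular mask and tgA the total glomerular pixel area; the score is
ZS = 100 * fpA / tgA (percent). Case-level screening uses the unweighted
mean ZS over a case's glomeruli compared against a cutoff (inclusive
``>=``, the tie going to the positive side as befits screening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GlomerulusScore",
    "CaseScore",
    "CaseRecord",
    "compute_zs",
    "case_zs",
    "classify_case",
    "score_table",
    "case_table",
]


@dataclass
class GlomerulusScore:
    fpA: int
    tgA: int
    zs: float  # percent, 100 * fpA / tgA
    region_id: str = ""
    case_id: str = ""


@dataclass
class CaseScore:
    case_id: str
    mean_zs: float
    n_glomeruli: int
    predicted: str | None = None  # "FN" | "control"
    cutoff_used: float | None = None


@dataclass
class CaseRecord:
    """Clinical metadata for one case; optional fields may be None."""

    case_id: str
    disease: str  # "FN" | "control"
    mpvs: float | None = None  # manual score, ISGFN 0-3 scale
    egfr: float | None = None  # ml/min/1.73 m^2
    proteinuria: float | None = None  # g/24 h
    sex: str | None = None


def compute_zs(
    podocyte_mask: np.ndarray,
    glomerulus_mask: np.ndarray,
    region_id: str = "",
    case_id: str = "",
) -> GlomerulusScore:
    """Score one glomerulus from binary masks of the same shape.

    Podocyte pixels outside the glomerular mask are excluded: the score
    is by definition a proportion of glomerular area.
    """
    pod = np.asarray(podocyte_mask).astype(bool)
    glom = np.asarray(glomerulus_mask).astype(bool)
    if pod.shape != glom.shape:
        raise ValueError("mask shapes differ")
    tgA = int(glom.sum())
    if tgA == 0:
        raise ValueError(
            "empty glomerulus mask: ZS undefined (skip this region)"
        )
    fpA = int((pod & glom).sum())
    return GlomerulusScore(
        fpA=fpA, tgA=tgA, zs=100.0 * fpA / tgA,
        region_id=region_id, case_id=case_id,
    )


def case_zs(scores: list[GlomerulusScore]) -> CaseScore:
    """Unweighted mean ZS over one case's glomeruli."""
    if not scores:
        raise ValueError("no glomerulus scores")
    case_ids = {s.case_id for s in scores}
    if len(case_ids) > 1:
        raise ValueError(f"scores span multiple cases: {sorted(case_ids)}")
    return CaseScore(
        case_id=scores[0].case_id,
        mean_zs=float(np.mean([s.zs for s in scores])),
        n_glomeruli=len(scores),
    )


def classify_case(case_score: CaseScore, cutoff: float) -> CaseScore:
    """Label a case FN iff its mean ZS >= cutoff (inclusive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return CaseScore(
        case_id=case_score.case_id,
        mean_zs=case_score.mean_zs,
        n_glomeruli=case_score.n_glomeruli,
        predicted="FN" if case_score.mean_zs >= cutoff else "control",
        cutoff_used=cutoff,
    )


def score_table(scores: list[GlomerulusScore]) -> pd.DataFrame:
    """Per-glomerulus CSV-ready table."""
    return pd.DataFrame(
        [
            {"case_id": s.case_id, "region_id": s.region_id,
             "fpA": s.fpA, "tgA": s.tgA, "zs": s.zs}
            for s in scores
        ]
    )


def case_table(cases: list[CaseScore]) -> pd.DataFrame:
    """Per-case CSV-ready table."""
    return pd.DataFrame(
        [
            {"case_id": c.case_id, "n_glomeruli": c.n_glomeruli,
             "mean_zs": c.mean_zs, "predicted": c.predicted,
             "cutoff_used": c.cutoff_used}
            for c in cases
        ]
    )
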