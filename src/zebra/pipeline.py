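"""End-to-end orchestration: simulate -> tile -> train -> infer ->
score -> evaluate, on a synthetic cohort with known ground truth.

``run_all`` reproduces the full screening workflow at desk scale: it
generates a cohort, extracts labelled 512x512 tiles at 0.5 um/px,
cross-validates the tile classifier and both segmenters at case level,
derives the ZEBRA score per glomerulus and case from the predicted
masks, selects a cutoff by Youden's J on the case-mean score, and emits
the statistical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, score, segment, synthesis, tiling

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "tiles_from_cohort"]


@dataclass
class RunConfig:
    cohort: synthesis.SyntheticCohortSpec = field(
        default_factory=synthesis.SyntheticCohortSpec
    )
    tiling: tiling.TilingConfig = field(default_factory=tiling.TilingConfig)
    cls: classify.TrainConfig = field(default_factory=classify.TrainConfig)
    seg: segment.SegTrainConfig = field(
        default_factory=segment.SegTrainConfig
    )
    k_folds: int = 5
    glomerulus_rule: str = "any_positive"
    cutoff: float | None = None  # None -> Youden-selected on case mean ZS
    n_resamples: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs: dict = {}
        if "cohort" in d:
            kwargs["cohort"] = synthesis.SyntheticCohortSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["cohort"].items()
            })
        if "tiling" in d:
            kwargs["tiling"] = tiling.TilingConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["tiling"].items()
            })
        if "cls" in d:
            kwargs["cls"] = classify.TrainConfig(**d["cls"])
        if "seg" in d:
            kwargs["seg"] = segment.SegTrainConfig(**d["seg"])
        for k in ("k_folds", "glomerulus_rule", "cutoff", "n_resamples",
                  "seed"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def tiles_from_cohort(
    spec: synthesis.SyntheticCohortSpec,
    cfg: tiling.TilingConfig,
) -> tuple[list[tiling.Tile], pd.DataFrame, pd.DataFrame]:
    """Generate the cohort case by case and turn every glomerulus crop
    into labelled tiles with aligned ground-truth masks.

    Full-resolution images are released as soon as each case is tiled,
    so memory stays proportional to the tile set. Tile labels come from
    the generator's ground truth: a tile is foamy iff its window holds
    at least one foamy-podocyte pixel. Returns (tiles, manifest,
    case_records).
    """
    tiles: list[tiling.Tile] = []
    manifest_rows = []
    case_rows = []
    for case in synthesis.iter_cases(spec):
        for g in case.glomeruli:
            h, w = g.image.shape[:2]
            region = tiling.RegionAnnotation(
                polygon=[(0, 0), (w, 0), (w, h), (0, h)],
                class_name="glomerulus",
                case_id=g.case_id, slide_id=g.slide_id,
                region_id=g.glomerulus_id,
            )
            for t in tiling.extract_tiles(
                g.image, region, cfg, src_mpp=g.mpp,
                aligned_masks={
                    "podocyte": g.podocyte_mask,
                    "glomerulus": g.glomerulus_mask,
                },
            ):
                t.label = (
                    "foamy" if t.masks["podocyte"].any() else "not_foamy"
                )
                tiles.append(t)
            manifest_rows.append({
                "case_id": g.case_id, "slide_id": g.slide_id,
                "glomerulus_id": g.glomerulus_id, "disease": case.disease,
                "label": g.label, "true_fraction": g.true_fraction,
                "mpp": g.mpp, "stain": case.stain,
            })
        case_rows.append({
            "case_id": case.case_id, "disease": case.disease,
            "mpvs": case.synthetic_mpvs, "sex": case.sex,
            "stain": case.stain,
        })
    return tiles, pd.DataFrame(manifest_rows), pd.DataFrame(case_rows)


def _tile_pred_frame(preds: list[classify.TilePrediction]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "case_id": p.case_id, "slide_id": p.slide_id,
            "region_id": p.region_id, "origin_x": p.origin[0],
            "origin_y": p.origin[1], "p_foamy": p.p_foamy,
            "predicted_label": p.predicted_label,
            "predicted": int(p.predicted_label == "foamy"),
            "truth": int(p.true_label == "foamy"),
        }
        for p in preds
    ])


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole pipeline; returns the result bundle and optionally
    writes CSVs + report to ``outdir``."""
    t0 = time.time()
    timings: dict[str, float] = {}

    spec = cfg.cohort
    tiles, manifest, case_records = tiles_from_cohort(spec, cfg.tiling)
    if not tiles:
        raise ValueError("cohort produced no tiles")
    timings["simulate_and_tile"] = time.time() - t0
    log.info("cohort: %d tiles from %d glomeruli, %d cases",
             len(tiles), len(manifest), len(case_records))

    folds = classify.make_case_folds(
        list(case_records["case_id"]), k=cfg.k_folds, seed=cfg.seed
    )

    # --- classification experiment -------------------------------------
    t1 = time.time()
    cls_res = classify.train_classifier(tiles, folds, cfg.cls)
    tile_preds = _tile_pred_frame(cls_res["oof"])
    timings["classify"] = time.time() - t1

    glom_truth = manifest.set_index("glomerulus_id")["label"].to_dict()
    glom_rows = []
    for rid, grp in tile_preds.groupby("region_id"):
        preds = [p for p in cls_res["oof"] if p.region_id == rid]
        label, sc = classify.aggregate_glomerulus(preds, cfg.glomerulus_rule)
        glom_rows.append({
            "case_id": grp["case_id"].iloc[0], "region_id": rid,
            "p_foamy": sc, "predicted_label": label,
            "predicted": int(label == "foamy"),
            "truth": int(glom_truth[rid] == "foamy"),
        })
    glom_preds = pd.DataFrame(glom_rows)

    disease = case_records.set_index("case_id")["disease"].to_dict()
    case_rows = []
    for cid, grp in glom_preds.groupby("case_id"):
        label = classify.aggregate_case(list(grp["predicted_label"]))
        case_rows.append({
            "case_id": cid, "p_foamy": float(grp["p_foamy"].max()),
            "predicted_label": label, "predicted": int(label == "foamy"),
            "truth": int(disease[cid] == "FN"),
        })
    case_preds = pd.DataFrame(case_rows)

    # --- segmentation experiment ---------------------------------------
    t2 = time.time()
    seg_pod_cfg = segment.SegTrainConfig(**{
        **asdict(cfg.seg), "target": "podocyte"
    })
    seg_glom_cfg = segment.SegTrainConfig(**{
        **asdict(cfg.seg), "target": "glomerulus"
    })
    seg_pod = segment.train_segmenter(tiles, folds, seg_pod_cfg)
    seg_glom = segment.train_segmenter(tiles, folds, seg_glom_cfg)
    timings["segment"] = time.time() - t2

    pod_masks = [seg_pod["oof_masks"][i] for i in range(len(tiles))]
    glom_masks = [seg_glom["oof_masks"][i] for i in range(len(tiles))]
    seg_metrics = {
        "podocyte": {
            agg: segment.compute_seg_metrics(
                pod_masks, [t.masks["podocyte"] for t in tiles], agg
            ).as_dict()
            for agg in ("global_pixel", "per_tile_mean")
        },
        "glomerulus": {
            agg: segment.compute_seg_metrics(
                glom_masks, [t.masks["glomerulus"] for t in tiles], agg
            ).as_dict()
            for agg in ("global_pixel", "per_tile_mean")
        },
    }
    sens, ppv = segment.seg_screen_metrics(
        [segment.tile_positive(m) for m in pod_masks],
        [t.label == "foamy" for t in tiles],
    )
    seg_screen = {"tile_sensitivity": sens, "tile_ppv": ppv}

    # --- ZEBRA score -----------------------------------------------------
    glom_scores: list[score.GlomerulusScore] = []
    skipped = []
    by_region: dict[str, list[int]] = {}
    for i, t in enumerate(tiles):
        by_region.setdefault(t.region_id, []).append(i)
    for rid, idxs in by_region.items():
        fpA = sum(int((pod_masks[i] & glom_masks[i]).sum()) for i in idxs)
        tgA = sum(int(glom_masks[i].sum()) for i in idxs)
        if tgA == 0:
            skipped.append(rid)
            continue
        glom_scores.append(score.GlomerulusScore(
            fpA=fpA, tgA=tgA, zs=100.0 * fpA / tgA,
            region_id=rid, case_id=tiles[idxs[0]].case_id,
        ))
    by_case: dict[str, list[score.GlomerulusScore]] = {}
    for s in glom_scores:
        by_case.setdefault(s.case_id, []).append(s)
    case_scores = [score.case_zs(v) for v in by_case.values()]
    case_score_df = score.case_table(case_scores)

    zs = case_score_df["mean_zs"].to_numpy(dtype=float)
    is_fn = case_score_df["case_id"].map(disease).eq("FN").to_numpy()
    roc = None
    if is_fn.any() and (~is_fn).any():
        roc = evaluate.youden_cutoff(zs, is_fn.astype(int))
    cutoff = cfg.cutoff if cfg.cutoff is not None else (
        roc.youden_cutoff if roc else 0.0
    )
    classified = [score.classify_case(c, max(cutoff, 0.0)) for c in case_scores]
    case_score_df = score.case_table(classified)

    # --- report ----------------------------------------------------------
    report = evaluate.evaluate_run(
        tile_preds, glom_preds, case_preds, case_score_df, case_records,
        n_resamples=cfg.n_resamples, seed=cfg.seed,
    )
    report["segmentation"] = seg_metrics
    report["segmentation_screen"] = seg_screen
    if skipped:
        report["notes"].append(
            f"{len(skipped)} regions skipped: empty predicted glomerulus mask"
        )
    timings["total"] = time.time() - t0
    result = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_tiles": len(tiles),
        "n_glomeruli": len(manifest),
        "n_cases": len(case_records),
        "tile_metrics": report.get("tile_metrics"),
        "glomerulus_metrics": report.get("glomerulus_metrics"),
        "case_metrics": report.get("case_metrics"),
        "seg_metrics": seg_metrics,
        "seg_screen": seg_screen,
        "cutoff_used": cutoff,
        "zs_roc": report.get("zs_roc"),
        "report": report,
        "timings": timings,
        "tables": {
            "manifest": manifest,
            "case_records": case_records,
            "tile_predictions": tile_preds,
            "glomerulus_predictions": glom_preds,
            "case_predictions": case_preds,
            "glomerulus_scores": score.score_table(glom_scores),
            "case_scores": case_score_df,
        },
    }
    if outdir is not None:
        _write_outputs(result, cfg, Path(outdir))
    return result


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _write_outputs(result: dict, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result["config_hash"], "seed": cfg.seed}
    for name, frame in result["tables"].items():
        f = frame.copy()
        f["config_hash"] = stamp["config_hash"]
        f["seed"] = stamp["seed"]
        f.to_csv(outdir / f"{name}.csv", index=False)
    report = {**result["report"], **stamp,
              "segmentation": result["seg_metrics"],
              "segmentation_screen": result["seg_screen"],
              "cutoff_used": result["cutoff_used"],
              "timings": result["timings"]}
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default)
    )
    (outdir / "report.txt").write_text(render_report(report))


def render_report(report: dict) -> str:
    """Human-readable rendering of the evaluation report."""
    lines = ["Screening pipeline evaluation report",
             "=" * 40,
             f"config: {report.get('config_hash', '-')}  "
             f"seed: {report.get('seed', '-')}", ""]
    for level in ("tile", "glomerulus", "case"):
        m = report.get(f"{level}_metrics")
        if not m:
            continue
        lines.append(f"[{level} level]  "
                     f"n={m['tp'] + m['fp'] + m['tn'] + m['fn']}")
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                  "f1", "auc_roc"):
            v = m.get(k)
            if v is None:
                lines.append(f"  {k:12s} missing")
                continue
            ci = m.get("bootstrap_cis", {}).get(k)
            tail = (f"  [95% CI {ci['lo95']:.3f}-{ci['hi95']:.3f}]"
                    if ci else "")
            lines.append(f"  {k:12s} {v:.3f}{tail}")
        lines.append("")
    seg = report.get("segmentation")
    if seg:
        for target, aggs in seg.items():
            g = aggs["global_pixel"]
            lines.append(
                f"[segmentation:{target}]  Dice {g['dice']:.3f}  "
                f"IoU {g['iou']:.3f} (global), "
                f"Dice {aggs['per_tile_mean']['dice']:.3f} (per-tile mean)"
            )
        sc = report.get("segmentation_screen", {})
        if sc:
            s = sc.get("tile_sensitivity")
            p = sc.get("tile_ppv")
            lines.append(
                "[segmentation screen]  tile sensitivity "
                f"{'-' if s is None else f'{s:.3f}'}  "
                f"PPV {'-' if p is None else f'{p:.3f}'}"
            )
        lines.append("")
    roc = report.get("zs_roc")
    if roc:
        lines.append(
            f"[ZEBRA score]  AUC {roc['auc']:.3f}  cutoff "
            f"{roc['youden_cutoff']:.3f} (sens {roc['youden_sens']:.2f}, "
            f"spec {roc['youden_spec']:.2f}, J {roc['J']:.2f})"
        )
    grp = report.get("zs_group_comparison")
    if grp:
        lines.append(
            f"  mean ZS: FN {grp['mean_zs_fn']:.3f} vs control "
            f"{grp['mean_zs_control']:.3f}  (Mann-Whitney U {grp['U']:.1f}, "
            f"p {grp['p']:.4g})"
        )
    for c in report.get("zs_vs_mpvs", []) or []:
        r = c["r_s"]
        lines.append(
            f"  Spearman ZS vs MPVS [{c['stratum']}]: "
            f"{'-' if r is None else f'{r:.2f}'} (n={c['n']})"
        )
    for note in report.get("notes", []):
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
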