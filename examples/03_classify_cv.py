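"""Tile classification with case-level 5-fold cross-validation.

Trains the foamy/not-foamy tile classifier so that all tiles of a
patient stay in one fold (no leakage), then pools held-out predictions
up to glomerulus and case level with the any-positive screening rule.
"""

import numpy as np

import zebra
from zebra import pipeline

spec = zebra.SyntheticCohortSpec(n_cases_pos=6, n_cases_neg=4,
                                 glomeruli_per_case=(2, 3), seed=2)
tiles, manifest, records = pipeline.tiles_from_cohort(
    spec, zebra.TilingConfig()
)
folds = zebra.make_case_folds(list(records["case_id"]), k=5, seed=2)
res = zebra.train_classifier(tiles, folds, zebra.TrainConfig(seed=2))

pred = np.array([p.predicted_label == p.true_label for p in res["oof"]])
print(f"{len(tiles)} tiles, held-out tile accuracy {pred.mean():.2f}")

truth = manifest.set_index("glomerulus_id")["label"]
by_region = {}
for p in res["oof"]:
    by_region.setdefault(p.region_id, []).append(p)
hits = 0
case_labels: dict[str, list] = {}
for rid, preds in by_region.items():
    label, _ = zebra.aggregate_glomerulus(preds, "any_positive")
    hits += label == truth[rid]
    case_labels.setdefault(preds[0].case_id, []).append(label)
print(f"glomerulus-level accuracy {hits / len(by_region):.2f}")

disease = records.set_index("case_id")["disease"]
case_ok = sum(
    (zebra.aggregate_case(v) == "foamy") == (disease[c] == "FN")
    for c, v in case_labels.items()
)
print(f"case-level accuracy {case_ok / len(case_labels):.2f} "
      f"(a case is positive iff any glomerulus is)")
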