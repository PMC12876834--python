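"""The statistical toolkit on its own: bootstrap CIs, group tests and
rank correlation.

These are the operators the evaluation report is built from; they can
be used directly on any prediction table.
"""

import numpy as np

from zebra import evaluate

rng = np.random.default_rng(0)

# --- classification metrics with percentile bootstrap CIs -------------
truth = rng.integers(0, 2, 200)
scores = np.clip(0.25 * rng.standard_normal(200) + 0.3 + 0.4 * truth, 0, 1)
pred = (scores >= 0.5).astype(int)
m = evaluate.confusion_metrics(pred, truth, scores=scores)
print(f"accuracy {m.accuracy:.2f}, sensitivity {m.sensitivity:.2f}, "
      f"specificity {m.specificity:.2f}, AUC {m.auc_roc:.2f}")
ci = evaluate.bootstrap_ci(
    lambda p, t: float(np.mean(p == t)), pred, truth,
    n_resamples=1000, seed=0, metric_name="accuracy",
)
print(f"accuracy 95% CI [{ci.lo95:.3f}, {ci.hi95:.3f}] "
      f"({ci.n_resamples} resamples)")

# --- group comparison and correlation ---------------------------------
zs_fn = rng.normal(0.49, 0.14, 15).clip(0)
zs_ctrl = rng.normal(0.10, 0.08, 15).clip(0)
u, p = evaluate.mann_whitney(zs_fn, zs_ctrl)
print(f"\nMann-Whitney U={u:.0f}, two-sided p={p:.2e} "
      f"({'significant' if p < 0.05 else 'ns'} at 0.05)")

roc = evaluate.youden_cutoff(
    np.r_[zs_fn, zs_ctrl], np.r_[np.ones(15), np.zeros(15)].astype(int)
)
print(f"AUC {roc.auc:.2f}; Youden cutoff {roc.youden_cutoff:.3f} "
      f"(sens {roc.youden_sens:.2f}, spec {roc.youden_spec:.2f})")

mpvs = 3 * zs_fn / zs_fn.max() + rng.normal(0, 0.3, 15)
r = evaluate.spearman(zs_fn, mpvs)
print(f"Spearman r_s(ZS, MPVS) = {r.r_s:.2f} (n={r.n})")
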