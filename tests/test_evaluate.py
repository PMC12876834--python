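"""Statistical operators against independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from zebra.evaluate import (auc_roc, bootstrap_ci, chi_square,
                            chi_square_corrected, confusion_metrics,
                            evaluate_run, mann_whitney, metrics_from_counts,
                            spearman, youden_cutoff)

# ---------------------------------------------------------------------------
# oracles (deliberately naive implementations)


def auc_pair_counting(scores, labels):
    """O(n^2) enumeration: P(random positive outranks random negative),
    ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def spearman_midrank_oracle(x, y):
    """Pearson correlation of explicitly computed mid-ranks."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    return np.corrcoef(rx, ry)[0, 1]


def youden_sweep_oracle(scores, labels):
    """Brute force over every threshold between sorted unique scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = np.concatenate((
        [uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]
    ))
    best_j, best_c = -np.inf, None
    for c in cands:
        pred = scores >= c
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_j, best_c


def mw_exact_oracle(a, b):
    """Two-sided exact p by full permutation enumeration."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n_a = len(a)
    center = n_a * len(b) / 2

    def u_of(idx):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        ranks = rankdata(pooled)
        return ranks[mask].sum() - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    total = extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        u = u_of(comb)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


# ---------------------------------------------------------------------------
# confusion metrics


class TestConfusionMetrics:
    def test_case_level_screening_table(self):
        # all 13 positive slides detected, 10 of 16 controls flagged
        m = metrics_from_counts(tp=13, fp=10, tn=6, fn=0, level="case")
        assert m.sensitivity == 1.0
        assert m.npv == 1.0
        assert round(m.ppv, 2) == 0.57
        assert round(m.specificity, 2) == 0.38

    def test_perfect_predictions(self):
        m = confusion_metrics([1, 0, 1], [1, 0, 1])
        for k in ("accuracy", "precision", "recall", "f1",
                  "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(m, k) == 1.0

    def test_undefined_ratios_are_missing_not_zero(self):
        m = confusion_metrics([0, 0], [0, 0])
        assert m.ppv is None and m.sensitivity is None
        assert m.specificity == 1.0

    def test_random_tables_match_formula_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            pred = rng.integers(0, 2, n)
            true = rng.integers(0, 2, n)
            m = confusion_metrics(pred, true)
            tp = np.sum((pred == 1) & (true == 1))
            fp = np.sum((pred == 1) & (true == 0))
            tn = np.sum((pred == 0) & (true == 0))
            fn = np.sum((pred == 0) & (true == 1))
            assert m.accuracy == pytest.approx((tp + tn) / n)
            if tp + fp:
                assert m.ppv == pytest.approx(tp / (tp + fp))
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))
            if m.precision and m.recall:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall)
                )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1], [1, 0])


class TestAuc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc_roc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_roc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            labels = np.r_[1, 0, rng.integers(0, 2, n)]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n + 2)
            assert auc_roc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12
            )


class TestBootstrap:
    def test_degenerate_sample_gives_zero_width(self):
        acc = lambda p, t: np.mean(p == t)
        ci = bootstrap_ci(acc, np.ones(20), np.ones(20), seed=0)
        assert ci.lo95 == ci.hi95 == ci.point == 1.0

    def test_same_seed_reproduces_interval(self, rng):
        p = rng.integers(0, 2, 50)
        t = rng.integers(0, 2, 50)
        acc = lambda pp, tt: np.mean(pp == tt)
        a = bootstrap_ci(acc, p, t, seed=42)
        b = bootstrap_ci(acc, p, t, seed=42)
        assert (a.lo95, a.hi95) == (b.lo95, b.hi95)

    def test_endpoints_are_order_statistics(self, rng):
        p = rng.random(60)
        t = rng.integers(0, 2, 60)
        mean_p = lambda pp, tt: float(np.mean(pp))
        ci = bootstrap_ci(mean_p, p, t, n_resamples=200, seed=3)
        assert ci.lo95 <= ci.point <= ci.hi95

    def test_mostly_undefined_metric_errors(self):
        bad = lambda p, t: None
        with pytest.raises(ValueError):
            bootstrap_ci(bad, np.ones(5), np.ones(5), n_resamples=10, seed=0)


class TestYouden:
    def test_perfect_separation(self):
        r = youden_cutoff([1.0, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert r.J == 1.0 and r.youden_sens == 1.0 and r.youden_spec == 1.0
        assert 0.2 < r.youden_cutoff < 0.9

    def test_matches_brute_force_sweep(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            labels = np.r_[1, 0, rng.integers(0, 2, n)]
            scores = rng.choice(np.linspace(0, 1, 7), size=n + 2)
            r = youden_cutoff(scores, labels)
            j_oracle, _ = youden_sweep_oracle(scores, labels)
            assert r.J == pytest.approx(j_oracle, abs=1e-12)

    def test_cutoff_falls_between_group_means(self, rng):
        # group geometry of the published case-level scores:
        # FN 0.49 +- 0.14 vs control 0.10 +- 0.08, n=15 per arm
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            fn = np.clip(r.normal(0.49, 0.14, 15), 0, None)
            ctrl = np.clip(r.normal(0.10, 0.08, 15), 0, None)
            scores = np.r_[fn, ctrl]
            labels = np.r_[np.ones(15), np.zeros(15)]
            res = youden_cutoff(scores, labels)
            if ctrl.mean() < res.youden_cutoff < fn.mean():
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_tie_break_prefers_lower_cutoff(self):
        # two thresholds achieve J=0.5; the lower one wins
        r = youden_cutoff([0.1, 0.4, 0.6, 0.9], [0, 1, 0, 1])
        assert r.youden_cutoff < 0.5


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).r_s == 1.0
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).r_s == -1.0

    def test_ties_match_midrank_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 20))
            x = rng.choice([1.0, 2.0, 3.0, 4.0], size=n)
            y = rng.choice([1.0, 2.0, 3.0], size=n)
            if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
                continue
            assert spearman(x, y).r_s == pytest.approx(
                spearman_midrank_oracle(x, y), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        base = spearman(x, y).r_s
        assert spearman(np.exp(x), y).r_s == pytest.approx(base)
        assert spearman(x, y**3).r_s == pytest.approx(base)

    def test_zero_variance_reported_missing(self):
        assert spearman([1, 1, 1], [1, 2, 3]).r_s is None


class TestMannWhitney:
    def test_tied_singletons(self):
        u, p = mann_whitney([5.0], [5.0])
        assert u == 0.5 and p == 1.0

    def test_fully_separated_three_vs_three(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_u_identity(self, rng):
        for _ in range(20):
            a = rng.random(int(rng.integers(2, 10)))
            b = rng.random(int(rng.integers(2, 10)))
            u_a, _ = mann_whitney(a, b)
            u_b, _ = mann_whitney(b, a)
            assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_small_samples_match_enumeration_oracle(self, rng):
        for _ in range(15):
            a = rng.choice([1.0, 2.0, 3.0, 4.0], size=int(rng.integers(2, 5)))
            b = rng.choice([1.0, 2.0, 3.0, 4.0], size=int(rng.integers(2, 5)))
            u, p = mann_whitney(a, b)
            u_o, p_o = mw_exact_oracle(a, b)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)

    def test_large_samples_use_normal_approximation(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 25)
        u, p = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))


class TestChiSquare:
    def test_proportional_table_is_null(self):
        stat, p = chi_square([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_formula(self):
        stat, _ = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)  # sum (O-E)^2/E with E=5

    def test_swap_invariance(self, rng):
        t = rng.integers(1, 30, size=(2, 2))
        s0, _ = chi_square(t)
        assert chi_square(t[::-1])[0] == pytest.approx(s0)
        assert chi_square(t[:, ::-1])[0] == pytest.approx(s0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [3, 4]])

    def test_yates_correction_shrinks_statistic(self):
        s0, _ = chi_square([[10, 2], [3, 9]])
        s1, _ = chi_square_corrected([[10, 2], [3, 9]])
        assert s1 < s0


class TestEvaluateRun:
    def _frames(self, rng, with_fn=True):
        n = 40
        truth = rng.integers(0, 2, n)
        p = np.clip(truth * 0.6 + rng.random(n) * 0.4, 0, 1)
        tile = pd.DataFrame({
            "predicted": (p >= 0.5).astype(int), "truth": truth,
            "p_foamy": p,
        })
        diseases = (["FN"] * 5 + ["control"] * 5) if with_fn else (
            ["control"] * 10
        )
        records = pd.DataFrame({
            "case_id": [f"c{i}" for i in range(10)],
            "disease": diseases,
            "mpvs": rng.random(10) * 3,
            "stain": ["HE"] * 5 + ["PAS"] * 5,
            "sex": ["F", "M"] * 5,
        })
        zs = [1.0 + rng.random() if d == "FN" else rng.random() * 0.3
              for d in diseases]
        scores = pd.DataFrame({
            "case_id": records["case_id"], "mean_zs": zs,
        })
        return tile, scores, records

    def test_full_report_has_all_sections(self, rng):
        tile, scores, records = self._frames(rng)
        rep = evaluate_run(tile, None, None, scores, records,
                           n_resamples=50, seed=0)
        assert "tile_metrics" in rep
        assert "zs_roc" in rep
        assert "zs_group_comparison" in rep
        assert rep["zs_vs_mpvs"]

    def test_controls_only_skips_roc_with_note(self, rng):
        tile, scores, records = self._frames(rng, with_fn=False)
        rep = evaluate_run(tile, None, None, scores, records,
                           n_resamples=50, seed=0)
        assert "zs_roc" not in rep
        assert any("one disease group" in n for n in rep["notes"])

    def test_report_metrics_equal_recomputation(self, rng):
        tile, scores, records = self._frames(rng)
        rep = evaluate_run(tile, None, None, scores, records,
                           n_resamples=50, seed=0)
        m = rep["tile_metrics"]
        oracle = confusion_metrics(tile["predicted"], tile["truth"])
        assert m["accuracy"] == pytest.approx(oracle.accuracy)
        assert m["ppv"] == pytest.approx(oracle.ppv)
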