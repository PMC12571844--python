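"""Every metric against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from ohcmatch.metrics import (accuracy, auc, auc_from_arrays,
                              coverage_contribution, exposure_rate,
                              ndcg_at_k, precision_at_k, recall_at_k)


def random_prediction_table(rng, n=500):
    scores = rng.random(n)
    labels = rng.integers(0, 2, size=n)
    return pd.DataFrame({
        "query_id": [f"q{i}" for i in range(n)],
        "physician_id": [f"p{rng.integers(0, 50)}" for _ in range(n)],
        "label": labels, "score": scores,
        "predicted": (scores >= 0.5).astype(int)})


def random_rec_table(rng, n_queries=40, tiers=None):
    recs = {}
    for qi in range(n_queries):
        n_c = int(rng.integers(1, 30))
        pids = [f"p{j:03d}" for j in rng.choice(60, size=n_c, replace=False)]
        scores = rng.random(n_c)
        rels = rng.integers(0, 2, size=n_c)
        order = sorted(range(n_c), key=lambda i: (-scores[i], pids[i]))
        recs[f"q{qi}"] = [(pids[i], float(scores[i]), int(rels[i]))
                          for i in order]
    return recs


@pytest.fixture()
def tier_map():
    return {f"p{j:03d}": ("head" if j < 6 else "middle" if j < 30 else "tail")
            for j in range(60)}


class TestAccuracy:
    def test_all_correct(self):
        t = pd.DataFrame({"label": [0, 1], "score": [0.1, 0.9],
                          "predicted": [0, 1]})
        assert accuracy(t) == 1.0

    def test_direct_formula(self):
        # TP=3 TN=4 FP=2 FN=1 -> 0.7
        labels = [1] * 3 + [0] * 4 + [0] * 2 + [1] * 1
        preds = [1] * 3 + [0] * 4 + [1] * 2 + [0] * 1
        t = pd.DataFrame({"label": labels, "predicted": preds,
                          "score": [0.5] * 10})
        assert accuracy(t) == pytest.approx(0.7)

    def test_counting_oracle_on_random_rows(self, rng):
        t = random_prediction_table(rng)
        expect = np.mean([int(l == p) for l, p in
                          zip(t["label"], t["predicted"])])
        assert accuracy(t) == pytest.approx(expect, abs=1e-12)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            accuracy(pd.DataFrame({"label": [], "predicted": [], "score": []}))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_from_arrays([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_from_arrays([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_exhaustive_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = 200
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)   # force some ties
            got = auc_from_arrays(labels, scores)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = ties = 0
            for sp in pos:
                for sn in neg:
                    wins += sp > sn
                    ties += sp == sn
            expect = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert abs(got - expect) < 1e-12

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, size=300)
        labels[:2] = [0, 1]
        scores = rng.random(300)
        a1 = auc_from_arrays(labels, scores)
        a2 = auc_from_arrays(labels, np.exp(3 * scores) + 7)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single-class"):
            auc_from_arrays([1, 1], [0.3, 0.4])

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        labels = rng.integers(0, 2, size=400)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(400), 2)
        assert auc_from_arrays(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestTopK:
    def test_precision_all_relevant(self):
        recs = {"q": [(f"p{i}", 1.0 - i / 20, 1) for i in range(10)]}
        assert precision_at_k(recs) == 1.0

    def test_precision_three_of_ten(self):
        recs = {"q": [(f"p{i}", 1.0 - i / 20, int(i < 3)) for i in range(15)]}
        assert precision_at_k(recs) == pytest.approx(0.3)

    def test_recall_closed_forms(self):
        recs = {"q1": [("a", 0.9, 1)] + [(f"b{i}", 0.1, 0) for i in range(12)],
                "q2": [(f"c{i}", 1 - i / 30, int(i < 2 or i > 10))
                       for i in range(14)]}
        # q1: 1/1; q2: 5 relevant (i in {0,1,11,12,13}), 2 in top 10 -> 0.4
        assert recall_at_k(recs) == pytest.approx(0.7)

    def test_ndcg_ideal_is_one(self):
        recs = {"q": [(f"p{i}", 1 - i / 20, int(i < 4)) for i in range(12)]}
        assert ndcg_at_k(recs) == pytest.approx(1.0)

    def test_ndcg_single_relevant_at_rank_two(self):
        recs = {"q": [("a", 0.9, 0), ("b", 0.8, 1), ("c", 0.7, 0)]}
        assert ndcg_at_k(recs) == pytest.approx(np.log(2) / np.log(3))

    def test_counting_oracles_on_random_tables(self, rng):
        recs = random_rec_table(rng, n_queries=100)
        k = 10
        p_vals, r_vals, n_vals = [], [], []
        for ranked in recs.values():
            rels = [r for _, _, r in ranked]
            top = rels[:k]
            p_vals.append(sum(top) / min(k, len(rels)))
            if sum(rels):
                r_vals.append(sum(top) / sum(rels))
                dcg = sum(r / np.log2(i + 2) for i, r in enumerate(top))
                idcg = sum(1 / np.log2(i + 2)
                           for i in range(min(sum(rels), k)))
                n_vals.append(dcg / idcg)
        assert precision_at_k(recs) == pytest.approx(np.mean(p_vals), abs=1e-12)
        assert recall_at_k(recs) == pytest.approx(np.mean(r_vals), abs=1e-12)
        assert ndcg_at_k(recs) == pytest.approx(np.mean(n_vals), abs=1e-12)

    def test_relabelling_invariance(self, rng):
        recs = random_rec_table(rng, n_queries=30)
        ren = {f"p{j:03d}": f"x{j:03d}" for j in range(60)}
        recs2 = {q: [(ren[p], s, r) for p, s, r in ranked]
                 for q, ranked in recs.items()}
        for fn in (precision_at_k, recall_at_k, ndcg_at_k):
            assert fn(recs) == pytest.approx(fn(recs2), abs=1e-12)


class TestBiasMetrics:
    def test_all_head_exposure(self, tier_map):
        recs = {"q": [(f"p{i:03d}", 1 - i / 20, 0) for i in range(5)]}
        ex = exposure_rate(recs, tier_map)
        assert ex == {"head": 1.0, "middle": 0.0, "tail": 0.0}

    def test_hand_counted_exposure(self, tier_map):
        # 2 queries x top-10 slots with 4 head among 20 -> head 0.2
        recs = {}
        for q in ("q1", "q2"):
            items = [(f"p{i:03d}", 1 - i / 40, 0) for i in range(3, 5)] + \
                    [(f"p{i:03d}", 0.5 - i / 100, 0) for i in range(30, 38)]
            recs[q] = items
        ex = exposure_rate(recs, tier_map)
        assert ex["head"] == pytest.approx(0.2)
        assert sum(ex.values()) == pytest.approx(1.0)

    def test_coverage_distinct_sets(self, tier_map):
        recs = {"q1": [("p000", 0.9, 0), ("p001", 0.8, 0), ("p030", 0.7, 0)],
                "q2": [("p000", 0.9, 0), ("p031", 0.6, 0), ("p032", 0.5, 0)]}
        cov = coverage_contribution(recs, tier_map)
        assert cov["head"] == pytest.approx(0.4)   # {p000,p001} of 5 distinct
        assert cov["tail"] == pytest.approx(0.6)

    def test_slot_and_set_counting_oracles(self, rng, tier_map):
        recs = random_rec_table(rng, n_queries=50)
        ex = exposure_rate(recs, tier_map)
        cov = coverage_contribution(recs, tier_map)
        slots = [tier_map[p] for ranked in recs.values()
                 for p, _, _ in ranked[:10]]
        seen = {p for ranked in recs.values() for p, _, _ in ranked[:10]}
        for t in ("head", "middle", "tail"):
            assert ex[t] == pytest.approx(
                sum(s == t for s in slots) / len(slots), abs=1e-12)
            assert cov[t] == pytest.approx(
                sum(tier_map[p] == t for p in seen) / len(seen), abs=1e-12)
        assert sum(ex.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(cov.values()) == pytest.approx(1.0, abs=1e-9)

    def test_unassigned_physician_raises(self):
        with pytest.raises(KeyError):
            exposure_rate({"q": [("zz", 0.5, 0)]}, {})
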