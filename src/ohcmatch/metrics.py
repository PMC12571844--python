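"""Evaluation metrics: classification, top-K ranking, popularity bias.

Two table shapes are used throughout:

* a **PredictionTable**: a DataFrame with columns ``query_id``,
  ``physician_id``, ``label``, ``score``, ``predicted`` (threshold 0.5) —
  one row per scored pair;
* a **RecommendationTable**: ``{query_id: [(physician_id, score,
  relevant), ...]}`` with each list already in rank order (score
  descending, ties by id ascending).

All ranking metrics are macro-averaged (each query weighted equally);
queries with no relevant candidate are excluded from recall/NDCG and
counted in the report.  AUC uses the Mann-Whitney rank statistic with the
0.5-tie convention.  Exposure rate is the share of top-K slots occupied by
a tier's physicians; coverage contribution is the share of distinct
recommended physicians belonging to the tier — each sums to 1 over tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def confusion(table: pd.DataFrame) -> dict[str, int]:
    y = table["label"].to_numpy()
    p = table["predicted"].to_numpy()
    return {"TP": int(((y == 1) & (p == 1)).sum()),
            "FP": int(((y == 0) & (p == 1)).sum()),
            "FN": int(((y == 1) & (p == 0)).sum()),
            "TN": int(((y == 0) & (p == 0)).sum())}


def accuracy(table: pd.DataFrame) -> float:
    """(TP + TN) / (TP + FP + FN + TN)."""
    if len(table) == 0:
        raise ValueError("accuracy of an empty prediction table")
    c = confusion(table)
    return (c["TP"] + c["TN"]) / len(table)


def auc_from_arrays(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class table")
    # average ranks handle ties with the 0.5 convention
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=np.float64)
    ranks[order] = np.arange(1, len(scores) + 1)
    _, inv, counts = np.unique(scores, return_inverse=True, return_counts=True)
    sums = np.zeros(len(counts))
    np.add.at(sums, inv, ranks)
    ranks = sums[inv] / counts[inv]
    r_pos = ranks[pos].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def auc(table: pd.DataFrame) -> float:
    return auc_from_arrays(table["label"].to_numpy(), table["score"].to_numpy())


# ---------------------------------------------------------------------------
# top-K ranking metrics
# ---------------------------------------------------------------------------

RecTable = dict[str, list[tuple[str, float, int]]]


def precision_at_k(recs: RecTable, k: int = 10) -> float:
    """Macro-averaged |relevant in top k| / min(k, list length)."""
    if not recs:
        raise ValueError("empty recommendation table")
    vals = []
    for ranked in recs.values():
        top = ranked[:k]
        vals.append(sum(rel for _, _, rel in top) / min(k, len(ranked)))
    return float(np.mean(vals))


def recall_at_k(recs: RecTable, k: int = 10) -> float:
    """Macro-averaged |relevant in top k| / |relevant|; queries with no
    relevant candidate are excluded."""
    vals = []
    for ranked in recs.values():
        n_rel = sum(rel for _, _, rel in ranked)
        if n_rel == 0:
            continue
        vals.append(sum(rel for _, _, rel in ranked[:k]) / n_rel)
    if not vals:
        raise ValueError("no query has a relevant candidate")
    return float(np.mean(vals))


def ndcg_at_k(recs: RecTable, k: int = 10) -> float:
    """Binary-relevance NDCG with log2 position discount."""
    vals = []
    for ranked in recs.values():
        rels = [rel for _, _, rel in ranked]
        n_rel = sum(rels)
        if n_rel == 0:
            continue
        dcg = sum(rel / np.log2(i + 2) for i, rel in enumerate(rels[:k]))
        idcg = sum(1.0 / np.log2(i + 2) for i in range(min(n_rel, k)))
        vals.append(dcg / idcg)
    if not vals:
        raise ValueError("no query has a relevant candidate")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# popularity-bias metrics
# ---------------------------------------------------------------------------

def exposure_rate(recs: RecTable, tiers: dict[str, str], k: int = 10
                  ) -> dict[str, float]:
    """Share of top-K recommendation slots occupied by each tier."""
    slots: dict[str, int] = {"head": 0, "middle": 0, "tail": 0}
    total = 0
    for ranked in recs.values():
        for pid, _, _ in ranked[:k]:
            if pid not in tiers:
                raise KeyError(f"physician {pid} has no tier assignment")
            slots[tiers[pid]] += 1
            total += 1
    if total == 0:
        raise ValueError("no recommendation slots")
    return {t: slots[t] / total for t in slots}


def coverage_contribution(recs: RecTable, tiers: dict[str, str], k: int = 10
                          ) -> dict[str, float]:
    """Share of distinct recommended physicians belonging to each tier."""
    seen: set[str] = set()
    for ranked in recs.values():
        seen.update(pid for pid, _, _ in ranked[:k])
    if not seen:
        raise ValueError("no physicians recommended")
    out = {"head": 0, "middle": 0, "tail": 0}
    for pid in seen:
        if pid not in tiers:
            raise KeyError(f"physician {pid} has no tier assignment")
        out[tiers[pid]] += 1
    return {t: out[t] / len(seen) for t in out}


def tier_recall_at_k(recs: RecTable, tiers: dict[str, str], k: int = 10
                     ) -> dict[str, float]:
    """Recall@k restricted to relevant physicians of each tier."""
    out = {}
    for tier in ("head", "middle", "tail"):
        vals = []
        for ranked in recs.values():
            rel_tier = [pid for pid, _, rel in ranked
                        if rel and tiers[pid] == tier]
            if not rel_tier:
                continue
            got = sum(1 for pid, _, rel in ranked[:k]
                      if rel and tiers[pid] == tier)
            vals.append(got / len(rel_tier))
        out[tier] = float(np.mean(vals)) if vals else float("nan")
    return out


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-subset classification + ranking + per-tier bias metrics."""

    subset: str
    classification: dict[str, dict[str, float]]   # all/cold/warm -> ACC/AUC/n
    ranking: dict[str, float]                     # P@k / R@k / NDCG@k
    tier_exposure: dict[str, float] = field(default_factory=dict)
    tier_coverage: dict[str, float] = field(default_factory=dict)
    tier_recall: dict[str, float] = field(default_factory=dict)
    n_queries: int = 0
    n_excluded_no_relevant: int = 0

    def to_dict(self) -> dict:
        return {"subset": self.subset, "classification": self.classification,
                "ranking": self.ranking, "tier_exposure": self.tier_exposure,
                "tier_coverage": self.tier_coverage,
                "tier_recall": self.tier_recall,
                "n_queries": self.n_queries,
                "n_excluded_no_relevant": self.n_excluded_no_relevant}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for part, vals in self.classification.items():
            for metric, v in vals.items():
                rows.append({"group": part, "metric": metric, "value": v})
        for metric, v in self.ranking.items():
            rows.append({"group": "ranking", "metric": metric, "value": v})
        for name, d in (("exposure", self.tier_exposure),
                        ("coverage", self.tier_coverage),
                        ("tier_recall", self.tier_recall)):
            for tier, v in d.items():
                rows.append({"group": tier, "metric": name, "value": v})
        return pd.DataFrame(rows)


def compute_report(results, subset: str = "test", augment: bool = True,
                   tiers: dict[str, str] | None = None,
                   seed: int | None = None, k: int | None = None
                   ) -> MetricReport:
    """Assemble a MetricReport from a fitted :class:`MatchingResults`."""
    from .corpus import assign_tiers
    k = results.model.train_config.k if k is None else k

    classification = {}
    for part in ("all", "cold", "warm"):
        name = subset if part == "all" else f"{subset}:{part}"
        inter = results._subset_interactions(name)
        if not inter:
            continue
        table = results.predictions(name, augment=augment)
        entry = {"n": len(table), "acc": accuracy(table)}
        labels = table["label"].to_numpy()
        entry["auc"] = (auc(table) if 0 < labels.sum() < len(labels)
                        else float("nan"))
        classification[part] = entry

    recs = results.recommendations(subset, augment=augment, seed=seed)
    ranking = {}
    n_excluded = 0
    if recs:
        ranking = {f"precision_at_{k}": precision_at_k(recs, k),
                   f"recall_at_{k}": recall_at_k(recs, k),
                   f"ndcg_at_{k}": ndcg_at_k(recs, k)}
        n_excluded = sum(1 for ranked in recs.values()
                         if not any(rel for _, _, rel in ranked))
    report = MetricReport(subset=subset, classification=classification,
                          ranking=ranking, n_queries=len(recs),
                          n_excluded_no_relevant=n_excluded)
    if recs:
        if tiers is None:
            tiers = assign_tiers(results.model.corpus.physicians)
        report.tier_exposure = exposure_rate(recs, tiers, k)
        report.tier_coverage = coverage_contribution(recs, tiers, k)
        report.tier_recall = tier_recall_at_k(recs, tiers, k)
    return report
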