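"""Corpus data model, JSON-lines I/O, vocabulary, splits and popularity tiers.

A corpus of an online health Q&A community consists of three record kinds:

* :class:`PatientQuery` — one consultation request (title/content token
  sequences, profile fields, semantic tags, day index),
* :class:`PhysicianProfile` — credentials plus a time-stamped reply history,
* :class:`Interaction` — a supervised (query, physician, adopted?) pair.

Storage is JSON-lines, one record per line, discriminated by ``record_type``.
Tokenization is out of scope: records carry pre-tokenized sequences, and the
synthetic generator emits tokens directly.  A pluggable tokenizer hook can be
applied upstream of this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable

import numpy as np

PAD, UNK, NULL_TOKEN = "<pad>", "<unk>", "<null>"

#: physicians with fewer replies than this are "cold" (sparse history)
DEFAULT_COLD_THRESHOLD = 5

#: head / middle / tail population shares used for popularity auditing
TIER_FRACTIONS = {"head": 0.10, "middle": 0.40, "tail": 0.50}


class CorpusError(ValueError):
    """Malformed or invariant-violating corpus content."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class PatientQuery:
    query_id: str
    title_tokens: list[str]
    content_tokens: list[str]
    profile: dict = field(default_factory=dict)
    tag_ids: list[tuple[int, int]] = field(default_factory=list)
    timestamp: int = 0

    def __post_init__(self):
        if not self.title_tokens:
            raise CorpusError(f"query {self.query_id}: empty title")
        self.tag_ids = [tuple(t) for t in self.tag_ids]
        prof = dict(self.profile)
        for key in ("gender", "region", "disease"):
            if prof.get(key) in (None, ""):
                prof[key] = "Unknown"
        prof.setdefault("age", None)
        prof.setdefault("history_flags", [])
        prof["history_flags"] = sorted(prof["history_flags"])
        self.profile = prof


@dataclass
class PhysicianProfile:
    physician_id: str
    title_rank: str
    hospital_tier: str
    specialty_id: str
    reply_history: list[tuple[int, list[str]]] = field(default_factory=list)

    def __post_init__(self):
        self.reply_history = [(int(d), list(toks)) for d, toks in self.reply_history]
        days = [d for d, _ in self.reply_history]
        if days != sorted(days):
            raise CorpusError(
                f"physician {self.physician_id}: reply_history not sorted by day")

    @property
    def reply_count(self) -> int:
        return len(self.reply_history)

    def is_cold(self, threshold: int = DEFAULT_COLD_THRESHOLD) -> bool:
        return self.reply_count < threshold


@dataclass
class Interaction:
    query_id: str
    physician_id: str
    label: int
    timestamp: int = 0

    def __post_init__(self):
        if self.label not in (0, 1):
            raise CorpusError(
                f"interaction ({self.query_id},{self.physician_id}): "
                f"label {self.label!r} not binary")
        self.label = int(self.label)


@dataclass
class Corpus:
    queries: dict[str, PatientQuery]
    physicians: dict[str, PhysicianProfile]
    interactions: list[Interaction]

    def __post_init__(self):
        seen = set()
        for it in self.interactions:
            key = (it.query_id, it.physician_id)
            if key in seen:
                raise CorpusError(f"duplicate interaction pair {key}")
            seen.add(key)
            if it.query_id not in self.queries:
                raise CorpusError(f"interaction references unknown query {it.query_id}")
            if it.physician_id not in self.physicians:
                raise CorpusError(
                    f"interaction references unknown physician {it.physician_id}")


# ---------------------------------------------------------------------------
# JSON-lines round trip
# ---------------------------------------------------------------------------

def _query_to_json(q: PatientQuery) -> dict:
    return {"record_type": "query", "query_id": q.query_id,
            "title_tokens": q.title_tokens, "content_tokens": q.content_tokens,
            "profile": {**q.profile, "history_flags": list(q.profile["history_flags"])},
            "tag_ids": [list(t) for t in q.tag_ids], "timestamp": q.timestamp}


def _physician_to_json(p: PhysicianProfile) -> dict:
    return {"record_type": "physician", "physician_id": p.physician_id,
            "title_rank": p.title_rank, "hospital_tier": p.hospital_tier,
            "specialty_id": p.specialty_id,
            "reply_history": [[d, toks] for d, toks in p.reply_history]}


def write_corpus(path, corpus: Corpus) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in corpus.queries.values():
            fh.write(json.dumps(_query_to_json(q), ensure_ascii=False) + "\n")
        for p in corpus.physicians.values():
            fh.write(json.dumps(_physician_to_json(p), ensure_ascii=False) + "\n")
        for it in corpus.interactions:
            fh.write(json.dumps({
                "record_type": "interaction", "query_id": it.query_id,
                "physician_id": it.physician_id, "label": it.label,
                "timestamp": it.timestamp}, ensure_ascii=False) + "\n")


_KNOWN_FIELDS = {
    "query": {"query_id", "title_tokens", "content_tokens", "profile",
              "tag_ids", "timestamp"},
    "physician": {"physician_id", "title_rank", "hospital_tier", "specialty_id",
                  "reply_history"},
    "interaction": {"query_id", "physician_id", "label", "timestamp"},
}


def read_corpus(path) -> Corpus:
    """Parse a JSON-lines corpus file, enforcing record invariants.

    Unknown fields are preserved-by-ignoring; malformed lines raise
    :class:`CorpusError` naming the line number, duplicate ids raise naming
    the id.
    """
    queries: dict[str, PatientQuery] = {}
    physicians: dict[str, PhysicianProfile] = {}
    interactions: list[Interaction] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            rtype = rec.get("record_type")
            if rtype not in _KNOWN_FIELDS:
                raise CorpusError(f"line {lineno}: unknown record_type {rtype!r}")
            kwargs = {k: v for k, v in rec.items() if k in _KNOWN_FIELDS[rtype]}
            try:
                if rtype == "query":
                    q = PatientQuery(**kwargs)
                    if q.query_id in queries:
                        raise CorpusError(f"duplicate query_id {q.query_id!r}")
                    queries[q.query_id] = q
                elif rtype == "physician":
                    p = PhysicianProfile(
                        **{**kwargs, "reply_history":
                           [(d, toks) for d, toks in kwargs.get("reply_history", [])]})
                    if p.physician_id in physicians:
                        raise CorpusError(f"duplicate physician_id {p.physician_id!r}")
                    physicians[p.physician_id] = p
                else:
                    interactions.append(Interaction(**kwargs))
            except TypeError as exc:
                raise CorpusError(f"line {lineno}: {exc}") from exc
    if not queries and not physicians and not interactions:
        raise CorpusError("empty corpus file")
    return Corpus(queries, physicians, interactions)


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

class Vocab:
    """Token alphabet with reserved ``<pad>`` (0) and ``<unk>`` (1) ids.

    Ids are assigned by corpus frequency (descending), ties broken
    lexicographically, so construction is deterministic.  A ``<null>`` token
    is always present (used by the ablation harness to blank out an input
    field with a learned embedding).
    """

    def __init__(self, token_to_id: dict[str, int]):
        self.token_to_id = token_to_id
        self.id_to_token = {i: t for t, i in token_to_id.items()}
        self.pad_id, self.unk_id = 0, 1
        self.null_id = token_to_id[NULL_TOKEN]

    def __len__(self) -> int:
        return len(self.token_to_id)

    def lookup(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def encode(self, tokens: Iterable[str]) -> list[int]:
        t2i, unk = self.token_to_id, self.unk_id
        return [t2i.get(t, unk) for t in tokens]


def iter_corpus_tokens(corpus: Corpus):
    from .encoders import profile_tokens, tag_tokens, credential_tokens
    for q in corpus.queries.values():
        yield from q.title_tokens
        yield from q.content_tokens
        yield from profile_tokens(q)
        yield from tag_tokens(q)
    for p in corpus.physicians.values():
        yield from credential_tokens(p)
        for _, toks in p.reply_history:
            yield from toks


def build_vocab(corpus: Corpus, min_count: int = 1) -> Vocab:
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = Counter(iter_corpus_tokens(corpus))
    counts.pop(PAD, None)
    counts.pop(UNK, None)
    counts.pop(NULL_TOKEN, None)
    if not counts:
        raise CorpusError("cannot build a vocabulary from an empty corpus")
    kept = sorted((t for t, c in counts.items() if c >= min_count),
                  key=lambda t: (-counts[t], t))
    token_to_id = {PAD: 0, UNK: 1, NULL_TOKEN: 2}
    for i, t in enumerate(kept, start=3):
        token_to_id[t] = i
    return Vocab(token_to_id)


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train: list[Interaction]
    validation: list[Interaction]
    test: list[Interaction]
    cold_mask: dict[str, bool]  # interaction key -> physician is cold

    @staticmethod
    def key(it: Interaction) -> str:
        return f"{it.query_id}\t{it.physician_id}"


def split_dataset(interactions: list[Interaction], corpus: Corpus,
                  ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0,
                  cold_threshold: int = DEFAULT_COLD_THRESHOLD) -> DatasetSplit:
    """Seed-reproducible shuffle + 6:2:2 partition into train/validation/test."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios {ratios} do not sum to 1")
    if len(interactions) < 5:
        raise ValueError("need at least 5 interactions to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(interactions))
    n = len(interactions)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    shuffled = [interactions[i] for i in order]
    train = shuffled[:n_train]
    validation = shuffled[n_train:n_train + n_val]
    test = shuffled[n_train + n_val:]
    cold_mask = {
        DatasetSplit.key(it):
            corpus.physicians[it.physician_id].is_cold(cold_threshold)
        for it in interactions}
    return DatasetSplit(train, validation, test, cold_mask)


# ---------------------------------------------------------------------------
# popularity tiers
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: list[float]) -> list[int]:
    raw = [f * n for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    # distribute leftover units to the largest fractional remainders
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def assign_tiers(physicians: dict[str, PhysicianProfile]) -> dict[str, str]:
    """Head/middle/tail (10/40/50%) assignment by reply volume.

    Sorting is by (reply_count desc, physician_id asc) so the assignment is
    invariant to input ordering; tier sizes follow largest-remainder rounding.
    """
    if len(physicians) < 10:
        raise ValueError("tier assignment needs at least 10 physicians")
    ranked = sorted(physicians.values(),
                    key=lambda p: (-p.reply_count, p.physician_id))
    names = list(TIER_FRACTIONS)
    sizes = _largest_remainder(len(ranked), [TIER_FRACTIONS[t] for t in names])
    out: dict[str, str] = {}
    idx = 0
    for tier, size in zip(names, sizes):
        for p in ranked[idx:idx + size]:
            out[p.physician_id] = tier
        idx += size
    return out
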