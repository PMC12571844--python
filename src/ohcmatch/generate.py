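"""Seeded synthetic online-health-community corpus generator.

The generator makes the matching problem's latent structure explicit: every
patient query and every physician carries one latent medical specialty, and
adoption labels depend only on whether the two specialties agree
(``Bernoulli(match_prob_same)`` vs ``Bernoulli(match_prob_diff)``).  Text
fields carry the specialty signal through their vocabulary: each token is
drawn from the entity's specialty-specific vocabulary with probability
``signal_strength`` and from a shared noise vocabulary otherwise.  Semantic
tags point at the specialty's major category with the same probability, and
the profile ``disease`` field is drawn from a specialty-linked disease pool
— so title, content, tags and profile all carry recoverable signal, while
region/gender/age are pure noise.

Structural statistics mimic a real community: titles average 15 tokens and
content 128 (Poisson, clipped to at least 1), the tag taxonomy has 8 major
and 32 minor categories, physician activity is Zipf-skewed, and reply
histories span a multi-month horizon so a 15-day recency window truncates
meaningfully.  Replies average 32 tokens (physician answers are typically
shorter than question bodies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Interaction, PatientQuery, PhysicianProfile

N_MAJOR, N_MINOR_PER_MAJOR = 8, 4   # 8 major / 32 minor tag categories

TITLE_RANKS = ["Chief", "AssociateChief", "Attending"]
TITLE_RANK_P = [0.2, 0.3, 0.5]
HOSPITAL_TIERS = ["3A", "3B", "2A", "2B"]
HOSPITAL_TIER_P = [0.35, 0.25, 0.25, 0.15]


@dataclass
class GeneratorConfig:
    n_specialties: int = 4
    n_patients: int = 1000
    n_physicians: int = 100
    n_interactions: int = 4000
    vocab_per_specialty: int = 50
    shared_noise_vocab: int = 200
    signal_strength: float = 0.7     # P(token comes from the specialty vocabulary)
    match_prob_same: float = 0.85    # adoption probability, matched specialties
    match_prob_diff: float = 0.10    # adoption probability, mismatched
    popularity_skew: float = 1.1     # Zipf exponent for physician activity
    horizon_days: int = 120
    title_len_mean: float = 15.0
    content_len_mean: float = 128.0
    reply_len_mean: float = 32.0
    mean_replies: float = 24.0       # corpus-average replies per physician
    min_replies: int = 5             # base corpus keeps every physician warm
    diseases_per_specialty: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("signal_strength", "match_prob_same", "match_prob_diff"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.match_prob_same <= self.match_prob_diff:
            raise ValueError("match_prob_same must exceed match_prob_diff "
                             "for a learnable corpus")
        if self.n_specialties > N_MAJOR:
            raise ValueError(f"at most {N_MAJOR} specialties (one per major "
                             "tag category)")
        if min(self.n_patients, self.n_physicians, self.n_interactions) < 1:
            raise ValueError("corpus sizes must be positive")
        if self.vocab_per_specialty < 1 or self.shared_noise_vocab < 1:
            raise ValueError("vocabulary sizes must be positive")


@dataclass
class LatentAssignment:
    """Ground-truth specialties, kept out of the corpus file on purpose."""
    query_specialty: dict[str, int] = field(default_factory=dict)
    physician_specialty: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"query_specialty": self.query_specialty,
                       "physician_specialty": self.physician_specialty}, fh)

    @classmethod
    def from_json(cls, path) -> "LatentAssignment":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["query_specialty"], raw["physician_specialty"])


def _draw_tokens(rng, spec: int, n: int, cfg: GeneratorConfig) -> list[str]:
    from_spec = rng.random(n) < cfg.signal_strength
    spec_ids = rng.integers(0, cfg.vocab_per_specialty, size=n)
    noise_ids = rng.integers(0, cfg.shared_noise_vocab, size=n)
    return [f"s{spec}w{spec_ids[i]}" if from_spec[i] else f"nw{noise_ids[i]}"
            for i in range(n)]


def _draw_len(rng, mean: float) -> int:
    return max(1, int(rng.poisson(mean)))


def _draw_tags(rng, spec: int, cfg: GeneratorConfig) -> list[tuple[int, int]]:
    n_tags = int(rng.integers(1, 4))
    tags = set()
    for _ in range(n_tags):
        if rng.random() < cfg.signal_strength:
            major = spec + 1                      # specialty's own major category
        else:
            major = int(rng.integers(1, N_MAJOR + 1))
        minor = int(rng.integers(1, N_MINOR_PER_MAJOR + 1))
        tags.add((major, minor))
    return sorted(tags)


def _draw_profile(rng, spec: int, cfg: GeneratorConfig) -> dict:
    if rng.random() < cfg.signal_strength:
        disease_spec = spec
    else:
        disease_spec = int(rng.integers(0, cfg.n_specialties))
    disease = f"d{disease_spec}_{int(rng.integers(0, cfg.diseases_per_specialty))}"
    age = int(np.clip(rng.normal(45, 16), 0, 99)) if rng.random() > 0.05 else None
    flags = [f"flag{int(i)}" for i in
             rng.choice(6, size=int(rng.integers(0, 3)), replace=False)]
    return {"age": age,
            "gender": rng.choice(["M", "F", "Unknown"], p=[0.45, 0.45, 0.10]),
            "region": f"R{int(rng.integers(1, 9))}",
            "disease": disease,
            "history_flags": sorted(flags)}


def _zipf_reply_counts(rng, cfg: GeneratorConfig) -> np.ndarray:
    """Zipf-skewed activity: counts proportional to rank^(-skew), scaled to
    the requested corpus average, floored at ``min_replies``."""
    ranks = np.arange(1, cfg.n_physicians + 1, dtype=float)
    weights = ranks ** (-cfg.popularity_skew)
    weights /= weights.sum()
    total = cfg.mean_replies * cfg.n_physicians
    counts = np.maximum(np.round(weights * total).astype(int), cfg.min_replies)
    return rng.permutation(counts)   # activity rank decoupled from id order


def generate_corpus(cfg: GeneratorConfig
                    ) -> tuple[Corpus, LatentAssignment]:
    """Generate a fully reproducible corpus with known latent specialties."""
    rng = np.random.default_rng(cfg.seed)
    latent = LatentAssignment()

    queries: dict[str, PatientQuery] = {}
    for i in range(cfg.n_patients):
        qid = f"q{i:05d}"
        spec = int(rng.integers(0, cfg.n_specialties))
        latent.query_specialty[qid] = spec
        queries[qid] = PatientQuery(
            query_id=qid,
            title_tokens=_draw_tokens(rng, spec, _draw_len(rng, cfg.title_len_mean), cfg),
            content_tokens=_draw_tokens(rng, spec, _draw_len(rng, cfg.content_len_mean), cfg),
            profile=_draw_profile(rng, spec, cfg),
            tag_ids=_draw_tags(rng, spec, cfg),
            timestamp=int(rng.integers(0, cfg.horizon_days)),
        )

    physicians: dict[str, PhysicianProfile] = {}
    reply_counts = _zipf_reply_counts(rng, cfg)
    for i in range(cfg.n_physicians):
        pid = f"p{i:04d}"
        spec = int(rng.integers(0, cfg.n_specialties))
        latent.physician_specialty[pid] = spec
        days = np.sort(rng.integers(0, cfg.horizon_days, size=reply_counts[i]))
        history = [(int(d),
                    _draw_tokens(rng, spec, _draw_len(rng, cfg.reply_len_mean), cfg))
                   for d in days]
        physicians[pid] = PhysicianProfile(
            physician_id=pid,
            title_rank=str(rng.choice(TITLE_RANKS, p=TITLE_RANK_P)),
            hospital_tier=str(rng.choice(HOSPITAL_TIERS, p=HOSPITAL_TIER_P)),
            specialty_id=f"S{spec}",
            reply_history=history,
        )

    qids = list(queries)
    by_spec: dict[int, list[str]] = {}
    for pid, spec in latent.physician_specialty.items():
        by_spec.setdefault(spec, []).append(pid)
    all_pids = list(physicians)

    interactions: list[Interaction] = []
    used: set[tuple[str, str]] = set()
    attempts = 0
    while len(interactions) < cfg.n_interactions:
        attempts += 1
        if attempts > 50 * cfg.n_interactions:
            raise ValueError("infeasible config: cannot sample enough "
                             "distinct (query, physician) pairs")
        qid = qids[int(rng.integers(0, len(qids)))]
        qspec = latent.query_specialty[qid]
        want_match = (len(interactions) % 2 == 0)   # ~50/50 matched pairs
        if want_match:
            pool = by_spec.get(qspec, [])
            if not pool:
                raise ValueError("infeasible config: a specialty has no physicians")
            pid = pool[int(rng.integers(0, len(pool)))]
        else:
            pid = all_pids[int(rng.integers(0, len(all_pids)))]
            if latent.physician_specialty[pid] == qspec:
                continue
        if (qid, pid) in used:
            continue
        used.add((qid, pid))
        p_adopt = (cfg.match_prob_same if latent.physician_specialty[pid] == qspec
                   else cfg.match_prob_diff)
        interactions.append(Interaction(
            query_id=qid, physician_id=pid,
            label=int(rng.random() < p_adopt),
            timestamp=queries[qid].timestamp))

    return Corpus(queries, physicians, interactions), latent


def make_cold_corpus(cfg: GeneratorConfig, fraction: float = 0.3,
                     cold_threshold: int = 5
                     ) -> tuple[Corpus, LatentAssignment, list[str]]:
    """Corpus where exactly ``ceil(fraction * n_physicians)`` physicians have
    0..cold_threshold-1 replies; their credentials keep the specialty signal.

    Returns ``(corpus, latent, cold_physician_ids)``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("cold fraction must be in (0, 1)")
    corpus, latent = generate_corpus(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC01D]))
    n_cold = int(np.ceil(fraction * cfg.n_physicians))
    cold_ids = sorted(rng.choice(sorted(corpus.physicians), size=n_cold,
                                 replace=False).tolist())
    for pid in cold_ids:
        p = corpus.physicians[pid]
        keep = int(rng.integers(0, cold_threshold))
        # keep the most recent `keep` replies so days stay sorted
        p.reply_history = p.reply_history[len(p.reply_history) - keep:]
    return corpus, latent, cold_ids
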