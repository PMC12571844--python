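"""Dual-channel patient-physician matching model.

The model follows the statsmodels idiom: :class:`ExpertMatchingModel` is
constructed from a corpus plus a train/validation/test split and a
configuration; :meth:`ExpertMatchingModel.fit` runs mini-batch training
(binary cross-entropy, Adam, batch 256, learning rate 0.01, at most four
epochs with early stopping on validation AUC) and returns a
:class:`MatchingResults` carrying the fitted parameters, the per-epoch log,
and evaluation / ranking / summary methods.

Architecture
------------
Patient channel: four token fields (title, content, profile, tags), each
embedded, convolved (width-3 windows, ReLU), attention-pooled, then
concatenated and affinely projected to a 128-dim patient vector ``e``.
Physician channel: credential tokens through the same field encoder give
``r_s``; the recent-window reply sequence is per-reply field-encoded, run
through a Bi-GRU whose directional states are averaged per step, and
attention-pooled into ``r_d``; ``r = [r_s, r_d]`` (128-dim).  The score is
``sigmoid(FC([e, r]))`` with a depth-4 fully connected stack on the 256-dim
joint vector.

Cold-start augmentation is part of the input pipeline: a physician whose
recency window is empty reads a credential-keyed surrogate temporal vector
(:class:`ColdStartAugmenter`) built from warm physicians' encodings — during
training the knowledge base is rebuilt from the current parameters each
epoch.  ``augment=False`` on the results surface substitutes zeros instead
(the baseline for the cold-start contrast experiment).

Training runs batched in ``float32`` on the autodiff graph of
:mod:`ohcmatch.nn`; the per-item ``float64`` pipeline in
:mod:`ohcmatch.encoders` / :mod:`ohcmatch.history` is the reference path the
tests hold this graph to.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .config import ModelConfig, TrainConfig, config_hash
from .corpus import (Corpus, DatasetSplit, Interaction, PatientQuery,
                     PhysicianProfile, Vocab, build_vocab, split_dataset)
from .encoders import (ConvAttnParams, credential_tokens, encode_field,
                       max_pool, pad_or_truncate, profile_tokens, tag_tokens)
from .history import GruParams, attend_history, bigru, select_recent

FIELD_NAMES = ("title", "content", "profile", "tags", "credentials", "reply")
MAX_CRED_LEN = 8


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape).astype(nn.DTYPE)


def _he(rng, shape):
    """Kaiming-uniform for ReLU layers: preserves activation scale so the
    scoring head emits O(1) logits at initialization (important here — the
    training budget is only a few epochs)."""
    limit = np.sqrt(6.0 / shape[0])
    return rng.uniform(-limit, limit, size=shape).astype(nn.DTYPE)


class ModelParams:
    """All trainable tensors plus the vocabulary and configuration."""

    def __init__(self, vocab: Vocab, cfg: ModelConfig, seed: int = 0):
        self.vocab = vocab
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 11]))
        V, de, dc, dh, dm = len(vocab), cfg.d_emb, cfg.d_conv, cfg.d_h, cfg.d_match
        win = 2 * cfg.half_window + 1

        emb = rng.uniform(-0.87, 0.87, size=(V, de)).astype(nn.DTYPE)
        emb[vocab.pad_id] = 0.0
        self.emb = nn.Parameter(emb, "emb")

        self.fields: dict[str, dict[str, nn.Parameter]] = {}
        base = None
        for name in FIELD_NAMES:
            if cfg.shared_field_params and base is not None:
                self.fields[name] = base
                continue
            fp = {"W_c": nn.Parameter(_he(rng, (win * de, dc)), f"{name}.W_c"),
                  "b_c": nn.Parameter(np.zeros(dc, nn.DTYPE), f"{name}.b_c"),
                  "v": nn.Parameter(_glorot(rng, (dc, 1)).ravel(), f"{name}.v"),
                  "v_b": nn.Parameter(np.zeros(1, nn.DTYPE), f"{name}.v_b")}
            self.fields[name] = fp
            base = fp

        pool_mult = 2 if cfg.maxpool_branch else 1
        self.W_p = nn.Parameter(_glorot(rng, (4 * dc * pool_mult, dm)), "W_p")
        self.b_p = nn.Parameter(np.zeros(dm, nn.DTYPE), "b_p")

        self.gru: dict[str, dict[str, nn.Parameter]] = {}
        for direction in ("fwd", "bwd"):
            self.gru[direction] = {
                g: nn.Parameter(_glorot(rng, (dh + dc * pool_mult, dh)),
                                f"gru_{direction}.{g}")
                for g in ("W_z", "W_r", "W")}

        d_hist = 2 * dh if cfg.history_concat else dh
        self.v_h = nn.Parameter(_glorot(rng, (d_hist, 1)).ravel(), "v_h")
        self.v_hb = nn.Parameter(np.zeros(1, nn.DTYPE), "v_hb")

        d_phys = dc * pool_mult + d_hist
        if d_phys == dm:
            self.W_r, self.b_r = None, None          # identity projection
        else:
            self.W_r = nn.Parameter(_glorot(rng, (d_phys, dm)), "W_r")
            self.b_r = nn.Parameter(np.zeros(dm, nn.DTYPE), "b_r")

        widths = [2 * dm]
        for _ in range(cfg.fc_depth - 1):
            widths.append(max(8, widths[-1] // 2))
        widths.append(1)
        self.head = [(nn.Parameter(_he(rng, (widths[i], widths[i + 1])),
                                   f"head{i}.W"),
                      nn.Parameter(np.zeros(widths[i + 1], nn.DTYPE), f"head{i}.b"))
                     for i in range(len(widths) - 1)]
        # the inner-product score path starts live (weight 1): it gives the
        # two channels a direct alignment gradient, which is what lets the
        # model latch on within the few-epoch training budget
        self.w_dot = (nn.Parameter(np.ones(1, nn.DTYPE), "w_dot")
                      if cfg.dot_score_term else None)

    # -- bookkeeping ------------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        out, seen = [], set()
        cand = [self.emb, self.W_p, self.b_p, self.v_h, self.v_hb]
        for fp in self.fields.values():
            cand += list(fp.values())
        for d in self.gru.values():
            cand += list(d.values())
        for W, b in self.head:
            cand += [W, b]
        if self.W_r is not None:
            cand += [self.W_r, self.b_r]
        if self.w_dot is not None:
            cand.append(self.w_dot)
        for p in cand:
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def copy_state(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data = state[p.name].copy()

    # -- per-item float64 views (reference pipeline) ----------------------
    def conv_attn(self, field: str) -> ConvAttnParams:
        fp = self.fields[field]
        return ConvAttnParams(W_c=fp["W_c"].data.astype(np.float64),
                              b_c=fp["b_c"].data.astype(np.float64),
                              v=fp["v"].data.astype(np.float64),
                              v_b=float(fp["v_b"].data[0]),
                              M=self.cfg.half_window)

    def gru_params(self, direction: str) -> GruParams:
        d = self.gru[direction]
        return GruParams(W_z=d["W_z"].data.astype(np.float64),
                         W_r=d["W_r"].data.astype(np.float64),
                         W=d["W"].data.astype(np.float64))

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {p.name: p.data for p in self.parameters()}
        meta = {"vocab": self.vocab.token_to_id,
                "config": self.cfg.__dict__ | {
                    "patient_fields": list(self.cfg.patient_fields),
                    "physician_sources": list(self.cfg.physician_sources)},
                "hash": config_hash(self.cfg)}
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "ModelParams":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = ModelConfig(**meta["config"])
            vocab = Vocab(meta["vocab"])
            obj = cls(vocab, cfg, seed=0)
            for p in obj.parameters():
                p.data = data[p.name].copy()
        return obj


# ---------------------------------------------------------------------------
# corpus encoding (token ids, masks, reply windows)
# ---------------------------------------------------------------------------

class EncodedCorpus:
    """Integer-id views of a corpus under a vocabulary and length policy."""

    def __init__(self, corpus: Corpus, vocab: Vocab, cfg: ModelConfig):
        self.corpus, self.vocab, self.cfg = corpus, vocab, cfg
        self.q_index = {qid: i for i, qid in enumerate(corpus.queries)}
        self.p_index = {pid: i for i, pid in enumerate(corpus.physicians)}
        nq, npy = len(self.q_index), len(self.p_index)
        lens = {"title": cfg.max_title_len, "content": cfg.max_content_len,
                "profile": cfg.max_profile_len, "tags": cfg.max_tags_len}
        self.field_ids = {f: np.zeros((nq, L), np.int64) for f, L in lens.items()}
        self.field_mask = {f: np.zeros((nq, L), bool) for f, L in lens.items()}
        for qid, q in corpus.queries.items():
            i = self.q_index[qid]
            toks = {"title": q.title_tokens, "content": q.content_tokens,
                    "profile": profile_tokens(q), "tags": tag_tokens(q)}
            for f, L in lens.items():
                ids, mask = pad_or_truncate(vocab.encode(toks[f]), L, vocab.pad_id)
                self.field_ids[f][i], self.field_mask[f][i] = ids, mask

        self.cred_ids = np.zeros((npy, MAX_CRED_LEN), np.int64)
        self.cred_mask = np.zeros((npy, MAX_CRED_LEN), bool)
        reply_rows, reply_days, offsets = [], [], {}
        for pid, p in corpus.physicians.items():
            j = self.p_index[pid]
            ids, mask = pad_or_truncate(vocab.encode(credential_tokens(p)),
                                        MAX_CRED_LEN, vocab.pad_id)
            self.cred_ids[j], self.cred_mask[j] = ids, mask
            start = len(reply_rows)
            for day, toks in p.reply_history:
                reply_rows.append(vocab.encode(toks))
                reply_days.append(day)
            offsets[j] = (start, len(reply_rows))
        Lr = cfg.max_reply_len
        self.reply_ids = np.zeros((max(len(reply_rows), 1), Lr), np.int64)
        self.reply_mask = np.zeros((max(len(reply_rows), 1), Lr), bool)
        for r, ids in enumerate(reply_rows):
            self.reply_ids[r], self.reply_mask[r] = pad_or_truncate(
                ids, Lr, vocab.pad_id)
        self.reply_day = np.asarray(reply_days or [0], np.int64)
        self.reply_offsets = offsets

        # null-token rows, used when an input field is ablated
        self.null_rows = {}
        for f, L in {**lens, "credentials": MAX_CRED_LEN}.items():
            ids = np.full(L, vocab.pad_id, np.int64)
            ids[0] = vocab.null_id
            mask = np.zeros(L, bool)
            mask[0] = True
            self.null_rows[f] = (ids, mask)

    def recent_window(self, p_idx: int, now: int) -> tuple[int, int]:
        """Row range into the reply arrays for the recency window at ``now``."""
        start, end = self.reply_offsets[p_idx]
        days = self.reply_day[start:end]
        lo = start + int(np.searchsorted(days, now - self.cfg.window_days, "right"))
        hi = start + int(np.searchsorted(days, now, "right"))
        lo = max(lo, hi - self.cfg.max_history)
        return lo, hi

    def encode_pairs(self, interactions: list[Interaction]) -> dict:
        """Vectorised batch descriptors for a list of interactions."""
        n = len(interactions)
        q_idx = np.fromiter((self.q_index[it.query_id] for it in interactions),
                            np.int64, n)
        p_idx = np.fromiter((self.p_index[it.physician_id] for it in interactions),
                            np.int64, n)
        labels = np.fromiter((it.label for it in interactions), np.int64, n)
        now = np.fromiter((it.timestamp for it in interactions), np.int64, n)
        windows = [self.recent_window(p, t) for p, t in zip(p_idx, now)]
        return {"q_idx": q_idx, "p_idx": p_idx, "labels": labels,
                "now": now, "windows": windows}


# ---------------------------------------------------------------------------
# batched forward graph
# ---------------------------------------------------------------------------

def _conv_windows(E: nn.Tensor, M: int) -> nn.Tensor:
    """Shifted-window im2col; zero boundary rows match per-item zero padding
    because the pad embedding row is pinned at zero."""
    return nn.shift_windows(E, M)


def _field_batch(params: ModelParams, name: str, ids: np.ndarray,
                 mask: np.ndarray, rng, training: bool,
                 drop: bool = True) -> nn.Tensor:
    """Batched embed -> conv -> attention-pool for one field; (N, d_conv)."""
    cfg = params.cfg
    fp = params.fields[name]
    N, L = ids.shape
    E = nn.embedding(params.emb, ids)
    win = _conv_windows(E, cfg.half_window)
    c = nn.relu(nn.add(nn.matmul(win, fp["W_c"]), fp["b_c"]))
    scores = nn.add(nn.reshape(nn.matmul(c, nn.reshape(fp["v"], (-1, 1))), (N, L)),
                    fp["v_b"])
    alpha = nn.tanh(scores)
    a = nn.masked_softmax(alpha, mask, axis=1)
    pooled = nn.sum_(nn.mul(c, nn.reshape(a, (N, L, 1))), axis=1)
    if cfg.maxpool_branch:
        pooled = nn.concat([pooled, nn.masked_max(c, mask[:, :, None], axis=1)],
                           axis=1)
    if drop and training:
        pooled = nn.dropout(pooled, cfg.dropout, rng, training)
    return pooled


def _gru_step_batch(h: nn.Tensor, x: nn.Tensor, g: dict) -> nn.Tensor:
    hx = nn.concat([h, x], axis=1)
    z = nn.sigmoid(nn.matmul(hx, g["W_z"]))
    r = nn.sigmoid(nn.matmul(hx, g["W_r"]))
    h_tilde = nn.tanh(nn.matmul(nn.concat([nn.mul(r, h), x], axis=1), g["W"]))
    return nn.add(h, nn.mul(z, nn.add(h_tilde, nn.mul(h, -1.0))))


def _gru_direction(params, E_steps: nn.Tensor, step_mask: np.ndarray,
                   direction: str, reverse: bool) -> list[nn.Tensor]:
    B, K, d = E_steps.shape
    dh = params.cfg.d_h
    g = params.gru[direction]
    h = nn.Tensor(np.zeros((B, dh), nn.DTYPE))
    order = range(K - 1, -1, -1) if reverse else range(K)
    states: dict[int, nn.Tensor] = {}
    for t in order:
        x = nn.reshape(nn.getitem(E_steps, (slice(None), t)), (B, d))
        m = step_mask[:, t:t + 1].astype(nn.DTYPE)
        h_new = _gru_step_batch(h, x, g)
        h = nn.add(h, nn.mul(nn.Tensor(m), nn.add(h_new, nn.mul(h, -1.0))))
        states[t] = h
    return [states[t] for t in range(K)]


def forward_pairs(params: ModelParams, enc: EncodedCorpus, batch: dict,
                  rng: np.random.Generator, training: bool,
                  surrogates: np.ndarray | None = None,
                  sl: slice = slice(None)) -> nn.Tensor:
    """Logits for a slice of an encoded pair batch.

    ``surrogates``: optional (n_physicians, d_hist) array substituted for the
    temporal vector of pairs whose recency window is empty (cold-start
    augmentation); ``None`` leaves those temporal vectors at zero.
    """
    cfg = params.cfg
    q_idx = batch["q_idx"][sl]
    p_idx = batch["p_idx"][sl]
    windows = batch["windows"][sl]
    B = len(q_idx)

    # -- patient channel; fixed fusion order e = [e_title, e_content,
    # e_profile, e_tags], ablated fields read the learned null token -------
    pooled_fields = []
    for fname in ("title", "content", "profile", "tags"):
        if fname in cfg.patient_fields:
            ids = enc.field_ids[fname][q_idx]
            mask = enc.field_mask[fname][q_idx]
        else:
            nid, nmask = enc.null_rows[fname]
            ids = np.tile(nid, (B, 1))
            mask = np.tile(nmask, (B, 1))
        pooled_fields.append(_field_batch(params, fname, ids, mask, rng, training))
    e = nn.add(nn.matmul(nn.concat(pooled_fields, axis=1), params.W_p),
               params.b_p)

    # -- physician static channel -----------------------------------------
    if "credentials" in cfg.physician_sources:
        cids, cmask = enc.cred_ids[p_idx], enc.cred_mask[p_idx]
    else:
        nid, nmask = enc.null_rows["credentials"]
        cids, cmask = np.tile(nid, (B, 1)), np.tile(nmask, (B, 1))
    r_s = _field_batch(params, "credentials", cids, cmask, rng, training)

    # -- physician temporal channel ---------------------------------------
    d_hist = 2 * cfg.d_h if cfg.history_concat else cfg.d_h
    if "history" in cfg.physician_sources:
        counts = np.array([hi - lo for lo, hi in windows], np.int64)
    else:
        counts = np.zeros(B, np.int64)
    K = int(counts.max()) if counts.size else 0
    if K > 0:
        rows = np.concatenate([np.arange(lo, hi) for (lo, hi), c
                               in zip(windows, counts) if c > 0]) \
            if counts.any() else np.empty(0, np.int64)
        b_idx = np.repeat(np.arange(B), counts)
        k_idx = np.concatenate([np.arange(c) for c in counts if c > 0])
        uniq, inv = np.unique(rows, return_inverse=True)
        rep_pooled = _field_batch(params, "reply", enc.reply_ids[uniq],
                                  enc.reply_mask[uniq], rng, training,
                                  drop=False)
        src = nn.getitem(rep_pooled, inv)
        d_in = rep_pooled.shape[1]
        E_steps = nn.scatter_rows(src, b_idx, k_idx, (B, K, d_in))
        step_mask = np.zeros((B, K), bool)
        step_mask[b_idx, k_idx] = True
        fwd = _gru_direction(params, E_steps, step_mask, "fwd", reverse=False)
        bwd = _gru_direction(params, E_steps, step_mask, "bwd", reverse=True)
        if cfg.history_concat:
            steps = [nn.concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
        else:
            steps = [nn.mul(nn.add(f, b), 0.5) for f, b in zip(fwd, bwd)]
        h_all = nn.stack(steps, axis=1)                       # (B, K, d_hist)
        scores = nn.add(nn.mul(nn.reshape(
            nn.matmul(h_all, nn.reshape(params.v_h, (-1, 1))), (B, K)),
            1.0 / np.sqrt(d_hist)), params.v_hb)
        a = nn.masked_softmax(nn.tanh(scores), step_mask, axis=1)
        r_d = nn.sum_(nn.mul(h_all, nn.reshape(a, (B, K, 1))), axis=1)
    else:
        r_d = nn.Tensor(np.zeros((B, d_hist), nn.DTYPE))

    if surrogates is not None:
        fill = np.where((counts == 0)[:, None], surrogates[p_idx], 0.0)
        r_d = nn.add(r_d, nn.Tensor(fill.astype(nn.DTYPE)))
    if training:
        r_s = nn.dropout(r_s, cfg.dropout, rng, training)
        r_d = nn.dropout(r_d, cfg.dropout, rng, training)

    r = nn.concat([r_s, r_d], axis=1)
    if params.W_r is not None:
        r = nn.add(nn.matmul(r, params.W_r), params.b_r)

    # -- scoring head ------------------------------------------------------
    z = nn.concat([e, r], axis=1)
    for i, (W, b) in enumerate(params.head):
        z = nn.add(nn.matmul(z, W), b)
        if i < len(params.head) - 1:
            z = nn.relu(z)
            if training:
                z = nn.dropout(z, cfg.dropout, rng, training)
    logits = nn.reshape(z, (B,))
    if params.w_dot is not None:
        logits = nn.add(logits, nn.mul(nn.sum_(nn.mul(e, r), axis=1),
                                       params.w_dot))
    return logits


# ---------------------------------------------------------------------------
# per-item reference encodings (inference / functional surface)
# ---------------------------------------------------------------------------

def encode_patient(query: PatientQuery, params: ModelParams) -> np.ndarray:
    """128-dim patient representation e (per-item float64 path)."""
    cfg = params.cfg
    vocab = params.vocab
    table = params.emb.data.astype(np.float64)
    lens = {"title": cfg.max_title_len, "content": cfg.max_content_len,
            "profile": cfg.max_profile_len, "tags": cfg.max_tags_len}
    toks = {"title": query.title_tokens, "content": query.content_tokens,
            "profile": profile_tokens(query), "tags": tag_tokens(query)}
    pooled = {}
    for name in ("title", "content", "profile", "tags"):
        if name in cfg.patient_fields:
            ids, mask = pad_or_truncate(vocab.encode(toks[name]), lens[name])
        else:
            ids, mask = pad_or_truncate([vocab.null_id], lens[name])
        fe = encode_field(ids, table, params.conv_attn(name), mask)
        vec = fe.pooled
        if cfg.maxpool_branch:
            vec = np.concatenate([vec, max_pool(fe.features, mask)])
        pooled[name] = vec
    concat = np.concatenate([pooled[n] for n in ("title", "content",
                                                 "profile", "tags")])
    return concat @ params.W_p.data.astype(np.float64) + \
        params.b_p.data.astype(np.float64)


def encode_credentials(physician: PhysicianProfile, params: ModelParams) -> np.ndarray:
    """Static credential encoding r_s."""
    vocab = params.vocab
    if "credentials" in params.cfg.physician_sources:
        ids, mask = pad_or_truncate(vocab.encode(credential_tokens(physician)),
                                    MAX_CRED_LEN)
    else:
        ids, mask = pad_or_truncate([vocab.null_id], MAX_CRED_LEN)
    fe = encode_field(ids, params.emb.data.astype(np.float64),
                      params.conv_attn("credentials"), mask)
    if params.cfg.maxpool_branch:
        return np.concatenate([fe.pooled, max_pool(fe.features, mask)])
    return fe.pooled


def encode_replies(replies: list[tuple[int, list[str]]],
                   params: ModelParams) -> np.ndarray:
    """Per-reply field encodings E = [e_1..e_k] (k, d_conv)."""
    vocab, cfg = params.vocab, params.cfg
    table = params.emb.data.astype(np.float64)
    cap = params.conv_attn("reply")
    out = []
    for _, toks in replies:
        ids, mask = pad_or_truncate(vocab.encode(toks), cfg.max_reply_len)
        fe = encode_field(ids, table, cap, mask)
        vec = fe.pooled
        if cfg.maxpool_branch:
            vec = np.concatenate([vec, max_pool(fe.features, mask)])
        out.append(vec)
    return np.stack(out)


def encode_physician(physician: PhysicianProfile, now: int,
                     params: ModelParams,
                     augmenter: "ColdStartAugmenter | None" = None,
                     zero_fallback: bool = True) -> np.ndarray:
    """128-dim physician representation r = [r_s, r_d].

    When the recency window is empty the temporal vector comes from the
    augmenter's surrogate (if provided), else zeros (``zero_fallback``),
    else an error is raised.
    """
    cfg = params.cfg
    r_s = encode_credentials(physician, params)
    recent = (select_recent(physician.reply_history, now, cfg.window_days,
                            cfg.max_history)
              if "history" in cfg.physician_sources else [])
    d_hist = 2 * cfg.d_h if cfg.history_concat else cfg.d_h
    if recent:
        E = encode_replies(recent, params)
        h = bigru(E, params.gru_params("fwd"), params.gru_params("bwd"),
                  concat=cfg.history_concat)
        _, r_d = attend_history(h, params.v_h.data.astype(np.float64),
                                float(params.v_hb.data[0]))
    elif augmenter is not None:
        r_d = augmenter.surrogate(physician)
    elif zero_fallback:
        r_d = np.zeros(d_hist)
    else:
        raise ValueError(
            f"physician {physician.physician_id} has no recent history and "
            "no cold-start augmentation is configured")
    r = np.concatenate([r_s, r_d])
    if params.W_r is not None:
        r = r @ params.W_r.data.astype(np.float64) + \
            params.b_r.data.astype(np.float64)
    return r


def score_pair(patient_rep: np.ndarray, physician_rep: np.ndarray,
               params: ModelParams) -> float:
    """sigmoid(FC([e, r])): match probability for one pair."""
    dm = params.cfg.d_match
    if patient_rep.shape != (dm,) or physician_rep.shape != (dm,):
        raise ValueError(f"representations must both have width {dm}")
    z = np.concatenate([patient_rep, physician_rep])
    for i, (W, b) in enumerate(params.head):
        z = z @ W.data.astype(np.float64) + b.data.astype(np.float64)
        if i < len(params.head) - 1:
            z = np.maximum(z, 0.0)
    u = float(z[0])
    if params.w_dot is not None:
        u += float(params.w_dot.data[0]) * float(patient_rep @ physician_rep)
    return 1.0 / (1.0 + np.exp(-u))


# ---------------------------------------------------------------------------
# cold-start augmentation
# ---------------------------------------------------------------------------

@dataclass
class ColdStartAugmenter:
    """Credential-keyed surrogate temporal vectors plus a synonym lexicon.

    ``physician_kb`` maps (specialty, title_rank, hospital_tier) to the mean
    temporal vector of warm physicians with those credentials, with
    per-specialty and global-mean fallbacks — a knowledge-base stand-in
    built entirely from training-set encodings.  ``symptom_lexicon`` maps a
    token to expansion tokens for sparse-query augmentation.
    """

    physician_kb: dict[tuple, np.ndarray]
    specialty_means: dict[str, np.ndarray]
    global_mean: np.ndarray
    symptom_lexicon: dict[str, set] = field(default_factory=dict)

    def __post_init__(self):
        if not self.physician_kb:
            raise ValueError("cold-start knowledge base is empty")

    def surrogate(self, physician: PhysicianProfile) -> np.ndarray:
        key = (physician.specialty_id, physician.title_rank,
               physician.hospital_tier)
        if key in self.physician_kb:
            return self.physician_kb[key]
        return self.specialty_means.get(physician.specialty_id,
                                        self.global_mean)

    def expand_query(self, query: PatientQuery, max_content_len: int = 128,
                     sparse_threshold: int = 8) -> PatientQuery:
        """Lexicon expansion for sparse queries (never removes tokens)."""
        if len(query.content_tokens) >= sparse_threshold or not self.symptom_lexicon:
            return query
        seen = set(query.title_tokens) | set(query.content_tokens)
        extra = []
        for tok in list(query.title_tokens) + list(query.content_tokens):
            for exp in sorted(self.symptom_lexicon.get(tok, ())):
                if exp not in seen:
                    seen.add(exp)
                    extra.append(exp)
        new_content = (list(query.content_tokens) + extra)[:max_content_len]
        return PatientQuery(query.query_id, list(query.title_tokens),
                            new_content, dict(query.profile),
                            list(query.tag_ids), query.timestamp)


def build_augmenter(params: ModelParams, corpus: Corpus,
                    cold_threshold: int | None = None,
                    symptom_lexicon: dict | None = None) -> ColdStartAugmenter:
    """Build surrogate vectors from warm physicians' temporal encodings.

    Each warm physician is encoded at the day of their last reply (so the
    recency window is never empty) and the resulting r_d vectors are
    averaged per credential key.
    """
    cfg = params.cfg
    thr = cold_threshold if cold_threshold is not None else cfg.cold_threshold
    buckets: dict[tuple, list[np.ndarray]] = {}
    for p in corpus.physicians.values():
        if p.is_cold(thr) or not p.reply_history:
            continue
        now = p.reply_history[-1][0]
        recent = select_recent(p.reply_history, now, cfg.window_days,
                               cfg.max_history)
        if not recent:
            continue
        E = encode_replies(recent, params)
        h = bigru(E, params.gru_params("fwd"), params.gru_params("bwd"),
                  concat=cfg.history_concat)
        _, r_d = attend_history(h, params.v_h.data.astype(np.float64),
                                float(params.v_hb.data[0]))
        key = (p.specialty_id, p.title_rank, p.hospital_tier)
        buckets.setdefault(key, []).append(r_d)
    kb = {k: np.mean(v, axis=0) for k, v in buckets.items()}
    spec: dict[str, list[np.ndarray]] = {}
    for (s, _, _), vec in kb.items():
        spec.setdefault(s, []).append(vec)
    specialty_means = {s: np.mean(v, axis=0) for s, v in spec.items()}
    global_mean = np.mean(list(kb.values()), axis=0)
    return ColdStartAugmenter(kb, specialty_means, global_mean,
                              symptom_lexicon or {})


def augment_cold_physician(physician: PhysicianProfile,
                           augmenter: ColdStartAugmenter,
                           cold_threshold: int = 5) -> np.ndarray:
    """Surrogate temporal vector for a sparse-history physician."""
    if physician.reply_count >= cold_threshold:
        raise ValueError(f"physician {physician.physician_id} is not cold "
                         f"({physician.reply_count} replies)")
    return augmenter.surrogate(physician)


def augment_sparse_query(query: PatientQuery, augmenter: ColdStartAugmenter,
                         max_content_len: int = 128,
                         sparse_threshold: int = 8) -> PatientQuery:
    return augmenter.expand_query(query, max_content_len, sparse_threshold)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

def _restrict_corpus(corpus: Corpus, interactions: list[Interaction]) -> Corpus:
    qids = {it.query_id for it in interactions}
    pids = {it.physician_id for it in interactions}
    return Corpus({q: corpus.queries[q] for q in corpus.queries if q in qids},
                  {p: corpus.physicians[p] for p in corpus.physicians
                   if p in pids},
                  list(interactions))


class ExpertMatchingModel:
    """Patient-physician matching model over an interaction corpus.

    Parameters
    ----------
    corpus : Corpus
        Queries, physicians and labelled interactions.
    split : DatasetSplit, optional
        Train/validation/test partition; built 6:2:2 from the training seed
        when omitted.
    model_config, train_config : optional
        Architecture and optimisation settings (defaults follow the
        published recipe; see :mod:`ohcmatch.config`).
    """

    def __init__(self, corpus: Corpus, split: DatasetSplit | None = None,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.corpus = corpus
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        if split is None:
            split = split_dataset(corpus.interactions, corpus,
                                  seed=self.train_config.seed,
                                  cold_threshold=self.model_config.cold_threshold)
        self.split = split
        # vocabulary from training interactions only (no test-token leakage)
        self.vocab = build_vocab(_restrict_corpus(corpus, split.train),
                                 min_count=self.train_config.min_count)

    @classmethod
    def from_corpus_file(cls, path, **kwargs) -> "ExpertMatchingModel":
        from .corpus import read_corpus
        return cls(read_corpus(path), **kwargs)

    def fit(self, seed: int | None = None, verbose: bool = False
            ) -> "MatchingResults":
        tc, mc = self.train_config, self.model_config
        master = int(tc.seed if seed is None else seed) % (2**31)
        ss = np.random.SeedSequence([master, 7])
        init_seed, shuffle_seed, drop_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]

        params = ModelParams(self.vocab, mc, seed=init_seed)
        enc = EncodedCorpus(self.corpus, self.vocab, mc)
        train_batch = enc.encode_pairs(self.split.train)
        val_batch = enc.encode_pairs(self.split.validation)
        y_val = val_batch["labels"]

        weight_names = {p.name for p in params.parameters()
                        if p.name != "emb" and p.data.ndim >= 2}
        opt = nn.Adam(params.parameters(), lr=tc.learning_rate,
                      weight_decay=tc.l2,
                      decay_filter=lambda p: p.name in weight_names)
        shuffle_rng = np.random.default_rng(shuffle_seed)
        drop_rng = np.random.default_rng(drop_seed)

        n = len(self.split.train)
        log, best = [], {"auc": -np.inf, "state": params.copy_state(),
                         "epoch": 0}
        bad_epochs = 0
        for epoch in range(1, tc.epochs + 1):
            # cold-start augmentation is part of the input pipeline: any
            # physician whose recency window is empty reads a surrogate
            # temporal vector from a knowledge base rebuilt from the current
            # parameters at the start of each epoch (zeros if no warm
            # physician exists to build it from)
            surrogates = _surrogate_table_for(params, self.corpus, enc)
            order = shuffle_rng.permutation(n)
            losses = []
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                sub = {"q_idx": train_batch["q_idx"][idx],
                       "p_idx": train_batch["p_idx"][idx],
                       "labels": train_batch["labels"][idx],
                       "now": train_batch["now"][idx],
                       "windows": [train_batch["windows"][i] for i in idx]}
                logits = forward_pairs(params, enc, sub, drop_rng,
                                       training=True, surrogates=surrogates)
                loss = nn.bce_with_logits(logits, sub["labels"])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch "
                        f"{start // tc.batch_size}: {float(loss.data)!r}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                params.emb.data[self.vocab.pad_id] = 0.0   # pad row pinned
                losses.append(float(loss.data))
            val_scores = _score_batch(params, enc, val_batch,
                                      surrogates=surrogates)
            val_auc = _safe_auc(y_val, val_scores)
            val_acc = float(((val_scores >= 0.5) == y_val).mean())
            log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_acc": val_acc, "val_auc": val_auc})
            if verbose:
                print(f"epoch {epoch}: loss={np.mean(losses):.4f} "
                      f"val_acc={val_acc:.4f} val_auc={val_auc:.4f}")
            if val_auc > best["auc"]:
                best = {"auc": val_auc, "state": params.copy_state(),
                        "epoch": epoch}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > tc.patience:
                    break
        params.load_state(best["state"])
        return MatchingResults(self, params, enc, log, best["epoch"], master)


def _score_batch(params: ModelParams, enc: EncodedCorpus, batch: dict,
                 surrogates: np.ndarray | None = None,
                 chunk: int = 1024) -> np.ndarray:
    n = len(batch["q_idx"])
    rng = np.random.default_rng(0)      # unused (no dropout at inference)
    out = np.empty(n, dtype=np.float64)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        logits = forward_pairs(params, enc, batch, rng, training=False,
                               surrogates=surrogates, sl=sl)
        out[sl] = 1.0 / (1.0 + np.exp(-logits.data.astype(np.float64)))
    return out


def _safe_auc(y: np.ndarray, scores: np.ndarray) -> float:
    from .metrics import auc_from_arrays
    if y.min() == y.max():
        return float("nan")
    return auc_from_arrays(y, scores)


def _surrogate_table_for(params: ModelParams, corpus: Corpus,
                         enc: EncodedCorpus) -> np.ndarray | None:
    """(n_physicians, d_hist) surrogate vectors under the current
    parameters, or None when no warm physician exists to build them from."""
    try:
        aug = build_augmenter(params, corpus,
                              cold_threshold=params.cfg.cold_threshold)
    except ValueError:
        return None
    d_hist = 2 * params.cfg.d_h if params.cfg.history_concat else params.cfg.d_h
    table = np.zeros((len(enc.p_index), d_hist), np.float64)
    for pid, j in enc.p_index.items():
        table[j] = aug.surrogate(corpus.physicians[pid])
    return table


class MatchingResults:
    """Fitted matching model: parameters, training log, evaluation."""

    def __init__(self, model: ExpertMatchingModel, params: ModelParams,
                 enc: EncodedCorpus, log: list[dict], best_epoch: int,
                 seed: int):
        self.model = model
        self.params = params
        self.enc = enc
        self.log = log
        self.best_epoch = best_epoch
        self.seed = seed
        self._augmenter: ColdStartAugmenter | None = None

    # -- scoring -----------------------------------------------------------
    def _surrogate_table(self, augment: bool) -> np.ndarray | None:
        """Surrogate vectors under the fitted parameters (cached).

        Augmentation is on by default everywhere because it is part of the
        model's input pipeline (training used it too); ``augment=False``
        gives the zero-temporal-vector baseline for contrast experiments.
        """
        if not augment:
            return None
        if getattr(self, "_surr_cache", None) is None:
            self._surr_cache = _surrogate_table_for(
                self.params, self.model.corpus, self.enc)
        return self._surr_cache

    def augmenter(self) -> ColdStartAugmenter:
        if self._augmenter is None:
            self._augmenter = build_augmenter(
                self.params, self.model.corpus,
                cold_threshold=self.params.cfg.cold_threshold)
        return self._augmenter

    def score_interactions(self, interactions: list[Interaction],
                           augment: bool = True) -> np.ndarray:
        batch = self.enc.encode_pairs(interactions)
        return _score_batch(self.params, self.enc, batch,
                            surrogates=self._surrogate_table(augment))

    def score_pair(self, query_id: str, physician_id: str,
                   now: int | None = None, augment: bool = True) -> float:
        q = self.model.corpus.queries[query_id]
        p = self.model.corpus.physicians[physician_id]
        now = q.timestamp if now is None else now
        e = encode_patient(q, self.params)
        r = encode_physician(p, now, self.params,
                             augmenter=self.augmenter() if augment else None)
        return score_pair(e, r, self.params)

    def rank_candidates(self, query_id: str, candidate_ids: list[str],
                        now: int | None = None, augment: bool = True
                        ) -> list[tuple[str, float]]:
        """Candidates sorted by score descending, ties by id ascending."""
        if not candidate_ids:
            raise ValueError("need at least one candidate")
        q = self.model.corpus.queries[query_id]
        now = q.timestamp if now is None else now
        # score in canonical id order so the ranking is invariant to the
        # caller's candidate ordering (float32 kernels are row-position
        # sensitive at the last ulp)
        cands = sorted(set(candidate_ids))
        pairs = [Interaction(query_id, pid, 0, now) for pid in cands]
        scores = self.score_interactions(pairs, augment=augment)
        order = sorted(range(len(cands)), key=lambda i: (-scores[i], cands[i]))
        return [(cands[i], float(scores[i])) for i in order]

    # -- evaluation ---------------------------------------------------------
    def predictions(self, subset: str = "test", augment: bool = True):
        """PredictionTable (DataFrame) for a split subset: all/cold/warm."""
        import pandas as pd
        inter = self._subset_interactions(subset)
        scores = self.score_interactions(inter, augment=augment)
        return pd.DataFrame({
            "query_id": [it.query_id for it in inter],
            "physician_id": [it.physician_id for it in inter],
            "label": [it.label for it in inter],
            "score": scores,
            "predicted": (scores >= 0.5).astype(int)})

    def _subset_interactions(self, subset: str) -> list[Interaction]:
        part, _, temp = subset.partition(":")
        inter = {"train": self.model.split.train,
                 "validation": self.model.split.validation,
                 "test": self.model.split.test}[part]
        if temp in ("cold", "warm"):
            cm = self.model.split.cold_mask
            want = temp == "cold"
            inter = [it for it in inter
                     if cm[DatasetSplit.key(it)] == want]
        return inter

    def recommendations(self, subset: str = "test", augment: bool = True,
                        n_negatives: int | None = None, seed: int | None = None
                        ) -> dict[str, list[tuple[str, float, int]]]:
        """Per-query ranked candidate lists (1+ positives, sampled negatives).

        Returns ``{query_id: [(physician_id, score, relevant), ...]}`` in
        rank order; candidate pools are the query's test positives plus
        negatives sampled (seed-reproducibly) from the remaining physicians.
        """
        tc = self.model.train_config
        n_neg = tc.n_negatives if n_negatives is None else n_negatives
        rng = np.random.default_rng(np.random.SeedSequence(
            [self.seed if seed is None else int(seed), 0x5EED]))
        inter = self._subset_interactions(subset)
        positives: dict[str, set] = {}
        for it in inter:
            if it.label == 1:
                positives.setdefault(it.query_id, set()).add(it.physician_id)
        ever_positive: dict[str, set] = {}
        for it in self.model.corpus.interactions:
            if it.label == 1:
                ever_positive.setdefault(it.query_id, set()).add(it.physician_id)
        all_pids = sorted(self.model.corpus.physicians)
        surrogates = self._surrogate_table(augment)

        out = {}
        flat_pairs, slices = [], {}
        for qid in sorted(positives):
            pos = sorted(positives[qid])
            pool = [p for p in all_pids
                    if p not in ever_positive.get(qid, ())]
            neg = list(rng.choice(pool, size=min(n_neg, len(pool)),
                                  replace=False))
            cands = pos + neg
            now = self.model.corpus.queries[qid].timestamp
            start = len(flat_pairs)
            flat_pairs += [Interaction(qid, pid, 0, now) for pid in cands]
            slices[qid] = (start, len(flat_pairs), pos, cands)
        if not flat_pairs:
            return {}
        batch = self.enc.encode_pairs(flat_pairs)
        scores = _score_batch(self.params, self.enc, batch,
                              surrogates=surrogates)
        for qid, (a, b, pos, cands) in slices.items():
            sc = scores[a:b]
            order = sorted(range(len(cands)), key=lambda i: (-sc[i], cands[i]))
            out[qid] = [(cands[i], float(sc[i]), int(cands[i] in pos))
                        for i in order]
        return out

    def evaluate(self, subset: str = "test", augment: bool = True,
                 tiers: dict[str, str] | None = None, seed: int | None = None):
        """Full MetricReport on a split subset; see :mod:`ohcmatch.metrics`."""
        from .metrics import compute_report
        return compute_report(self, subset=subset, augment=augment,
                              tiers=tiers, seed=seed)

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        import pandas as pd
        tc, mc = self.model.train_config, self.params.cfg
        lines = ["Expert Matching Model Results",
                 "=" * 64,
                 f"interactions: {len(self.model.corpus.interactions)} "
                 f"(train {len(self.model.split.train)} / "
                 f"val {len(self.model.split.validation)} / "
                 f"test {len(self.model.split.test)})",
                 f"vocab size: {len(self.params.vocab)}   "
                 f"d_emb={mc.d_emb} d_conv={mc.d_conv} d_h={mc.d_h} "
                 f"d_match={mc.d_match} fc_depth={mc.fc_depth}",
                 f"optimizer: Adam lr={tc.learning_rate} batch={tc.batch_size} "
                 f"epochs<={tc.epochs} dropout={mc.dropout} l2={tc.l2}",
                 f"seed: {self.seed}   best epoch: {self.best_epoch}",
                 "-" * 64,
                 pd.DataFrame(self.log).to_string(index=False),
                 "=" * 64]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.params.save(path)
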