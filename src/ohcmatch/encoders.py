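"""Patient-channel text encoder: embedding, windowed convolution, attention.

Every input field (question title, question content, profile details,
semantic tags — and, on the physician side, credential fields and each
historical reply) runs through the same pipeline::

    tokens --embedding--> W --width-(2M+1) conv + ReLU--> c --attention--> e

with attention scores ``alpha_i = tanh(v . c_i + v_b)`` softmax-normalised
over real (non-pad) positions and the pooled vector ``e = sum_i a_i c_i``.
Structured fields (profile, tags, credentials) are rendered into token
sequences by a fixed ``field=value`` serialization before encoding.

The functions here are the straight per-item reference path in ``float64``;
mini-batch training uses the autodiff graph in :mod:`ohcmatch.model`, which
is held equivalent to this path by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import PatientQuery, PhysicianProfile


# ---------------------------------------------------------------------------
# structured-field serialization (fixed order => deterministic encodings)
# ---------------------------------------------------------------------------

def _age_token(age) -> str:
    if age is None:
        return "age=Unknown"
    return f"age={10 * (int(age) // 10)}s"


def profile_tokens(query: PatientQuery) -> list[str]:
    p = query.profile
    toks = [_age_token(p.get("age")),
            f"gender={p.get('gender', 'Unknown')}",
            f"region={p.get('region', 'Unknown')}",
            f"disease={p.get('disease', 'Unknown')}"]
    toks += [f"history={h}" for h in p.get("history_flags", [])]
    return toks


def tag_tokens(query: PatientQuery) -> list[str]:
    toks = []
    for major, minor in sorted(query.tag_ids):
        toks.append(f"major={major}")
        toks.append(f"tag={major}.{minor}")
    return toks or ["tag=Unknown"]


def credential_tokens(physician: PhysicianProfile) -> list[str]:
    return [f"title={physician.title_rank}",
            f"tier={physician.hospital_tier}",
            f"specialty={physician.specialty_id}"]


def pad_or_truncate(ids: list[int], length: int, pad_id: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad (or truncate) to ``length``; returns (ids, real-position mask)."""
    ids = list(ids[:length])
    mask = np.zeros(length, dtype=bool)
    mask[:len(ids)] = True
    out = np.full(length, pad_id, dtype=np.int64)
    out[:len(ids)] = ids
    return out, mask


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ConvAttnParams:
    """Convolution + attention parameters for one field encoder.

    ``W_c`` maps a concatenated ``(2M+1) * d_emb`` embedding window to
    ``d_conv`` features; ``v``/``v_b`` score each feature vector for the
    softmax attention.
    """

    W_c: np.ndarray   # ((2M+1)*d_emb, d_conv)
    b_c: np.ndarray   # (d_conv,)
    v: np.ndarray     # (d_conv,)
    v_b: float
    M: int = 1

    def __post_init__(self):
        win = 2 * self.M + 1
        if self.W_c.shape[0] % win:
            raise ValueError("W_c first dimension must be (2M+1)*d_emb")
        if self.b_c.shape != (self.W_c.shape[1],):
            raise ValueError("b_c width must equal d_conv")
        if self.v.shape != (self.W_c.shape[1],):
            raise ValueError("v width must equal d_conv")


@dataclass
class FieldEncoding:
    features: np.ndarray   # (n, d_conv) per-position features c_i
    weights: np.ndarray    # (n,) attention weights a_i (zero on masked slots)
    pooled: np.ndarray     # (d_conv,) attention-weighted sum


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def embed(token_ids, table: np.ndarray) -> np.ndarray:
    """Row lookup: position i of the output is ``table[token_ids[i]]``."""
    ids = np.asarray(token_ids, dtype=np.int64)
    if ids.size and (ids.min() < 0 or ids.max() >= table.shape[0]):
        raise IndexError("token id outside embedding table")
    return table[ids]


def conv_window(W: np.ndarray, params: ConvAttnParams) -> np.ndarray:
    """Width-(2M+1) token convolution with ReLU and zero boundary padding.

    ``c_i = relu(W_c . concat(W[i-M..i+M]) + b_c)`` with 'same' output
    length: windows that extend past either end read zero vectors.
    """
    n, d = W.shape
    M = params.M
    if params.W_c.shape[0] != (2 * M + 1) * d:
        raise ValueError(f"embedding width {d} inconsistent with W_c "
                         f"{params.W_c.shape}")
    padded = np.vstack([np.zeros((M, d), W.dtype), W, np.zeros((M, d), W.dtype)])
    windows = np.concatenate([padded[k:k + n] for k in range(2 * M + 1)], axis=1)
    return np.maximum(windows @ params.W_c + params.b_c, 0.0)


def attention_pool(c: np.ndarray, params: ConvAttnParams,
                   mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """tanh-scored softmax attention over unmasked positions.

    Returns ``(weights, pooled)`` with ``sum(weights) == 1`` over real
    positions and ``pooled = sum_i a_i c_i``.
    """
    n = c.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("attention over a fully masked sequence")
    alpha = np.tanh(c @ params.v + params.v_b)
    scores = np.where(mask, alpha, -np.inf)
    scores = scores - scores[mask].max()
    e = np.where(mask, np.exp(scores), 0.0)
    a = e / e.sum()
    return a, a @ c


def encode_field(token_ids, table: np.ndarray, params: ConvAttnParams,
                 mask: np.ndarray | None = None) -> FieldEncoding:
    """Full field pipeline: embed -> conv_window -> attention_pool."""
    W = embed(token_ids, table)
    c = conv_window(W, params)
    a, pooled = attention_pool(c, params, mask)
    return FieldEncoding(features=c, weights=a, pooled=pooled)


def max_pool(c: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    if mask is None:
        mask = np.ones(c.shape[0], dtype=bool)
    return c[np.asarray(mask, dtype=bool)].max(axis=0)
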