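"""Physician temporal channel: recency window, Bi-GRU, step attention.

A physician's recent replies (left-open window ``(now - window_days, now]``,
truncated to the most recent ``max_history``) are each encoded with the text
encoder, run through a bidirectional GRU whose per-step states are the
arithmetic mean of the forward and backward directions, and pooled with a
scaled tanh-score attention into the temporal vector ``r_d``.  Concatenated
with the credential encoding ``r_s`` this yields the physician
representation ``r = [r_s, r_d]``.

Like :mod:`ohcmatch.encoders`, these are the per-item ``float64`` reference
implementations; batched training mirrors them in :mod:`ohcmatch.model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GruParams:
    """One GRU direction. Gate matrices act on ``concat([h_prev, x_t])``.

    ``z_t = sigmoid(W_z . [h, x])`` (update), ``r_t = sigmoid(W_r . [h, x])``
    (reset), ``h~_t = tanh(W . [r_t * h, x])``,
    ``h_t = (1 - z_t) * h + z_t * h~_t``.
    """

    W_z: np.ndarray  # (d_h + d_in, d_h)
    W_r: np.ndarray  # (d_h + d_in, d_h)
    W: np.ndarray    # (d_h + d_in, d_h)

    @property
    def d_h(self) -> int:
        return self.W_z.shape[1]

    def __post_init__(self):
        if not (self.W_z.shape == self.W_r.shape == self.W.shape):
            raise ValueError("GRU gate matrices must share one shape")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def select_recent(history: list[tuple[int, list[str]]], now: int,
                  window_days: int = 15, max_history: int = 32
                  ) -> list[tuple[int, list[str]]]:
    """Replies with day in ``(now - window_days, now]``, most recent
    ``max_history`` kept, chronological order preserved."""
    recent = [(d, toks) for d, toks in history if now - window_days < d <= now]
    return recent[-max_history:]


def gru_step(h_prev: np.ndarray, x_t: np.ndarray, params: GruParams) -> np.ndarray:
    hx = np.concatenate([h_prev, x_t])
    if hx.shape[0] != params.W_z.shape[0]:
        raise ValueError(f"GRU input width {hx.shape[0]} != "
                         f"{params.W_z.shape[0]}")
    z = _sigmoid(hx @ params.W_z)
    r = _sigmoid(hx @ params.W_r)
    h_tilde = np.tanh(np.concatenate([r * h_prev, x_t]) @ params.W)
    return (1.0 - z) * h_prev + z * h_tilde


def gru_pass(E: np.ndarray, params: GruParams) -> np.ndarray:
    """Unidirectional pass from a zero initial state; returns all states."""
    h = np.zeros(params.d_h, dtype=E.dtype)
    states = np.empty((E.shape[0], params.d_h), dtype=E.dtype)
    for t in range(E.shape[0]):
        h = gru_step(h, E[t], params)
        states[t] = h
    return states


def bigru(E: np.ndarray, params_fwd: GruParams, params_bwd: GruParams,
          concat: bool = False) -> np.ndarray:
    """Bidirectional GRU; per step the aligned directional states are
    averaged (``concat=True`` concatenates them instead)."""
    if E.shape[0] < 1:
        raise ValueError("bigru needs at least one step")
    fwd = gru_pass(E, params_fwd)
    bwd = gru_pass(E[::-1], params_bwd)[::-1]
    if concat:
        return np.concatenate([fwd, bwd], axis=1)
    return 0.5 * (fwd + bwd)


def attend_history(h: np.ndarray, v: np.ndarray, v_b: float) -> tuple[np.ndarray, np.ndarray]:
    """Scaled tanh-score softmax attention over history steps.

    Scores are ``tanh((v . h_i) / sqrt(d_h) + v_b)``; the 1/sqrt(d_h)
    scaling keeps scores comparable across state widths (tied duplicated
    features leave them invariant).  Returns ``(weights, r_d)``.
    """
    if h.shape[0] < 1:
        raise ValueError("cannot attend over an empty history; cold "
                         "physicians must go through augmentation")
    alpha = np.tanh(h @ v / np.sqrt(h.shape[1]) + v_b)
    e = np.exp(alpha - alpha.max())
    a = e / e.sum()
    return a, a @ h
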