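"""Configuration dataclasses and YAML round-trip.

Defaults follow the published training recipe for this architecture: batch
size 256, learning rate 0.01, at most 4 epochs with early stopping on
validation AUC, dropout 0.5, binary cross-entropy loss and an adaptive-moment
optimizer.  Dimension defaults: 64-wide embeddings and convolution features,
64-wide GRU states, 128-wide matched representations (so the joint
patient-physician vector entering the scoring head is 256-wide).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

PATIENT_FIELDS = ("title", "content", "tags", "profile")
PHYSICIAN_SOURCES = ("credentials", "history")


@dataclass
class ModelConfig:
    d_emb: int = 64
    d_conv: int = 64
    d_h: int = 64
    d_match: int = 128
    fc_depth: int = 4                # scoring-head depth (1..6)
    dropout: float = 0.5
    half_window: int = 1             # M: convolution half-window (width 2M+1)
    window_days: int = 15            # recency window for reply histories
    max_history: int = 32            # most recent replies kept in the window
    cold_threshold: int = 5          # replies below which a physician is cold
    max_title_len: int = 16
    max_content_len: int = 128
    max_profile_len: int = 16
    max_tags_len: int = 16
    max_reply_len: int = 64
    shared_field_params: bool = False   # one ConvAttn parameter set for all fields
    history_concat: bool = False        # concat fwd/bwd GRU states instead of mean
    maxpool_branch: bool = False        # concat a max-pool branch to attention pool
    dot_score_term: bool = True         # auxiliary inner-product term in the head
    patient_fields: tuple = PATIENT_FIELDS
    physician_sources: tuple = PHYSICIAN_SOURCES

    def __post_init__(self):
        if not (1 <= self.fc_depth <= 6):
            raise ValueError("fc_depth must be in 1..6")
        if not self.patient_fields or not self.physician_sources:
            raise ValueError("at least one patient field and one physician "
                             "source must be enabled")
        unknown = set(self.patient_fields) - set(PATIENT_FIELDS)
        unknown |= set(self.physician_sources) - set(PHYSICIAN_SOURCES)
        if unknown:
            raise ValueError(f"unknown input fields: {sorted(unknown)}")
        self.patient_fields = tuple(self.patient_fields)
        self.physician_sources = tuple(self.physician_sources)


@dataclass
class TrainConfig:
    batch_size: int = 256
    learning_rate: float = 0.01
    epochs: int = 4
    patience: int = 1                # early stopping on validation AUC
    l2: float = 3e-4                 # effective L2 coefficient (see methods note)
    min_count: int = 1               # vocabulary frequency threshold
    n_negatives: int = 49            # sampled negatives per query for top-K metrics
    k: int = 10                      # ranking cutoff
    sparse_content_threshold: int = 8  # below this, query-side augmentation kicks in
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


def config_to_dict(*cfgs) -> dict:
    out = {}
    for cfg in cfgs:
        out[type(cfg).__name__] = dataclasses.asdict(cfg)
    return out


def config_hash(*cfgs) -> str:
    blob = json.dumps(config_to_dict(*cfgs), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_yaml_config(path) -> tuple[ModelConfig, TrainConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_keys = {f.name for f in dataclasses.fields(ModelConfig)}
    train_keys = {f.name for f in dataclasses.fields(TrainConfig)}
    flat = {}
    for section in raw.values() if all(isinstance(v, dict) for v in raw.values()) and raw else [raw]:
        flat.update(section)
    unknown = set(flat) - model_keys - train_keys
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    mc = ModelConfig(**{k: v for k, v in flat.items() if k in model_keys})
    tc = TrainConfig(**{k: v for k, v in flat.items() if k in train_keys})
    return mc, tc


def dump_yaml_config(path, model_cfg: ModelConfig, train_cfg: TrainConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(model_cfg, train_cfg), fh, sort_keys=True)
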