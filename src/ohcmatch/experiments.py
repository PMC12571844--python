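"""Runnable experiment harnesses: input-field ablations and cold-start.

The ablation harness trains one model per input-variant per seed with
otherwise identical configuration and reports mean +- sd for every metric.
The standard variant ladder mirrors the usual ablation design for this
architecture: patient-side E1 (content only), E2 (tags only), E3 (title
only), E4 (title+content), E5 (full context), and physician-side F1
(credentials only), F2 (reply history only), F3 (both).  Disabled fields
are replaced by a learned null-token sequence, not dropped, so tensor
shapes and parameter counts stay identical across variants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, TrainConfig
from .corpus import Corpus
from .generate import GeneratorConfig, generate_corpus, make_cold_corpus
from .model import ExpertMatchingModel


@dataclass(frozen=True)
class AblationVariant:
    name: str
    patient_fields: tuple[str, ...]
    physician_sources: tuple[str, ...]

    def __post_init__(self):
        if not self.patient_fields or not self.physician_sources:
            raise ValueError(f"variant {self.name}: enables no input fields")


STANDARD_VARIANTS = {
    "E1": AblationVariant("E1", ("content",), ("credentials", "history")),
    "E2": AblationVariant("E2", ("tags",), ("credentials", "history")),
    "E3": AblationVariant("E3", ("title",), ("credentials", "history")),
    "E4": AblationVariant("E4", ("title", "content"), ("credentials", "history")),
    "E5": AblationVariant("E5", ("title", "content", "tags", "profile"),
                          ("credentials", "history")),
    "F1": AblationVariant("F1", ("title", "content", "tags", "profile"),
                          ("credentials",)),
    "F2": AblationVariant("F2", ("title", "content", "tags", "profile"),
                          ("history",)),
    "F3": AblationVariant("F3", ("title", "content", "tags", "profile"),
                          ("credentials", "history")),
}


def _fit_and_score(corpus: Corpus, model_cfg: ModelConfig,
                   train_cfg: TrainConfig, seed: int) -> dict[str, float]:
    tc = dataclasses.replace(train_cfg, seed=seed)
    model = ExpertMatchingModel(corpus, model_config=model_cfg, train_config=tc)
    res = model.fit()
    report = res.evaluate("test")
    out = {"acc": report.classification["all"]["acc"],
           "auc": report.classification["all"]["auc"]}
    out.update(report.ranking)
    return out


def run_ablation(corpus: Corpus, variants: list[AblationVariant],
                 seeds: list[int],
                 model_cfg: ModelConfig | None = None,
                 train_cfg: TrainConfig | None = None,
                 verbose: bool = False) -> dict[str, dict[str, dict[str, float]]]:
    """Train/evaluate each variant on each seed.

    Returns ``{variant: {metric: {"mean": .., "sd": .., "values": [..]}}}``.
    """
    if not variants:
        raise ValueError("no ablation variants given")
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    out: dict[str, dict[str, dict[str, float]]] = {}
    for var in variants:
        cfg = dataclasses.replace(model_cfg,
                                  patient_fields=var.patient_fields,
                                  physician_sources=var.physician_sources)
        per_seed = [_fit_and_score(corpus, cfg, train_cfg, s) for s in seeds]
        metrics = per_seed[0].keys()
        out[var.name] = {
            m: {"mean": float(np.mean([r[m] for r in per_seed])),
                "sd": float(np.std([r[m] for r in per_seed])),
                "values": [float(r[m]) for r in per_seed]}
            for m in metrics}
        if verbose:
            print(f"{var.name}: auc={out[var.name]['auc']['mean']:.4f} "
                  f"+- {out[var.name]['auc']['sd']:.4f}")
    return out


def cold_start_experiment(gen_cfg: GeneratorConfig | None = None,
                          cold_fraction: float = 0.3,
                          seeds: list[int] = (0, 1, 2, 3, 4),
                          model_cfg: ModelConfig | None = None,
                          train_cfg: TrainConfig | None = None,
                          verbose: bool = False) -> dict:
    """Cold-split AUC with and without credential-surrogate augmentation.

    For each seed a corpus with ``cold_fraction`` cold physicians is
    generated, one model is trained, and the cold test subset is scored
    twice: with the zero temporal vector (baseline) and with the
    knowledge-base surrogate.  Returns per-seed AUCs and the mean gap.
    """
    gen_cfg = gen_cfg or GeneratorConfig()
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    rows = []
    for seed in seeds:
        cfg = dataclasses.replace(gen_cfg, seed=seed)
        corpus, _, _ = make_cold_corpus(cfg, fraction=cold_fraction,
                                        cold_threshold=model_cfg.cold_threshold)
        tc = dataclasses.replace(train_cfg, seed=seed)
        res = ExpertMatchingModel(corpus, model_config=model_cfg,
                                  train_config=tc).fit()
        from .metrics import auc
        base = auc(res.predictions("test:cold", augment=False))
        aug = auc(res.predictions("test:cold", augment=True))
        rows.append({"seed": seed, "auc_zero": base, "auc_augmented": aug,
                     "gap": aug - base})
        if verbose:
            print(f"seed {seed}: zero={base:.4f} augmented={aug:.4f}")
    gaps = [r["gap"] for r in rows]
    return {"per_seed": rows, "mean_gap": float(np.mean(gaps)),
            "mean_auc_zero": float(np.mean([r["auc_zero"] for r in rows])),
            "mean_auc_augmented": float(np.mean([r["auc_augmented"]
                                                 for r in rows]))}


def learnability_experiment(gen_cfg: GeneratorConfig | None = None,
                            seeds: list[int] = (0, 1, 2, 3, 4),
                            model_cfg: ModelConfig | None = None,
                            train_cfg: TrainConfig | None = None,
                            shuffled_control: bool = True,
                            verbose: bool = False) -> dict:
    """Synthetic-recovery check: test AUC per seed, plus a shuffled-label
    control (labels permuted before splitting) that must stay near chance."""
    gen_cfg = gen_cfg or GeneratorConfig(signal_strength=0.8)
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    out = {"auc": [], "acc": [], "control_auc": []}
    for seed in seeds:
        corpus, _ = generate_corpus(dataclasses.replace(gen_cfg, seed=seed))
        tc = dataclasses.replace(train_cfg, seed=seed)
        res = ExpertMatchingModel(corpus, model_config=model_cfg,
                                  train_config=tc).fit()
        from .metrics import accuracy, auc
        table = res.predictions("test")
        out["auc"].append(auc(table))
        out["acc"].append(accuracy(table))
        if shuffled_control:
            rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC7A0]))
            labels = rng.permutation([it.label for it in corpus.interactions])
            shuffled = Corpus(
                corpus.queries, corpus.physicians,
                [dataclasses.replace(it, label=int(l))
                 for it, l in zip(corpus.interactions, labels)])
            res_c = ExpertMatchingModel(shuffled, model_config=model_cfg,
                                        train_config=tc).fit()
            table = res_c.predictions("test")
            from .metrics import auc
            out["control_auc"].append(auc(table))
        if verbose:
            print(f"seed {seed}: auc={out['auc'][-1]:.4f}"
                  + (f" control={out['control_auc'][-1]:.4f}"
                     if shuffled_control else ""))
    return out
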