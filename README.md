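# ohcmatch — patient–physician expert matching for online health Q&A

Patients on online health communities (OHCs) post medical questions; many
physicians answer; the questioner may *adopt* one answer.  Routing each new
question to the physicians most likely to give an adopted answer is an
expert-recommendation problem with two awkward properties: the two sides are
described by very different data (short noisy patient text vs. credentialed
professionals with long reply histories), and the physician population has a
heavy-tailed activity distribution that invites popularity bias and
cold-start failures.

`ohcmatch` implements a dual-channel neural matching model for this setting,
together with everything needed to study it without platform data: a seeded
synthetic community generator with a controllable latent-specialty signal, a
cold-start augmentation path, and a full evaluation suite (classification,
top-K ranking, and popularity-bias auditing).

## The model

**Patient channel.**  Each input field — question title `w = [w_1..w_n]`,
content, profile details, semantic tags — is embedded, passed through a
width-3 token convolution with ReLU,

    c_i = relu(W_c · [W_{i-1}, W_i, W_{i+1}] + b_c),

and reduced by tanh-scored softmax attention pooling,

    α_i = tanh(v·c_i + v_b),   a_i = softmax(α)_i,   e_field = Σ_i a_i c_i.

The four field vectors are concatenated and projected to the 128-dim patient
representation `e`.

**Physician channel.**  Credential tokens (title rank, hospital tier,
specialty) go through the same field encoder to give the static vector
`r_s`.  The replies of the last 15 days are each field-encoded into
`E = [e_1..e_k]`, run through a bidirectional GRU

    z_t = σ(W_z·[h_{t-1}, E_t]),  r_t = σ(W_r·[h_{t-1}, E_t]),
    h̃_t = tanh(W·[r_t ⊙ h_{t-1}, E_t]),  h_t = (1−z_t)⊙h_{t-1} + z_t⊙h̃_t,

whose forward/backward states are averaged per step and pooled with scaled
tanh-score attention into the temporal vector `r_d`; the physician
representation is `r = [r_s, r_d]` (128-dim).

**Scoring.**  The joint 256-dim vector `[e, r]` passes through a depth-4
fully connected stack to a logit, plus a learned inner-product term
`w·(eᵀr)`, and a sigmoid gives the match probability.  Training is binary
cross-entropy with Adam (batch 256, lr 0.01, dropout 0.5, ≤ 4 epochs with
early stopping on validation AUC).

**Cold start.**  Physicians with fewer than 5 replies get a surrogate
temporal vector looked up from a credential-keyed knowledge base built from
warm physicians' encodings ((specialty, title, tier) mean, falling back to
the specialty mean, then the global mean); sparse queries can be expanded
through a pluggable synonym lexicon.

## Worked example

```python
from ohcmatch import (ExpertMatchingModel, GeneratorConfig, TrainConfig,
                      generate_corpus)

corpus, latent = generate_corpus(GeneratorConfig(signal_strength=0.8, seed=1))
model = ExpertMatchingModel(corpus, train_config=TrainConfig(seed=1))
results = model.fit(verbose=True)
# epoch 1: loss=1.4987 val_acc=0.6825 val_auc=0.7432
# epoch 2: loss=0.6968 val_acc=0.8237 val_auc=0.8606
# epoch 3: loss=0.5885 val_acc=0.8425 val_auc=0.8823
# epoch 4: loss=0.5260 val_acc=0.8625 val_auc=0.8986

report = results.evaluate("test")
print(report.classification["all"])
# {'n': 800, 'acc': 0.835, 'auc': 0.8544}
print(report.ranking)
# {'precision_at_10': 0.0791, 'recall_at_10': 0.6899, 'ndcg_at_10': 0.3289}
print(report.tier_exposure)
# {'head': 0.1140, 'middle': 0.3953, 'tail': 0.4907}
```

The corpus embeds a known latent structure — every query and physician has
one specialty, and adoption is far likelier when they agree (0.85 vs 0.10)
— so test AUC measures how completely the model recovers that structure
from text, tags, credentials and reply histories.  With half the candidate
pairs specialty-matched, the label noise caps the achievable test AUC near
0.88; the trained model's ≈ 0.85–0.88 across seeds means the latent
specialties are recovered almost completely.  The ranking block scores each
test query against its adopted physician(s) plus 49 sampled negatives — a
recall@10 of 0.69 says the adopted physician lands in the top 10 of 50 for
~69% of queries (precision@10 is capped at 0.1 by the one-positive design).
The tier block shows how top-10 slots distribute over head (top 10% by
reply volume), middle (40%) and tail (50%) physicians.

A thin CLI wraps the same library surface:

```bash
ohcmatch generate --out corpus.jsonl --latent latent.json --seed 1
ohcmatch train --corpus corpus.jsonl --out model.npz
ohcmatch recommend --model model.npz --corpus corpus.jsonl --query-id q00007 --k 10
ohcmatch evaluate --model model.npz --corpus corpus.jsonl --report report.json
ohcmatch bias-report --model model.npz --corpus corpus.jsonl --out bias.json
```

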