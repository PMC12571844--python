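# Methods

This note documents the modelling assumptions, parameter defaults and
design decisions behind `ohcmatch`, and what the synthetic experiments do
and do not establish.

## Problem and model

The task is binary matching: given a patient query (title, content,
profile, semantic tags) and a physician (credentials, time-stamped reply
history), predict the probability that the physician's answer would be
adopted.  Ranking physicians per query by this probability yields the
recommendation list; top-K and per-tier metrics audit its quality and
fairness.

The architecture is dual-channel:

* every token field is reduced by the same encoder family — embedding
  lookup → width-3 token convolution with ReLU ('same' padding, zero
  vectors past the boundaries) → tanh-scored softmax attention pooling.
  Padded positions are excluded from the softmax; since the pad embedding
  row is pinned at zero, a padded batch encodes exactly like the unpadded
  per-item sequence;
* the physician's recent replies (left-open window `(now − 15 d, now]`,
  most recent 32 kept) are each field-encoded, passed through a Bi-GRU
  (zero initial states, per-step mean of the two directions), and pooled
  over steps with attention whose scores are scaled by `1/sqrt(d_h)` so
  they are comparable across state widths;
* the scoring head concatenates the 128-dim patient and physician vectors
  and applies a fully connected stack (default depth 4:
  256→128→64→32→1, ReLU between, dropout after each hidden layer) plus a
  learned scalar times the inner product `eᵀr`, then a sigmoid.

### The inner-product score path

The head exposes both readings of the scoring equation — the concatenated
256-dim joint vector through the FC stack, and the direct inner product of
the two representations — as complementary paths into the same logit, with
the inner-product weight initialised at 1.  This is deliberate: under the
published recipe the training budget is ~40 Adam steps (batch 256 on a few
thousand pairs, ≤ 4 epochs), far too few for two independently-initialised
channels to align through a deep head alone (empirically the concatenation
path stays at chance for many epochs before latching).  The bilinear path
gives both encoders a direct alignment gradient from step one, which is
what makes the few-epoch recipe workable; the FC path then learns the
non-bilinear corrections.  Setting `dot_score_term=False` recovers the
concatenation-only head.

### Initialisation

ReLU layers (convolutions, FC stack) use Kaiming-uniform; attention vectors
and the GRU gates use Glorot-uniform; embeddings are uniform in
±0.87 (≈ unit variance per coordinate).  The scales matter here: with a
few-step training budget the head must emit O(1) logits from the start, or
the early gradient signal drowns in dropout noise.

## Training recipe

Binary cross-entropy on logits; Adam (β₁ = 0.9, β₂ = 0.999); batch 256;
learning rate 0.01; at most 4 epochs with early stopping (patience 1) on
validation AUC, keeping the best-validation checkpoint; dropout 0.5 on
pooled field vectors, on the physician channel vectors and after each
hidden head layer, at train time only.  The vocabulary is built from the
training split only (frequency ≥ 1; unseen tokens map to `<unk>`).

Weight decay: the architecture's published recipe quotes a regularisation
coefficient of 3, which cannot be a raw L2 multiplier at learning rate
0.01 (it would dominate the loss by orders of magnitude); `ohcmatch`
applies L2 with an effective coefficient of 3·10⁻⁴ on weight matrices
(not embeddings or biases), and the literal value remains available via
`TrainConfig.l2`.

Numerics: training runs batched in float32 on the package's reverse-mode
autodiff engine; the per-item reference pipeline is float64.  The test
suite holds the two paths together to 1e-4 on probability scale and checks
every primitive against finite differences.  Runs are bit-reproducible for
a fixed master seed and BLAS threading configuration; all internal seeds
(initialisation, shuffling, dropout, negative sampling) derive from the
master seed via `SeedSequence`.

## Cold start

A physician with fewer than 5 replies (configurable) is *cold*.
Augmentation is part of the model's input pipeline, not an evaluation-time
patch: whenever a physician's recency window is empty, the temporal slot is
filled by a surrogate from a credential-keyed knowledge base — warm
physicians are encoded at the day of their last reply, their temporal
vectors averaged per (specialty, title rank, hospital tier) key, with
specialty-mean and global-mean fallbacks.  During training the knowledge
base is rebuilt from the current parameters at the start of every epoch, so
the model learns to *use* the surrogate slot; this is what makes the
zero-vector baseline (`augment=False`) a genuine contrast — a model trained
on zeros learns to route around the temporal channel, and substituting a
surrogate afterwards changes nothing.  The knowledge base is a stand-in
built entirely from the training corpus; no external ontology is
consulted.  Sparse queries
(content < 8 tokens) can be expanded through a user-supplied synonym
lexicon (expansion only ever adds tokens).

An honest caveat about the synthetic cold-start contrast: the surrogate is
a deterministic function of the credential fields, and in the default
generator the credential `specialty` field is a *sufficient statistic* for
the latent specialty — so once training has aligned the credential tokens,
the surrogate carries no information the static channel lacks, and the
measured cold-split AUC gap between augmented and zero-vector scoring is
near zero (both sit at the label-noise ceiling).  On real platforms
registered specialties are coarse, noisy proxies for a physician's actual
practice focus, which is exactly the regime where a history-derived
knowledge base adds value; the harness measures the gap, it does not
presuppose it.

## Synthetic corpus

The generator makes the matching problem's premise explicit: queries and
physicians carry one latent specialty each, and adoption depends only on
specialty agreement — `Bernoulli(0.85)` if matched, `Bernoulli(0.10)`
otherwise, with candidate pairs sampled ≈ 50/50 matched/mismatched to
avoid extreme class imbalance.  Text carries the signal through vocabulary
choice (each token specialty-specific with probability `s`, shared noise
otherwise); tags point at the specialty's major category with probability
`s` (8 major / 32 minor categories); the profile's disease field is drawn
from a specialty-linked pool with probability `s` while age, gender and
region are pure noise.  Defaults: 4 specialties, 1000 patients, 100
physicians, 4000 interactions, titles ≈ Poisson(15) tokens, content
≈ Poisson(128), replies ≈ Poisson(32) (physician answers are typically
shorter than question bodies), Zipf(1.1) physician activity with a
corpus mean of 24 replies over a 120-day horizon — so the 15-day recency
window truncates histories meaningfully.  The base corpus keeps every
physician at ≥ 5 replies; `make_cold_corpus` then thins an exact fraction
of physicians to 0–4 replies, keeping their credentials informative.

Because labels depend only on specialty agreement, the Bayes-optimal test
AUC is bounded by the label noise: with `s = 0.8` defaults it sits near
0.88, so a trained model reaching ≈ 0.86–0.88 has recovered the latent
structure nearly completely, and recovery — not raw AUC — is the claim the
synthetic experiments support.  What the generator does **not** emulate:
real medical language (tokens are symbolic), answer-quality and authority
effects on adoption (available as an optional extension, default off),
platform timestamp patterns, and the negative-sampling ambiguity of real
adoption logs (which physician replies count as negatives is an assumption
everywhere in this literature).  Passing tests therefore demonstrate
architectural correctness and recoverability of planted structure, not
clinical performance.

## Evaluation

Classification metrics (accuracy at threshold 0.5; Mann–Whitney AUC with
the 0.5 tie convention) are computed per split subset — all, cold (the
physician is cold), warm.  Ranking metrics are macro-averaged per query
over candidate sets of the query's test positives plus 49 sampled
negatives (physicians never adopted by that query); queries with no
relevant candidate are excluded from recall/NDCG and counted in the
report.  NDCG uses binary relevance with the log₂ discount (a
graded-relevance hook exists).  Popularity tiers cut physicians at
10/40/50% by reply volume (largest-remainder rounding, ties broken by id);
exposure rate is a tier's share of top-10 slots, coverage contribution its
share of distinct recommended physicians — each sums to 1.  Latency
metrics are deliberately excluded (hardware-dependent).

## Ablation harness

Variants disable input fields by replacing them with a learned `<null>`
token sequence (shapes and parameter counts unchanged): E1 content-only,
E2 tags-only, E3 title-only, E4 title+content, E5 full context on the
patient side; F1 credentials-only, F2 history-only, F3 both on the
physician side.  Each variant trains per seed with otherwise identical
configuration; reports give mean ± sd.  Expected direction (verified in
the acceptance suite at 1500 interactions, 5 seeds): richer inputs never
hurt — E5 ≥ E4 ≥ E3, F3 ≥ max(F1, F2).

## Problem sizes used in the test suite

Unit tests run on corpora of 100–400 interactions; the acceptance suite
uses the standard 4000-interaction corpus for recovery and cold-start
checks and 1500 interactions for the 30-run ablation grid.  These sizes
were chosen so the complete suite runs in minutes on a single CPU while
keeping every statistical check comfortably powered.

## Known limitations

* No subword/contextual text modelling; the tokenizer is a pluggable hook
  and the generator emits tokens directly.
* The GRU runs step-by-step in Python; histories are short by construction
  (≤ 32 steps), so no truncated-BPTT machinery is provided.
* `λ = 3` as printed in the recipe is interpreted, not reproduced (see
  above).
* Tier-restricted recall follows the natural reading (recall over relevant
  physicians of that tier); other readings exist.
* The outlier filter for reply length operates on token counts, not raw
  character counts.
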