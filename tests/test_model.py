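"""Model assembly: scoring head, batched-vs-reference equivalence,
cold-start augmentation, ranking, determinism and checkpointing."""

import dataclasses

import numpy as np
import pytest

from ohcmatch import (ExpertMatchingModel, GeneratorConfig, ModelConfig,
                      TrainConfig, generate_corpus, make_cold_corpus)
from ohcmatch import nn
from ohcmatch.corpus import build_vocab
from ohcmatch.model import (EncodedCorpus, ModelParams, build_augmenter,
                            augment_cold_physician, augment_sparse_query,
                            encode_patient, encode_physician, forward_pairs,
                            score_pair, ColdStartAugmenter)


@pytest.fixture(scope="module")
def setup(request):
    cfg = GeneratorConfig(n_interactions=150, n_patients=60, n_physicians=15,
                          title_len_mean=6, content_len_mean=18,
                          reply_len_mean=8, mean_replies=12,
                          signal_strength=0.8, seed=42)
    corpus, latent = generate_corpus(cfg)
    vocab = build_vocab(corpus)
    mcfg = ModelConfig()
    params = ModelParams(vocab, mcfg, seed=5)
    enc = EncodedCorpus(corpus, vocab, mcfg)
    return corpus, latent, vocab, params, enc


class TestScoringHead:
    def test_zero_head_gives_half(self, setup):
        corpus, _, vocab, params, enc = setup
        zeroed = ModelParams(vocab, params.cfg, seed=5)
        for W, b in zeroed.head:
            W.data[:] = 0.0
            b.data[:] = 0.0
        if zeroed.w_dot is not None:
            zeroed.w_dot.data[:] = 0.0
        q = next(iter(corpus.queries.values()))
        p = next(iter(corpus.physicians.values()))
        e = encode_patient(q, zeroed)
        r = encode_physician(p, now=q.timestamp, params=zeroed)
        assert score_pair(e, r, zeroed) == pytest.approx(0.5)

    def test_logistic_closed_form(self, setup):
        _, _, vocab, params, _ = setup
        dm = params.cfg.d_match
        head_only = ModelParams(vocab, params.cfg, seed=5)
        if head_only.w_dot is not None:
            head_only.w_dot.data[:] = 0.0
        for u in (-2.0, 0.0, 3.0):
            for W, b in head_only.head:
                W.data[:] = 0.0
                b.data[:] = 0.0
            head_only.head[-1][1].data[:] = u   # final bias = pre-activation
            s = score_pair(np.zeros(dm), np.zeros(dm), head_only)
            assert s == pytest.approx(1 / (1 + np.exp(-u)), abs=1e-9)

    def test_forward_oracle_depth_four(self, setup):
        """Straight-line re-implementation of the full FC stack."""
        _, _, _, params, _ = setup
        rng = np.random.default_rng(0)
        e, r = rng.normal(size=128), rng.normal(size=128)
        got = score_pair(e, r, params)
        z = np.concatenate([e, r])
        for i, (W, b) in enumerate(params.head):
            z = z @ W.data.astype(np.float64) + b.data.astype(np.float64)
            if i < len(params.head) - 1:
                z = np.maximum(z, 0)
        u = z[0]
        if params.w_dot is not None:
            u += float(params.w_dot.data[0]) * (e @ r)
        assert got == pytest.approx(1 / (1 + np.exp(-u)), abs=1e-6)

    def test_width_mismatch_raises(self, setup):
        _, _, _, params, _ = setup
        with pytest.raises(ValueError):
            score_pair(np.zeros(64), np.zeros(128), params)


class TestBatchedEquivalence:
    def test_batched_forward_matches_per_item_pipeline(self, setup):
        """The float32 training graph and the float64 reference path agree
        to 1e-4 on logit scale over real corpus pairs."""
        corpus, _, _, params, enc = setup
        inters = corpus.interactions[:24]
        batch = enc.encode_pairs(inters)
        rng = np.random.default_rng(0)
        logits = forward_pairs(params, enc, batch, rng, training=False)
        probs = 1 / (1 + np.exp(-logits.data.astype(np.float64)))
        for i, it in enumerate(inters):
            q = corpus.queries[it.query_id]
            p = corpus.physicians[it.physician_id]
            e = encode_patient(q, params)
            r = encode_physician(p, now=it.timestamp, params=params)
            assert probs[i] == pytest.approx(score_pair(e, r, params),
                                             abs=1e-4)

    def test_probability_range_over_random_pairs(self, setup):
        corpus, _, _, params, enc = setup
        batch = enc.encode_pairs(corpus.interactions)
        rng = np.random.default_rng(0)
        logits = forward_pairs(params, enc, batch, rng, training=False)
        probs = 1 / (1 + np.exp(-logits.data))
        assert np.all((probs > 0) & (probs < 1))


class TestTraining:
    def test_identical_seeds_identical_first_epoch_loss(self, setup):
        corpus, _, _, _, _ = setup
        tc = TrainConfig(epochs=1, seed=9)
        r1 = ExpertMatchingModel(corpus, train_config=tc).fit()
        r2 = ExpertMatchingModel(corpus, train_config=tc).fit()
        assert r1.log[0]["train_loss"] == r2.log[0]["train_loss"]
        assert r1.log[0]["val_auc"] == r2.log[0]["val_auc"]

    def test_different_seed_changes_training(self, setup):
        corpus, _, _, _, _ = setup
        r1 = ExpertMatchingModel(corpus, train_config=TrainConfig(
            epochs=1, seed=1)).fit()
        r2 = ExpertMatchingModel(corpus, train_config=TrainConfig(
            epochs=1, seed=2)).fit()
        assert r1.log[0]["train_loss"] != r2.log[0]["train_loss"]

    def test_epoch_log_schema_and_summary(self, tiny_results):
        assert {"epoch", "train_loss", "val_acc", "val_auc"} <= \
            set(tiny_results.log[0])
        text = tiny_results.summary()
        assert "Adam" in text and "val_auc" in text


class TestRanking:
    def test_singleton_candidate(self, tiny_results):
        corpus = tiny_results.model.corpus
        qid = next(iter(corpus.queries))
        pid = next(iter(corpus.physicians))
        ranked = tiny_results.rank_candidates(qid, [pid])
        assert len(ranked) == 1 and ranked[0][0] == pid

    def test_order_is_descending_with_id_tiebreak(self, tiny_results):
        corpus = tiny_results.model.corpus
        qid = next(iter(corpus.queries))
        cands = sorted(corpus.physicians)
        ranked = tiny_results.rank_candidates(qid, cands)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        for (p1, s1), (p2, s2) in zip(ranked, ranked[1:]):
            if s1 == s2:
                assert p1 < p2

    def test_candidate_order_permutation_invariant(self, tiny_results):
        corpus = tiny_results.model.corpus
        qid = next(iter(corpus.queries))
        cands = sorted(corpus.physicians)
        r1 = tiny_results.rank_candidates(qid, cands)
        r2 = tiny_results.rank_candidates(qid, cands[::-1])
        assert r1 == r2

    def test_matches_per_item_scoring_order(self, tiny_results):
        """Sort oracle: ranking equals sorting independently computed
        per-item scores."""
        corpus = tiny_results.model.corpus
        qid = sorted(corpus.queries)[0]
        cands = sorted(corpus.physicians)[:8]
        ranked = tiny_results.rank_candidates(qid, cands)
        solo = {pid: tiny_results.score_pair(qid, pid) for pid in cands}
        expect = sorted(cands, key=lambda p: (-solo[p], p))
        assert [p for p, _ in ranked] == expect
        for pid, s in ranked:
            assert s == pytest.approx(solo[pid], abs=1e-4)


@pytest.fixture(scope="module")
def cold_setup():
    cfg = GeneratorConfig(n_interactions=200, n_patients=80,
                          n_physicians=40, title_len_mean=6,
                          content_len_mean=15, reply_len_mean=8,
                          mean_replies=14, signal_strength=0.9, seed=77)
    corpus, latent, cold_ids = make_cold_corpus(cfg, fraction=0.3)
    vocab = build_vocab(corpus)
    params = ModelParams(vocab, ModelConfig(), seed=1)
    return corpus, latent, cold_ids, params


class TestColdStart:

    def test_exact_key_lookup_and_fallback_chain(self, cold_setup):
        corpus, _, cold_ids, params = cold_setup
        aug = build_augmenter(params, corpus)
        warm_keys = set(aug.physician_kb)
        cold = corpus.physicians[cold_ids[0]]
        key = (cold.specialty_id, cold.title_rank, cold.hospital_tier)
        vec = aug.surrogate(cold)
        if key in warm_keys:
            np.testing.assert_array_equal(vec, aug.physician_kb[key])
        else:
            np.testing.assert_array_equal(
                vec, aug.specialty_means.get(cold.specialty_id,
                                             aug.global_mean))

    def test_unseen_key_falls_back_to_specialty_mean(self, cold_setup):
        corpus, _, _, params = cold_setup
        aug = build_augmenter(params, corpus)
        from ohcmatch.corpus import PhysicianProfile
        ghost = PhysicianProfile("ghost", "NoSuchRank", "9Z",
                                 next(iter(aug.specialty_means)), [])
        np.testing.assert_array_equal(
            aug.surrogate(ghost), aug.specialty_means[ghost.specialty_id])

    def test_surrogate_closer_to_own_specialty_centroid(self, cold_setup):
        """Nearest-centroid oracle on the latent assignment."""
        corpus, latent, cold_ids, params = cold_setup
        aug = build_augmenter(params, corpus)
        # specialty centroids of warm temporal vectors
        cent = {s: v for s, v in aug.specialty_means.items()}
        hits = total = 0
        for pid in cold_ids:
            p = corpus.physicians[pid]
            if p.specialty_id not in cent or len(cent) < 2:
                continue
            vec = aug.surrogate(p)
            sims = {s: float(vec @ c / (np.linalg.norm(vec) *
                                        np.linalg.norm(c) + 1e-12))
                    for s, c in cent.items()}
            total += 1
            hits += max(sims, key=sims.get) == p.specialty_id
        assert total > 0 and hits / total > 0.5

    def test_cold_physician_scorable_without_error(self, cold_setup):
        corpus, _, cold_ids, params = cold_setup
        aug = build_augmenter(params, corpus)
        cold = corpus.physicians[cold_ids[0]]
        r = encode_physician(cold, now=100, params=params, augmenter=aug)
        assert r.shape == (params.cfg.d_match,)
        assert np.all(np.isfinite(r))

    def test_no_history_no_augmentation_raises(self, cold_setup):
        corpus, _, cold_ids, params = cold_setup
        empty = [p for p in corpus.physicians.values() if p.reply_count == 0]
        if not empty:
            pytest.skip("no fully empty physician generated")
        with pytest.raises(ValueError, match="cold"):
            encode_physician(empty[0], now=100, params=params,
                             augmenter=None, zero_fallback=False)

    def test_augment_cold_physician_guards_warm(self, cold_setup):
        corpus, _, cold_ids, params = cold_setup
        aug = build_augmenter(params, corpus)
        warm = next(p for p in corpus.physicians.values()
                    if p.reply_count >= 5)
        with pytest.raises(ValueError, match="not cold"):
            augment_cold_physician(warm, aug)

    def test_empty_kb_rejected_at_construction(self):
        with pytest.raises(ValueError, match="empty"):
            ColdStartAugmenter({}, {}, np.zeros(4))


class TestQueryAugmentation:
    def _aug(self, lexicon):
        return ColdStartAugmenter({("S0", "Chief", "3A"): np.zeros(64)},
                                  {}, np.zeros(64), lexicon)

    def test_empty_lexicon_identity(self, setup):
        corpus, _, _, _, _ = setup
        q = next(iter(corpus.queries.values()))
        out = augment_sparse_query(q, self._aug({}), sparse_threshold=10**6)
        assert out.content_tokens == q.content_tokens

    def test_toy_lexicon_appends_expansion(self):
        from ohcmatch.corpus import PatientQuery
        q = PatientQuery("q", ["cough"], ["bad", "cough", "today"], {}, [(1, 1)])
        out = augment_sparse_query(q, self._aug({"cough": {"tussis"}}),
                                   sparse_threshold=8)
        assert out.content_tokens == ["bad", "cough", "today", "tussis"]

    def test_expansion_never_shrinks(self, setup):
        corpus, _, _, _, _ = setup
        aug = self._aug({"nw1": {"syn1", "syn2"}})
        for q in list(corpus.queries.values())[:20]:
            out = augment_sparse_query(q, aug, sparse_threshold=10**6)
            assert len(out.content_tokens) >= len(q.content_tokens)


class TestCheckpoint:
    def test_save_load_round_trip_bit_exact(self, tmp_path, tiny_results):
        path = tmp_path / "model.npz"
        tiny_results.save(path)
        back = ModelParams.load(path)
        for p in tiny_results.params.parameters():
            match = [q for q in back.parameters() if q.name == p.name]
            assert match, p.name
            np.testing.assert_array_equal(p.data, match[0].data)
        assert back.vocab.token_to_id == tiny_results.params.vocab.token_to_id

    def test_loaded_model_scores_identically(self, tmp_path, tiny_results):
        path = tmp_path / "model.npz"
        tiny_results.save(path)
        back = ModelParams.load(path)
        corpus = tiny_results.model.corpus
        q = next(iter(corpus.queries.values()))
        p = next(iter(corpus.physicians.values()))
        s1 = score_pair(encode_patient(q, tiny_results.params),
                        encode_physician(p, q.timestamp, tiny_results.params),
                        tiny_results.params)
        s2 = score_pair(encode_patient(q, back),
                        encode_physician(p, q.timestamp, back), back)
        assert s1 == pytest.approx(s2, abs=1e-12)
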