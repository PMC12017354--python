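"""Hierarchical biRNN token tagger: forward pass, gradients, training."""

import numpy as np
import pytest

from narrafnirs.datatypes import InputError
from narrafnirs.tagger import (BiRnnTagger, encode_document, forward_tagger,
                               init_params, loss_and_grads, sentence_vectors,
                               train_tagger)


def small_params(vocab=5, d=3, h=4, hu=3, seed=0):
    return init_params(vocab, embed_dim=d, hidden=h, upper_hidden=hu,
                       seed=seed)


class TestForward:
    def test_zero_weights_give_half_probabilities(self):
        p = {k: np.zeros_like(v) for k, v in small_params().items()}
        out = forward_tagger([0, 1, 2], p)
        np.testing.assert_allclose(out["p_emotional"], 0.5)
        np.testing.assert_allclose(out["p_factual"], 0.5)

    def test_single_token_is_one_cell_step(self):
        # hand-rolled recursion: from zero state, h1 = tanh(x W + b)
        p = small_params(seed=3)
        out = forward_tagger([2], p)
        x = p["E"][2]
        hf = np.tanh(x @ p["f_Wx"] + p["f_b"])
        hb = np.tanh(x @ p["b_Wx"] + p["b_b"])
        np.testing.assert_allclose(out["H"][0], np.r_[hf, hb], atol=1e-12)

    def test_reversal_symmetry(self):
        # reversing the input and swapping fwd/bwd cells (and the head
        # blocks acting on each half) reverses the output sequence
        p = small_params(seed=4)
        h = p["f_b"].size
        q = dict(p)
        q["f_Wx"], q["b_Wx"] = p["b_Wx"], p["f_Wx"]
        q["f_Wh"], q["b_Wh"] = p["b_Wh"], p["f_Wh"]
        q["f_b"], q["b_b"] = p["b_b"], p["f_b"]
        q["U_e"] = np.vstack([p["U_e"][h:], p["U_e"][:h]])
        q["U_f"] = np.vstack([p["U_f"][h:], p["U_f"][:h]])
        seq = [0, 3, 1, 4, 2]
        a = forward_tagger(seq, p)
        b = forward_tagger(seq[::-1], q)
        np.testing.assert_allclose(a["p_emotional"], b["p_emotional"][::-1],
                                   atol=1e-12)

    def test_softmax_rows_normalised(self):
        p = small_params(seed=1)
        out = forward_tagger([0, 1, 2, 3, 4], p)
        np.testing.assert_allclose(out["softmax_emotion"].sum(axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(out["softmax_fact"].sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_markers_pass_through_in_order(self):
        p = small_params()
        markers = [0.4, 1.2, 3.3]
        out = forward_tagger([1, 2, 3], p, markers=markers)
        assert out["markers"] == markers

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            forward_tagger([], small_params())

    def test_oov_index_out_of_range_rejected(self):
        with pytest.raises(InputError):
            forward_tagger([99], small_params())


class TestHierarchy:
    def test_sentence_vector_dimension_is_twice_hidden(self):
        p = init_params(10, embed_dim=8, hidden=32, upper_hidden=16, seed=0)
        s = sentence_vectors([[1, 2], [3]], p)
        assert s.shape == (2, 64)

    def test_identical_sentences_encode_identically(self):
        p = small_params(seed=2)
        s = sentence_vectors([[1, 2, 3]] * 4, p)
        assert np.ptp(s, axis=0).max() == 0.0

    def test_single_sentence_document_is_one_upper_step(self):
        p = small_params(seed=5)
        s1 = sentence_vectors([[1, 4, 2]], p)[0]
        expected = np.tanh(s1 @ p["u_Wx"] + p["u_b"])
        np.testing.assert_allclose(
            encode_document([[1, 4, 2]], p), expected, atol=1e-12)

    def test_empty_document_rejected(self):
        with pytest.raises(InputError):
            encode_document([], small_params())


class TestGradients:
    def test_analytic_matches_central_differences(self):
        p = small_params(vocab=5, d=3, h=4, seed=9)
        seqs = [np.array([1, 3, 0])]
        ye = [np.array([1, 0, 1])]
        yf = [np.array([0, 0, 1])]
        _, grads = loss_and_grads(p, seqs, ye, yf)
        eps = 1e-6
        worst = 0.0
        for name in p:
            if name.startswith("u_"):
                continue  # upper RNN does not enter the token loss
            flat = p[name].ravel()
            gflat = grads[name].ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = loss_and_grads(p, seqs, ye, yf)
                flat[i] = orig - eps
                lm, _ = loss_and_grads(p, seqs, ye, yf)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - gflat[i]))
        assert worst < 1e-5

    def test_upper_rnn_untouched_by_token_loss(self):
        p = small_params(seed=9)
        _, grads = loss_and_grads(p, [np.array([1, 2])], [np.array([1, 0])],
                                  [np.array([0, 1])])
        assert not grads["u_Wx"].any()


class TestTraining:
    def corpus(self):
        # lexically separable 2-word-per-class vocabulary
        rng = np.random.default_rng(0)
        vocab = {"calm": 0, "fear": 1, "date": 2, "tree": 3}
        emo = {"fear"}
        fact = {"date"}
        X, y = [], []
        for _ in range(40):
            words = list(rng.choice(list(vocab), size=6))
            X.append(words)
            y.append(np.array([[int(w in emo), int(w in fact)]
                               for w in words]))
        return X, y

    def test_seeded_training_is_deterministic(self):
        X, y = self.corpus()
        a = BiRnnTagger(embed_dim=4, hidden=4, epochs=15, lr=0.5,
                        min_count=1, random_state=1).fit(X, y)
        b = BiRnnTagger(embed_dim=4, hidden=4, epochs=15, lr=0.5,
                        min_count=1, random_state=1).fit(X, y)
        assert a.loss_curve_ == b.loss_curve_

    def test_loss_non_increasing(self):
        X, y = self.corpus()
        m = BiRnnTagger(embed_dim=4, hidden=6, epochs=60, lr=0.5,
                        min_count=1, random_state=0).fit(X, y)
        diffs = np.diff(m.loss_curve_)
        assert diffs.max() < 1e-3

    def test_separable_corpus_perfect_holdout(self):
        X, y = self.corpus()
        m = BiRnnTagger(embed_dim=6, hidden=8, epochs=120, lr=1.0,
                        min_count=1, random_state=0).fit(X[:30], y[:30])
        assert m.score(X[30:], y[30:]) == 1.0

    def test_single_class_corpus_rejected(self):
        with pytest.raises(InputError):
            train_tagger([np.array([0, 1])], [np.array([0, 0])],
                         [np.array([0, 1])], vocab_size=3)

    def test_sklearn_param_interface(self):
        m = BiRnnTagger(hidden=12)
        assert m.get_params()["hidden"] == 12
        m.set_params(epochs=5)
        assert m.epochs == 5


class TestLexiconAgreement:
    def test_neural_tags_agree_with_lexicon(self, tiny_spec, lexicon):
        """After desk-scale training the network reproduces lexicon tags.

        Emotional = generating category in {negative, positive}; factual =
        generating category factual.  Transcripts are chunked into
        sentence-sized sequences; rare neutral words fall back to the OOV
        embedding, which itself learns the neutral mapping.
        """
        from narrafnirs.synthetic import generate_cohort, generate_transcript

        subjects = generate_cohort(tiny_spec)
        docs = []
        for subj in subjects:
            tr = generate_transcript(subj, tiny_spec)
            toks = list(tr.tokens["token"])
            cats = list(tr.tokens["category"])
            docs.append((toks, cats))
        X, y = [], []
        for toks, cats in docs:
            for i in range(0, len(toks), 15):
                chunk_t = toks[i:i + 15]
                chunk_c = cats[i:i + 15]
                X.append(chunk_t)
                y.append(np.array([[int(c in ("negative", "positive")),
                                    int(c == "factual")] for c in chunk_c]))
        n_train = int(0.8 * len(X))
        m = BiRnnTagger(embed_dim=8, hidden=8, epochs=150, lr=3.0,
                        min_count=1, random_state=0).fit(X[:n_train],
                                                         y[:n_train])
        assert m.score(X[n_train:], y[n_train:]) >= 0.95
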