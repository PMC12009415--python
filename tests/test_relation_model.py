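"""BiGRU + attention classifier: exact oracles, invariants, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rehabminer.corpus_io import EntityMention, QARecord, SplitSpec, stratified_split
from rehabminer.encoder import EncodedInstance, LookupBackend, encode_dataset
from rehabminer.relation_model import (
    ModelConfig,
    RelationModel,
    attention_pool,
    bigru_forward,
    classify,
    predict_triples,
)
from rehabminer.synth_corpus import GeneratorConfig, generate_corpus


def _enc(matrix, mask, label=None):
    return EncodedInstance(
        matrix=np.asarray(matrix, float), mask=np.asarray(mask, bool), label=label
    )


class TestAttentionPool:
    def test_matches_brute_force_oracle(self, rng):
        """alpha and c equal an independent elementwise computation."""
        L, H2 = 5, 4
        H = rng.normal(size=(L, H2))
        omega = rng.normal(size=H2)
        mask = np.array([True, True, True, False, False])
        alpha, c = attention_pool(H, omega, mask)
        # brute force: scores via explicit loops, softmax by hand
        scores = [sum(omega[j] * np.tanh(H[t, j]) for j in range(H2))
                  for t in range(L)]
        exp = [np.exp(scores[t]) if mask[t] else 0.0 for t in range(L)]
        alpha_bf = np.array(exp) / sum(exp)
        c_bf = sum(alpha_bf[t] * H[t] for t in range(L))
        assert np.allclose(alpha, alpha_bf, atol=1e-8)
        assert np.allclose(c, c_bf, atol=1e-8)

    def test_identical_rows_give_uniform_weights(self):
        H = np.tile([[0.3, -0.2]], (4, 1))
        mask = np.array([True, True, True, False])
        alpha, c = attention_pool(H, np.array([1.0, 2.0]), mask)
        assert np.allclose(alpha[:3], 1 / 3)
        assert np.allclose(c, H[0])

    def test_zero_omega_gives_mean_of_unmasked_rows(self, rng):
        H = rng.normal(size=(6, 4))
        mask = np.array([True] * 4 + [False] * 2)
        alpha, c = attention_pool(H, np.zeros(4), mask)
        assert np.allclose(c, H[:4].mean(axis=0))

    def test_all_masked_is_degenerate(self, rng):
        with pytest.raises(ValueError):
            attention_pool(rng.normal(size=(3, 2)), np.ones(2), np.zeros(3, bool))

    @given(
        H=arrays(float, (6, 4), elements=st.floats(-5, 5)),
        omega=arrays(float, (4,), elements=st.floats(-3, 3)),
        mask_bits=st.lists(st.booleans(), min_size=6, max_size=6).filter(any),
    )
    @settings(derandomize=True, max_examples=50)
    def test_simplex_and_convexity_invariants(self, H, omega, mask_bits):
        """alpha is a simplex over unmasked rows; c lies in their
        coordinate-wise hull."""
        mask = np.array(mask_bits)
        alpha, c = attention_pool(H, omega, mask)
        assert np.all(alpha >= 0)
        assert np.all(alpha[~mask] == 0.0)
        assert np.isclose(alpha.sum(), 1.0, atol=1e-9)
        sub = H[mask]
        assert np.all(c >= sub.min(axis=0) - 1e-9)
        assert np.all(c <= sub.max(axis=0) + 1e-9)


class TestBigruForward:
    def test_paper_architecture_shapes(self):
        """32 hidden units per direction on 200-token input: H is 200 x 64."""
        cfg = ModelConfig(hidden_units=32, seed=0)
        model = RelationModel(cfg, D=768)
        enc = _enc(np.random.default_rng(0).normal(size=(200, 768)),
                   np.ones(200, bool))
        H = bigru_forward(enc, model.params)
        assert H.shape == (200, 64)
        alpha, c = attention_pool(H, model.params["omega"], enc.mask)
        assert c.shape == (64,)

    def test_all_masked_input_gives_zero_H(self):
        model = RelationModel(ModelConfig(hidden_units=3, seed=0), D=4)
        enc = _enc(np.zeros((5, 4)), np.zeros(5, bool))
        assert np.all(bigru_forward(enc, model.params) == 0.0)

    def test_masked_positions_give_zero_rows(self, rng):
        model = RelationModel(ModelConfig(hidden_units=3, seed=1), D=4)
        X = rng.normal(size=(6, 4))
        mask = np.array([True, True, True, False, False, False])
        X[~mask] = 0.0
        H = bigru_forward(_enc(X, mask), model.params)
        assert np.all(H[~mask] == 0.0)
        assert np.any(H[mask] != 0.0)

    def test_sequence_reversal_swaps_direction_blocks(self, rng):
        """With tied forward/backward parameters, reversing the tokens
        mirrors H and swaps its two u-wide halves."""
        u = 3
        model = RelationModel(ModelConfig(hidden_units=u, seed=2), D=4)
        for name in ("Wx", "Wh", "bx", "bh"):
            model.params[f"b_{name}"] = model.params[f"f_{name}"].copy()
        X = rng.normal(size=(5, 4))
        mask = np.ones(5, bool)
        H = bigru_forward(_enc(X, mask), model.params)
        H_rev = bigru_forward(_enc(X[::-1], mask), model.params)
        assert np.allclose(H_rev[::-1, :u], H[:, u:], atol=1e-10)
        assert np.allclose(H_rev[::-1, u:], H[:, :u], atol=1e-10)


class TestClassify:
    def test_uniform_logits_give_uniform_probs(self):
        scores = classify(np.zeros(2), np.zeros((2, 4)), np.zeros(4))
        assert np.allclose(scores.probs, 0.25)
        assert scores.predicted == "DS"  # lowest-index tie-break

    def test_two_logit_closed_form(self):
        W = np.array([[1.0, 0.0]])
        scores = classify(np.array([1.0]), W, np.zeros(2), labels=("A", "B"))
        e = np.e
        assert np.allclose(scores.probs, [e / (e + 1), 1 / (e + 1)], atol=1e-9)
        assert scores.predicted == "A"

    def test_probs_normalised_for_random_logits(self, rng):
        for _ in range(20):
            c = rng.normal(size=6)
            scores = classify(c, rng.normal(size=(6, 4)), rng.normal(size=4))
            assert np.isclose(scores.probs.sum(), 1.0, atol=1e-6)
            assert scores.predicted == ("DS", "SFD", "NSFD", "UKN")[scores.probs.argmax()]

    def test_non_finite_logits_rejected(self):
        with pytest.raises(FloatingPointError):
            classify(np.array([np.inf, 0.0]), np.eye(2), np.zeros(2), labels=("A", "B"))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Every analytic gradient (both GRU directions, attention, head,
        and the input features) agrees with central differences."""
        cfg = ModelConfig(hidden_units=2, labels=("A", "B", "C"),
                          dropout=0.0, seed=1)
        model = RelationModel(cfg, D=3)
        X = rng.normal(size=(2, 4, 3))
        mask = np.ones((2, 4), bool)
        mask[0, 2:] = False
        y = np.array([0, 2])
        _, grads, dX = model.loss_and_grads(X, mask, y, need_dX=True)
        eps = 1e-6

        def num_grad(get, set_):
            old = get()
            set_(old + eps)
            l1, _, _ = model.loss_and_grads(X, mask, y)
            set_(old - eps)
            l2, _, _ = model.loss_and_grads(X, mask, y)
            set_(old)
            return (l1 - l2) / (2 * eps)

        for name, p in model.params.items():
            flat = p.reshape(-1)
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                def get(i=i, flat=flat):
                    return flat[i]

                def set_(v, i=i, flat=flat):
                    flat[i] = v

                assert abs(num_grad(get, set_) - grads[name].reshape(-1)[i]) < 1e-7, name
        flatX = X.reshape(-1)
        for i in rng.choice(flatX.size, size=8, replace=False):
            def get(i=i):
                return flatX[i]

            def set_(v, i=i):
                flatX[i] = v

            assert abs(num_grad(get, set_) - dX.reshape(-1)[i]) < 1e-7


def _toy_separable(n_per_class=10, L=6, D=5, seed=0):
    """Two classes distinguished by which of two tokens appears."""
    backend = LookupBackend(L=L, D=D, seed=seed)
    insts = []
    rng = np.random.default_rng(seed)
    for label, token in (("DS", "hot"), ("SFD", "cold")):
        for i in range(n_per_class):
            filler = " ".join(rng.choice(["a", "b", "c"], size=3))
            insts.append(backend.encode(f"# {token} {filler} *", label=label))
    return insts, backend


class TestTraining:
    def test_loss_non_increasing_on_separable_data(self):
        insts, backend = _toy_separable()
        cfg = ModelConfig(hidden_units=4, labels=("DS", "SFD"), dropout=0.0,
                          batch_size=20, epochs=15, optimizer="sgd",
                          learning_rate=0.05, seed=0)
        model = RelationModel(cfg, D=5)
        trace = model.fit(insts, insts, backend=backend, train_embeddings=False)
        losses = [t["loss"] for t in trace]
        assert all(b <= a + 1e-6 for a, b in zip(losses, losses[1:]))
        assert losses[-1] < losses[0]

    def test_zero_learning_rate_changes_nothing(self):
        insts, backend = _toy_separable()
        cfg = ModelConfig(hidden_units=4, labels=("DS", "SFD"), dropout=0.0,
                          batch_size=20, epochs=4, optimizer="sgd",
                          learning_rate=0.0, seed=0)
        model = RelationModel(cfg, D=5)
        before = {k: v.copy() for k, v in model.params.items()}
        trace = model.fit(insts, insts, backend=backend, train_embeddings=False)
        after = model.params
        for k in before:
            assert np.array_equal(before[k], after[k])
        losses = [t["loss"] for t in trace]
        assert np.ptp(losses) < 1e-12

    def test_same_seed_same_validation_curve(self):
        insts, backend = _toy_separable()
        cfg = ModelConfig(hidden_units=4, labels=("DS", "SFD"), epochs=3,
                          batch_size=8, seed=7)
        traces = []
        for _ in range(2):
            model = RelationModel(cfg, D=5)
            traces.append(
                model.fit(insts, insts, backend=backend, train_embeddings=False)
            )
        assert traces[0] == traces[1]

    def test_empty_training_set_rejected(self):
        model = RelationModel(ModelConfig(labels=("DS", "SFD")), D=4)
        with pytest.raises(ValueError):
            model.fit([], [])

    def test_noise_degrades_f1_on_average(self):
        """Held-out F1 at heavy noise does not exceed the noiseless F1
        (averaged over seeds) — the attention layer has more to filter."""

        def run(seed, noise):
            _, golds = generate_corpus(
                GeneratorConfig(n_records=200, seed=seed,
                                noise_sentence_rate=noise)
            )
            tr, va, te = stratified_split(golds, SplitSpec(seed=seed))
            backend = LookupBackend(L=48, D=24, seed=seed)
            etr = encode_dataset(backend, tr)
            eva = encode_dataset(backend, va)
            ete = encode_dataset(backend, te)
            model = RelationModel(
                ModelConfig(hidden_units=16, epochs=8, seed=seed), D=24
            )
            model.fit(etr, eva, backend=backend)
            return model.score(ete)["F1"]

        seeds = (0, 1, 2)
        clean = np.mean([run(s, 0.0) for s in seeds])
        noisy = np.mean([run(s, 0.8) for s in seeds])
        assert noisy <= clean + 1e-9


class TestPredictTriples:
    def test_record_without_disease_yields_no_triples(self):
        backend = LookupBackend(L=16, D=8, seed=0)
        model = RelationModel(ModelConfig(hidden_units=2, seed=0), D=8)
        rec = QARecord(
            record_id="r", question_title="", question_content="sym0 hurts",
            answers=["rest"],
            mentions=[EntityMention("sym0", "SYM", 0, 4)],
        )
        assert predict_triples([rec], model, backend) == []

    def test_candidate_pairs_are_classified(self, small_corpus):
        records, _ = small_corpus
        backend = LookupBackend(L=64, D=8, seed=0)
        model = RelationModel(ModelConfig(hidden_units=2, seed=0), D=8)
        triples = predict_triples(records[:10], model, backend)
        assert triples, "DIS-bearing records must produce candidate triples"
        assert all(t.relation in ("DS", "SFD", "NSFD", "UKN") for t in triples)
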