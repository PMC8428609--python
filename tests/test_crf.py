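import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from bionerkit.core_types import BIOES, EntityMention
from bionerkit.crf_tagger import (
    TagDictionary,
    TaggerModel,
    bioes_transition_mask,
    crf_marginals,
    crf_nll_op,
    log_partition,
    nll_loss,
    score_path,
    viterbi,
)
from bionerkit.embeddings import EmbeddingStack, WordEmbeddingTable
from bionerkit._autodiff import Parameter, Tensor

from conftest import make_sentence


def enumerate_scores(e, T):
    n, K = e.shape
    return {p: score_path(e, T, p) for p in itertools.product(range(K), repeat=n)}


def random_instance(rng, max_n=6, max_k=5):
    n = int(rng.integers(1, max_n + 1))
    K = int(rng.integers(1, max_k + 1))
    return rng.normal(size=(n, K)), rng.normal(size=(K + 2, K + 2))


class TestScorePath:
    def test_all_zero_single_token(self):
        e = np.zeros((1, 1))
        T = np.zeros((3, 3))
        assert score_path(e, T, [0]) == 0.0

    def test_sum_of_emissions_when_transitions_zero(self):
        e = np.array([[1.0, 0.0], [0.0, 1.0]])
        T = np.zeros((4, 4))
        assert score_path(e, T, [0, 1]) == 2.0

    def test_matches_term_by_term_oracle(self, rng):
        e = rng.normal(size=(4, 3))
        T = rng.normal(size=(5, 5))
        tags = [2, 0, 1, 1]
        expected = T[3, 2] + e[0, 2] + T[2, 0] + e[1, 0] + T[0, 1] + e[2, 1] + T[1, 1] + e[3, 1] + T[1, 4]
        assert score_path(e, T, tags) == pytest.approx(expected, abs=1e-12)

    def test_index_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_path(np.zeros((1, 2)), np.zeros((4, 4)), [2])


class TestLogPartition:
    def test_two_equal_paths(self):
        assert log_partition(np.zeros((1, 2)), np.zeros((4, 4))) == pytest.approx(np.log(2))

    def test_single_path(self):
        assert log_partition(np.zeros((1, 1)), np.zeros((3, 3))) == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            e, T = random_instance(rng)
            expected = logsumexp(list(enumerate_scores(e, T).values()))
            assert log_partition(e, T) == pytest.approx(expected, abs=1e-8)

    def test_rejects_nonfinite_emissions(self):
        e = np.array([[np.inf, 0.0]])
        with pytest.raises(ValueError):
            log_partition(e, np.zeros((4, 4)))

    def test_per_position_shift_invariance(self, rng):
        # adding c to every emission of one position shifts logZ by exactly c
        e, T = random_instance(rng, max_n=5, max_k=4)
        base = log_partition(e, T)
        shifted = e.copy()
        shifted[0] += 1.7
        assert log_partition(shifted, T) == pytest.approx(base + 1.7, abs=1e-9)


class TestNLL:
    def test_zero_when_single_possible_path(self):
        e = np.zeros((3, 1))
        T = np.zeros((3, 3))
        assert nll_loss(e, T, [0, 0, 0]) == pytest.approx(0.0)

    def test_equals_negative_log_enumerated_probability(self, rng):
        for _ in range(20):
            e, T = random_instance(rng, max_n=5, max_k=4)
            scores = enumerate_scores(e, T)
            logZ = logsumexp(list(scores.values()))
            gold = tuple(int(rng.integers(e.shape[1])) for _ in range(e.shape[0]))
            assert nll_loss(e, T, list(gold)) == pytest.approx(logZ - scores[gold], abs=1e-8)

    def test_strictly_positive_with_multiple_paths(self, rng):
        e, T = rng.normal(size=(3, 2)), rng.normal(size=(4, 4))
        assert nll_loss(e, T, [0, 1, 0]) > 0


class TestViterbi:
    def test_decoupled_chain_is_argmax(self, rng):
        e = rng.normal(size=(5, 4))
        T = np.zeros((6, 6))
        path, score = viterbi(e, T)
        assert path == list(np.argmax(e, axis=1))
        assert score == pytest.approx(e.max(axis=1).sum())

    def test_all_zero_scores_tie_break_to_tag_zero(self):
        path, score = viterbi(np.zeros((4, 3)), np.zeros((5, 5)))
        assert path == [0, 0, 0, 0] and score == 0.0

    def test_matches_brute_force_maximum(self, rng):
        for _ in range(40):
            e, T = random_instance(rng)
            scores = enumerate_scores(e, T)
            path, score = viterbi(e, T)
            assert score == pytest.approx(max(scores.values()), abs=1e-10)
            assert score == pytest.approx(score_path(e, T, path), abs=1e-10)

    def test_tie_break_lowest_index_at_latest_differing_position(self, rng):
        # quantized scores force ties; oracle = reversed-lexicographic minimum
        for _ in range(30):
            n, K = int(rng.integers(1, 5)), int(rng.integers(2, 4))
            e = rng.integers(0, 2, size=(n, K)).astype(float)
            T = rng.integers(0, 2, size=(K + 2, K + 2)).astype(float)
            scores = enumerate_scores(e, T)
            best = max(scores.values())
            optima = [p for p, s in scores.items() if abs(s - best) < 1e-12]
            expected = min(optima, key=lambda p: tuple(reversed(p)))
            path, _ = viterbi(e, T)
            assert tuple(path) == expected


class TestMarginals:
    def test_path_probabilities_sum_to_one(self, rng):
        for _ in range(20):
            e, T = random_instance(rng, max_n=5, max_k=4)
            scores = enumerate_scores(e, T)
            logZ = log_partition(e, T)
            total = sum(np.exp(s - logZ) for s in scores.values())
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_unary_marginals_match_enumeration(self, rng):
        e, T = random_instance(rng, max_n=4, max_k=3)
        n, K = e.shape
        scores = enumerate_scores(e, T)
        logZ, unary, _ = crf_marginals(e, T)
        for i in range(n):
            for k in range(K):
                expected = sum(
                    np.exp(s - logZ) for p, s in scores.items() if p[i] == k
                )
                assert unary[i, k] == pytest.approx(expected, abs=1e-8)

    def test_gradient_matches_finite_differences(self, rng):
        e = Parameter(rng.normal(size=(4, 3)))
        T = Parameter(rng.normal(size=(5, 5)))
        gold = np.array([0, 2, 1, 1])
        crf_nll_op(e, T, gold).backward()
        eps = 1e-6
        for p in (e, T):
            flat = p.data.ravel()
            grad = p.grad.ravel()
            for idx in range(0, flat.size, 3):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(crf_nll_op(Tensor(e.data), Tensor(T.data), gold).data)
                flat[idx] = orig - eps
                down = float(crf_nll_op(Tensor(e.data), Tensor(T.data), gold).data)
                flat[idx] = orig
                assert grad[idx] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


class TestTaggerModel:
    @pytest.fixture()
    def model(self):
        stack = EmbeddingStack([WordEmbeddingTable(dim=8, seed=0)])
        return TaggerModel(stack, ["Gene"], hidden_size=8, seed=0)

    def test_untrained_predictions_are_wellformed(self, model):
        sent = make_sentence(["TLK9", "is", "mutated", "."])
        mentions = model.predict(sent)
        for m in mentions:
            assert m.end > m.start and m.type == "Gene"

    def test_empty_sentence_predicts_empty(self, model):
        from bionerkit.core_types import Sentence

        assert model.predict(Sentence((), doc_id="x")) == []

    def test_prediction_deterministic(self, model):
        sent = make_sentence(["TLK9", "levels", "rose", "."])
        assert model.predict(sent) == model.predict(sent)

    def test_overfits_single_sentence(self):
        from bionerkit._autodiff import clip_gradients, sgd_step, zero_gradients
        from bionerkit.core_types import spans_to_tags

        stack = EmbeddingStack([WordEmbeddingTable(dim=8, seed=1)])
        model = TaggerModel(stack, ["Gene"], hidden_size=8, seed=1)
        sent = make_sentence(["TLK9", "is", "mutated", "."])
        gold = [EntityMention(0, 4, "Gene", "TLK9")]
        feats = stack.embed_sentence(sent)
        gold_idx = model.tag_dict.encode(spans_to_tags(sent, gold, BIOES))
        params = model.parameters()
        for _ in range(150):
            zero_gradients(params)
            loss = model.loss(feats, gold_idx)
            loss.backward()
            clip_gradients(params, 5.0)
            sgd_step(params, 0.5)
        assert model.predict(sent) == gold

    def test_checkpoint_round_trip(self, model, tmp_path):
        sent = make_sentence(["TLK9", "is", "here", "."])
        before = model.predict(sent)
        model.save(tmp_path / "tagger.npz")
        loaded = TaggerModel.load(tmp_path / "tagger.npz", model.stack)
        assert loaded.predict(sent) == before
        for a, b in zip(model.parameters(), loaded.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_strict_mask_forbids_impossible_bigrams(self):
        td = TagDictionary(["Gene"], BIOES)
        mask = bioes_transition_mask(td)
        o, b, i, e_, s = (td.index[t] for t in ("O", "B-Gene", "I-Gene", "E-Gene", "S-Gene"))
        assert mask[o, e_] < 0  # O -> E-X impossible
        assert mask[b, i] == 0  # B -> I fine
        assert mask[b, o] < 0  # B must continue the mention
        assert mask[td.start, i] < 0
        assert mask[s, td.stop] == 0
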