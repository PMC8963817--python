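import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rpistack import rna_embedding as re_
from rpistack.seqio import SequenceRecord


def rna(seq, rid="r"):
    return SequenceRecord(rid, seq, "rna")


class TestTokenize:
    def test_overlapping_3mers(self):
        assert re_.tokenize(rna("ACGUA")) == ["ACG", "CGU", "GUA"]

    def test_repeated_base(self):
        assert re_.tokenize(rna("AAAA")) == ["AAA", "AAA"]

    def test_ambiguous_windows_skipped_entirely(self, caplog):
        with caplog.at_level("WARNING"):
            assert re_.tokenize(rna("ACNGU")) == []
        assert "no valid tokens" in caplog.text

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="length 2"):
            re_.tokenize(rna("AC"))

    @given(st.text(alphabet="ACGU", min_size=3, max_size=60))
    def test_token_count_is_length_minus_two(self, seq):
        assert len(re_.tokenize(rna(seq))) == len(seq) - 2


class TestCooccurrence:
    def _corpus(self, words):
        return re_.KmerCorpus(sentences=[np.array([re_.WORD_INDEX[w] for w in words])])

    def test_hand_counted_three_token_sentence(self):
        X = re_.build_cooccurrence(self._corpus(["AAA", "CCC", "AAA"]), window=1)
        i, j = re_.WORD_INDEX["AAA"], re_.WORD_INDEX["CCC"]
        assert X.counts[i, j] == 2
        assert X.counts[j, i] == 2
        assert X.counts[i, i] == 0
        assert X.probabilities[j, i] == 1.0

    def test_rows_normalize_and_matrix_symmetric(self, rng):
        sentences = [rng.integers(0, re_.V, size=30) for _ in range(4)]
        X = re_.build_cooccurrence(re_.KmerCorpus(sentences=sentences), window=3)
        np.testing.assert_allclose(X.counts, X.counts.T)
        p = X.probabilities
        pos = X.row_totals > 0
        np.testing.assert_allclose(p[pos].sum(axis=1), 1.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            re_.build_cooccurrence(re_.KmerCorpus(sentences=[]), window=2)


class TestGloveWeight:
    def test_saturation_branch(self):
        assert re_.glove_weight(100.0) == 1.0
        assert re_.glove_weight(200.0) == 1.0

    def test_zero_count(self):
        assert re_.glove_weight(0.0) == 0.0

    def test_power_law_below_xmax(self):
        assert re_.glove_weight(50.0, x_max=100.0, alpha=0.75) == pytest.approx(0.5 ** 0.75)


@pytest.fixture(scope="module")
def toy_training():
    rng = np.random.default_rng(5)
    sentences = [rng.integers(0, 5, size=60) for _ in range(4)]
    X = re_.build_cooccurrence(re_.KmerCorpus(sentences=sentences), window=2)
    config = re_.GloVeConfig(dim=8, epochs=50, seed=5)
    return X, config, re_.train_glove(X, config)


class TestTrainGlove:
    def test_loss_strictly_decreases_early(self, toy_training):
        _, _, model = toy_training
        losses = model.loss_history
        assert all(b < a for a, b in zip(losses[:10], losses[1:11]))
        assert losses[-1] <= losses[0]

    def test_recorded_loss_matches_independent_recomputation(self, toy_training):
        X, config, model = toy_training
        J = re_.glove_loss(model.w, model.w_ctx, model.b, model.b_ctx,
                           X.counts, config.x_max, config.alpha)
        assert J == pytest.approx(model.loss_history[-1], rel=1e-12)

    def test_deterministic_under_seed(self, toy_training):
        X, config, model = toy_training
        again = re_.train_glove(X, config)
        assert (model.w == again.w).all() and (model.b_ctx == again.b_ctx).all()

    def test_numerical_gradient_matches_analytic(self):
        rng = np.random.default_rng(2)
        counts = np.zeros((re_.V, re_.V))
        idx = [re_.WORD_INDEX[w] for w in ("AAA", "CCC", "GGG")]
        for a in idx:
            for b in idx:
                if a != b:
                    counts[a, b] = rng.integers(1, 20)
        w = rng.normal(size=(re_.V, 4)) * 0.1
        wc = rng.normal(size=(re_.V, 4)) * 0.1
        b = rng.normal(size=re_.V) * 0.1
        bc = rng.normal(size=re_.V) * 0.1
        gw, gwc, gb, gbc = re_.glove_gradients(w, wc, b, bc, counts)
        eps = 1e-6
        for arr, grad, pos in ((w, gw, (idx[0], 1)), (wc, gwc, (idx[1], 2)),
                               (b, gb, (idx[2],)), (bc, gbc, (idx[0],))):
            up, down = arr.copy(), arr.copy()
            up[pos] += eps
            down[pos] -= eps
            args = {id(w): w, id(wc): wc, id(b): b, id(bc): bc}
            args[id(arr)] = up
            j_up = re_.glove_loss(args[id(w)], args[id(wc)], args[id(b)], args[id(bc)], counts)
            args[id(arr)] = down
            j_down = re_.glove_loss(args[id(w)], args[id(wc)], args[id(b)], args[id(bc)], counts)
            numeric = (j_up - j_down) / (2 * eps)
            assert numeric == pytest.approx(grad[pos], abs=1e-4)

    def test_invalid_configs_rejected(self, toy_training):
        X, _, _ = toy_training
        with pytest.raises(ValueError):
            re_.train_glove(X, re_.GloVeConfig(dim=0))
        with pytest.raises(ValueError):
            re_.train_glove(X, re_.GloVeConfig(epochs=0))
        with pytest.raises(ValueError):
            re_.train_glove(re_.CooccurrenceMatrix(np.zeros((re_.V, re_.V)), np.zeros(re_.V)))


class TestEmbedWord:
    def test_vector_length_is_dim(self, toy_training):
        _, config, model = toy_training
        assert re_.embed_word(model, "AAA").shape == (config.dim,)

    def test_dna_style_token_unknown(self, toy_training):
        _, _, model = toy_training
        with pytest.raises(KeyError, match="TTT"):
            re_.embed_word(model, "TTT")


class TestLfsPool:
    def test_identical_vectors_pool_to_repeats(self):
        v = np.arange(4.0)
        out = re_.lfs_pool(np.tile(v, (22, 1)), G=11)
        np.testing.assert_allclose(out, np.tile(v, 11))

    def test_short_input_zero_fills_trailing_blocks(self):
        vecs = np.arange(10.0).reshape(5, 2)
        out = re_.lfs_pool(vecs, G=11).reshape(11, 2)
        np.testing.assert_allclose(out[:5], vecs)
        assert not out[5:].any()

    def test_block_sizes_larger_first(self, rng):
        vecs = rng.normal(size=(23, 3))
        out = re_.lfs_pool(vecs, G=11).reshape(11, 3)
        sizes = [3] + [2] * 10
        start = 0
        for g, size in enumerate(sizes):
            np.testing.assert_allclose(out[g], vecs[start:start + size].mean(axis=0))
            start += size

    @given(st.integers(min_value=0, max_value=60), st.integers(min_value=1, max_value=13))
    def test_matches_loop_oracle(self, L, G):
        rng = np.random.default_rng(L * 17 + G)
        vecs = rng.normal(size=(L, 2))
        out = re_.lfs_pool(vecs, G=G).reshape(G, 2)
        base, rem = divmod(L, G)
        start = 0
        for g in range(G):
            size = base + 1 if g < rem else base
            expected = vecs[start:start + size].mean(axis=0) if size else np.zeros(2)
            np.testing.assert_allclose(out[g], expected)
            start += size

    def test_invalid_group_count(self):
        with pytest.raises(ValueError):
            re_.lfs_pool(np.zeros((3, 2)), G=0)


class TestFeatureVectorAndExport:
    def test_fixed_length_regardless_of_rna_length(self, toy_training):
        _, _, model = toy_training
        emb = model.embedding_matrix
        for seq in ("ACGUA", "ACGU" * 50):
            vec = re_.rna_feature_vector(rna(seq), emb, G=11)
            assert vec.shape == (11 * emb.shape[1],)

    def test_tsv_roundtrip(self, toy_training, tmp_path):
        _, _, model = toy_training
        path = tmp_path / "emb.tsv"
        re_.save_embedding_tsv(model, path)
        matrix, meta = re_.load_embedding_tsv(path)
        np.testing.assert_allclose(matrix, model.embedding_matrix)
        assert meta["d"] == str(model.config.dim)
        assert meta["window"] == str(model.config.window)
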