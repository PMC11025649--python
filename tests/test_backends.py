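import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embinfer import (
    FormatError,
    FunctionEncoder,
    OOVError,
    TokenizerConfig,
    cosine_similarity,
    discourse_vector,
    embed_target,
    load_word_vectors,
    tokenize,
    write_word_vectors,
)
from conftest import make_lexicon, random_rotation


class TestTokenize:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("A moment later, she heard", ["a", "moment", "later", "she", "heard"]),
            ("", []),
            ("   ", []),
            ("Hello, world!", ["hello", "world"]),
            ("one ... two", ["one", "two"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    def test_preserving_config(self):
        cfg = TokenizerConfig(lowercase=False, strip_punctuation=False)
        assert tokenize("Hello, World!", cfg) == ["Hello,", "World!"]

    @given(st.lists(st.text(alphabet="abcdefghij", min_size=1, max_size=8), max_size=20))
    @settings(deadline=None)
    def test_idempotent_on_clean_tokens(self, words):
        tokens = tokenize(" ".join(words))
        assert tokenize(" ".join(tokens)) == tokens


class TestWordVectorIO:
    def test_glove_text_roundtrip(self, tmp_path):
        lex = make_lexicon({"aa": [0.25, -1.5], "bb": [1e-7, 3.25], "cc": [2.0, 0.1]})
        path = write_word_vectors(lex, tmp_path / "vec.txt", format="glove-text")
        loaded = load_word_vectors(path, format="glove-text")
        assert len(loaded) == 3 and loaded.dim == 2
        for w, v in lex.vectors.items():
            assert np.array_equal(loaded.lookup(w), v)  # bit-exact

    def test_word2vec_text_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        lex = make_lexicon({f"w{i}": rng.standard_normal(5) for i in range(7)})
        path = write_word_vectors(lex, tmp_path / "vec.txt", format="word2vec-text")
        loaded = load_word_vectors(path, format="word2vec-text")
        assert len(loaded) == 7
        for w, v in lex.vectors.items():
            assert np.array_equal(loaded.lookup(w), v)

    def test_word2vec_bin(self, tmp_path):
        vals = {"cat": np.array([0.5, -2.0, 3.0], dtype="<f4"),
                "dog": np.array([1.0, 0.0, -1.25], dtype="<f4")}
        path = tmp_path / "vec.bin"
        with open(path, "wb") as fh:
            fh.write(b"2 3\n")
            for w, v in vals.items():
                fh.write(w.encode() + b" " + v.tobytes())
        lex = load_word_vectors(path, format="word2vec-bin")
        assert lex.dim == 3
        for w, v in vals.items():
            assert np.allclose(lex.lookup(w), v)

    def test_header_count_mismatch(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("5 2\na 1 2\nb 3 4\nc 5 6\nd 7 8\n")
        with pytest.raises(FormatError, match="declares 5"):
            load_word_vectors(path, format="word2vec-text")

    def test_ragged_line_names_lineno(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("a 1 2\nb 3\n")
        with pytest.raises(FormatError, match="line 2"):
            load_word_vectors(path, format="glove-text")

    def test_empty_file(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("")
        with pytest.raises(FormatError):
            load_word_vectors(path, format="glove-text")

    def test_duplicates_keep_first(self, tmp_path, caplog):
        path = tmp_path / "vec.txt"
        path.write_text("a 1 2\na 3 4\nb 5 6\n")
        with caplog.at_level("WARNING"):
            lex = load_word_vectors(path, format="glove-text")
        assert np.array_equal(lex.lookup("a"), [1.0, 2.0])
        assert any("duplicate" in r.message for r in caplog.records)


class TestDiscourseVector:
    def test_single_word_is_own_vector(self, tiny_lexicon):
        assert np.array_equal(
            discourse_vector(tiny_lexicon, "alpha"), tiny_lexicon.lookup("alpha")
        )

    def test_mean_of_two(self, tiny_lexicon):
        assert np.allclose(discourse_vector(tiny_lexicon, "alpha beta"), [0.5, 0.5])

    def test_repeated_word_equals_word(self, tiny_lexicon):
        vec = discourse_vector(tiny_lexicon, "beta beta beta beta beta")
        assert np.allclose(vec, tiny_lexicon.lookup("beta"), atol=1e-12)

    def test_permutation_invariance_exact(self, tiny_lexicon):
        rng = np.random.default_rng(1)
        words = ["alpha", "beta", "gamma", "delta", "alpha", "gamma"]
        base = discourse_vector(tiny_lexicon, " ".join(words))
        for _ in range(10):
            rng.shuffle(words)
            assert np.array_equal(base, discourse_vector(tiny_lexicon, " ".join(words)))

    def test_oov_skipped_from_sum_and_count(self, tiny_lexicon):
        assert np.array_equal(
            discourse_vector(tiny_lexicon, "alpha unknown"),
            tiny_lexicon.lookup("alpha"),
        )

    def test_all_oov_raises_with_count(self, tiny_lexicon):
        with pytest.raises(ValueError, match="2 OOV"):
            discourse_vector(tiny_lexicon, "foo bar")

    def test_oov_error_policy(self):
        lex = make_lexicon({"a": [1.0, 0.0]}, oov_policy="error")
        with pytest.raises(OOVError):
            discourse_vector(lex, "a b")


class TestCosine:
    @pytest.mark.parametrize(
        "u, v, expected",
        [([1, 0], [1, 0], 1.0), ([1, 0], [0, 1], 0.0), ([1, 0], [-1, 0], -1.0)],
    )
    def test_reference_angles(self, u, v, expected):
        assert cosine_similarity(np.array(u, float), np.array(v, float)) == expected

    def test_zero_norm_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity(np.zeros(2), np.ones(2))

    def test_dim_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity(np.ones(2), np.ones(3))

    def test_symmetry_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            u, v = rng.standard_normal(6), rng.standard_normal(6)
            c = cosine_similarity(u, v)
            assert c == cosine_similarity(v, u)
            assert abs(c) <= 1.0
            assert np.isclose(c, cosine_similarity(3.7 * u, 0.2 * v), atol=1e-12)

    @pytest.mark.parametrize("dim", [2, 5, 10])
    def test_rotation_invariance(self, dim):
        rng = np.random.default_rng(dim)
        for _ in range(20):
            u, v = rng.standard_normal(dim), rng.standard_normal(dim)
            q = random_rotation(rng, dim)
            assert np.isclose(
                cosine_similarity(u, v), cosine_similarity(q @ u, q @ v), atol=1e-10
            )


class TestEmbedTarget:
    def test_static_lookup(self):
        lex = make_lexicon({"crash": [0.3, 0.4]})
        assert np.array_equal(embed_target(lex, "crash"), [0.3, 0.4])

    def test_static_oov_names_word(self, tiny_lexicon):
        with pytest.raises(OOVError, match="missingword"):
            embed_target(tiny_lexicon, "missingword")

    def test_case_policy_lookup(self):
        lex = make_lexicon({"Crash": [1.0, 0.0]})
        assert np.array_equal(embed_target(lex, "CRASH"), [1.0, 0.0])

    def test_contextual_encoder_deterministic(self):
        enc = FunctionEncoder(
            lambda text: np.array([float(sum(map(ord, text))), float(len(text))]),
            dim=2,
            name="charcodes",
        )
        assert np.array_equal(embed_target(enc, "word"), embed_target(enc, "word"))
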