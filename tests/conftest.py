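import numpy as np
import pytest

from embinfer import StaticLexicon, SyntheticConfig, generate_world


def make_lexicon(words_vectors: dict, **kwargs) -> StaticLexicon:
    vecs = {w: np.asarray(v, dtype=float) for w, v in words_vectors.items()}
    dim = len(next(iter(vecs.values())))
    return StaticLexicon(vectors=vecs, dim=dim, **kwargs)


@pytest.fixture
def tiny_lexicon() -> StaticLexicon:
    return make_lexicon(
        {
            "alpha": [1.0, 0.0],
            "beta": [0.0, 1.0],
            "gamma": [1.0, 1.0],
            "delta": [-1.0, 0.0],
        }
    )


@pytest.fixture(scope="session")
def small_world():
    """A small planted world shared by read-only tests."""
    cfg = SyntheticConfig(
        dim=8,
        vocab_size=20,
        n_chwilla_pairs=10,
        n_metusalem_items=12,
        n_mckoon_items=10,
        seed=42,
    )
    return generate_world(cfg)


def random_rotation(rng: np.random.Generator, dim: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


def rotate_lexicon(lexicon: StaticLexicon, q: np.ndarray) -> StaticLexicon:
    return StaticLexicon(
        vectors={w: q @ v for w, v in lexicon.vectors.items()},
        dim=lexicon.dim,
        oov_policy=lexicon.oov_policy,
        case_policy=lexicon.case_policy,
        name=lexicon.name + "-rotated",
    )
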