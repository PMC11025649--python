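"""Embedding backends: static lexicons, contextual encoders, and cosine geometry.

Two families of backends are supported, mirroring the two families of
language models the evaluation framework compares:

* **Static lexicons** assign one context-independent vector per word
  (word2vec / GloVe style).  A multi-word text is represented by the
  unweighted arithmetic mean of its word vectors (the *discourse vector*),
  which is by construction invariant to word order.
* **Contextual encoders** map a whole text to a fixed-length vector through
  an arbitrary deterministic callable, and may therefore be sensitive to
  word order.

All similarity comparisons use the cosine of the angle between vectors
(1 = identical direction, 0 = orthogonal, -1 = antiparallel).
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "OOVError",
    "TokenizerConfig",
    "StaticLexicon",
    "ContextualEncoder",
    "FunctionEncoder",
    "Backend",
    "tokenize",
    "load_word_vectors",
    "write_word_vectors",
    "discourse_vector",
    "cosine_similarity",
    "embed_target",
    "embed_text",
]


class FormatError(ValueError):
    """A word-vector file does not conform to its declared dialect."""


class OOVError(KeyError):
    """A required word is missing from a static lexicon's vocabulary."""

    def __str__(self) -> str:  # KeyError quotes its payload; we want prose
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class TokenizerConfig:
    """Word-splitting rule used to turn text into lexicon keys.

    The default (lowercase, strip surrounding punctuation, split on
    whitespace) matches how word2vec/GloVe vocabularies are usually keyed.
    """

    lowercase: bool = True
    strip_punctuation: bool = True
    token_pattern: str = "whitespace"


def tokenize(text: str, config: TokenizerConfig = TokenizerConfig()) -> list[str]:
    """Split ``text`` into word tokens according to ``config``.

    Deterministic; the empty string yields an empty list.  Tokens that are
    pure punctuation are dropped when ``strip_punctuation`` is set.
    """
    tokens = []
    for raw in text.split():
        tok = raw
        if config.strip_punctuation:
            tok = tok.strip(string.punctuation)
        if config.lowercase:
            tok = tok.lower()
        if tok:
            tokens.append(tok)
    return tokens


def _as_vector(values: Iterable[float]) -> np.ndarray:
    vec = np.asarray(values, dtype=np.float64)
    if vec.ndim != 1 or vec.size < 1:
        raise ValueError("embedding vectors must be 1-d with dim >= 1")
    if not np.all(np.isfinite(vec)):
        raise ValueError("embedding vector has non-finite components")
    return vec


@dataclass
class StaticLexicon:
    """A word -> vector map with fixed dimensionality.

    Parameters
    ----------
    vectors
        Mapping from word to a 1-d float vector; all of length ``dim``.
    oov_policy
        ``"skip"`` excludes out-of-vocabulary context tokens from the
        discourse average (they count neither in the sum nor the
        denominator); ``"error"`` raises on any OOV token.  Target words
        are never skipped regardless of policy.
    case_policy
        ``"lower"`` folds lookups (and stored keys) to lowercase;
        ``"preserve"`` matches keys verbatim.
    """

    vectors: dict[str, np.ndarray]
    dim: int
    oov_policy: str = "skip"
    case_policy: str = "lower"
    name: str = "static-lexicon"

    def __post_init__(self) -> None:
        if self.oov_policy not in ("skip", "error"):
            raise ValueError(f"unknown oov_policy {self.oov_policy!r}")
        if self.case_policy not in ("lower", "preserve"):
            raise ValueError(f"unknown case_policy {self.case_policy!r}")
        if self.case_policy == "lower":
            self.vectors = {w.lower(): v for w, v in self.vectors.items()}
        for word, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(
                    f"vector for {word!r} has length {vec.shape}, expected ({self.dim},)"
                )

    def _key(self, word: str) -> str:
        return word.lower() if self.case_policy == "lower" else word

    def __contains__(self, word: str) -> bool:
        return self._key(word) in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def lookup(self, word: str) -> np.ndarray:
        """Return the stored vector for ``word`` (after case policy).

        Raises :class:`OOVError` if the word is not in the vocabulary.
        """
        key = self._key(word)
        try:
            return self.vectors[key]
        except KeyError:
            raise OOVError(f"word {word!r} not in vocabulary (size {len(self)})") from None


class ContextualEncoder:
    """Contract for contextual backends: a deterministic text -> vector map.

    Subclasses implement :meth:`encode`; the output must have length
    ``dim`` for any input, and the same text must always yield the same
    vector once the encoder is constructed.
    """

    dim: int
    name: str

    def encode(self, text: str) -> np.ndarray:
        raise NotImplementedError


class FunctionEncoder(ContextualEncoder):
    """Wrap a plain callable as a :class:`ContextualEncoder`."""

    def __init__(self, fn: Callable[[str], np.ndarray], dim: int, name: str):
        self._fn = fn
        self.dim = dim
        self.name = name

    def encode(self, text: str) -> np.ndarray:
        vec = _as_vector(self._fn(text))
        if vec.shape != (self.dim,):
            raise ValueError(
                f"encoder {self.name!r} returned length {vec.size}, expected {self.dim}"
            )
        return vec


Backend = Union[StaticLexicon, ContextualEncoder]


# ---------------------------------------------------------------------------
# Word-vector file I/O
#
# Dialects:
#   glove-text     one "word v1 ... vd" line per word, no header
#   word2vec-text  first line "count dim", then as glove-text
#   word2vec-bin   first line "count dim\n" in ASCII, then for each word the
#                  word bytes, a space, and dim little-endian float32 values
# ---------------------------------------------------------------------------

_FORMATS = ("glove-text", "word2vec-text", "word2vec-bin")


def _parse_text_line(line: str, lineno: int, dim: int | None) -> tuple[str, np.ndarray]:
    parts = line.rstrip("\n").split(" ")
    if len(parts) < 2:
        raise FormatError(f"line {lineno}: expected 'word v1 ... vd'")
    word = parts[0]
    try:
        vec = np.array(parts[1:], dtype=np.float64)
    except ValueError:
        raise FormatError(f"line {lineno}: non-numeric vector component") from None
    if dim is not None and vec.size != dim:
        raise FormatError(
            f"line {lineno}: vector length {vec.size} does not match dim {dim}"
        )
    return word, vec


def load_word_vectors(
    path: str | Path,
    format: str = "glove-text",
    oov_policy: str = "skip",
    case_policy: str = "lower",
) -> StaticLexicon:
    """Load a static lexicon from a word-vector file.

    Duplicate words keep the first occurrence (a warning is logged).
    Malformed headers or ragged vector lengths raise :class:`FormatError`
    naming the offending line; an empty file is an error.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")

    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    n_dup = 0

    def _store(word: str, vec: np.ndarray) -> None:
        nonlocal n_dup
        if word in vectors:
            n_dup += 1
        else:
            vectors[word] = vec

    if format == "word2vec-bin":
        with open(path, "rb") as fh:
            header = fh.readline().decode("utf-8", errors="replace").split()
            if len(header) != 2:
                raise FormatError("line 1: expected header 'count dim'")
            try:
                count, dim = int(header[0]), int(header[1])
            except ValueError:
                raise FormatError("line 1: non-integer header fields") from None
            for i in range(count):
                word_bytes = bytearray()
                while True:
                    ch = fh.read(1)
                    if ch == b"":
                        raise FormatError(f"entry {i + 1}: truncated file")
                    if ch == b" ":
                        break
                    if ch != b"\n":  # tolerate leading newlines between entries
                        word_bytes.extend(ch)
                buf = fh.read(4 * dim)
                if len(buf) != 4 * dim:
                    raise FormatError(f"entry {i + 1}: truncated vector")
                vec = np.frombuffer(buf, dtype="<f4").astype(np.float64)
                _store(word_bytes.decode("utf-8"), vec)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
        start = 0
        declared: int | None = None
        if format == "word2vec-text":
            if not lines:
                raise FormatError("empty file")
            header = lines[0].split()
            if len(header) != 2:
                raise FormatError("line 1: expected header 'count dim'")
            try:
                declared, dim = int(header[0]), int(header[1])
            except ValueError:
                raise FormatError("line 1: non-integer header fields") from None
            start = 1
        for lineno, line in enumerate(lines[start:], start=start + 1):
            if not line.strip():
                continue
            word, vec = _parse_text_line(line, lineno, dim)
            if dim is None:
                dim = vec.size
            _store(word, vec)
        if declared is not None and len(vectors) + n_dup != declared:
            raise FormatError(
                f"header declares {declared} words but file contains "
                f"{len(vectors) + n_dup}"
            )

    if not vectors:
        raise FormatError(f"no word vectors found in {path}")
    if n_dup:
        logger.warning("%s: %d duplicate words; kept first occurrences", path, n_dup)
    assert dim is not None
    lex = StaticLexicon(
        vectors=vectors,
        dim=int(dim),
        oov_policy=oov_policy,
        case_policy=case_policy,
        name=path.stem,
    )
    logger.info("loaded %d vectors of dim %d from %s", len(lex), dim, path)
    return lex


def write_word_vectors(
    lexicon: StaticLexicon, path: str | Path, format: str = "glove-text"
) -> Path:
    """Write a lexicon in a text dialect with full float64 round-trip precision."""
    if format not in ("glove-text", "word2vec-text"):
        raise ValueError("writer supports the text dialects only")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if format == "word2vec-text":
            fh.write(f"{len(lexicon)} {lexicon.dim}\n")
        for word, vec in lexicon.vectors.items():
            comps = " ".join(format_float(x) for x in vec)
            fh.write(f"{word} {comps}\n")
    return path


def format_float(x: float) -> str:
    """Shortest decimal representation that round-trips a float64 exactly."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# Vector operations
# ---------------------------------------------------------------------------


def discourse_vector(
    lexicon: StaticLexicon, text: str, config: TokenizerConfig = TokenizerConfig()
) -> np.ndarray:
    """Unweighted mean of the vectors of all resolved tokens of ``text``.

    OOV tokens are excluded from both the sum and the count under the
    ``skip`` policy, and raise under ``error``.  The resolved vectors are
    accumulated in sorted-token order so the result is *exactly* invariant
    under any permutation of the token multiset (no float-summation-order
    artifacts) — the order-blindness characteristic of averaged static
    representations.
    """
    tokens = tokenize(text, config)
    resolved: list[str] = []
    n_oov = 0
    for tok in tokens:
        if tok in lexicon:
            resolved.append(tok)
        elif lexicon.oov_policy == "error":
            raise OOVError(f"token {tok!r} not in vocabulary")
        else:
            n_oov += 1
    if not resolved:
        raise ValueError(
            f"no resolvable tokens in text ({len(tokens)} tokens, {n_oov} OOV)"
        )
    if n_oov:
        logger.debug("discourse_vector: skipped %d OOV tokens", n_oov)
    resolved.sort()
    total = np.zeros(lexicon.dim)
    for tok in resolved:
        total += lexicon.lookup(tok)
    return total / len(resolved)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between ``u`` and ``v``, in [-1, 1].

    Symmetric, invariant to positive rescaling of either argument.
    Zero-norm vectors raise (a silent NaN would corrupt downstream t
    statistics).
    """
    u = _as_vector(u)
    v = _as_vector(v)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.size} vs {v.size}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def embed_target(backend: Backend, word: str) -> np.ndarray:
    """Embed a single target word.

    Static backends look the word up directly (OOV is an error — a missing
    target invalidates the trial and is never silently skipped); contextual
    backends encode the word as a one-word text.
    """
    if isinstance(backend, StaticLexicon):
        return backend.lookup(word)
    return backend.encode(word)


def embed_text(
    backend: Backend, text: str, config: TokenizerConfig = TokenizerConfig()
) -> np.ndarray:
    """Embed a multi-word text: averaged word vectors for static backends,
    the encoder output for contextual backends."""
    if isinstance(backend, StaticLexicon):
        return discourse_vector(backend, text, config)
    return backend.encode(text)
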