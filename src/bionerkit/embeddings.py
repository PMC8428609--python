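"""Word-level embeddings and stacking with char-LM contextual embeddings.

The word table follows the subword-hashing scheme: in-vocabulary words use
their stored vector; out-of-vocabulary words are embedded as the mean of
hashed character n-gram bucket vectors of the angle-bracket-padded word
(``<word>``), so lookup is total over arbitrary Unicode strings.
Lowercasing is off by default — gene symbols are case-sensitive.
"""

from __future__ import annotations

import numpy as np

from .char_lm import CharLM, embed_tokens
from .core_types import Sentence

__all__ = ["WordEmbeddingTable", "CharLMEmbedding", "EmbeddingStack", "embed_word", "embed_sentence", "fnv1a"]

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


def fnv1a(data: bytes) -> int:
    """64-bit FNV-1a hash."""
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & _MASK64
    return h


def char_ngrams(word: str, n_min: int, n_max: int) -> list[str]:
    """All contiguous n-grams of '<word>' for n in [n_min, n_max]."""
    padded = f"<{word}>"
    return [
        padded[i : i + n]
        for n in range(n_min, n_max + 1)
        for i in range(len(padded) - n + 1)
    ]


class WordEmbeddingTable:
    """Context-free word vectors with hashed-subword OOV fallback."""

    def __init__(self, dim: int = 16, n_min: int = 3, n_max: int = 5,
                 n_buckets: int = 4096, seed: int = 0, lowercase: bool = False,
                 vectors: dict[str, np.ndarray] | None = None,
                 bucket_vectors: np.ndarray | None = None):
        if n_min < 1 or n_max < n_min:
            raise ValueError("need 1 <= n_min <= n_max")
        self.dim = dim
        self.n_min = n_min
        self.n_max = n_max
        self.n_buckets = n_buckets
        self.lowercase = lowercase
        self.vectors = {} if vectors is None else dict(vectors)
        for w, v in self.vectors.items():
            if len(v) != dim:
                raise ValueError(f"vector for {w!r} has length {len(v)}, expected {dim}")
        if bucket_vectors is None:
            rng = np.random.default_rng(seed)
            bucket_vectors = rng.normal(0.0, 1.0, size=(n_buckets, dim))
        self.bucket_vectors = np.asarray(bucket_vectors, dtype=np.float64)
        if self.bucket_vectors.shape != (n_buckets, dim):
            raise ValueError("bucket_vectors shape mismatch")

    @property
    def name(self):
        return "word-hash"

    def embed_word(self, word: str) -> np.ndarray:
        if not word:
            raise ValueError("cannot embed an empty word")
        if self.lowercase:
            word = word.lower()
        vec = self.vectors.get(word)
        if vec is not None:
            return np.asarray(vec, dtype=np.float64)
        grams = char_ngrams(word, self.n_min, self.n_max)
        if not grams:
            return np.zeros(self.dim)
        idx = [fnv1a(g.encode("utf-8")) % self.n_buckets for g in grams]
        return self.bucket_vectors[idx].mean(axis=0)

    def embed(self, sentence: Sentence) -> np.ndarray:
        if not sentence.tokens:
            return np.zeros((0, self.dim))
        return np.stack([self.embed_word(tok.text) for tok in sentence.tokens])

    @classmethod
    def from_text_file(cls, path, n_min: int = 3, n_max: int = 5,
                       n_buckets: int = 4096, seed: int = 0) -> "WordEmbeddingTable":
        """Read `word v1 .. vD` lines; an `N D` header line is tolerated."""
        vectors: dict[str, np.ndarray] = {}
        dim = None
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle):
                parts = line.rstrip("\n").split(" ")
                if lineno == 0 and len(parts) == 2:
                    continue  # header
                if len(parts) < 2:
                    continue
                word, values = parts[0], parts[1:]
                vec = np.array([float(v) for v in values])
                if dim is None:
                    dim = len(vec)
                elif len(vec) != dim:
                    raise ValueError(f"{path}: ragged vector for {word!r}")
                vectors[word] = vec
        if dim is None:
            raise ValueError(f"{path}: no vectors found")
        return cls(dim=dim, n_min=n_min, n_max=n_max, n_buckets=n_buckets,
                   seed=seed, vectors=vectors)


class CharLMEmbedding:
    """Contextual token embeddings from a forward + backward char LM pair."""

    def __init__(self, fwd: CharLM, bwd: CharLM):
        if fwd.hidden_dim != bwd.hidden_dim:
            raise ValueError("forward/backward hidden dims differ")
        self.fwd = fwd
        self.bwd = bwd
        self.dim = fwd.hidden_dim + bwd.hidden_dim

    @property
    def name(self):
        return "char-lm"

    def embed(self, sentence: Sentence) -> np.ndarray:
        return embed_tokens(self.fwd, self.bwd, sentence)


class EmbeddingStack:
    """Fixed-order concatenation of embedding sources."""

    def __init__(self, sources):
        sources = list(sources)
        if not sources:
            raise ValueError("embedding stack must have at least one source")
        self.sources = sources
        self.total_dim = sum(s.dim for s in sources)

    def embed_sentence(self, sentence: Sentence) -> np.ndarray:
        n = len(sentence.tokens)
        parts = []
        for src in self.sources:
            mat = src.embed(sentence)
            if mat.shape != (n, src.dim):
                raise ValueError(
                    f"source {src.name!r} returned shape {mat.shape}, "
                    f"expected {(n, src.dim)}"
                )
            parts.append(mat)
        if not parts:
            return np.zeros((n, 0))
        return np.concatenate(parts, axis=1)


def embed_word(table: WordEmbeddingTable, word: str) -> np.ndarray:
    return table.embed_word(word)


def embed_sentence(stack: EmbeddingStack, sentence: Sentence) -> np.ndarray:
    return stack.embed_sentence(sentence)
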