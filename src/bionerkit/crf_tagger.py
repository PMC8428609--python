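"""BiLSTM-CRF sequence labeler.

The linear-chain CRF primitives (path scoring, exact log-partition via the
forward recursion in log space, forward-backward marginals, Viterbi
decoding) are plain-numpy functions over an emission matrix (n_tokens x
n_tags) and a transition matrix with reserved START/STOP states at indices
K and K+1.  ``T[i, j]`` is the score of tag j following tag i.

Viterbi ties are broken deterministically: among optimal paths the one
with the lowest tag index at the latest differing position is returned.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.special import logsumexp

from ._autodiff import Parameter, Tensor, _accum
from .core_types import BIOES, Sentence, TagScheme, tags_to_spans
from .embeddings import EmbeddingStack

__all__ = [
    "TagDictionary",
    "TaggerModel",
    "score_path",
    "log_partition",
    "nll_loss",
    "viterbi",
    "crf_marginals",
]

CHECKPOINT_VERSION = 1


class TagDictionary:
    """Bijection between tag strings and dense indices, plus START/STOP."""

    def __init__(self, entity_types, scheme: TagScheme = BIOES):
        self.scheme = scheme
        self.entity_types = tuple(entity_types)
        self.tags = scheme.tag_inventory(self.entity_types)
        self.index = {t: i for i, t in enumerate(self.tags)}
        self.n_tags = len(self.tags)
        self.start = self.n_tags
        self.stop = self.n_tags + 1

    def __len__(self):
        return self.n_tags + 2

    def encode(self, tag_strings) -> np.ndarray:
        try:
            return np.array([self.index[t] for t in tag_strings], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"tag {exc.args[0]!r} not in dictionary") from None

    def decode(self, indices) -> list[str]:
        return [self.tags[i] for i in indices]


# ---------------------------------------------------------------------------
# CRF primitives


def _check(e, T):
    e = np.asarray(e, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if e.ndim != 2 or e.shape[0] < 1:
        raise ValueError("emissions must be (n_tokens >= 1, n_tags)")
    K = e.shape[1]
    if T.shape != (K + 2, K + 2):
        raise ValueError(f"transitions must be ({K + 2},{K + 2}) incl. START/STOP")
    if not np.isfinite(e).all():
        raise ValueError("non-finite emission score")
    return e, T, K


def score_path(e, T, tags) -> float:
    """Additive chain score of one tag path, START and STOP included."""
    e, T, K = _check(e, T)
    tags = np.asarray(tags, dtype=np.intp)
    if len(tags) != e.shape[0]:
        raise ValueError("path length must equal number of tokens")
    if tags.min() < 0 or tags.max() >= K:
        raise ValueError("tag index out of range")
    start, stop = K, K + 1
    score = T[start, tags[0]] + e[np.arange(len(tags)), tags].sum()
    score += T[tags[:-1], tags[1:]].sum()
    score += T[tags[-1], stop]
    return float(score)


def log_partition(e, T) -> float:
    """log sum over all tag paths of exp(score), by the forward recursion."""
    e, T, K = _check(e, T)
    start, stop = K, K + 1
    alpha = T[start, :K] + e[0]
    for i in range(1, e.shape[0]):
        alpha = logsumexp(alpha[:, None] + T[:K, :K], axis=0) + e[i]
    return float(logsumexp(alpha + T[:K, stop]))


def nll_loss(e, T, gold) -> float:
    """Negative log-likelihood of the gold path; always >= 0."""
    return log_partition(e, T) - score_path(e, T, gold)


def viterbi(e, T) -> tuple[list[int], float]:
    """Highest-scoring tag path and its score.

    ``np.argmax`` returns the first (lowest-index) maximizer, and the path
    is reconstructed from the end, so among tied optima the returned path
    has the lowest tag index at the latest position where optima differ.
    """
    e, T, K = _check(e, T)
    n = e.shape[0]
    start, stop = K, K + 1
    delta = T[start, :K] + e[0]
    back = np.empty((n, K), dtype=np.intp)
    for i in range(1, n):
        cand = delta[:, None] + T[:K, :K]
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(K)] + e[i]
    final = delta + T[:K, stop]
    last = int(np.argmax(final))
    path = [last]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    path.reverse()
    return path, float(final[last])


def crf_marginals(e, T):
    """Forward-backward: (logZ, unary marginals, expected transition counts).

    The transition-count matrix has the same (K+2, K+2) layout as T; its
    START row and STOP column hold the first/last-position marginals.
    """
    e, T, K = _check(e, T)
    n = e.shape[0]
    start, stop = K, K + 1
    alpha = np.empty((n, K))
    alpha[0] = T[start, :K] + e[0]
    for i in range(1, n):
        alpha[i] = logsumexp(alpha[i - 1][:, None] + T[:K, :K], axis=0) + e[i]
    log_z = float(logsumexp(alpha[-1] + T[:K, stop]))
    beta = np.empty((n, K))
    beta[-1] = T[:K, stop]
    for i in range(n - 2, -1, -1):
        beta[i] = logsumexp(T[:K, :K] + (e[i + 1] + beta[i + 1])[None, :], axis=1)
    unary = np.exp(alpha + beta - log_z)
    pair = np.zeros((K + 2, K + 2))
    for i in range(n - 1):
        pair[:K, :K] += np.exp(
            alpha[i][:, None] + T[:K, :K] + (e[i + 1] + beta[i + 1])[None, :] - log_z
        )
    pair[start, :K] = unary[0]
    pair[:K, stop] = unary[-1]
    return log_z, unary, pair


def crf_nll_op(emissions: Tensor, transitions: Tensor, gold: np.ndarray) -> Tensor:
    """Differentiable CRF negative log-likelihood (analytic gradient)."""
    gold = np.asarray(gold, dtype=np.intp)
    e, T = emissions.data, transitions.data
    log_z, unary, pair = crf_marginals(e, T)
    loss = log_z - score_path(e, T, gold)
    n, K = e.shape
    start, stop = K, K + 1

    def backward(grad, emissions=emissions, transitions=transitions):
        ge = unary.copy()
        ge[np.arange(n), gold] -= 1.0
        gt = pair.copy()
        gt[start, gold[0]] -= 1.0
        np.add.at(gt, (gold[:-1], gold[1:]), -1.0)
        gt[gold[-1], stop] -= 1.0
        _accum(emissions, grad * ge)
        _accum(transitions, grad * gt)

    return Tensor(np.asarray(loss), parents=(emissions, transitions), backward=backward)


# ---------------------------------------------------------------------------
# the tagger


def bioes_transition_mask(tag_dict: TagDictionary, penalty: float = -1e4) -> np.ndarray:
    """Additive mask forbidding impossible BIOES bigrams (strict mode)."""
    size = len(tag_dict)
    mask = np.zeros((size, size))
    start, stop = tag_dict.start, tag_dict.stop

    def parts(i):
        if i == start:
            return "START", None
        if i == stop:
            return "STOP", None
        return tag_dict.scheme.parse(tag_dict.tags[i])

    for i in range(size):
        pi, ti = parts(i)
        for j in range(size):
            pj, tj = parts(j)
            if pj == "START" or pi == "STOP":
                ok = False
            elif pi in ("B", "I"):
                # inside a mention: must continue it
                ok = pj in ("I", "E") and tj == ti
            else:  # O, E, S, START: outside a mention
                ok = pj in ("O", "B", "S", "STOP")
            if not ok:
                mask[i, j] = penalty
    return mask


class TaggerModel:
    """Embedding stack -> BiLSTM encoder -> emission projection -> CRF."""

    def __init__(self, stack: EmbeddingStack, entity_types,
                 hidden_size: int = 32, scheme: TagScheme = BIOES,
                 seed: int = 0, strict_transitions: bool = False):
        self.stack = stack
        self.tag_dict = TagDictionary(entity_types, scheme)
        self.hidden_size = hidden_size
        self.scheme = scheme
        self.strict_transitions = strict_transitions
        d_in, h, K = stack.total_dim, hidden_size, self.tag_dict.n_tags
        rng = np.random.default_rng(seed)
        sx, sh = 1.0 / np.sqrt(max(d_in, 1)), 1.0 / np.sqrt(h)

        def lstm_params():
            b = np.zeros(4 * h)
            b[h:2 * h] = 1.0
            return {
                "Wx": Parameter(rng.uniform(-sx, sx, size=(d_in, 4 * h))),
                "Wh": Parameter(rng.uniform(-sh, sh, size=(h, 4 * h))),
                "b": Parameter(b),
            }

        self.fwd = lstm_params()
        self.bwd = lstm_params()
        self.proj_W = Parameter(rng.uniform(-sh, sh, size=(2 * h, K)))
        self.proj_b = Parameter(np.zeros(K))
        self.trans = Parameter(rng.normal(0.0, 0.01, size=(K + 2, K + 2)))
        self._mask = bioes_transition_mask(self.tag_dict) if strict_transitions else None

    def parameters(self):
        return (
            [self.fwd[k] for k in ("Wx", "Wh", "b")]
            + [self.bwd[k] for k in ("Wx", "Wh", "b")]
            + [self.proj_W, self.proj_b, self.trans]
        )

    @property
    def transitions(self) -> np.ndarray:
        T = self.trans.data
        return T + self._mask if self._mask is not None else T

    def _lstm_pass(self, rows, params):
        h_dim = self.hidden_size
        h = Tensor(np.zeros((1, h_dim)))
        c = Tensor(np.zeros((1, h_dim)))
        out = []
        for x in rows:
            g = x @ params["Wx"] + h @ params["Wh"] + params["b"]
            i = g[:, 0 * h_dim:1 * h_dim].sigmoid()
            f = g[:, 1 * h_dim:2 * h_dim].sigmoid()
            z = g[:, 2 * h_dim:3 * h_dim].tanh()
            o = g[:, 3 * h_dim:4 * h_dim].sigmoid()
            c = f * c + i * z
            h = o * c.tanh()
            out.append(h)
        return out

    def emissions(self, features: np.ndarray) -> Tensor:
        """Emission scores (n_tokens x n_tags) from a token-feature matrix."""
        n = features.shape[0]
        rows = [Tensor(features[i:i + 1]) for i in range(n)]
        h_f = self._lstm_pass(rows, self.fwd)
        h_b = self._lstm_pass(rows[::-1], self.bwd)[::-1]
        enc = Tensor.concat(
            [Tensor.concat([h_f[i], h_b[i]], axis=1) for i in range(n)], axis=0
        )
        return enc @ self.proj_W + self.proj_b

    def loss(self, features: np.ndarray, gold_indices: np.ndarray) -> Tensor:
        e = self.emissions(features)
        if self._mask is not None:
            return crf_nll_op(e, self.trans + Tensor(self._mask), gold_indices)
        return crf_nll_op(e, self.trans, gold_indices)

    def decode(self, features: np.ndarray) -> list[int]:
        if features.shape[0] == 0:
            return []
        e = self.emissions(features).data
        path, _ = viterbi(e, self.transitions)
        return path

    def predict(self, sentence: Sentence):
        """Predict entity mentions for one sentence (deterministic)."""
        if len(sentence.tokens) == 0:
            return []
        features = self.stack.embed_sentence(sentence)
        tags = self.tag_dict.decode(self.decode(features))
        return tags_to_spans(sentence, tags, self.scheme)

    # ---- checkpointing ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        names = self._param_names()
        return {name: p.data.copy() for name, p in zip(names, self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        names = self._param_names()
        for name, p in zip(names, self.parameters()):
            p.data[...] = state[name]

    @staticmethod
    def _param_names():
        return [
            "fwd.Wx", "fwd.Wh", "fwd.b", "bwd.Wx", "bwd.Wh", "bwd.b",
            "proj.W", "proj.b", "trans",
        ]

    def save(self, path):
        meta = {
            "format_version": CHECKPOINT_VERSION,
            "hidden_size": self.hidden_size,
            "entity_types": list(self.tag_dict.entity_types),
            "scheme": self.scheme.name,
            "strict_transitions": self.strict_transitions,
            "input_dim": self.stack.total_dim,
        }
        arrays = {name.replace(".", "_"): arr for name, arr in self.state_dict().items()}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, stack: EmbeddingStack) -> "TaggerModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            if meta.get("format_version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta.get('format_version')!r}")
            if stack.total_dim != meta["input_dim"]:
                raise ValueError(
                    f"stack dim {stack.total_dim} != checkpoint input dim {meta['input_dim']}"
                )
            model = cls(
                stack, meta["entity_types"], hidden_size=meta["hidden_size"],
                scheme=TagScheme(meta["scheme"]),
                strict_transitions=meta["strict_transitions"],
            )
            model.load_state_dict({
                name: data[name.replace(".", "_")] for name in cls._param_names()
            })
        return model
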