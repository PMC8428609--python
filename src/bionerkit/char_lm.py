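"""Character-level recurrent language model and contextual token embeddings.

A single-layer LSTM over characters, trained by next-character
cross-entropy with truncated backpropagation through time (hidden state
carried between consecutive chunks of the same stream).  A forward and a
backward model together provide contextual token embeddings: the forward
half is the hidden state after the token's last character, the backward
half the backward model's hidden state after consuming (in reverse) the
token's first character.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._autodiff import Parameter, Tensor, clip_gradients, cross_entropy, sgd_step, zero_gradients
from .core_types import Sentence

__all__ = ["CharVocab", "CharLM", "LMConfig", "train_lm", "perplexity", "embed_tokens"]

CHECKPOINT_VERSION = 1


class CharVocab:
    """Character inventory with reserved UNK/BOS/EOS symbols.

    Indices are dense from 0: UNK=0, BOS=1, EOS=2, then the inventory in
    sorted order.  Unknown characters always map to UNK.
    """

    UNK, BOS, EOS = 0, 1, 2
    N_SPECIALS = 3

    def __init__(self, inventory):
        inventory = tuple(dict.fromkeys(inventory))
        self.inventory = inventory
        self._index = {ch: i + self.N_SPECIALS for i, ch in enumerate(inventory)}
        if len(self._index) != len(inventory):
            raise ValueError("inventory characters must be unique")

    @classmethod
    def from_text(cls, text: str) -> "CharVocab":
        return cls(sorted(set(text)))

    def __len__(self):
        return self.N_SPECIALS + len(self.inventory)

    def index(self, ch: str) -> int:
        return self._index.get(ch, self.UNK)

    def encode(self, text: str) -> np.ndarray:
        return np.fromiter((self.index(ch) for ch in text), dtype=np.intp, count=len(text))


@dataclass(frozen=True)
class LMConfig:
    char_embedding_dim: int = 16
    hidden_dim: int = 32
    sequence_length: int = 32
    batch_size: int = 8
    epochs: int = 5
    learning_rate: float = 1.0
    clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        for name in ("char_embedding_dim", "hidden_dim", "sequence_length", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class CharLM:
    """Single-layer LSTM language model over characters."""

    def __init__(self, vocab: CharVocab, direction: str = "forward",
                 char_embedding_dim: int = 16, hidden_dim: int = 32, seed: int = 0):
        if direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        self.vocab = vocab
        self.direction = direction
        self.char_embedding_dim = char_embedding_dim
        self.hidden_dim = hidden_dim
        V, E, H = len(vocab), char_embedding_dim, hidden_dim
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(H)
        self.emb = Parameter(rng.uniform(-0.1, 0.1, size=(V, E)))
        self.Wx = Parameter(rng.uniform(-scale, scale, size=(E, 4 * H)))
        self.Wh = Parameter(rng.uniform(-scale, scale, size=(H, 4 * H)))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        self.Wo = Parameter(rng.uniform(-scale, scale, size=(H, V)))
        self.bo = Parameter(np.zeros(V))
        self.training_log: list[dict] = []

    def parameters(self):
        return [self.emb, self.Wx, self.Wh, self.b, self.Wo, self.bo]

    # ---- differentiable forward (training) ---------------------------------

    def _step(self, x: Tensor, h: Tensor, c: Tensor):
        H = self.hidden_dim
        g = x @ self.Wx + h @ self.Wh + self.b
        i = g[:, 0 * H:1 * H].sigmoid()
        f = g[:, 1 * H:2 * H].sigmoid()
        z = g[:, 2 * H:3 * H].tanh()
        o = g[:, 3 * H:4 * H].sigmoid()
        c = f * c + i * z
        h = o * c.tanh()
        return h, c

    def chunk_loss(self, inputs: np.ndarray, targets: np.ndarray, state=None):
        """Mean next-char cross-entropy on a (batch, time) chunk.

        Returns (loss Tensor, detached final state) so TBPTT can carry the
        state into the next chunk without extending the graph.
        """
        B, T = inputs.shape
        H = self.hidden_dim
        if state is None:
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
        else:
            h, c = Tensor(state[0]), Tensor(state[1])
        logits = []
        for t in range(T):
            x = self.emb[inputs[:, t]]
            h, c = self._step(x, h, c)
            logits.append(h @ self.Wo + self.bo)
        flat = Tensor.concat(logits, axis=0)  # (T*B, V), time-major blocks
        flat_targets = targets.T.reshape(-1)
        loss = cross_entropy(flat, flat_targets)
        return loss, (h.data.copy(), c.data.copy())

    # ---- pure-numpy forward (inference / embedding extraction) -------------

    def hidden_states(self, indices: np.ndarray) -> np.ndarray:
        """Hidden state after consuming each symbol of a 1-D index sequence."""
        H = self.hidden_dim
        E, Wx, Wh, b = self.emb.data, self.Wx.data, self.Wh.data, self.b.data
        h = np.zeros(H)
        c = np.zeros(H)
        out = np.empty((len(indices), H))
        for t, ix in enumerate(indices):
            g = E[ix] @ Wx + h @ Wh + b
            i = _sigmoid(g[0 * H:1 * H])
            f = _sigmoid(g[1 * H:2 * H])
            z = np.tanh(g[2 * H:3 * H])
            o = _sigmoid(g[3 * H:4 * H])
            c = f * c + i * z
            h = o * np.tanh(c)
            out[t] = h
        return out

    def step_log_probs(self, indices: np.ndarray) -> np.ndarray:
        """Log P(next char | prefix) for each step; rows sum to 1 in prob space."""
        states = self.hidden_states(indices)
        logits = states @ self.Wo.data + self.bo.data
        logits -= logits.max(axis=1, keepdims=True)
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        return logp

    # ---- checkpointing ------------------------------------------------------

    def save(self, path):
        meta = {
            "format_version": CHECKPOINT_VERSION,
            "direction": self.direction,
            "char_embedding_dim": self.char_embedding_dim,
            "hidden_dim": self.hidden_dim,
            "inventory": "".join(self.vocab.inventory),
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
            emb=self.emb.data, Wx=self.Wx.data, Wh=self.Wh.data,
            b=self.b.data, Wo=self.Wo.data, bo=self.bo.data,
        )

    @classmethod
    def load(cls, path) -> "CharLM":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            if meta.get("format_version") != CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta.get('format_version')!r}"
                )
            lm = cls(
                CharVocab(meta["inventory"]),
                direction=meta["direction"],
                char_embedding_dim=meta["char_embedding_dim"],
                hidden_dim=meta["hidden_dim"],
            )
            for name in ("emb", "Wx", "Wh", "b", "Wo", "bo"):
                getattr(lm, name).data[...] = data[name]
        return lm


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def train_lm(text: str, config: LMConfig = LMConfig(), direction: str = "forward") -> CharLM:
    """Train a character LM on a raw text stream by next-char prediction.

    Deterministic given ``config.seed``: same seed and text reproduce the
    parameter trajectory bit for bit.  Backward models are trained on the
    reversed stream.
    """
    if not text:
        raise ValueError("cannot train a language model on empty text")
    if len(text) < config.sequence_length:
        raise ValueError("text shorter than one sequence_length")
    vocab = CharVocab.from_text(text)
    lm = CharLM(
        vocab, direction=direction,
        char_embedding_dim=config.char_embedding_dim,
        hidden_dim=config.hidden_dim, seed=config.seed,
    )
    stream = vocab.encode(text if direction == "forward" else text[::-1])

    B = max(1, min(config.batch_size, len(stream) // max(1, config.sequence_length)))
    L = len(stream) // B
    data = stream[: B * L].reshape(B, L)
    bos = np.full((B, 1), CharVocab.BOS, dtype=np.intp)
    inputs_all = np.concatenate([bos, data[:, :-1]], axis=1)
    targets_all = data
    params = lm.parameters()

    for epoch in range(config.epochs):
        state = None  # fresh state per epoch; carried across chunks within it
        total, n_chunks = 0.0, 0
        for lo in range(0, L, config.sequence_length):
            hi = min(lo + config.sequence_length, L)
            zero_gradients(params)
            loss, state = lm.chunk_loss(inputs_all[:, lo:hi], targets_all[:, lo:hi], state)
            loss.backward()
            clip_gradients(params, config.clip)
            sgd_step(params, config.learning_rate)
            total += float(loss.data)
            n_chunks += 1
        mean = total / n_chunks
        lm.training_log.append({"epoch": epoch, "loss": mean, "ppl": float(np.exp(mean))})
    return lm


def perplexity(lm: CharLM, text: str) -> float:
    """exp(mean next-character negative log-likelihood); always >= 1."""
    if not text:
        raise ValueError("perplexity of empty text is undefined")
    if lm.direction == "backward":
        text = text[::-1]
    idx = lm.vocab.encode(text)
    inputs = np.concatenate([[CharVocab.BOS], idx[:-1]])
    logp = lm.step_log_probs(inputs)
    nll = -logp[np.arange(len(idx)), idx].mean()
    return float(np.exp(nll))


def embed_tokens(fwd: CharLM, bwd: CharLM, sentence: Sentence) -> np.ndarray:
    """Contextual token embeddings of size 2*hidden_dim from two char LMs.

    The sentence is processed as one character sequence (inter-token gaps
    rendered as spaces).  Purely deterministic: repeated calls are
    bit-identical.
    """
    if fwd.hidden_dim != bwd.hidden_dim:
        raise ValueError(
            f"hidden dims differ: forward {fwd.hidden_dim} vs backward {bwd.hidden_dim}"
        )
    if fwd.direction != "forward" or bwd.direction != "backward":
        raise ValueError("embed_tokens needs one forward and one backward model")
    n = len(sentence.tokens)
    if n == 0:
        return np.zeros((0, fwd.hidden_dim + bwd.hidden_dim))
    text = sentence.text()
    base = sentence.start

    f_in = np.concatenate([[CharVocab.BOS], fwd.vocab.encode(text)])
    f_states = fwd.hidden_states(f_in)  # f_states[k+1] = after text[k]
    b_in = np.concatenate([[CharVocab.BOS], bwd.vocab.encode(text[::-1])])
    b_states = bwd.hidden_states(b_in)

    out = np.empty((n, fwd.hidden_dim + bwd.hidden_dim))
    for i, tok in enumerate(sentence.tokens):
        last = tok.end - base - 1
        first = tok.start - base
        out[i, : fwd.hidden_dim] = f_states[last + 1]
        out[i, fwd.hidden_dim :] = b_states[(len(text) - 1 - first) + 1]
    return out
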