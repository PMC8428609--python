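"""CoNLL column-format corpus I/O, pluggable segmentation and corpus merging.

The canonical dialect: UTF-8, Unix newlines, whitespace-separated columns
with the token in column 0 and the tag in the last column, ``#`` comment
lines, and a blank line terminating each sentence.  When no source document
accompanies a file, character offsets are reconstructed by joining tokens
with single spaces (deterministic and reversible).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from .core_types import (
    BIOES,
    Example,
    EntityMention,
    NERCorpus,
    Sentence,
    TagScheme,
    Token,
    spans_to_tags,
    tags_to_spans,
)

__all__ = [
    "ColumnFormat",
    "Segmenter",
    "DEFAULT_FORMAT",
    "read_conll",
    "write_conll",
    "segment_document",
    "merge_for_type",
    "remove_corpora",
    "load_manifest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnFormat:
    token_column: int = 0
    tag_column: int = -1
    comment_prefix: str = "#"

    def __post_init__(self):
        if self.token_column < 0:
            raise ValueError("token_column must be >= 0")
        if self.token_column == self.tag_column:
            raise ValueError("token and tag columns must differ")

    @property
    def n_columns(self) -> int:
        return max(self.token_column, self.tag_column if self.tag_column >= 0 else 1) + 1


DEFAULT_FORMAT = ColumnFormat()


def read_conll(
    path,
    fmt: ColumnFormat = DEFAULT_FORMAT,
    scheme: TagScheme = BIOES,
    doc_id: str | None = None,
):
    """Parse a CoNLL column file into (Sentence, mentions) examples.

    Tags are decoded into mentions under ``scheme``.  Offsets restart at 0
    for every sentence and assume single-space joining.
    """
    path = Path(path)
    examples: list[Example] = []
    words: list[str] = []
    tags: list[str] = []
    base_id = doc_id if doc_id is not None else path.stem

    def flush():
        if not words:
            return
        sent = Sentence.from_words(words, doc_id=f"{base_id}-s{len(examples)}")
        mentions = tags_to_spans(sent, tags, scheme)
        examples.append(Example(sent, mentions, source=base_id))
        words.clear()
        tags.clear()

    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if fmt.comment_prefix and line.startswith(fmt.comment_prefix):
                continue
            if not line.strip():
                flush()
                continue
            fields = line.split()
            if len(fields) < fmt.n_columns:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {fmt.n_columns} columns, "
                    f"got {len(fields)}: {line!r}"
                )
            words.append(fields[fmt.token_column])
            tags.append(fields[fmt.tag_column])
    flush()
    return examples


def write_conll(
    examples,
    path,
    fmt: ColumnFormat = DEFAULT_FORMAT,
    scheme: TagScheme = BIOES,
):
    """Write examples to a CoNLL column file parseable by :func:`read_conll`.

    Unused columns between token and tag are filled with ``_``.
    """
    path = Path(path)
    tag_col = fmt.tag_column if fmt.tag_column >= 0 else fmt.n_columns - 1
    width = max(fmt.token_column, tag_col) + 1
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for ex in examples:
            tags = spans_to_tags(ex.sentence, ex.mentions, scheme)
            for tok, tag in zip(ex.sentence.tokens, tags):
                fields = ["_"] * width
                fields[fmt.token_column] = tok.text
                fields[tag_col] = tag
                handle.write(" ".join(fields) + "\n")
            handle.write("\n")


# ---------------------------------------------------------------------------
# segmentation


_SENTENCE_END = re.compile(r"[.?!](?=\s|$)")
_TOKEN = re.compile(r"\w+|[^\w\s]")


def _rule_sentence_splitter(text: str) -> list[tuple[int, int]]:
    """Split at ., ? or ! followed by whitespace or end of text.

    Deliberately abbreviation-blind; swap in a smarter splitter via
    :class:`Segmenter` if needed.
    """
    bounds = []
    start = 0
    for m in _SENTENCE_END.finditer(text):
        bounds.append((start, m.end()))
        start = m.end()
    if text[start:].strip():
        bounds.append((start, len(text)))
    return [(s, e) for s, e in bounds if text[s:e].strip()]


def _rule_tokenizer(sentence_text: str) -> list[tuple[int, int]]:
    """Whitespace tokenization with punctuation split into its own tokens."""
    return [(m.start(), m.end()) for m in _TOKEN.finditer(sentence_text)]


@dataclass(frozen=True)
class Segmenter:
    sentence_splitter: Callable[[str], list[tuple[int, int]]] = _rule_sentence_splitter
    tokenizer: Callable[[str], list[tuple[int, int]]] = _rule_tokenizer


DEFAULT_SEGMENTER = Segmenter()


def segment_document(text: str, seg: Segmenter = DEFAULT_SEGMENTER, doc_id: str = "") -> list[Sentence]:
    """Split raw text into sentences of offset-carrying tokens.

    All offsets point into ``text``: ``text[tok.start:tok.end] == tok.text``.
    """
    sentences = []
    for si, (s_lo, s_hi) in enumerate(seg.sentence_splitter(text)):
        _validate_bounds(text, [(s_lo, s_hi)])
        chunk = text[s_lo:s_hi]
        tok_bounds = seg.tokenizer(chunk)
        _validate_bounds(chunk, tok_bounds)
        tokens = tuple(
            Token(chunk[lo:hi], s_lo + lo, s_lo + hi) for lo, hi in tok_bounds
        )
        if tokens:
            sentences.append(Sentence(tokens, doc_id=f"{doc_id}-s{si}" if doc_id else f"s{si}"))
    return sentences


def _validate_bounds(text, bounds):
    prev = 0
    for lo, hi in bounds:
        if not (0 <= lo < hi <= len(text)) or lo < prev:
            raise ValueError(f"segmenter produced invalid bounds ({lo},{hi})")
        prev = hi


# ---------------------------------------------------------------------------
# corpus pool operations


def merge_for_type(corpora, etype: str, dev_fraction: float = 0.1, seed: int = 0) -> NERCorpus:
    """Union the train/dev splits of several corpora for one entity type.

    Mentions of other types are dropped (with a logged count); test splits
    are kept per-corpus rather than merged, so evaluation stays per-source.
    Corpora without a dev split donate a seeded slice of their train split.
    """
    corpora = list(corpora)
    if not corpora:
        raise ValueError("merge_for_type requires at least one corpus")
    for c in corpora:
        if etype not in c.entity_types:
            raise ValueError(f"corpus {c.name!r} does not annotate {etype!r}")

    dropped = 0
    merged = NERCorpus(
        name=f"merged-{etype}-" + "+".join(c.name for c in corpora),
        entity_types={etype},
    )

    def keep(examples, source_name):
        nonlocal dropped
        out = []
        for ex in examples:
            kept = [m for m in ex.mentions if m.type == etype]
            dropped += len(ex.mentions) - len(kept)
            out.append(Example(ex.sentence, kept, source=source_name))
        return out

    rng = np.random.default_rng(seed)
    for c in corpora:
        train = keep(c.train, c.name)
        dev = keep(c.dev, c.name)
        if not dev and train:
            n_dev = max(1, int(round(dev_fraction * len(train))))
            order = rng.permutation(len(train))
            dev_idx = set(order[:n_dev].tolist())
            dev = [ex for i, ex in enumerate(train) if i in dev_idx]
            train = [ex for i, ex in enumerate(train) if i not in dev_idx]
            logger.info("corpus %s donated %d train sentences as dev", c.name, n_dev)
        merged.train.extend(train)
        merged.dev.extend(dev)
        test = keep(c.test, c.name)
        merged.test.extend(test)
        merged.test_by_corpus[c.name] = test
    if dropped:
        logger.info("merge_for_type(%s): dropped %d mentions of other types", etype, dropped)
    return merged


def remove_corpora(pool, held_out) -> list:
    """Drop named corpora from a pool (leakage guard for held-out evaluation)."""
    pool = list(pool)
    names = {c.name for c in pool}
    for name in held_out:
        if name not in names:
            raise ValueError(f"corpus {name!r} not present in pool {sorted(names)}")
    remaining = [c for c in pool if c.name not in set(held_out)]
    if not remaining:
        logger.warning("remove_corpora left an empty pool")
    return remaining


def load_manifest(path, scheme: TagScheme = BIOES) -> list[NERCorpus]:
    """Load corpora listed in a YAML manifest.

    Schema: ``corpora: [{name, entity_types: [..], splits: {train: f, ...}}]``
    with file paths relative to the manifest.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        manifest = yaml.safe_load(handle)
    corpora = []
    for entry in manifest.get("corpora", []):
        corpus = NERCorpus(name=entry["name"], entity_types=set(entry["entity_types"]))
        for split, rel in entry.get("splits", {}).items():
            if split not in ("train", "dev", "test"):
                raise ValueError(f"unknown split {split!r} in manifest")
            examples = read_conll(path.parent / rel, scheme=scheme, doc_id=entry["name"])
            for ex in examples:
                ex.source = entry["name"]
            getattr(corpus, split).extend(examples)
        corpus.validate()
        corpora.append(corpus)
    return corpora
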