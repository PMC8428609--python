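"""Shared data model: tokens, sentences, typed mention spans, corpora and
the span <-> tag-sequence encodings.

Offset conventions are fixed here once and for all: character offsets are
0-based with half-open ends, and ``document_text[start:end]`` must reproduce
a token's or mention's surface text exactly.

The internal tagging scheme is BIOES; IOB2 is supported for file I/O
compatibility.  Both encodings of the same mention set decode to identical
mentions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "CANONICAL_ENTITY_TYPES",
    "EntityTypeRegistry",
    "Token",
    "Sentence",
    "EntityMention",
    "TagScheme",
    "IOB2",
    "BIOES",
    "Example",
    "NERCorpus",
    "spans_to_tags",
    "tags_to_spans",
    "BoundaryWarning",
    "TagDecodeError",
]

CANONICAL_ENTITY_TYPES = ("CellLine", "Chemical", "Disease", "Gene", "Species")


class BoundaryWarning(UserWarning):
    """A mention span did not align to token boundaries and was expanded."""


class TagDecodeError(ValueError):
    """A tag string could not be interpreted under the active scheme."""


class EntityTypeRegistry:
    """Registry of entity type names.

    The five canonical biomedical types are always present; extension names
    may be registered as long as they are unique and non-empty.
    """

    def __init__(self):
        self._names = list(CANONICAL_ENTITY_TYPES)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._names

    def register(self, name: str) -> str:
        if not name:
            raise ValueError("entity type name must be non-empty")
        if name in self._names:
            raise ValueError(f"entity type {name!r} is already registered")
        self._names.append(name)
        return name


#: Default registry used when corpora do not supply their own.
DEFAULT_REGISTRY = EntityTypeRegistry()


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int

    def __post_init__(self):
        if not self.text:
            raise ValueError("token text must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"token span [{self.start},{self.end}) is empty")
        if self.end - self.start != len(self.text):
            raise ValueError(
                f"token span [{self.start},{self.end}) does not cover "
                f"{self.text!r} (length {len(self.text)})"
            )


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]
    doc_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        prev_end = -1
        for tok in self.tokens:
            if tok.start < prev_end:
                raise ValueError(
                    f"token spans must be strictly increasing and "
                    f"non-overlapping; {tok!r} starts before {prev_end}"
                )
            prev_end = tok.end

    def __len__(self):
        return len(self.tokens)

    @property
    def start(self) -> int:
        return self.tokens[0].start if self.tokens else 0

    @property
    def end(self) -> int:
        return self.tokens[-1].end if self.tokens else 0

    def text(self) -> str:
        """Render the sentence, preserving inter-token gaps as spaces."""
        if not self.tokens:
            return ""
        base = self.tokens[0].start
        out = [" "] * (self.tokens[-1].end - base)
        for tok in self.tokens:
            out[tok.start - base : tok.end - base] = tok.text
        return "".join(out)

    @classmethod
    def from_words(cls, words, doc_id: str = "", offset: int = 0) -> "Sentence":
        """Build a sentence from bare word strings, single-space joined."""
        tokens = []
        pos = offset
        for w in words:
            tokens.append(Token(w, pos, pos + len(w)))
            pos += len(w) + 1
        return cls(tuple(tokens), doc_id=doc_id)


@dataclass(frozen=True)
class EntityMention:
    start: int
    end: int
    type: str
    text: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"mention span [{self.start},{self.end}) is empty")

    def overlaps(self, other: "EntityMention") -> bool:
        return max(self.start, other.start) < min(self.end, other.end)


@dataclass(frozen=True)
class TagScheme:
    """A span-boundary tag encoding: IOB2 or BIOES.

    Tag strings are ``PREFIX-TYPENAME`` or the outside tag ``O``.
    """

    name: str

    _PREFIXES = {"IOB2": ("B", "I"), "BIOES": ("B", "I", "E", "S")}

    def __post_init__(self):
        if self.name not in self._PREFIXES:
            raise ValueError(f"unknown tag scheme {self.name!r}")

    @property
    def prefixes(self) -> tuple[str, ...]:
        return self._PREFIXES[self.name]

    def tag_inventory(self, entity_types) -> list[str]:
        tags = ["O"]
        for etype in entity_types:
            tags.extend(f"{p}-{etype}" for p in self.prefixes)
        return tags

    def parse(self, tag: str) -> tuple[str, str | None]:
        """Split a tag into (prefix, type); 'O' parses to ('O', None)."""
        if tag == "O":
            return "O", None
        prefix, sep, etype = tag.partition("-")
        if not sep or prefix not in self._PREFIXES["BIOES"] or not etype:
            raise TagDecodeError(f"unknown tag {tag!r} under scheme {self.name}")
        if prefix not in self.prefixes:
            raise TagDecodeError(f"prefix {prefix!r} not valid in scheme {self.name}")
        return prefix, etype


IOB2 = TagScheme("IOB2")
BIOES = TagScheme("BIOES")


@dataclass
class Example:
    """One annotated sentence: gold mentions plus source-corpus provenance."""

    sentence: Sentence
    mentions: list[EntityMention]
    source: str = ""


@dataclass
class NERCorpus:
    """Train/dev/test annotated sentences for a set of entity types."""

    name: str
    entity_types: set[str]
    train: list[Example] = field(default_factory=list)
    dev: list[Example] = field(default_factory=list)
    test: list[Example] = field(default_factory=list)
    #: test splits of component corpora, kept separate after merging
    test_by_corpus: dict[str, list[Example]] = field(default_factory=dict)

    def splits(self):
        return {"train": self.train, "dev": self.dev, "test": self.test}

    def validate(self):
        """Check corpus-level invariants; raises ValueError on violation."""
        for split_name, examples in self.splits().items():
            for ex in examples:
                sent = ex.sentence
                for m in ex.mentions:
                    if m.type not in self.entity_types:
                        raise ValueError(
                            f"{self.name}/{split_name}: mention type {m.type!r} "
                            f"not in corpus entity types {sorted(self.entity_types)}"
                        )
                    if sent.tokens and not (sent.start <= m.start and m.end <= sent.end):
                        raise ValueError(
                            f"{self.name}/{split_name}: mention [{m.start},{m.end}) "
                            f"outside sentence range [{sent.start},{sent.end})"
                        )
                _check_same_type_overlaps(ex.mentions)
        return self


def _check_same_type_overlaps(mentions):
    by_type: dict[str, list[EntityMention]] = {}
    for m in mentions:
        by_type.setdefault(m.type, []).append(m)
    for etype, group in by_type.items():
        group = sorted(group, key=lambda m: (m.start, m.end))
        for a, b in zip(group, group[1:]):
            if a.overlaps(b):
                raise ValueError(
                    f"overlapping gold mentions of type {etype}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def _mention_token_range(sentence: Sentence, mention: EntityMention) -> tuple[int, int]:
    """Smallest token index range [i, j] covering the mention's characters.

    Non-token-aligned boundaries are expanded outward with a warning.
    """
    first = last = None
    for i, tok in enumerate(sentence.tokens):
        if tok.end > mention.start and tok.start < mention.end:
            if first is None:
                first = i
            last = i
    if first is None:
        raise ValueError(
            f"mention [{mention.start},{mention.end}) covers no token of the sentence"
        )
    lo, hi = sentence.tokens[first], sentence.tokens[last]
    if lo.start != mention.start or hi.end != mention.end:
        warnings.warn(
            f"mention [{mention.start},{mention.end}) of type {mention.type} "
            f"expanded to token boundaries [{lo.start},{hi.end})",
            BoundaryWarning,
            stacklevel=3,
        )
    return first, last


def spans_to_tags(sentence: Sentence, mentions, scheme: TagScheme = BIOES) -> list[str]:
    """Encode mention spans as one tag string per token.

    Mentions of the same type must not overlap.  Mentions whose character
    boundaries fall inside a token are expanded outward to the smallest
    covering token run (a :class:`BoundaryWarning` is emitted).
    """
    _check_same_type_overlaps(mentions)
    ranges = []
    for m in mentions:
        first, last = _mention_token_range(sentence, m)
        ranges.append((first, last, m))
    # after expansion, same-type token ranges must still be disjoint
    seen: dict[str, list[tuple[int, int]]] = {}
    for first, last, m in ranges:
        for f0, l0 in seen.get(m.type, []):
            if first <= l0 and f0 <= last:
                raise ValueError(
                    f"mentions of type {m.type} overlap after token expansion "
                    f"(token ranges [{f0},{l0}] and [{first},{last}])"
                )
        seen.setdefault(m.type, []).append((first, last))

    tags = ["O"] * len(sentence.tokens)
    for first, last, m in sorted(ranges, key=lambda r: (r[0], r[1])):
        if scheme.name == "BIOES":
            if first == last:
                tags[first] = f"S-{m.type}"
            else:
                tags[first] = f"B-{m.type}"
                for i in range(first + 1, last):
                    tags[i] = f"I-{m.type}"
                tags[last] = f"E-{m.type}"
        else:  # IOB2
            tags[first] = f"B-{m.type}"
            for i in range(first + 1, last + 1):
                tags[i] = f"I-{m.type}"
    return tags


def tags_to_spans(sentence: Sentence, tags, scheme: TagScheme = BIOES) -> list[EntityMention]:
    """Decode a tag sequence into mention spans.

    Decoding is lenient: any contiguous run of same-type non-O tags forms a
    span, split at positions that signal a new mention (a B or S tag, or a
    tag following an E or S tag).  Malformed runs (orphan I/E) therefore
    still yield spans rather than being dropped.
    """
    if len(tags) != len(sentence.tokens):
        raise ValueError(
            f"{len(tags)} tags for {len(sentence.tokens)} tokens"
        )
    parsed = [scheme.parse(t) for t in tags]
    spans: list[EntityMention] = []
    run_start = None
    run_type = None

    def close(run_start, last_index):
        lo = sentence.tokens[run_start]
        hi = sentence.tokens[last_index]
        text = sentence.text()[lo.start - sentence.start : hi.end - sentence.start]
        spans.append(EntityMention(lo.start, hi.end, run_type, text))

    prev_prefix = "O"
    for i, (prefix, etype) in enumerate(parsed):
        starts_new = (
            prefix in ("B", "S")
            or etype != run_type
            or prev_prefix in ("E", "S")
        )
        if run_type is not None and (prefix == "O" or starts_new):
            close(run_start, i - 1)
            run_start = run_type = None
        if prefix != "O" and run_type is None:
            run_start, run_type = i, etype
        prev_prefix = prefix
    if run_type is not None:
        close(run_start, len(parsed) - 1)
    return spans
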