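"""Seeded generator of toy biomedical-like NER corpora and raw LM text.

Stands in for real gold corpora so the full pipeline (LM training, tagger
training, cross-corpus merging, evaluation) is exercisable at desk scale.
Annotation-convention divergence across pseudo-corpora is controllable:
a corpus may include a trailing type keyword inside its gold spans (e.g.
gold ``"TLK9 gene"`` vs ``"TLK9"``) and may jitter gold boundaries by one
character, emulating cross-corpus differences in entity definitions.

All randomness flows from a single spec seed through a named stream per
split, so each split is independently reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .core_types import EntityMention, Example, NERCorpus, Sentence

__all__ = ["GeneratorSpec", "generate_corpus", "generate_lm_text", "default_dictionaries"]


# Invented surface forms, disjoint across types so toy tasks stay learnable.
_DICTIONARIES: dict[str, list[str]] = {
    "Gene": [
        "TLK9", "BRX2", "KQR17", "ZNF77", "PLQ3", "MYR8",
        "HOXQ1", "GAT6", "FZD21", "RBM44", "SOXV3", "TTK5",
    ],
    "Disease": [
        "velastosis", "brenchitis", "mexoplasia", "cardiolexia",
        "neurothraxis", "quorinoma", "spinal dystraphy", "chronic bexitis",
        "ocular tremexia", "lymphatic verosis",
    ],
    "Chemical": [
        "flumetoxate", "bezarol", "quintramide", "oxyphenadol",
        "cloxabrine", "tephrostatin", "metalyxine", "sorbiquat", "dextrazole",
    ],
    "Species": [
        "Murexia velans", "Carposoma leptum", "Trichovora silvae",
        "Quercomyces albus", "Neophila currax", "Vulpimys arctos",
        "Brachyura nitens", "Helicosoma parvum",
    ],
    "CellLine": [
        "QX-9", "VLM-203", "TRK-77b", "KBR-12", "NV-44", "LPT-8", "MGC-31",
    ],
}

_KEYWORDS = {
    "Gene": "gene",
    "Disease": "disease",
    "Chemical": "exposure",
    "Species": "specimens",
    "CellLine": "cells",
}

_ENTITY_TEMPLATES = [
    ["expression", "of", "{E}", "was", "markedly", "elevated", "."],
    ["we", "observed", "that", "{E}", "regulates", "downstream", "signaling", "."],
    ["mutations", "in", "{E}", "were", "detected", "in", "all", "samples", "."],
    ["{E}", "levels", "correlated", "with", "outcome", "."],
    ["the", "role", "of", "{E}", "remains", "poorly", "understood", "."],
    ["analysis", "revealed", "a", "strong", "association", "with", "{E}", "."],
    ["patients", "carrying", "{E}", "showed", "improved", "response", "."],
    ["knockdown", "of", "{E}", "reduced", "proliferation", "."],
]

_FILLER_TEMPLATES = [
    ["the", "results", "were", "consistent", "across", "replicates", "."],
    ["no", "significant", "difference", "was", "observed", "."],
    ["samples", "were", "processed", "using", "standard", "protocols", "."],
    ["further", "validation", "is", "required", "."],
    ["data", "were", "analyzed", "with", "a", "mixed", "model", "."],
]


def default_dictionaries(entity_types) -> dict[str, list[str]]:
    return {t: list(_DICTIONARIES[t]) for t in entity_types}


@dataclass(frozen=True)
class GeneratorSpec:
    name: str = "synthetic"
    entity_types: tuple[str, ...] = ("Gene",)
    n_train: int = 100
    n_dev: int = 20
    n_test: int = 20
    density: float = 0.7
    include_trailing_keyword: bool = False
    keyword_prob: float = 1.0
    boundary_jitter: int = 0
    char_noise: float = 0.0
    seed: int = 0
    dictionaries: dict[str, list[str]] | None = None
    templates: tuple[tuple[str, ...], ...] | None = None

    def __post_init__(self):
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0,1]")
        if not 0.0 <= self.char_noise <= 1.0:
            raise ValueError("char_noise must be in [0,1]")
        if self.boundary_jitter not in (0, 1):
            raise ValueError("boundary_jitter must be 0 or 1")

    def resolved_dictionaries(self) -> dict[str, list[str]]:
        dicts = self.dictionaries if self.dictionaries is not None else default_dictionaries(self.entity_types)
        for etype in self.entity_types:
            if not dicts.get(etype):
                raise ValueError(f"empty surface-form dictionary for type {etype!r}")
        return dicts


_SPLIT_STREAMS = {"train": 0, "dev": 1, "test": 2}


def generate_corpus(spec: GeneratorSpec) -> NERCorpus:
    """Render a seeded toy corpus with exactly consistent gold offsets."""
    dicts = spec.resolved_dictionaries()
    entity_templates = (
        [list(t) for t in spec.templates] if spec.templates is not None else _ENTITY_TEMPLATES
    )
    corpus = NERCorpus(name=spec.name, entity_types=set(spec.entity_types))
    sizes = {"train": spec.n_train, "dev": spec.n_dev, "test": spec.n_test}
    for split, n in sizes.items():
        rng = np.random.default_rng([spec.seed, _SPLIT_STREAMS[split]])
        examples = getattr(corpus, split)
        for i in range(n):
            doc_id = f"{spec.name}-{split}-{i}"
            examples.append(_render_sentence(spec, dicts, entity_templates, rng, doc_id))
    return corpus.validate()


def _render_sentence(spec, dicts, entity_templates, rng, doc_id) -> Example:
    with_entity = rng.random() < spec.density
    if with_entity:
        template = entity_templates[rng.integers(len(entity_templates))]
        etype = spec.entity_types[rng.integers(len(spec.entity_types))]
        surface = dicts[etype][rng.integers(len(dicts[etype]))]
    else:
        template = _FILLER_TEMPLATES[rng.integers(len(_FILLER_TEMPLATES))]
        etype = surface = None

    words: list[str] = []
    entity_range = None  # word-index range [lo, hi) of the gold span
    for part in template:
        if part == "{E}":
            entity_words = surface.split()
            lo = len(words)
            words.extend(entity_words)
            hi = len(words)
            if spec.include_trailing_keyword and rng.random() < spec.keyword_prob:
                words.append(_KEYWORDS[etype])
                hi += 1
            entity_range = (lo, hi)
        else:
            word = part
            if spec.char_noise > 0 and word.isalpha():
                chars = list(word)
                for k in range(len(chars)):
                    if rng.random() < spec.char_noise:
                        chars[k] = string.ascii_lowercase[rng.integers(26)]
                word = "".join(chars)
            words.append(word)

    sent = Sentence.from_words(words, doc_id=doc_id)
    mentions: list[EntityMention] = []
    if entity_range is not None:
        lo, hi = entity_range
        start = sent.tokens[lo].start
        end = sent.tokens[hi - 1].end
        if spec.boundary_jitter and hi < len(sent.tokens):
            end += spec.boundary_jitter  # systematic shift into the gap
        text = sent.text()[start - sent.start : end - sent.start]
        mentions.append(EntityMention(start, end, etype, text))
    return Example(sent, mentions, source=spec.name)


# ---------------------------------------------------------------------------
# raw text for LM training


def generate_lm_text(
    alphabet: str,
    style: str,
    length: int,
    seed: int = 0,
    transition: np.ndarray | None = None,
    entity_types: tuple[str, ...] = ("Gene",),
) -> str:
    """Deterministic raw-text stream for toy language-model training.

    styles:
      ``periodic`` — cycle through ``alphabet`` in order (entropy 0 given
        one character of context).
      ``markov`` — first-order chain over ``alphabet``; pass ``transition``
        (row-stochastic, shape k x k) for a known-entropy source, otherwise
        a seeded random one is drawn.
      ``template`` — sentences rendered from the corpus generator's
        dictionaries, so LM states become informative for the tagger.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if style == "periodic":
        if not alphabet:
            raise ValueError("periodic style needs a non-empty alphabet")
        reps = -(-length // len(alphabet))
        return (alphabet * reps)[:length]
    if style == "markov":
        k = len(alphabet)
        if k == 0:
            raise ValueError("markov style needs a non-empty alphabet")
        rng = np.random.default_rng(seed)
        if transition is None:
            transition = rng.dirichlet(np.ones(k) * 2.0, size=k)
        transition = np.asarray(transition, dtype=float)
        if transition.shape != (k, k):
            raise ValueError(f"transition must be {k}x{k}")
        if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        state = int(rng.integers(k))
        out = []
        for _ in range(length):
            out.append(alphabet[state])
            state = int(rng.choice(k, p=transition[state]))
        return "".join(out)
    if style == "template":
        spec = GeneratorSpec(
            name="lm", entity_types=tuple(entity_types), n_train=0, n_dev=0, n_test=0, seed=seed
        )
        dicts = spec.resolved_dictionaries()
        rng = np.random.default_rng([seed, 3])
        pieces: list[str] = []
        total = 0
        while total < length:
            ex = _render_sentence(spec, dicts, _ENTITY_TEMPLATES, rng, doc_id="lm")
            s = ex.sentence.text()
            pieces.append(s)
            total += len(s) + 1
        return " ".join(pieces)[:length]
    raise ValueError(f"unknown LM text style {style!r}")


def markov_stationary(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    transition = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()
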