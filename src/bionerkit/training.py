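"""Cross-corpus training: one tagger per entity type on merged corpora,
plus the pretrain-then-finetune protocol for held-out target corpora.

Optimization is plain SGD on the CRF negative log-likelihood with
decay-on-plateau: the learning rate is multiplied by ``lr_decay_factor``
after ``patience`` epochs without dev micro-F1 improvement, and training
stops when it falls below ``min_lr`` or the epoch limit is reached.  The
checkpoint with the best dev F1 is returned.  Embedding sources are
treated as frozen feature extractors, so token features are precomputed
once per corpus.

A leakage audit is kept on every training log: no sentence of any test
split is ever presented to an optimizer step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autodiff import clip_gradients, sgd_step, zero_gradients
from .core_types import Example, NERCorpus, spans_to_tags, tags_to_spans
from .corpus_io import merge_for_type
from .crf_tagger import TaggerModel
from .embeddings import EmbeddingStack, WordEmbeddingTable
from .evaluation import EXACT, EvalReport, match_and_count

__all__ = ["TrainConfig", "train_ner", "train_per_type", "pretrain_finetune", "evaluate_model"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 4
    learning_rate: float = 1.0
    lr_decay_factor: float = 0.5
    patience: int = 3
    min_lr: float = 1e-3
    clip: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.patience) < 1:
            raise ValueError("epochs, batch_size and patience must be >= 1")
        if self.learning_rate <= 0 or self.min_lr <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must be in (0,1)")


def _featurize(model: TaggerModel, examples) -> list[tuple[np.ndarray, np.ndarray]]:
    """Precompute (token features, gold tag indices) per sentence."""
    out = []
    for ex in examples:
        feats = model.stack.embed_sentence(ex.sentence)
        gold = model.tag_dict.encode(spans_to_tags(ex.sentence, ex.mentions, model.scheme))
        out.append((feats, gold))
    return out


def _dev_f1(model: TaggerModel, dev_data, dev_examples) -> float:
    rep = EvalReport(protocol=EXACT)
    for (feats, _), ex in zip(dev_data, dev_examples):
        tags = model.tag_dict.decode(model.decode(feats))
        pred = tags_to_spans(ex.sentence, tags, model.scheme)
        rep.add(match_and_count(ex.mentions, pred, EXACT))
    return rep.micro_f1


def train_ner(corpus: NERCorpus, model: TaggerModel, cfg: TrainConfig):
    """Train a tagger on one corpus; returns (best-dev model, training log).

    Reproducible given ``cfg.seed``: batch order and every update are
    deterministic functions of the seed, corpus and initial weights.
    """
    if not corpus.train:
        raise ValueError(f"corpus {corpus.name!r} has an empty train split")
    dev_examples = corpus.dev if corpus.dev else corpus.train
    train_data = _featurize(model, [ex for ex in corpus.train if len(ex.sentence.tokens)])
    train_examples = [ex for ex in corpus.train if len(ex.sentence.tokens)]
    dev_data = _featurize(model, dev_examples)

    test_ids = {id(ex) for ex in corpus.test}
    for split in corpus.test_by_corpus.values():
        test_ids.update(id(ex) for ex in split)
    leaked = sum(1 for ex in train_examples if id(ex) in test_ids)
    leaked += sum(1 for ex in dev_examples if id(ex) in test_ids)

    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    lr = cfg.learning_rate
    best_f1 = -1.0
    best_loss = np.inf
    best_state = None
    epochs_since_best = 0
    log: list[dict] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_data))
        total_loss = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            batch = order[lo : lo + cfg.batch_size]
            zero_gradients(params)
            batch_loss = 0.0
            for idx in batch:
                feats, gold = train_data[idx]
                loss = model.loss(feats, gold)
                loss.backward(np.asarray(1.0 / len(batch)))
                batch_loss += float(loss.data)
            clip_gradients(params, cfg.clip)
            sgd_step(params, lr)
            total_loss += batch_loss
        dev_f1 = _dev_f1(model, dev_data, dev_examples)
        entry = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": total_loss / max(1, len(train_data)),
            "dev_f1": dev_f1,
        }
        log.append(entry)
        if dev_f1 > best_f1:
            best_f1 = dev_f1
            best_state = model.state_dict()
        # plateau detection: an epoch counts as progress if dev F1 improved
        # or the train loss is still clearly descending (>= 1% drop)
        if dev_f1 > max((e["dev_f1"] for e in log[:-1]), default=-1.0) or \
                entry["train_loss"] < best_loss * 0.99:
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                lr *= cfg.lr_decay_factor
                epochs_since_best = 0
        best_loss = min(best_loss, entry["train_loss"])
        if lr < cfg.min_lr:
            break
        if best_f1 >= 1.0 and epoch >= 1:
            break  # nothing left to improve on dev
    if best_state is not None:
        model.load_state_dict(best_state)
    training_log = {
        "epochs": log,
        "best_dev_f1": best_f1,
        "leakage_audit": {"test_sentences_seen_by_optimizer": leaked},
    }
    assert leaked == 0, "test split leaked into training"
    return model, training_log


def default_stack(seed: int = 0, word_dim: int = 16, char_lm_pair=None) -> EmbeddingStack:
    sources = []
    if char_lm_pair is not None:
        from .embeddings import CharLMEmbedding

        sources.append(CharLMEmbedding(*char_lm_pair))
    sources.append(WordEmbeddingTable(dim=word_dim, seed=seed))
    return EmbeddingStack(sources)


def train_per_type(corpora, etype: str, cfg: TrainConfig,
                   stack: EmbeddingStack | None = None,
                   hidden_size: int = 32, merge_seed: int = 0):
    """Merge all corpora annotating ``etype`` and train a single-type model."""
    corpora = list(corpora)
    usable = [c for c in corpora if etype in c.entity_types]
    for c in corpora:
        if etype not in c.entity_types:
            logger.warning("corpus %s does not annotate %s; excluded", c.name, etype)
    if not usable:
        raise ValueError(f"no corpus in the pool annotates {etype!r}")
    merged = merge_for_type(usable, etype, seed=merge_seed)
    if stack is None:
        stack = default_stack(seed=cfg.seed)
    model = TaggerModel(stack, [etype], hidden_size=hidden_size, seed=cfg.seed)
    model, log = train_ner(merged, model, cfg)
    model.training_log = log
    return model


def pretrain_finetune(pool, target: NERCorpus, etype: str,
                      cfg_pre: TrainConfig, cfg_ft: TrainConfig,
                      stack: EmbeddingStack | None = None,
                      hidden_size: int = 32, holdout_fraction: float = 0.1):
    """Pretrain on a corpus pool, then finetune on the target's train+dev.

    The target must not be in the pool (leakage guard).  Because finetuning
    consumes the target dev split as training data, phase-2 model selection
    uses a seeded holdout slice of the target train split.  The target test
    split is never touched.
    """
    pool = list(pool)
    for c in pool:
        if c.name == target.name or c is target:
            raise ValueError(
                f"target corpus {target.name!r} present in pretraining pool"
            )
    if stack is None:
        stack = default_stack(seed=cfg_pre.seed)

    if pool:
        model = train_per_type(pool, etype, cfg_pre, stack=stack, hidden_size=hidden_size)
        phase1_state = model.state_dict()
    else:
        model = TaggerModel(stack, [etype], hidden_size=hidden_size, seed=cfg_pre.seed)
        phase1_state = model.state_dict()

    rng = np.random.default_rng(cfg_ft.seed)
    train = [ex for ex in target.train if ex.mentions is not None]
    n_hold = max(1, int(round(holdout_fraction * len(train)))) if train else 0
    order = rng.permutation(len(train))
    hold_idx = set(order[:n_hold].tolist())
    ft_train = [ex for i, ex in enumerate(train) if i not in hold_idx]
    ft_dev = [ex for i, ex in enumerate(train) if i in hold_idx]
    ft_corpus = NERCorpus(
        name=f"{target.name}-finetune",
        entity_types={etype},
        train=[_filter_type(ex, etype) for ex in ft_train + list(target.dev)],
        dev=[_filter_type(ex, etype) for ex in ft_dev],
        test=list(target.test),
    )
    model, log = train_ner(ft_corpus, model, cfg_ft)
    model.training_log = log
    model.phase1_state = phase1_state
    return model


def _filter_type(ex: Example, etype: str) -> Example:
    return Example(ex.sentence, [m for m in ex.mentions if m.type == etype], ex.source)


def evaluate_model(model: TaggerModel, examples, protocol) -> EvalReport:
    """Predict over examples and score against their gold mentions."""
    rep = EvalReport(protocol=protocol)
    for ex in examples:
        pred = model.predict(ex.sentence)
        rep.add(match_and_count(ex.mentions, pred, protocol))
    return rep
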