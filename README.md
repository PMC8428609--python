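# bionerkit

A self-contained toolkit for biomedical-style named entity recognition:
character-level language-model embeddings plus hashed-subword word
embeddings feed a BiLSTM-CRF tagger, trained **per entity type** on the
union of multiple harmonized corpora, and scored with mention-level span
matching under two protocols (exact with per-boundary character tolerance,
and lenient any-overlap).

Everything runs at desk scale on one CPU: the neural components are
implemented in NumPy with a small reverse-mode autodiff engine, and a
seeded synthetic-corpus generator stands in for large gold corpora so the
whole pipeline — LM pretraining, cross-corpus tagger training,
pretrain-then-finetune transfer, evaluation — is exercisable end to end in
minutes.

## Layout

| module | contents |
| --- | --- |
| `bionerkit.core_types` | tokens/sentences/mentions, IOB2 + BIOES span↔tag codecs, corpus validation |
| `bionerkit.corpus_io` | CoNLL column I/O, pluggable sentence/word segmentation, corpus merging and pool filtering |
| `bionerkit.char_lm` | character LSTM LM (next-char training, perplexity, contextual token embeddings) |
| `bionerkit.embeddings` | word table with hashed character-n-gram OOV fallback, embedding stacking |
| `bionerkit.crf_tagger` | exact linear-chain CRF (forward recursion, forward-backward, Viterbi) + BiLSTM tagger |
| `bionerkit.training` | SGD harness with decay-on-plateau, per-type cross-corpus training, pretrain/finetune |
| `bionerkit.evaluation` | mention matching protocols, per-type / micro / macro P-R-F1 reports |
| `bionerkit.synthetic_data` | seeded toy corpora with controllable annotation-convention divergence; raw LM text |
| `bionerkit.cli` | `bionerkit` command-line entry points |

## CLI quick start

```bash
# 1. synthetic CoNLL corpora + manifest + raw LM text
bionerkit make-fixtures --out-dir fixtures --seed 1 --n-train 80

# 2. forward + backward character LMs
bionerkit train-lm --text fixtures/lm_text.txt --out-dir lm --epochs 6 --seed 1

# 3. one tagger for the Gene type, trained on the union of all corpora
bionerkit train-ner --corpus-manifest fixtures/manifest.yaml \
    --entity-type Gene --charlm-dir lm --out-dir model --seed 1

# 4. tag new text (CoNLL or JSON mention-list output)
bionerkit predict --model model --input fixtures/pseudo0.test.conll \
    --input-format conll --out pred.conll

# 5. mention-level scoring (exact ±1 char, or --protocol overlap)
bionerkit evaluate --gold fixtures/pseudo0.test.conll --pred pred.conll \
    --protocol exact --tolerance 1 --out report.json
```

## Conventions

- Character offsets are 0-based half-open; `text[start:end]` always equals
  the mention/token surface string.
- Internal tag scheme is BIOES; IOB2 is supported for file I/O. Malformed
  tag runs decode leniently (any contiguous same-type non-O run is a span).
- Gold mentions of the same type must not overlap; different types may
  (models are single-type).
- All training, generation and evaluation paths are deterministic given a
  seed.
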