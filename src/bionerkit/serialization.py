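"""Model-bundle persistence: a directory holding the tagger checkpoint and
every embedding source it depends on, plus a versioned metadata file."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .char_lm import CharLM
from .crf_tagger import TaggerModel
from .embeddings import CharLMEmbedding, EmbeddingStack, WordEmbeddingTable

BUNDLE_VERSION = 1


def save_word_table(table: WordEmbeddingTable, path):
    words = sorted(table.vectors)
    meta = {
        "dim": table.dim, "n_min": table.n_min, "n_max": table.n_max,
        "n_buckets": table.n_buckets, "lowercase": table.lowercase,
        "words": words,
    }
    vecs = (
        np.stack([table.vectors[w] for w in words])
        if words else np.zeros((0, table.dim))
    )
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
        vectors=vecs, bucket_vectors=table.bucket_vectors,
    )


def load_word_table(path) -> WordEmbeddingTable:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode("utf-8"))
        vectors = {w: v for w, v in zip(meta["words"], data["vectors"])}
        return WordEmbeddingTable(
            dim=meta["dim"], n_min=meta["n_min"], n_max=meta["n_max"],
            n_buckets=meta["n_buckets"], lowercase=meta["lowercase"],
            vectors=vectors, bucket_vectors=data["bucket_vectors"],
        )


def save_bundle(model: TaggerModel, out_dir):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sources = []
    for i, src in enumerate(model.stack.sources):
        if isinstance(src, CharLMEmbedding):
            src.fwd.save(out_dir / f"source{i}_charlm_fwd.npz")
            src.bwd.save(out_dir / f"source{i}_charlm_bwd.npz")
            sources.append({"kind": "char-lm", "index": i})
        elif isinstance(src, WordEmbeddingTable):
            save_word_table(src, out_dir / f"source{i}_words.npz")
            sources.append({"kind": "word-hash", "index": i})
        else:
            raise ValueError(f"cannot serialize embedding source {src!r}")
    model.save(out_dir / "tagger.npz")
    meta = {"format_version": BUNDLE_VERSION, "sources": sources}
    (out_dir / "bundle.json").write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def load_bundle(bundle_dir) -> TaggerModel:
    bundle_dir = Path(bundle_dir)
    meta = json.loads((bundle_dir / "bundle.json").read_text(encoding="utf-8"))
    if meta.get("format_version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta.get('format_version')!r}")
    sources = []
    for entry in meta["sources"]:
        i = entry["index"]
        if entry["kind"] == "char-lm":
            fwd = CharLM.load(bundle_dir / f"source{i}_charlm_fwd.npz")
            bwd = CharLM.load(bundle_dir / f"source{i}_charlm_bwd.npz")
            sources.append(CharLMEmbedding(fwd, bwd))
        elif entry["kind"] == "word-hash":
            sources.append(load_word_table(bundle_dir / f"source{i}_words.npz"))
        else:
            raise ValueError(f"unknown source kind {entry['kind']!r}")
    return TaggerModel.load(bundle_dir / "tagger.npz", EmbeddingStack(sources))
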