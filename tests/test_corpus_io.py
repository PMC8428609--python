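import pytest

from bionerkit.core_types import BIOES, IOB2, EntityMention, Example, NERCorpus, Sentence
from bionerkit.corpus_io import (
    ColumnFormat,
    DEFAULT_FORMAT,
    load_manifest,
    merge_for_type,
    read_conll,
    remove_corpora,
    segment_document,
    write_conll,
)
from bionerkit.synthetic_data import GeneratorSpec, generate_corpus

from conftest import make_sentence


class TestReadConll:
    def test_minimal_file(self, tmp_path):
        f = tmp_path / "c.conll"
        f.write_text("BRCA1 B-Gene\nmutated O\n\n", encoding="utf-8")
        examples = read_conll(f)
        assert len(examples) == 1
        (ex,) = examples
        assert [t.text for t in ex.sentence.tokens] == ["BRCA1", "mutated"]
        assert ex.mentions == [EntityMention(0, 5, "Gene", "BRCA1")]

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.conll"
        f.write_text("", encoding="utf-8")
        assert read_conll(f) == []

    def test_comments_and_missing_trailing_blank(self, tmp_path):
        f = tmp_path / "c.conll"
        f.write_text("# doc 1\nTLK9 S-Gene\n", encoding="utf-8")
        examples = read_conll(f)
        assert len(examples) == 1
        assert examples[0].mentions[0].type == "Gene"

    def test_ragged_line_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "bad.conll"
        f.write_text("ok O\nbroken\n\n", encoding="utf-8")
        with pytest.raises(ValueError, match=":2"):
            read_conll(f)

    def test_unknown_tag_rejected_by_name(self, tmp_path):
        f = tmp_path / "bad.conll"
        f.write_text("tok Z-Gene\n\n", encoding="utf-8")
        with pytest.raises(ValueError, match="Z-Gene"):
            read_conll(f)

    def test_custom_columns(self, tmp_path):
        f = tmp_path / "c.conll"
        f.write_text("1 BRCA1 NN S-Gene\n\n", encoding="utf-8")
        fmt = ColumnFormat(token_column=1, tag_column=3)
        examples = read_conll(f, fmt=fmt)
        assert examples[0].sentence.tokens[0].text == "BRCA1"
        assert examples[0].mentions[0].type == "Gene"

    def test_invalid_format(self):
        with pytest.raises(ValueError):
            ColumnFormat(token_column=2, tag_column=2)


class TestWriteConll:
    def test_empty_input_empty_file(self, tmp_path):
        out = tmp_path / "o.conll"
        write_conll([], out)
        assert out.read_text(encoding="utf-8") == ""

    def test_one_sentence_one_block(self, tmp_path):
        out = tmp_path / "o.conll"
        sent = make_sentence(["TLK9", "rose"])
        write_conll([Example(sent, [EntityMention(0, 4, "Gene", "TLK9")])], out)
        assert out.read_text(encoding="utf-8") == "TLK9 S-Gene\nrose O\n\n"

    def test_round_trip_content_identity(self, tmp_path):
        corpus = generate_corpus(GeneratorSpec(n_train=25, n_dev=0, n_test=0, seed=9))
        f1 = tmp_path / "a.conll"
        f2 = tmp_path / "b.conll"
        write_conll(corpus.train, f1)
        reread = read_conll(f1)
        write_conll(reread, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert [ex.mentions for ex in reread] == [ex.mentions for ex in corpus.train]

    def test_scheme_conversion_preserves_mentions(self, tmp_path):
        corpus = generate_corpus(GeneratorSpec(n_train=10, n_dev=0, n_test=0, seed=2))
        f = tmp_path / "iob2.conll"
        write_conll(corpus.train, f, scheme=IOB2)
        reread = read_conll(f, scheme=IOB2)
        assert [ex.mentions for ex in reread] == [ex.mentions for ex in corpus.train]


class TestSegmentDocument:
    def test_simple_sentence(self):
        sents = segment_document("BRCA1 is mutated.")
        assert len(sents) == 1
        assert [t.text for t in sents[0].tokens] == ["BRCA1", "is", "mutated", "."]

    def test_abbreviation_blind_split(self):
        sents = segment_document("A. B.")
        assert len(sents) == 2

    def test_offsets_point_into_source(self):
        text = "TLK9 rose sharply.  Then it fell!  Why?"
        for sent in segment_document(text):
            for tok in sent.tokens:
                assert text[tok.start : tok.end] == tok.text

    def test_degenerate_text(self):
        assert segment_document("   ") == []


def _corpus(name, n_train, etypes=("Gene",), seed=0, with_dev=True):
    spec = GeneratorSpec(name=name, entity_types=tuple(etypes), n_train=n_train,
                         n_dev=5 if with_dev else 0, n_test=5, seed=seed)
    return generate_corpus(spec)


class TestMergeForType:
    def test_train_sizes_add(self):
        a, b = _corpus("a", 10), _corpus("b", 15, seed=1)
        merged = merge_for_type([a, b], "Gene")
        assert len(merged.train) == 25
        assert len(merged.dev) == len(a.dev) + len(b.dev)

    def test_self_merge_doubles_counts(self):
        a = _corpus("a", 10)
        merged = merge_for_type([a, a], "Gene")
        assert len(merged.train) == 20

    def test_other_type_mentions_dropped(self):
        c = _corpus("gd", 30, etypes=("Gene", "Disease"), seed=4)
        merged = merge_for_type([c], "Gene")
        for ex in merged.train + merged.dev + merged.test:
            assert all(m.type == "Gene" for m in ex.mentions)

    def test_mention_counts_add_per_component(self):
        a, b = _corpus("a", 12, seed=5), _corpus("b", 18, seed=6)
        n_a = sum(len(ex.mentions) for ex in a.train) + sum(len(ex.mentions) for ex in a.dev)
        n_b = sum(len(ex.mentions) for ex in b.train) + sum(len(ex.mentions) for ex in b.dev)
        merged = merge_for_type([a, b], "Gene")
        n_m = sum(len(ex.mentions) for ex in merged.train) + sum(len(ex.mentions) for ex in merged.dev)
        assert n_m == n_a + n_b

    def test_test_splits_kept_per_corpus(self):
        a, b = _corpus("a", 10), _corpus("b", 10, seed=1)
        merged = merge_for_type([a, b], "Gene")
        assert set(merged.test_by_corpus) == {"a", "b"}
        assert len(merged.test_by_corpus["a"]) == len(a.test)

    def test_missing_dev_split_donated_from_train(self):
        c = _corpus("nodev", 20, with_dev=False)
        merged = merge_for_type([c], "Gene", dev_fraction=0.1, seed=0)
        assert len(merged.dev) == 2
        assert len(merged.train) == 18

    def test_provenance_recorded(self):
        a, b = _corpus("a", 5), _corpus("b", 5, seed=1)
        merged = merge_for_type([a, b], "Gene")
        assert {ex.source for ex in merged.train} == {"a", "b"}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            merge_for_type([], "Gene")

    def test_wrong_type_rejected(self):
        with pytest.raises(ValueError):
            merge_for_type([_corpus("a", 5)], "Disease")


class TestRemoveCorpora:
    def _pool(self, n):
        return [NERCorpus(name=f"c{i}", entity_types={"Gene"}) for i in range(n)]

    def test_remove_three_of_pool(self):
        pool = self._pool(23)
        remaining = remove_corpora(pool, ["c0", "c1", "c2"])
        assert len(remaining) == 20

    def test_remove_none_is_identity(self):
        pool = self._pool(4)
        assert remove_corpora(pool, []) == pool

    def test_remove_all_allowed(self):
        pool = self._pool(2)
        assert remove_corpora(pool, ["c0", "c1"]) == []

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            remove_corpora(self._pool(2), ["nope"])


class TestManifest:
    def test_manifest_round_trip(self, tmp_path):
        corpus = generate_corpus(GeneratorSpec(name="m0", n_train=8, n_dev=3, n_test=3, seed=1))
        for split, examples in corpus.splits().items():
            write_conll(examples, tmp_path / f"m0.{split}.conll")
        (tmp_path / "manifest.yaml").write_text(
            "corpora:\n"
            "- name: m0\n"
            "  entity_types: [Gene]\n"
            "  splits: {train: m0.train.conll, dev: m0.dev.conll, test: m0.test.conll}\n",
            encoding="utf-8",
        )
        (loaded,) = load_manifest(tmp_path / "manifest.yaml")
        assert loaded.name == "m0"
        assert len(loaded.train) == 8 and len(loaded.dev) == 3 and len(loaded.test) == 3
        assert sum(len(ex.mentions) for ex in loaded.train) == sum(
            len(ex.mentions) for ex in corpus.train
        )
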