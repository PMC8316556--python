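"""Shared fixtures: one small synthetic world generated once per session."""

from __future__ import annotations

import pytest

from genepheno.association import compute_associations, count_occurrences
from genepheno.corpus_io import corpus_sentences
from genepheno.lexicon import load_gene_list
from genepheno.mentions import PhenotypeIndex
from genepheno.pipeline import build_lexicon_files
from genepheno.standardize import CategoryTable, HpoHierarchy
from genepheno.synthetic import PlantingSpec, generate_corpus, generate_vocabulary


class World:
    """A generated corpus plus everything mined from it."""

    def __init__(self, root, spec: PlantingSpec):
        self.root = root
        self.spec = spec
        self.vocab_paths = generate_vocabulary(spec, root / "vocab")
        self.truth = generate_corpus(spec, root / "corpus")
        self.truth.write_gold_jsonl(root / "gold.jsonl")
        self.gold_path = root / "gold.jsonl"
        self.corpus_dir = root / "corpus"
        self.lexicon = build_lexicon_files(
            self.vocab_paths["concepts"], self.vocab_paths["semtypes"],
            self.vocab_paths["asdpto"], root / "lexicon.json",
        )
        self.genes = load_gene_list(self.vocab_paths["genes"])
        self.hierarchy = HpoHierarchy.from_obo(self.vocab_paths["hpo"])
        self.table = CategoryTable()
        self.index = PhenotypeIndex(self.lexicon)
        self.sentences = corpus_sentences(self.corpus_dir)
        self.counts = count_occurrences(
            self.sentences, self.genes, self.index, self.lexicon,
            self.hierarchy, self.table,
        )
        self.records = compute_associations(self.counts)


@pytest.fixture(scope="session")
def small_world(tmp_path_factory) -> World:
    """300-sentence corpus: fast enough for every module's integration tests."""
    spec = PlantingSpec(n_articles=6, sentences_per_article=50, seed=11)
    return World(tmp_path_factory.mktemp("small_world"), spec)
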