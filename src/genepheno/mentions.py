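"""Dictionary-based mention detection.

Gene symbols are matched case-sensitively against the raw token stream as
whole tokens (so the gene ``CAT`` does not fire inside "scatter", and
``cars`` in prose does not hit the gene ``CARS``). Phenotype terms are
pre-lemmatized into an n-gram index and matched against the sentence's
lemma stream; overlapping candidate matches are resolved longest-first,
then leftmost, producing a non-overlapping final set whose spans are mapped
back to raw characters. A sentence with at least one gene and one phenotype
mention is a *target sentence*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import Sentence
from .lexicon import GeneLexicon, PhenotypeConcept, PhenotypeLexicon
from .textproc import preprocess_term

logger = logging.getLogger(__name__)

__all__ = ["Mention", "TargetSentence", "PhenotypeIndex", "match_genes",
           "match_phenotypes", "find_target_sentences", "extract_pairs"]


@dataclass(frozen=True)
class Mention:
    kind: str                       # "gene" | "phenotype"
    surface: str
    lexicon_ref: tuple[str, ...]    # gene: (symbol,); phenotype: candidate (cui, source) keys flattened
    sentence_ref: tuple[str, int]
    span: tuple[int, int]           # 0-based half-open char interval

    @property
    def candidates(self) -> tuple[str, ...]:
        return self.lexicon_ref


@dataclass
class TargetSentence:
    sentence: Sentence
    gene_mentions: list[Mention]
    phenotype_mentions: list[Mention]

    def __post_init__(self) -> None:
        if not self.gene_mentions or not self.phenotype_mentions:
            raise ValueError("target sentence requires >=1 gene and >=1 phenotype mention")


class PhenotypeIndex:
    """Lemma n-gram index over phenotype terms.

    Each term (preferred name or synonym) is normalized with
    :func:`preprocess_term`; the key maps to the candidate concepts sharing
    that normalized form. Degenerate terms (empty after normalization) are
    excluded with a warning.
    """

    def __init__(self, lexicon: PhenotypeLexicon):
        self.terms: dict[tuple[str, ...], list[PhenotypeConcept]] = {}
        self.max_len = 0
        for concept in lexicon.ordered():
            for term in sorted(concept.synonyms):
                key = preprocess_term(term)
                if not key:
                    logger.warning("degenerate phenotype term %r (%s) excluded",
                                   term, concept.concept_id)
                    continue
                bucket = self.terms.setdefault(key, [])
                if concept not in bucket:
                    bucket.append(concept)
                self.max_len = max(self.max_len, len(key))

    def candidates(self, key: tuple[str, ...]) -> list[PhenotypeConcept]:
        return self.terms.get(key, [])


def match_genes(sentence: Sentence, genes: GeneLexicon) -> list[Mention]:
    """Whole-token, case-sensitive gene-symbol matches; all occurrences."""
    out: list[Mention] = []
    for tok in sentence.raw_tokens:
        if tok.text in genes:
            out.append(
                Mention(
                    kind="gene",
                    surface=tok.text,
                    lexicon_ref=(tok.text,),
                    sentence_ref=sentence.key,
                    span=(tok.start, tok.end),
                )
            )
    return out


def _concept_sort_key(c: PhenotypeConcept) -> tuple[int, str]:
    return (c.priority_rank, c.concept_id)


def match_phenotypes(sentence: Sentence, index: PhenotypeIndex) -> list[Mention]:
    """Contiguous lemma n-gram matches, longest-first then leftmost.

    Returns a non-overlapping set of mentions whose character spans cover
    the matched raw tokens. Ties among equal-length overlapping terms are
    already collapsed at the index level (one key, several candidates);
    candidate order within a mention is by source priority then concept id.
    """
    lemmas = sentence.lemmas
    tokens = sentence.lemma_tokens
    n = len(lemmas)
    taken = [False] * n
    found: list[tuple[int, int, list[PhenotypeConcept]]] = []
    for length in range(min(index.max_len, n), 0, -1):
        for start in range(0, n - length + 1):
            if any(taken[start:start + length]):
                continue
            key = tuple(lemmas[start:start + length])
            cands = index.candidates(key)
            if cands:
                found.append((start, length, sorted(cands, key=_concept_sort_key)))
                for i in range(start, start + length):
                    taken[i] = True
    out: list[Mention] = []
    for start, length, cands in sorted(found):
        first, last = tokens[start], tokens[start + length - 1]
        out.append(
            Mention(
                kind="phenotype",
                surface=sentence.raw_text[first.start:last.end],
                lexicon_ref=tuple(f"{c.concept_id}|{c.source}" for c in cands),
                sentence_ref=sentence.key,
                span=(first.start, last.end),
            )
        )
    return out


def find_target_sentences(
    sentences: list[Sentence], genes: GeneLexicon, index: PhenotypeIndex
) -> list[TargetSentence]:
    """Sentences with at least one gene and one phenotype mention, in
    (article_id, index) order."""
    out: list[TargetSentence] = []
    for sent in sorted(sentences, key=lambda s: s.key):
        g = match_genes(sent, genes)
        if not g:
            continue
        p = match_phenotypes(sent, index)
        if not p:
            continue
        out.append(TargetSentence(sent, g, p))
    return out


def extract_pairs(target: TargetSentence) -> list[tuple[str, Mention]]:
    """Distinct gene symbols x distinct phenotype mentions of one sentence.

    Phenotype identity is the candidate set (so two surface mentions of the
    same term in one sentence collapse to one pair per gene).
    """
    symbols = sorted({m.lexicon_ref[0] for m in target.gene_mentions})
    seen: dict[tuple[str, ...], Mention] = {}
    for m in target.phenotype_mentions:
        seen.setdefault(m.lexicon_ref, m)
    return [(g, m) for g in symbols for m in seen.values()]
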