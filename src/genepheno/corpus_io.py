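"""Article XML ingestion and sentence preprocessing.

Articles arrive as JATS/PMC-style XML. Text is taken from the article title,
abstract and body paragraphs in document order; reference lists, tables and
figure captions are excluded (boilerplate like institution names in
references is a known source of spurious dictionary hits). Each article is
segmented into sentences, and each sentence is preprocessed into a lemma
token stream for phenotype matching alongside the raw token stream used for
case-sensitive gene-symbol matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

from .textproc import Token, preprocess_text, split_sentences

logger = logging.getLogger(__name__)

__all__ = ["Article", "Sentence", "read_article_xml", "read_corpus",
           "segment_sentences", "preprocess_sentence", "corpus_sentences",
           "write_sentence_table"]

#: JATS elements whose text must not be mined.
_EXCLUDED_TAGS = {
    "ref-list", "table-wrap", "table", "fig", "caption", "xref",
    "disp-formula", "inline-formula", "supplementary-material",
}


@dataclass
class Article:
    article_id: str
    title: str
    body_text: list[str] = field(default_factory=list)

    @property
    def text_blocks(self) -> list[str]:
        blocks = [self.title] if self.title else []
        return blocks + self.body_text


@dataclass
class Sentence:
    """One segmented sentence with provenance and preprocessing products."""

    article_id: str
    index: int
    raw_text: str
    lemmas: list[str] = field(default_factory=list)
    lemma_tokens: list[Token] = field(default_factory=list)
    raw_tokens: list[Token] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.article_id, self.index)


def _collect_text(element: etree._Element, parts: list[str]) -> None:
    tag = etree.QName(element).localname if isinstance(element.tag, str) else None
    if tag in _EXCLUDED_TAGS:
        return
    if element.text:
        parts.append(element.text)
    for child in element:
        _collect_text(child, parts)
        if child.tail:
            parts.append(child.tail)


def _element_text(element: etree._Element | None) -> str:
    if element is None:
        return ""
    parts: list[str] = []
    _collect_text(element, parts)
    return " ".join(" ".join(parts).split())


def read_article_xml(path: str | Path) -> Article:
    """Parse one JATS-like XML file into an :class:`Article`.

    Raises :class:`lxml.etree.XMLSyntaxError` for malformed XML; corpus-level
    readers catch it and skip the file.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()

    def first(xpath: str) -> etree._Element | None:
        hits = root.xpath(xpath)
        return hits[0] if hits else None

    article_id = _element_text(first(".//front//article-id")) or path.stem
    title = _element_text(first(".//article-title"))
    blocks: list[str] = []
    abstract = first(".//abstract")
    if abstract is not None:
        for p in abstract.iter("p"):
            text = _element_text(p)
            if text:
                blocks.append(text)
    body = first(".//body")
    if body is not None:
        for p in body.iter("p"):
            if any(etree.QName(a).localname in _EXCLUDED_TAGS
                   for a in p.iterancestors() if isinstance(a.tag, str)):
                continue
            text = _element_text(p)
            if text:
                blocks.append(text)
    return Article(article_id=article_id, title=title, body_text=blocks)


def read_corpus(corpus_dir: str | Path) -> Iterator[Article]:
    """Yield articles from every ``.xml``/``.nxml`` file in *corpus_dir*.

    Malformed files are skipped with a logged error; the run continues.
    Files are visited in sorted name order for reproducibility.
    """
    corpus_dir = Path(corpus_dir)
    paths = sorted(p for p in corpus_dir.iterdir()
                   if p.suffix.lower() in {".xml", ".nxml"})
    for path in paths:
        try:
            yield read_article_xml(path)
        except etree.XMLSyntaxError as exc:
            logger.error("skipping malformed article %s: %s", path.name, exc)


def segment_sentences(article: Article) -> list[Sentence]:
    """Segment an article's text blocks into raw sentences, indexed from 0."""
    sentences: list[Sentence] = []
    for block in article.text_blocks:
        for raw in split_sentences(block):
            sentences.append(Sentence(article.article_id, len(sentences), raw))
    return sentences


def preprocess_sentence(
    sentence: Sentence, stopwords: Iterable[str] | None = None
) -> Sentence:
    """Fill the lemma and raw token streams of *sentence* in place."""
    from .textproc import tokenize

    sentence.lemmas, sentence.lemma_tokens = preprocess_text(
        sentence.raw_text, stopwords
    )
    sentence.raw_tokens = tokenize(sentence.raw_text)
    return sentence


def corpus_sentences(
    corpus_dir: str | Path, stopwords: Iterable[str] | None = None
) -> list[Sentence]:
    """Read, segment and preprocess every sentence of a corpus directory."""
    out: list[Sentence] = []
    for article in read_corpus(corpus_dir):
        for sent in segment_sentences(article):
            out.append(preprocess_sentence(sent, stopwords))
    return out


def write_sentence_table(sentences: list[Sentence], path: str | Path) -> None:
    """Audit TSV of (article_id, index, raw_text)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("article_id\tindex\traw_text\n")
        for s in sentences:
            fh.write(f"{s.article_id}\t{s.index}\t{s.raw_text}\n")
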