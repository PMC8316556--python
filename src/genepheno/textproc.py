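"""Deterministic text preprocessing: tokenization, sentence segmentation,
stop-word removal and lemmatization.

The pipeline mines English biomedical prose for dictionary terms, so the
requirements are modest but strict: every step must be reproducible across
runs and machines (no model downloads, no global state), and token positions
must map back to character spans in the raw sentence so that mentions can be
reported with offsets.

Tokens are maximal runs of alphanumerics plus internal hyphens, apostrophes
and periods (so ``22q11``, ``X-linked`` and ``et al.``'s ``al`` survive as
single tokens). The lemmatizer is rule-based: an irregular-form table plus
ordered suffix rules for plural nouns and -ing/-ed verb forms. It is
intentionally conservative -- dictionary matching only needs sentence tokens
and vocabulary terms to normalize to the *same* string, not to a
linguistically perfect lemma.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

__all__ = [
    "Token",
    "tokenize",
    "split_sentences",
    "lemmatize_token",
    "default_stopwords",
    "preprocess_text",
    "preprocess_term",
]


@dataclass(frozen=True)
class Token:
    """A raw token with its half-open character span in the source string."""

    text: str
    start: int
    end: int


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:['\-][A-Za-z0-9]+)*")


def tokenize(text: str) -> list[Token]:
    """Split *text* into tokens, keeping 0-based half-open character spans."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

# Abbreviations that commonly precede a period without ending the sentence.
_ABBREVIATIONS = {
    "al", "approx", "cf", "dr", "e.g", "ed", "eds", "eq", "et", "etc",
    "fig", "figs", "i.e", "jr", "mr", "mrs", "ms", "no", "nos", "prof",
    "ref", "refs", "sec", "st", "suppl", "tab", "vol", "vols", "vs",
}

_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+|$)")


def split_sentences(text: str) -> list[str]:
    """Segment *text* into sentences with deterministic rules.

    A boundary is a run of ``.!?`` followed by whitespace, unless the period
    terminates a known abbreviation or a single capital letter (an initial),
    or the next visible character is lowercase or a digit (mid-sentence
    period, e.g. "Fig. 2" keeps going only when followed by lowercase; "Fig.
    2" followed by a digit is also glued).
    """
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end(1)
        word = text[:m.start(1)].rsplit(None, 1)
        prev = word[-1].rstrip(".").lower() if word else ""
        nxt_idx = m.end()
        nxt = text[nxt_idx:nxt_idx + 1]
        if "." in m.group(1):
            if prev in _ABBREVIATIONS or (len(prev) == 1 and prev.isalpha() and text[m.start(1) - 2:m.start(1) - 1].isupper()):
                continue
            if nxt and (nxt.islower() or nxt.isdigit()):
                continue
        chunk = text[start:end].strip()
        if chunk:
            sentences.append(chunk)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# Lemmatization
# ---------------------------------------------------------------------------

_IRREGULAR = {
    "children": "child",
    "criteria": "criterion",
    "feet": "foot",
    "geese": "goose",
    "men": "man",
    "mice": "mouse",
    "people": "person",
    "phenomena": "phenomenon",
    "teeth": "tooth",
    "women": "woman",
    "worse": "bad",
    "went": "go",
}

# Latin/Greek medical plurals seen constantly in phenotype vocabularies.
_MEDICAL_SUFFIXES = [
    ("epsies", "epsy"),      # epilepsies -> epilepsy
    ("omata", "oma"),        # carcinomata -> carcinoma
    ("ses", "sis"),          # diagnoses -> diagnosis, scleroses -> sclerosis
    ("iae", "ia"),           # sequelae-like forms
]

_VOWELS = set("aeiou")


def _strip_plural(word: str) -> str:
    for suf, rep in _MEDICAL_SUFFIXES:
        if word.endswith(suf) and len(word) > len(suf) + 1:
            return word[: -len(suf)] + rep
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ches", "shes", "sses", "xes", "zes")) and len(word) > 4:
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")) and len(word) > 3:
        return word[:-1]
    return word


def _strip_verb(word: str) -> str:
    if word.endswith("ing") and len(word) > 5:
        stem = word[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]                      # running -> run
        if stem[-1] not in _VOWELS and stem[-2] in _VOWELS and len(stem) > 3:
            return stem
        return stem
    if word.endswith("ed") and len(word) > 4:
        stem = word[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
            return stem[:-1]                      # stopped -> stop
        if stem.endswith(("at", "iz", "os", "us", "as")):
            return stem + "e"                     # associated -> associate
        return stem
    return word


def lemmatize_token(token: str) -> str:
    """Lowercase and lemmatize one token (noun plural and verb-form rules)."""
    word = token.lower()
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    stripped = _strip_plural(word)
    if stripped != word:
        return stripped
    return _strip_verb(word)


# ---------------------------------------------------------------------------
# Stop words & composed pipelines
# ---------------------------------------------------------------------------

def default_stopwords() -> frozenset[str]:
    """Load the packaged stop-word list (one token per line, '#' comments)."""
    text = resources.files("genepheno.data").joinpath("stopwords.txt").read_text("utf-8")
    words = {ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")}
    return frozenset(words)


_DEFAULT_STOPWORDS: frozenset[str] | None = None


def _stopwords(stopwords: Iterable[str] | None) -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if stopwords is not None:
        return frozenset(stopwords)
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = default_stopwords()
    return _DEFAULT_STOPWORDS


def preprocess_text(
    text: str, stopwords: Iterable[str] | None = None
) -> tuple[list[str], list[Token]]:
    """Tokenize, remove stop words and lemmatize *text*.

    Returns the lemma sequence and the parallel list of surviving raw tokens
    (which carry the character spans, so ``lemmas[i]`` maps to
    ``tokens[i].start:tokens[i].end`` in *text*).
    """
    stops = _stopwords(stopwords)
    lemmas: list[str] = []
    kept: list[Token] = []
    for tok in tokenize(text):
        if tok.text.lower() in stops:
            continue
        lemma = lemmatize_token(tok.text)
        if not lemma:
            continue
        lemmas.append(lemma)
        kept.append(tok)
    return lemmas, kept


def preprocess_term(term: str, stopwords: Iterable[str] | None = None) -> tuple[str, ...]:
    """Normalize a vocabulary term to its lemma n-gram key.

    Stop words inside multi-word terms are dropped ("Loss of purposeful hand
    use" and "loss purposeful hand use" normalize identically). A term that
    consists solely of stop words reduces to the empty tuple; callers must
    exclude such degenerate terms from the match index (with a warning).
    """
    stops = _stopwords(stopwords)
    return tuple(
        lemmatize_token(t.text)
        for t in tokenize(term)
        if t.text.lower() not in stops
    )
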