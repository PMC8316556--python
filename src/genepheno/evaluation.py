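"""Evaluation against gold annotations and reference association databases.

Two complementary checks: (1) precision/recall of mined mentions against a
manually curated gold standard, scored at the gene, phenotype and sentence
level; (2) a per-risk-class true-positive rate against a reference
gene-phenotype association database, where a gene counts as a true positive
when at least one of its mined associations also appears in the reference.

Gold files are JSONL, one article per line::

    {"article_id": "A1",
     "genes": [[sentence_index, "SYMBOL"], ...],
     "phenotypes": [[sentence_index, "CONCEPT_ID"], ...],
     "target_sentences": [sentence_index, ...]}

Mention identity is (article, sentence, lexicon reference) — spans are
deliberately ignored so annotation need not be character-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .association import AssociationRecord
from .mentions import TargetSentence

__all__ = ["GoldAnnotation", "PRResult", "load_gold_jsonl", "predicted_sets",
           "precision_recall", "reference_tp_rate", "load_reference_tsv"]

GeneKey = tuple[str, int, str]
SentKey = tuple[str, int]


@dataclass
class GoldAnnotation:
    genes: set[GeneKey]
    phenotypes: set[GeneKey]
    sentences: set[SentKey]


@dataclass(frozen=True)
class PRResult:
    level: str
    benchmark: int
    tp: int
    fp: int
    fn: int
    precision: float  # percent, 1-decimal precision reported downstream
    recall: float


def load_gold_jsonl(path: str | Path) -> GoldAnnotation:
    genes: set[GeneKey] = set()
    phens: set[GeneKey] = set()
    sents: set[SentKey] = set()
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        aid = rec["article_id"]
        genes.update((aid, int(i), s) for i, s in rec.get("genes", []))
        phens.update((aid, int(i), c) for i, c in rec.get("phenotypes", []))
        sents.update((aid, int(i)) for i in rec.get("target_sentences", []))
    return GoldAnnotation(genes=genes, phenotypes=phens, sentences=sents)


def predicted_sets(
    targets: Sequence[TargetSentence],
    standardized_ids: dict[tuple[str, ...], str] | None = None,
) -> tuple[set[GeneKey], set[GeneKey], set[SentKey]]:
    """Mined mention sets keyed like the gold standard.

    Phenotype identity is the standardized concept id when a mapping from
    candidate sets to concept ids is supplied, else the first candidate's
    concept id.
    """
    genes: set[GeneKey] = set()
    phens: set[GeneKey] = set()
    sents: set[SentKey] = set()
    for t in targets:
        aid, idx = t.sentence.key
        sents.add((aid, idx))
        for m in t.gene_mentions:
            genes.add((aid, idx, m.lexicon_ref[0]))
        for m in t.phenotype_mentions:
            if standardized_ids and m.lexicon_ref in standardized_ids:
                cid = standardized_ids[m.lexicon_ref]
            else:
                cid = m.lexicon_ref[0].split("|")[0]
            phens.add((aid, idx, cid))
    return genes, phens, sents


def precision_recall(predicted: set, gold: set, level: str) -> PRResult:
    """Set-based precision/recall at one level (gene, phenotype, sentence).

    tp = |predicted ∩ gold|, fp = |predicted \\ gold|, fn = |gold \\ predicted|;
    benchmark = tp + fn. Percentages are rounded to one decimal.
    """
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    precision = round(100.0 * tp / (tp + fp), 1) if tp + fp else 0.0
    recall = round(100.0 * tp / (tp + fn), 1) if tp + fn else 0.0
    return PRResult(level=level, benchmark=tp + fn, tp=tp, fp=fp, fn=fn,
                    precision=precision, recall=recall)


def load_reference_tsv(path: str | Path) -> set[tuple[str, str]]:
    """Reference association file: TSV of (gene symbol, phenotype id)."""
    pairs: set[tuple[str, str]] = set()
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2:
            pairs.add((parts[0], parts[1]))
    if not pairs:
        raise ValueError(f"empty reference association file: {path}")
    return pairs


def reference_tp_rate(
    records: Iterable[AssociationRecord],
    reference: set[tuple[str, str]],
    risk_classes: dict[str, str],
) -> dict[str, tuple[int, int, float]]:
    """Per-risk-class true-positive rates against a reference database.

    Only genes present in both the mined records and the reference are
    evaluated. A gene is a true positive when at least one of its mined
    (gene, phenotype) pairs appears in the reference; phenotype identity is
    the HPO id when the standardized concept has one, else the concept id.
    Returns class -> (true positives, evaluated genes, rate).
    """
    if not reference:
        raise ValueError("empty reference")
    ref_genes = {g for g, _ in reference}
    mined: dict[str, set[str]] = {}
    for r in records:
        pid = r.phenotype.hpo_id or r.phenotype.concept_id
        mined.setdefault(r.gene, set()).add(pid)
    out: dict[str, tuple[int, int, float]] = {}
    classes: dict[str, list[str]] = {}
    for g in mined:
        if g in ref_genes:
            classes.setdefault(risk_classes.get(g, "NA"), []).append(g)
    for cls, members in sorted(classes.items()):
        tps = sum(1 for g in members
                  if any((g, p) in reference for p in mined[g]))
        out[cls] = (tps, len(members), tps / len(members))
    return out


def write_pr_table(results: Sequence[PRResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("level\tbenchmark\ttp\tfp\tfn\tprecision\trecall\n")
        for r in results:
            fh.write(f"{r.level}\t{r.benchmark}\t{r.tp}\t{r.fp}\t{r.fn}\t"
                     f"{r.precision:.1f}%\t{r.recall:.1f}%\n")
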