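"""Sentence-level co-occurrence counting and NPMI association scoring.

A gene G and a standardized phenotype P are associated in proportion to how
much more often they share a sentence than chance predicts. With n_tot the
total number of corpus sentences, n_G and n_P the numbers of sentences
mentioning the gene and the phenotype, and n_GP the number mentioning both,
the normalized pointwise mutual information is

    NPMI(G, P) = ln( n_GP * n_tot / (n_G * n_P) ) / ( -ln( n_GP / n_tot ) )

which lies in [-1, 1]: -1 when the two never co-occur (taken as the n_GP -> 0
limit), 0 when they occur independently, and 1 when they always co-occur
(n_GP = n_G = n_P). Low-confidence associations are filtered with strict
thresholds NPMI > 0 and n_GP > 5 by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .corpus_io import Sentence
from .lexicon import GeneLexicon
from .mentions import PhenotypeIndex, match_genes, match_phenotypes
from .standardize import (CategoryTable, HpoHierarchy, StandardizedPhenotype,
                          standardize_mention)

__all__ = ["CorpusCounts", "AssociationRecord", "npmi", "count_occurrences",
           "compute_associations", "filter_associations",
           "rank_phenotypes_for_gene", "summarize_frequencies",
           "write_associations_tsv"]

PhenKey = tuple[str, str]  # (concept_id, source)


@dataclass
class CorpusCounts:
    """Per-gene, per-phenotype and joint sentence counts over a corpus."""

    n_tot: int = 0
    n_G: dict[str, int] = field(default_factory=dict)
    n_P: dict[PhenKey, int] = field(default_factory=dict)
    n_GP: dict[tuple[str, PhenKey], int] = field(default_factory=dict)
    papers_G: dict[str, int] = field(default_factory=dict)
    phenotypes: dict[PhenKey, StandardizedPhenotype] = field(default_factory=dict)

    def validate(self) -> None:
        for (g, p), n in self.n_GP.items():
            if n > min(self.n_G.get(g, 0), self.n_P.get(p, 0)):
                raise ValueError(f"count corruption: n_GP({g},{p})={n} exceeds marginals")


@dataclass(frozen=True)
class AssociationRecord:
    gene: str
    phenotype: StandardizedPhenotype
    n_G: int
    n_P: int
    n_GP: int
    n_tot: int
    npmi: float


def npmi(n_G: int, n_P: int, n_GP: int, n_tot: int) -> float:
    """Evaluate NPMI for one count configuration.

    Boundary conventions are the analytic limits: ``n_GP = 0`` gives -1 and
    ``n_GP = n_tot`` gives 1. The result is clamped to [-1, 1] against
    floating-point rounding. ``n_GP`` exceeding a marginal is fatal (count
    corruption upstream).
    """
    if n_tot <= 0:
        raise ValueError("n_tot must be positive")
    if n_GP < 0 or n_G < n_GP or n_P < n_GP:
        raise ValueError(f"invalid counts: n_GP={n_GP}, n_G={n_G}, n_P={n_P}")
    if n_G < 1 or n_P < 1:
        raise ValueError("n_G and n_P must be >= 1")
    if n_GP == 0:
        return -1.0
    if n_GP == n_tot or n_GP == n_G == n_P:
        # co-occurrence-complete: the ratio is exactly 1 analytically
        return 1.0
    pmi = math.log(n_GP * n_tot / (n_G * n_P))
    denom = -math.log(n_GP / n_tot)
    return max(-1.0, min(1.0, pmi / denom))


def count_occurrences(
    sentences: Iterable[Sentence],
    genes: GeneLexicon,
    index: PhenotypeIndex,
    lexicon,
    hierarchy: HpoHierarchy | None = None,
    table: CategoryTable | None = None,
) -> CorpusCounts:
    """Count gene/phenotype/joint sentence occurrences over the whole corpus.

    Every corpus sentence contributes to ``n_tot``; a sentence contributes at
    most 1 to each of n_G(g), n_P(p) and n_GP(g, p) no matter how many times
    a symbol or synonym repeats within it. Phenotype counting is at the
    standardized-concept level, so all synonyms of one concept pool into one
    n_P.
    """
    counts = CorpusCounts()
    std_cache: dict[tuple[str, ...], StandardizedPhenotype] = {}
    gene_articles: dict[str, set[str]] = {}
    for sent in sentences:
        counts.n_tot += 1
        symbols = {m.lexicon_ref[0] for m in match_genes(sent, genes)}
        phens: set[PhenKey] = set()
        for m in match_phenotypes(sent, index):
            ref = m.lexicon_ref
            if ref not in std_cache:
                cands = [lexicon.concepts[tuple(r.split("|"))] for r in ref]
                std_cache[ref] = standardize_mention(cands, hierarchy, table)
            std = std_cache[ref]
            counts.phenotypes[std.key] = std
            phens.add(std.key)
        for g in symbols:
            counts.n_G[g] = counts.n_G.get(g, 0) + 1
            gene_articles.setdefault(g, set()).add(sent.article_id)
        for p in phens:
            counts.n_P[p] = counts.n_P.get(p, 0) + 1
        for g in symbols:
            for p in phens:
                counts.n_GP[(g, p)] = counts.n_GP.get((g, p), 0) + 1
    counts.papers_G = {g: len(a) for g, a in gene_articles.items()}
    counts.validate()
    return counts


def compute_associations(counts: CorpusCounts) -> list[AssociationRecord]:
    """One record per observed co-occurring (gene, phenotype) pair."""
    records = []
    for (g, p), n_gp in sorted(counts.n_GP.items()):
        records.append(
            AssociationRecord(
                gene=g,
                phenotype=counts.phenotypes[p],
                n_G=counts.n_G[g],
                n_P=counts.n_P[p],
                n_GP=n_gp,
                n_tot=counts.n_tot,
                npmi=npmi(counts.n_G[g], counts.n_P[p], n_gp, counts.n_tot),
            )
        )
    return records


def filter_associations(
    records: Iterable[AssociationRecord],
    npmi_min: float = 0.0,
    count_min: int = 5,
) -> list[AssociationRecord]:
    """Keep records with npmi > npmi_min and n_GP > count_min (both strict)."""
    return [r for r in records if r.npmi > npmi_min and r.n_GP > count_min]


def _rank_key(r: AssociationRecord) -> tuple[float, int, str]:
    return (-r.npmi, -r.n_GP, r.phenotype.concept_id)


def rank_phenotypes_for_gene(
    gene: str, records: Iterable[AssociationRecord], k: int = 3
) -> list[AssociationRecord]:
    """Top-k records for *gene* by descending NPMI, ties by n_GP then id."""
    mine = sorted((r for r in records if r.gene == gene), key=_rank_key)
    return mine[:k]


def summarize_frequencies(
    counts: CorpusCounts,
    genes: GeneLexicon,
    records: Iterable[AssociationRecord] | None = None,
    top_n: int = 30,
) -> dict:
    """Frequency summaries: risk-class shares and top-N genes/phenotypes.

    Gene shares are over the distinct genes observed in the corpus;
    association shares (if *records* given) are over association records.
    Top genes rank by number of distinct referencing articles; top
    phenotypes by mention-sentence count, annotated with their category.
    """
    def class_shares(items: list[str]) -> dict[str, float]:
        out: dict[str, float] = {}
        for cls in ["1", "2", "3", "S", "NA"]:
            hits = sum(1 for g in items if genes.risk_class(g) == cls)
            out[cls] = 100.0 * hits / len(items) if items else 0.0
        return out

    observed = sorted(counts.n_G)
    summary = {
        "gene_class_percent": class_shares(observed),
        "top_genes": [
            {"gene": g, "papers": n, "risk_class": genes.risk_class(g)}
            for g, n in sorted(counts.papers_G.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        ],
        "top_phenotypes": [
            {
                "concept_id": p[0],
                "preferred_name": counts.phenotypes[p].preferred_name,
                "category": counts.phenotypes[p].top_level_category,
                "sentences": n,
            }
            for p, n in sorted(counts.n_P.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        ],
    }
    if records is not None:
        rec_list = list(records)
        summary["association_class_percent"] = {
            cls: (100.0 * sum(1 for r in rec_list if genes.risk_class(r.gene) == cls)
                  / len(rec_list) if rec_list else 0.0)
            for cls in ["1", "2", "3", "S", "NA"]
        }
    return summary


_TSV_HEADER = ("gene\tconcept_id\tpreferred_name\tsource\thpo_id\tcategory\t"
               "n_G\tn_P\tn_GP\tn_tot\tnpmi\n")


def write_associations_tsv(records: Iterable[AssociationRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_TSV_HEADER)
        for r in records:
            p = r.phenotype
            fh.write(f"{r.gene}\t{p.concept_id}\t{p.preferred_name}\t{p.source}\t"
                     f"{p.hpo_id or ''}\t{p.top_level_category}\t"
                     f"{r.n_G}\t{r.n_P}\t{r.n_GP}\t{r.n_tot}\t{r.npmi:.6f}\n")


def read_associations_tsv(path: str | Path) -> list[AssociationRecord]:
    records: list[AssociationRecord] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected association TSV header in {path}")
        for line in fh:
            (gene, cid, name, source, hpo_id, category,
             n_g, n_p, n_gp, n_tot, val) = line.rstrip("\n").split("\t")
            records.append(
                AssociationRecord(
                    gene=gene,
                    phenotype=StandardizedPhenotype(
                        concept_id=cid, preferred_name=name, source=source,
                        hpo_id=hpo_id or None, top_level_category=category,
                    ),
                    n_G=int(n_g), n_P=int(n_p), n_GP=int(n_gp), n_tot=int(n_tot),
                    npmi=float(val),
                )
            )
    return records


def export_per_gene_json(records: Iterable[AssociationRecord], path: str | Path) -> None:
    by_gene: dict[str, list[dict]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(
            {"concept_id": r.phenotype.concept_id,
             "preferred_name": r.phenotype.preferred_name,
             "npmi": r.npmi, "n_GP": r.n_GP}
        )
    Path(path).write_text(json.dumps(by_gene, indent=1, sort_keys=True), "utf-8")
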