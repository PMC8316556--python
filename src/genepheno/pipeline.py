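"""End-to-end pipeline orchestration.

Wires the stages together: lexicon build -> sentence extraction -> mention
mining -> standardization -> NPMI scoring -> (optionally) clustering,
network construction and evaluation. Every run writes a JSON manifest
echoing the effective configuration, seeds and package version, so any
output directory is self-describing and reruns are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .association import (compute_associations, count_occurrences,
                          filter_associations, summarize_frequencies,
                          write_associations_tsv)
from .corpus_io import corpus_sentences, write_sentence_table
from .evaluation import (load_gold_jsonl, precision_recall, predicted_sets,
                         write_pr_table)
from .lexicon import (GeneLexicon, PhenotypeLexicon, SemanticTypeFilter,
                      build_phenotype_lexicon, load_gene_list,
                      parse_asdpto_terms, parse_concept_file,
                      parse_semantic_types)
from .mentions import PhenotypeIndex, find_target_sentences
from .network import (betweenness_centrality, build_graph,
                      global_average_npmi, top_fraction, write_centrality,
                      write_edge_list)
from .standardize import CategoryTable, HpoHierarchy
from .profiles import (build_matrix, concordance, embed_2d, kmeans_cluster,
                       label_by_top_category)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "build_lexicon_files", "run_pipeline"]


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run (serialized to manifest)."""

    corpus_dir: str
    lexicon_json: str
    genes_path: str
    hpo_path: str | None = None
    out_dir: str = "genepheno_out"
    npmi_min: float = 0.0
    count_min: int = 5
    edge_threshold_mode: str = "global_mean"   # or "global_mean_positive"
    top_fraction: float = 0.10
    weighted_paths: bool = True
    k: int | None = None
    seed: int = 0
    perplexity: float = 30.0
    gold_path: str | None = None


def build_lexicon_files(
    concepts_path: str | Path,
    semtypes_path: str | Path,
    asdpto_path: str | Path | None,
    out_path: str | Path,
    semantic_filter: SemanticTypeFilter = SemanticTypeFilter(),
) -> PhenotypeLexicon:
    """Stage: parse vocabulary files and persist the filtered lexicon."""
    rows = parse_concept_file(concepts_path)
    semtypes = parse_semantic_types(semtypes_path)
    asdpto = parse_asdpto_terms(asdpto_path) if asdpto_path else []
    lexicon = build_phenotype_lexicon(rows, semtypes, semantic_filter, asdpto)
    lexicon.to_json(out_path)
    return lexicon


def run_pipeline(config: RunConfig) -> dict:
    """Run mining, scoring and the downstream analyses per *config*.

    Returns a summary dict (also written as ``manifest.json`` alongside the
    stage outputs in ``config.out_dir``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = PhenotypeLexicon.from_json(config.lexicon_json)
    genes = load_gene_list(config.genes_path)
    hierarchy = HpoHierarchy.from_obo(config.hpo_path) if config.hpo_path else None
    table = CategoryTable()
    index = PhenotypeIndex(lexicon)

    sentences = corpus_sentences(config.corpus_dir)
    write_sentence_table(sentences, out / "sentences.tsv")

    counts = count_occurrences(sentences, genes, index, lexicon, hierarchy, table)
    records = compute_associations(counts)
    write_associations_tsv(records, out / "associations_all.tsv")
    kept = filter_associations(records, config.npmi_min, config.count_min)
    write_associations_tsv(kept, out / "associations_filtered.tsv")

    summary: dict = {
        "version": __version__,
        "config": asdict(config),
        "n_sentences": counts.n_tot,
        "n_genes": len(counts.n_G),
        "n_phenotypes": len(counts.n_P),
        "n_associations": len(records),
        "n_associations_filtered": len(kept),
        "frequencies": summarize_frequencies(counts, genes, kept),
    }

    # Clustering (needs k and at least 3 genes with positive-NPMI profiles)
    if config.k is not None:
        matrix = build_matrix(records)
        if len(matrix) >= 3:
            coords = embed_2d(matrix, seed=config.seed, perplexity=config.perplexity)
            coords.to_csv(out / "tsne_coords.tsv", sep="\t")
            clusters = kmeans_cluster(coords, config.k, seed=config.seed)
            labels = label_by_top_category(records)
            shared = sorted(set(clusters) & set(labels))
            if shared:
                scores = concordance([clusters[g] for g in shared],
                                     [labels[g] for g in shared])
                summary["concordance"] = asdict(scores)
            with (out / "clusters.tsv").open("w", encoding="utf-8") as fh:
                fh.write("gene\tcluster\tcategory\n")
                for g in matrix.index:
                    fh.write(f"{g}\t{clusters[g]}\t{labels.get(g, 'NA')}\n")
        else:
            logger.warning("skipping clustering: fewer than 3 genes")

    # Network over risk-class genes
    if kept:
        threshold = global_average_npmi(
            kept, positive_only=config.edge_threshold_mode == "global_mean_positive"
        )
        risk = {g: genes.risk_class(g) for g in counts.n_G}
        node_genes = [g for g in counts.n_G if genes.risk_class(g) != "NA"] or sorted(counts.n_G)
        graph = build_graph(kept, node_genes, threshold, risk)
        write_edge_list(graph, out / "network_edges.tsv")
        scores = betweenness_centrality(graph, weighted=config.weighted_paths)
        write_centrality(scores, out / "centrality.tsv", risk)
        selected = top_fraction(scores, config.top_fraction)
        (out / "top_genes.tsv").write_text(
            "".join(f"{g}\t{risk.get(g, 'NA')}\n" for g in selected), "utf-8"
        )
        summary["network"] = {
            "threshold": threshold,
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "top_genes": selected,
        }

    # Evaluation against a gold standard
    if config.gold_path:
        gold = load_gold_jsonl(config.gold_path)
        targets = find_target_sentences(sentences, genes, index)
        pred_g, pred_p, pred_s = predicted_sets(targets)
        results = [
            precision_recall(pred_g, gold.genes, "gene"),
            precision_recall(pred_p, gold.phenotypes, "phenotype"),
            precision_recall(pred_s, gold.sentences, "sentence"),
        ]
        write_pr_table(results, out / "evaluation.tsv")
        summary["evaluation"] = {r.level: {"precision": r.precision, "recall": r.recall}
                                 for r in results}

    (out / "manifest.json").write_text(json.dumps(summary, indent=1, default=str), "utf-8")
    return summary
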