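"""Gene phenotype-profile clustering and concordance scoring.

Genes are represented by binary phenotype profiles: entry (g, p) is 1 when
the NPMI of the association is strictly positive, else 0. The profiles are
embedded in 2-D with t-SNE and clustered with k-means; the clustering is
compared against an ontology-derived labeling (each gene labeled by the
top-level category of its highest-NPMI phenotype) with four concordance
metrics computed from the cluster-vs-label contingency table:

* adjusted Rand index (pair counting, chance corrected; may be negative),
* Jaccard index (agreeing pairs over pairs joined in either partition),
* normalized mutual information (symmetric, arithmetic-mean normalization),
* purity (fraction of items in the majority reference label of their
  cluster; the second argument is the reference labeling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .association import AssociationRecord, _rank_key

__all__ = ["build_matrix", "label_by_top_category", "embed_2d", "kmeans_cluster",
           "adjusted_rand_index", "jaccard_index",
           "normalized_mutual_information", "purity", "ConcordanceScores",
           "concordance"]


def build_matrix(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Binary gene x phenotype incidence keyed by NPMI > 0 (strict).

    Rows are genes, columns phenotype concept ids, both sorted, so the build
    is idempotent and independent of record order.
    """
    genes = sorted({r.gene for r in records})
    phens = sorted({r.phenotype.concept_id for r in records})
    mat = pd.DataFrame(0, index=genes, columns=phens, dtype=np.int8)
    for r in records:
        if r.npmi > 0:
            mat.loc[r.gene, r.phenotype.concept_id] = 1
    return mat


def label_by_top_category(records: Sequence[AssociationRecord]) -> dict[str, str]:
    """Label each gene by the category of its maximum-NPMI phenotype.

    Ties follow the ranking rule (NPMI desc, then n_GP desc, then concept
    id). Genes whose top phenotype has category "NA" are dropped — only
    genes traceable to an HPO top-level category are labeled.
    """
    best: dict[str, AssociationRecord] = {}
    for r in sorted(records, key=_rank_key):
        best.setdefault(r.gene, r)
    return {
        g: r.phenotype.top_level_category
        for g, r in sorted(best.items())
        if r.phenotype.top_level_category != "NA"
    }


def embed_2d(
    matrix: pd.DataFrame,
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> pd.DataFrame:
    """t-SNE embedding of the gene profiles into 2-D.

    Deterministic for a fixed seed. Perplexity is clipped below the number
    of genes as t-SNE requires; fewer than 3 genes is an error.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError(f"t-SNE embedding needs >= 3 genes, got {n}")
    perplexity = min(perplexity, n - 1)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        max_iter=n_iter,
        init="pca",
    )
    coords = tsne.fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=matrix.index, columns=["tsne1", "tsne2"])


def kmeans_cluster(
    coordinates: pd.DataFrame, k: int, seed: int = 0
) -> dict[str, int]:
    """k-means over the embedding; deterministic for a fixed seed."""
    n = len(coordinates)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(coordinates.to_numpy(dtype=float))
    present = set(labels)
    empty = [c for c in range(k) if c not in present]
    if empty:
        import logging
        logging.getLogger(__name__).warning("empty clusters: %s", empty)
    return dict(zip(coordinates.index, (int(x) for x in labels)))


# ---------------------------------------------------------------------------
# Concordance metrics (contingency-table definitions)
# ---------------------------------------------------------------------------

def _contingency(a: Sequence[Hashable], b: Sequence[Hashable]) -> np.ndarray:
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty label vectors")
    rows = {lab: i for i, lab in enumerate(dict.fromkeys(a))}
    cols = {lab: j for j, lab in enumerate(dict.fromkeys(b))}
    table = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for x, y in zip(a, b):
        table[rows[x], cols[y]] += 1
    return table


def _pair_counts(table: np.ndarray) -> tuple[float, float, float, float]:
    """(agree-together, in-a-only, in-b-only, agree-apart) pair counts."""
    n = table.sum()
    together = comb(table, 2).sum()
    a_pairs = comb(table.sum(axis=1), 2).sum()
    b_pairs = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    return (
        float(together),
        float(a_pairs - together),
        float(b_pairs - together),
        float(total - a_pairs - b_pairs + together),
    )


def adjusted_rand_index(a: Sequence[Hashable], b: Sequence[Hashable]) -> float:
    """Chance-corrected pair-counting agreement; 1 iff identical partitions."""
    table = _contingency(a, b)
    n = table.sum()
    together = comb(table, 2).sum()
    a_pairs = comb(table.sum(axis=1), 2).sum()
    b_pairs = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = a_pairs * b_pairs / total if total else 0.0
    max_index = (a_pairs + b_pairs) / 2.0
    if max_index == expected:
        return 1.0
    return float((together - expected) / (max_index - expected))


def jaccard_index(a: Sequence[Hashable], b: Sequence[Hashable]) -> float:
    """Pairs joined in both partitions over pairs joined in either."""
    s11, s10, s01, _ = _pair_counts(_contingency(a, b))
    denom = s11 + s10 + s01
    return float(s11 / denom) if denom else 1.0


def normalized_mutual_information(
    a: Sequence[Hashable], b: Sequence[Hashable]
) -> float:
    """Mutual information normalized by the mean of the two entropies."""
    table = _contingency(a, b).astype(float)
    n = table.sum()
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    pab = table / n
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(pab > 0, np.log(pab / np.outer(pa, pb)), 0.0)
    mi = float((pab * log_term).sum())
    ha = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    mean_h = (ha + hb) / 2.0
    if mean_h == 0.0:
        return 1.0  # both partitions trivial -> identical
    return max(0.0, min(1.0, mi / mean_h))


def purity(clusters: Sequence[Hashable], reference: Sequence[Hashable]) -> float:
    """Fraction of items falling in the majority reference label of their
    cluster. The second argument is the reference labeling."""
    table = _contingency(clusters, reference)
    return float(table.max(axis=1).sum() / table.sum())


@dataclass(frozen=True)
class ConcordanceScores:
    adjusted_rand: float
    jaccard: float
    nmi: float
    purity: float


def concordance(
    clusters: Sequence[Hashable], reference: Sequence[Hashable]
) -> ConcordanceScores:
    """All four metrics for one (clustering, reference-labeling) pair."""
    return ConcordanceScores(
        adjusted_rand=adjusted_rand_index(clusters, reference),
        jaccard=jaccard_index(clusters, reference),
        nmi=normalized_mutual_information(clusters, reference),
        purity=purity(clusters, reference),
    )
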