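"""Gene-phenotype matrix, embedding/clustering, and concordance metrics."""

import itertools
import math
import random

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from genepheno.association import AssociationRecord, npmi
from genepheno.profiles import (adjusted_rand_index, build_matrix, concordance,
                                embed_2d, jaccard_index, kmeans_cluster,
                                label_by_top_category,
                                normalized_mutual_information, purity)
from genepheno.standardize import StandardizedPhenotype


def record(gene, cid, value, n_gp=10, category="NA"):
    return AssociationRecord(
        gene=gene,
        phenotype=StandardizedPhenotype(concept_id=cid, preferred_name=cid,
                                        source="HPO", hpo_id="HP:1",
                                        top_level_category=category),
        n_G=20, n_P=20, n_GP=n_gp, n_tot=1000, npmi=value,
    )


class TestBuildMatrix:
    def test_positive_npmi_sets_one(self):
        mat = build_matrix([record("G1", "P1", 0.4), record("G2", "P2", -0.1)])
        assert mat.loc["G1", "P1"] == 1
        assert mat.to_numpy().sum() == 1

    def test_zero_npmi_is_zero_entry(self):
        mat = build_matrix([record("G1", "P1", 0.0)])
        assert mat.loc["G1", "P1"] == 0

    def test_row_sums_count_positive_records(self):
        recs = [record(f"G{i}", f"P{i}", v)
                for i, v in enumerate([0.5, 0.2, -0.3, 0.0, 0.7])]
        assert build_matrix(recs).to_numpy().sum() == 3

    def test_order_independence(self):
        recs = [record("G2", "P1", 0.4), record("G1", "P2", 0.6)]
        assert build_matrix(recs).equals(build_matrix(list(reversed(recs))))


class TestLabelByTopCategory:
    def test_top_phenotype_category_wins(self):
        labels = label_by_top_category([
            record("G1", "P1", 0.9, category="Neoplasm"),
            record("G1", "P2", 0.5, category="Growth abnormality"),
        ])
        assert labels == {"G1": "Neoplasm"}

    def test_gene_with_na_top_phenotype_dropped(self):
        labels = label_by_top_category([
            record("G1", "P1", 0.9, category="NA"),
            record("G1", "P2", 0.5, category="Neoplasm"),
        ])
        assert labels == {}

    def test_tie_follows_ranking_rule(self):
        labels = label_by_top_category([
            record("G1", "P2", 0.5, n_gp=10, category="Neoplasm"),
            record("G1", "P1", 0.5, n_gp=20, category="Growth abnormality"),
        ])
        assert labels == {"G1": "Growth abnormality"}


@pytest.fixture(scope="module")
def block_matrix():
    recs = []
    for i in range(5):                           # block 1: phenotypes P0-P4
        for j in range(5):
            recs.append(record(f"A{i}", f"P{j}", 0.5))
    for i in range(5):                           # block 2: phenotypes Q0-Q4
        for j in range(5):
            recs.append(record(f"B{i}", f"Q{j}", 0.5))
    return build_matrix(recs)


class TestEmbedAndCluster:
    def test_same_seed_same_coordinates(self, block_matrix):
        c1 = embed_2d(block_matrix, seed=3, perplexity=3)
        c2 = embed_2d(block_matrix, seed=3, perplexity=3)
        assert np.array_equal(c1.to_numpy(), c2.to_numpy())

    def test_block_structure_preserved(self, block_matrix):
        coords = embed_2d(block_matrix, seed=3, perplexity=3)
        a = coords.loc[[f"A{i}" for i in range(5)]].to_numpy()
        b = coords.loc[[f"B{i}" for i in range(5)]].to_numpy()
        intra = max(np.linalg.norm(x - y) for x in a for y in a)
        inter = min(np.linalg.norm(x - y) for x in a for y in b)
        assert inter > intra

    def test_too_few_genes_fatal(self):
        with pytest.raises(ValueError, match=">= 3 genes"):
            embed_2d(build_matrix([record("G1", "P1", 0.5), record("G2", "P1", 0.5)]))

    def test_kmeans_recovers_separated_blobs(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        coords = pd.DataFrame(pts, index=[f"g{i}" for i in range(20)],
                              columns=["tsne1", "tsne2"])
        labels = kmeans_cluster(coords, k=2, seed=1)
        first = {labels[f"g{i}"] for i in range(10)}
        second = {labels[f"g{i}"] for i in range(10, 20)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_k_equals_n_gives_singletons(self):
        import pandas as pd
        coords = pd.DataFrame([[0, 0], [1, 1], [2, 2], [3, 3]],
                              index=list("abcd"), columns=["tsne1", "tsne2"])
        labels = kmeans_cluster(coords, k=4, seed=0)
        assert len(set(labels.values())) == 4

    def test_invalid_k_fatal(self):
        import pandas as pd
        coords = pd.DataFrame([[0, 0], [1, 1]], index=["a", "b"],
                              columns=["tsne1", "tsne2"])
        with pytest.raises(ValueError):
            kmeans_cluster(coords, k=5, seed=0)


# ---------------------------------------------------------------------------
# Concordance metrics against a brute-force pair-enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_metrics(a, b):
    """Pair enumeration + contingency arithmetic, independent of the package."""
    n = len(a)
    s11 = s10 = s01 = s00 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        s11 += same_a and same_b
        s10 += same_a and not same_b
        s01 += same_b and not same_a
        s00 += not same_a and not same_b
    total = s11 + s10 + s01 + s00
    exp = (s11 + s10) * (s11 + s01) / total if total else 0.0
    mx = ((s11 + s10) + (s11 + s01)) / 2.0
    ari = 1.0 if mx == exp else (s11 - exp) / (mx - exp)
    jac = s11 / (s11 + s10 + s01) if (s11 + s10 + s01) else 1.0
    # NMI from explicit joint distribution
    from collections import Counter
    pa = {k: v / n for k, v in Counter(a).items()}
    pb = {k: v / n for k, v in Counter(b).items()}
    pab = {k: v / n for k, v in Counter(zip(a, b)).items()}
    mi = sum(p * math.log(p / (pa[x] * pb[y])) for (x, y), p in pab.items())
    ha = -sum(p * math.log(p) for p in pa.values())
    hb = -sum(p * math.log(p) for p in pb.values())
    nmi_val = 1.0 if ha + hb == 0 else mi / ((ha + hb) / 2)
    # purity: majority reference label per cluster
    pur = sum(Counter(y for x, y in zip(a, b) if x == c).most_common(1)[0][1]
              for c in set(a)) / n
    return ari, jac, max(0.0, min(1.0, nmi_val)), pur


def random_partitions(seed, n, ka, kb):
    rng = random.Random(seed)
    return ([rng.randrange(ka) for _ in range(n)],
            [rng.randrange(kb) for _ in range(n)])


class TestConcordanceMetrics:
    def test_identical_partitions_score_one_on_all_metrics(self):
        a = ["x", "x", "y", "z", "z", "y"]
        scores = concordance(a, list(a))
        assert scores.adjusted_rand == scores.jaccard == scores.nmi == scores.purity == 1.0

    def test_purity_worked_example(self):
        # cluster x: 1 item, majority 1; cluster y: labels y,y,y -> 2+1? no:
        # a=[A,A,B,B], b=[x,y,y,y]: cluster A majority count 1, cluster B count 2
        assert purity(["A", "A", "B", "B"], ["x", "y", "y", "y"]) == 0.75

    @pytest.mark.parametrize("seed,n,ka,kb", [
        (0, 8, 2, 2), (1, 12, 3, 2), (2, 20, 4, 5), (3, 30, 5, 3),
        (4, 30, 2, 7), (5, 17, 3, 3),
    ])
    def test_all_metrics_match_pair_enumeration_oracle(self, seed, n, ka, kb):
        a, b = random_partitions(seed, n, ka, kb)
        ari, jac, nmi_val, pur = brute_force_metrics(a, b)
        assert adjusted_rand_index(a, b) == pytest.approx(ari, abs=1e-12)
        assert jaccard_index(a, b) == pytest.approx(jac, abs=1e-12)
        assert normalized_mutual_information(a, b) == pytest.approx(nmi_val, abs=1e-10)
        assert purity(a, b) == pytest.approx(pur, abs=1e-12)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_ari_and_nmi_agree_with_sklearn(self, seed):
        a, b = random_partitions(seed, 25, 3, 4)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-10)
        assert normalized_mutual_information(a, b) == pytest.approx(
            normalized_mutual_info_score(a, b, average_method="arithmetic"), abs=1e-10)

    def test_relabeling_invariance(self):
        a, b = random_partitions(7, 20, 3, 3)
        remap = {0: 7, 1: 5, 2: 9}
        a2 = [remap[x] for x in a]
        assert purity(a, b) == purity(a2, b)
        assert normalized_mutual_information(a, b) == pytest.approx(
            normalized_mutual_information(a2, b), abs=1e-12)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(a2, b), abs=1e-12)

    def test_ari_near_zero_for_random_labels(self):
        values = []
        for seed in range(100):
            rng = random.Random(seed)
            structure = [i // 10 for i in range(50)]
            noise = [rng.randrange(5) for _ in range(50)]
            values.append(adjusted_rand_index(noise, structure))
        assert abs(sum(values) / len(values)) < 0.1

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            purity([1, 2], [1, 2, 3])
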