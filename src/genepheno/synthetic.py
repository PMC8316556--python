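"""Synthetic corpora and miniature vocabularies with planted ground truth.

The generator emulates the pipeline's real inputs at desk scale: a
JATS-style XML corpus in which gene symbols and phenotype terms are planted
per sentence with controlled probabilities, plus format-valid miniature
concept/semantic-type files (RRF dialect), an ASDPTO flat term list, a
minimal HPO is-a hierarchy and a gene list. Because planting probabilities
are known, every downstream quantity has an analytic expectation: expected
sentence counts are binomial and the NPMI of a planted pair follows from
its joint and marginal probabilities, so estimator convergence can be
checked without any licensed vocabulary or real articles.

Planting model: each body sentence is an independent trial. For each
(gene, phenotype) pair with a configured joint probability, one uniform
draw couples the pair so that P(both) = p_joint while marginals stay at
their configured values; unpaired genes and phenotypes are independent
Bernoulli draws. Sentences then render every present entity; sentences with
no entities become filler prose free of lexicon terms. Articles carry an
empty title, so the number of corpus sentences equals the number of planted
slots exactly.

All randomness flows from the spec's single seed; no global random state is
touched.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from lxml import etree

__all__ = ["PlantedGene", "PlantedPhenotype", "PlantingSpec", "GroundTruth",
           "generate_vocabulary", "generate_corpus", "analytic_npmi",
           "expected_counts"]


@dataclass(frozen=True)
class PlantedGene:
    symbol: str
    risk_class: str = "NA"
    prob: float = 0.05


@dataclass(frozen=True)
class PlantedPhenotype:
    concept_id: str
    prob: float = 0.05


# Miniature vocabulary catalogue. Each entry: concept id, the sources it
# appears in, its term strings (first = preferred), semantic types, HPO id.
# Covers one synonym set, one multi-source concept (HPO+MSH priority check),
# one multi-word term, ASDPTO and non-HPO concepts (category "NA").
_CATALOGUE: dict[str, dict] = {
    "C0036572": {  # multi-source concept: HPO wins priority over MSH
        "sources": ("HPO", "MSH"),
        "terms": ("Seizure", "Seizures", "Epileptic seizure"),
        "types": ("T184",),
        "hpo_id": "HP:0001250",
    },
    "C0004352": {
        "sources": ("HPO",),
        "terms": ("Autism", "Autistic disorder"),
        "types": ("T048",),
        "hpo_id": "HP:0000717",
    },
    "C0006142": {  # multi-word terms, MSH only -> top-level category "NA"
        "sources": ("MSH",),
        "terms": ("Breast cancer", "Breast carcinoma", "Malignant neoplasm of breast"),
        "types": ("T047",),
        "hpo_id": None,
    },
    "ASDPTO:0815": {
        "sources": ("ASDPTO",),
        "terms": ("Language impairment", "Language disorder"),
        "types": (),
        "hpo_id": None,
    },
    "C0026850": {
        "sources": ("OMIM",),
        "terms": ("Muscular dystrophy", "Muscular dystrophies"),
        "types": ("T047",),
        "hpo_id": None,
    },
    "C0028754": {
        "sources": ("HPO",),
        "terms": ("Obesity", "Having too much body fat"),
        "types": ("T047",),
        "hpo_id": "HP:0001513",
    },
}

# Vocabulary-only extras exercising the filters; never planted in sentences.
_EXTRAS: dict[str, dict] = {
    "C0006826": {  # matched by noise-mode distractors ("National Cancer Center")
        "sources": ("MSH",),
        "terms": ("Cancer", "Cancers"),
        "types": ("T047",),
        "hpo_id": None,
    },
    "C0205191": {  # SNOMED concept with a temporal type only -> filtered out
        "sources": ("SNOMEDCT_US",),
        "terms": ("Chronicity",),
        "types": ("T079",),
        "hpo_id": None,
    },
    "C9000001": {  # HPO concept with an excluded type -> filtered out
        "sources": ("HPO",),
        "terms": ("Inheritance modifier",),
        "types": ("T045",),
        "hpo_id": "HP:9000001",
    },
}

_MINI_HPO_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0002664
name: Neoplasm
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001507
name: Growth abnormality
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0012638
name: Abnormal nervous system physiology
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0000708
name: Behavioral abnormality
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0001250
name: Seizure
is_a: HP:0012638 ! Abnormal nervous system physiology

[Term]
id: HP:0000717
name: Autism
is_a: HP:0000708 ! Behavioral abnormality

[Term]
id: HP:0004323
name: Abnormality of body weight
is_a: HP:0001507 ! Growth abnormality

[Term]
id: HP:0001513
name: Obesity
is_a: HP:0004323 ! Abnormality of body weight
"""

_FILLERS = (
    "The protocol was approved by the institutional review board.",
    "Participants provided written informed consent before enrollment.",
    "Statistical analyses were performed with standard software.",
    "Samples were stored at low temperature until processing.",
    "The authors declare no competing interests.",
)

_DISTRACTORS = (
    "The National Cancer Center released updated screening guidelines.",
    "Funding was provided by the National Cancer Center research program.",
)


@dataclass
class PlantingSpec:
    """Study conditions for one synthetic corpus.

    Defaults give a 5,000-sentence corpus (50 articles of 100 sentences)
    with per-sentence mention probabilities of a few percent — the order of
    magnitude at which prominent genes and phenotypes recur in a focused
    literature corpus — and four coupled gene-phenotype pairs spanning
    strong to weak dependence.
    """

    n_articles: int = 50
    sentences_per_article: int = 100
    genes: tuple[PlantedGene, ...] = (
        PlantedGene("MECP2", "1", 0.06),
        PlantedGene("FMR1", "1", 0.05),
        PlantedGene("CNTNAP2", "2", 0.04),
        PlantedGene("DRD2", "3", 0.03),
        PlantedGene("BRCA2", "3", 0.03),
        PlantedGene("CACNA1A", "S", 0.02),
        PlantedGene("TP53", "NA", 0.02),
    )
    phenotypes: tuple[PlantedPhenotype, ...] = (
        PlantedPhenotype("C0036572", 0.05),   # seizure
        PlantedPhenotype("C0004352", 0.06),   # autism
        PlantedPhenotype("C0006142", 0.03),   # breast cancer
        PlantedPhenotype("ASDPTO:0815", 0.03),  # language impairment
        PlantedPhenotype("C0026850", 0.02),   # muscular dystrophy
        PlantedPhenotype("C0028754", 0.02),   # obesity
    )
    joint_boost: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("MECP2", "C0036572"): 0.030,
        ("BRCA2", "C0006142"): 0.015,
        ("CNTNAP2", "ASDPTO:0815"): 0.012,
        ("DRD2", "C0028754"): 0.008,
    })
    seed: int = 0
    noise: bool = False

    def __post_init__(self) -> None:
        gene_p = {g.symbol: g.prob for g in self.genes}
        phen_p = {p.concept_id: p.prob for p in self.phenotypes}
        for prob in list(gene_p.values()) + list(phen_p.values()):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        seen_g: set[str] = set()
        seen_p: set[str] = set()
        for (g, p), pj in self.joint_boost.items():
            if g not in gene_p or p not in phen_p:
                raise ValueError(f"joint_boost pair ({g}, {p}) not planted")
            if g in seen_g or p in seen_p:
                raise ValueError("each entity may appear in at most one joint pair")
            seen_g.add(g)
            seen_p.add(p)
            if pj > min(gene_p[g], phen_p[p]) or gene_p[g] + phen_p[p] - pj > 1.0:
                raise ValueError(f"infeasible joint probability for ({g}, {p})")
        for p in self.phenotypes:
            if p.concept_id not in _CATALOGUE:
                raise ValueError(f"unknown phenotype concept {p.concept_id}")

    @property
    def n_sentences(self) -> int:
        return self.n_articles * self.sentences_per_article

    def gene_prob(self, symbol: str) -> float:
        return next(g.prob for g in self.genes if g.symbol == symbol)

    def phen_prob(self, concept_id: str) -> float:
        return next(p.prob for p in self.phenotypes if p.concept_id == concept_id)

    def joint_prob(self, symbol: str, concept_id: str) -> float:
        if (symbol, concept_id) in self.joint_boost:
            return self.joint_boost[(symbol, concept_id)]
        return self.gene_prob(symbol) * self.phen_prob(concept_id)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlantingSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        kwargs = dict(raw)
        if "genes" in kwargs:
            kwargs["genes"] = tuple(PlantedGene(**g) for g in kwargs["genes"])
        if "phenotypes" in kwargs:
            kwargs["phenotypes"] = tuple(PlantedPhenotype(**p) for p in kwargs["phenotypes"])
        if "joint_boost" in kwargs:
            kwargs["joint_boost"] = {
                (d["gene"], d["phenotype"]): d["prob"] for d in kwargs["joint_boost"]
            }
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PlantingSpec":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Vocabulary generation
# ---------------------------------------------------------------------------

def _rrf_row(cui: str, lang: str, sab: str, code: str, term: str,
             preferred: bool) -> str:
    fields = [""] * 16
    fields[0] = cui
    fields[1] = lang
    fields[6] = "Y" if preferred else "N"
    fields[11] = sab
    fields[12] = "PT" if preferred else "SY"
    fields[13] = code
    fields[14] = term
    return "|".join(fields)


def generate_vocabulary(spec: PlantingSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the miniature vocabulary files for *spec* into *out_dir*.

    Returns the paths keyed by role: concepts, semtypes, asdpto, hpo, genes.
    With no planted phenotypes the concept files are valid but empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    planted = [p.concept_id for p in spec.phenotypes]
    entries: dict[str, dict] = {cid: _CATALOGUE[cid] for cid in planted}
    if planted:
        entries.update(_EXTRAS)

    conso_lines: list[str] = []
    sty_lines: list[str] = []
    asdpto_lines: list[str] = []
    for cid in sorted(entries):
        entry = entries[cid]
        if "ASDPTO" in entry["sources"]:
            terms = entry["terms"]
            asdpto_lines.append(f"{cid}\t{terms[0]}\t{'|'.join(terms[1:])}")
            continue
        for sab in entry["sources"]:
            code = entry["hpo_id"] if (sab == "HPO" and entry["hpo_id"]) else cid
            for i, term in enumerate(entry["terms"]):
                conso_lines.append(_rrf_row(cid, "ENG", sab, code, term, i == 0))
        for tui in entry["types"]:
            sty_lines.append(f"{cid}|{tui}|")
    if planted:
        # one non-English row: exercises the language filter silently
        conso_lines.append(_rrf_row("C0036572", "FRE", "MSH", "C0036572",
                                    "Crise epileptique", False))

    paths = {
        "concepts": out_dir / "concepts.rrf",
        "semtypes": out_dir / "semtypes.rrf",
        "asdpto": out_dir / "asdpto.tsv",
        "hpo": out_dir / "hpo_mini.obo",
        "genes": out_dir / "genes.tsv",
    }
    paths["concepts"].write_text("\n".join(conso_lines) + ("\n" if conso_lines else ""), "utf-8")
    paths["semtypes"].write_text("\n".join(sty_lines) + ("\n" if sty_lines else ""), "utf-8")
    paths["asdpto"].write_text("\n".join(asdpto_lines) + ("\n" if asdpto_lines else ""), "utf-8")
    paths["hpo"].write_text(_MINI_HPO_OBO, "utf-8")
    paths["genes"].write_text(
        "".join(f"{g.symbol}\t{g.risk_class}\n" for g in spec.genes), "utf-8"
    )
    return paths


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted mentions and count tables for one generated corpus."""

    spec: PlantingSpec
    per_sentence: dict[tuple[str, int], tuple[frozenset[str], frozenset[str]]]
    n_tot: int
    n_G: dict[str, int]
    n_P: dict[str, int]
    n_GP: dict[tuple[str, str], int]

    @property
    def target_sentences(self) -> set[tuple[str, int]]:
        return {k for k, (g, p) in self.per_sentence.items() if g and p}

    def write_gold_jsonl(self, path: str | Path) -> None:
        """Gold standard over target sentences (the association context):
        gene/phenotype mention lists cover sentences containing both."""
        by_article: dict[str, dict] = {}
        for (aid, idx), (genes, phens) in sorted(self.per_sentence.items()):
            rec = by_article.setdefault(
                aid, {"article_id": aid, "genes": [], "phenotypes": [],
                      "target_sentences": []}
            )
            if genes and phens:
                rec["genes"].extend([idx, g] for g in sorted(genes))
                rec["phenotypes"].extend([idx, p] for p in sorted(phens))
                rec["target_sentences"].append(idx)
        with Path(path).open("w", encoding="utf-8") as fh:
            for aid in sorted(by_article):
                fh.write(json.dumps(by_article[aid]) + "\n")


def _render_sentence(rng: random.Random, genes: list[str], phens: list[str]) -> str:
    def join(words: list[str]) -> str:
        return words[0] if len(words) == 1 else ", ".join(words[:-1]) + " and " + words[-1]

    phen_terms = [rng.choice(sorted(_CATALOGUE[c]["terms"])).lower() for c in phens]
    if genes and phens:
        return (f"In this cohort, {join(sorted(genes))} was associated with "
                f"{join(phen_terms)} in affected individuals.")
    if genes:
        return f"Expression of {join(sorted(genes))} was measured across the cohort."
    return f"Several participants presented with {join(phen_terms)} during follow-up."


def _draw_presence(
    rng: random.Random, spec: PlantingSpec
) -> tuple[set[str], set[str]]:
    genes: set[str] = set()
    phens: set[str] = set()
    paired_g = {g for g, _ in spec.joint_boost}
    paired_p = {p for _, p in spec.joint_boost}
    for (g, p) in sorted(spec.joint_boost):
        pj = spec.joint_boost[(g, p)]
        pg, pp = spec.gene_prob(g), spec.phen_prob(p)
        u = rng.random()
        if u < pj:
            genes.add(g)
            phens.add(p)
        elif u < pg:
            genes.add(g)
        elif u < pg + pp - pj:
            phens.add(p)
    for g in spec.genes:
        if g.symbol not in paired_g and rng.random() < g.prob:
            genes.add(g.symbol)
    for p in spec.phenotypes:
        if p.concept_id not in paired_p and rng.random() < p.prob:
            phens.add(p.concept_id)
    return genes, phens


def generate_corpus(spec: PlantingSpec, out_dir: str | Path) -> GroundTruth:
    """Write the XML corpus for *spec* and return its ground truth.

    One article per file (``A0001.xml`` ...), one sentence per body
    paragraph, empty titles — so sentence indices and the total sentence
    count seen by the reader match the planted slots exactly. Reproducible:
    the same spec (including seed) yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    per_sentence: dict[tuple[str, int], tuple[frozenset[str], frozenset[str]]] = {}
    n_G: dict[str, int] = {}
    n_P: dict[str, int] = {}
    n_GP: dict[tuple[str, str], int] = {}
    filler_cycle = 0

    for a in range(spec.n_articles):
        aid = f"A{a + 1:04d}"
        root = etree.Element("article")
        front = etree.SubElement(root, "front")
        meta = etree.SubElement(front, "article-meta")
        etree.SubElement(meta, "article-id").text = aid
        tg = etree.SubElement(meta, "title-group")
        etree.SubElement(tg, "article-title")  # empty on purpose
        body = etree.SubElement(root, "body")
        for idx in range(spec.sentences_per_article):
            genes, phens = _draw_presence(rng, spec)
            if genes or phens:
                text = _render_sentence(rng, sorted(genes), sorted(phens))
            elif spec.noise and rng.random() < 0.05:
                text = _DISTRACTORS[filler_cycle % len(_DISTRACTORS)]
                filler_cycle += 1
            else:
                text = _FILLERS[filler_cycle % len(_FILLERS)]
                filler_cycle += 1
            etree.SubElement(body, "p").text = text
            per_sentence[(aid, idx)] = (frozenset(genes), frozenset(phens))
            for g in genes:
                n_G[g] = n_G.get(g, 0) + 1
            for p in phens:
                n_P[p] = n_P.get(p, 0) + 1
            for g in genes:
                for p in phens:
                    n_GP[(g, p)] = n_GP.get((g, p), 0) + 1
        (out_dir / f"{aid}.xml").write_bytes(
            etree.tostring(root, pretty_print=True, xml_declaration=True,
                           encoding="UTF-8")
        )
    return GroundTruth(spec=spec, per_sentence=per_sentence,
                       n_tot=spec.n_sentences, n_G=n_G, n_P=n_P, n_GP=n_GP)


# ---------------------------------------------------------------------------
# Analytic expectations
# ---------------------------------------------------------------------------

def analytic_npmi(spec: PlantingSpec, pair: tuple[str, str]) -> float:
    """NPMI of the planted joint/marginal probabilities for *pair*.

    Zero joint probability returns -1 by the limit convention; joint
    probability 1 returns 1.
    """
    g, p = pair
    pj = spec.joint_prob(g, p)
    if pj == 0.0:
        return -1.0
    if pj == 1.0:
        return 1.0
    pg, pp = spec.gene_prob(g), spec.phen_prob(p)
    return max(-1.0, min(1.0, math.log(pj / (pg * pp)) / (-math.log(pj))))


def expected_counts(spec: PlantingSpec) -> dict:
    """Binomial expectations and standard deviations for every count."""
    n = spec.n_sentences

    def stats(prob: float) -> dict[str, float]:
        return {"mean": n * prob, "sd": math.sqrt(n * prob * (1.0 - prob))}

    return {
        "n_tot": n,
        "genes": {g.symbol: stats(g.prob) for g in spec.genes},
        "phenotypes": {p.concept_id: stats(p.prob) for p in spec.phenotypes},
        "pairs": {
            f"{g}|{p}": stats(spec.joint_prob(g, p))
            for g in (x.symbol for x in spec.genes)
            for p in (y.concept_id for y in spec.phenotypes)
        },
    }
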