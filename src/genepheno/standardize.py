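"""Phenotype standardization and top-level category assignment.

A phenotype mention may match synonyms from several source vocabularies.
Standardization resolves each mention to one concept by source priority —
HPO first, then ASDPTO, OMIM, DDB, SNOMED-CT (US) and MSH — and reports the
concept's preferred name. Concepts carrying an HPO id are further assigned
one of the 23 top-level phenotypic categories, the children of "Phenotypic
abnormality" in the HPO is-a hierarchy; concepts outside HPO (or unreachable
from any category root) get category "NA".
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .lexicon import PhenotypeConcept, PhenotypeLexicon
from .mentions import TargetSentence, extract_pairs

logger = logging.getLogger(__name__)

__all__ = ["TOP_LEVEL_CATEGORIES", "DEFAULT_CATEGORY_ROOTS", "CategoryTable",
           "HpoHierarchy", "StandardizedPhenotype", "resolve_candidates",
           "standardize_mention", "top_level_category", "standardize_corpus",
           "StandardizedPair"]

#: The 23 top-level phenotypic categories (children of Phenotypic abnormality).
TOP_LEVEL_CATEGORIES: tuple[str, ...] = (
    "Abnormal cellular phenotype",
    "Abnormality of blood and blood-forming tissues",
    "Abnormality of head or neck",
    "Abnormality of limbs",
    "Abnormality of metabolism/homeostasis",
    "Abnormality of prenatal development or birth",
    "Abnormality of the breast",
    "Abnormality of the cardiovascular system",
    "Abnormality of the digestive system",
    "Abnormality of the ear",
    "Abnormality of the endocrine system",
    "Abnormality of the eye",
    "Abnormality of the genitourinary system",
    "Abnormality of the immune system",
    "Abnormality of the integument",
    "Abnormality of the musculoskeletal system",
    "Abnormality of the nervous system",
    "Abnormality of the respiratory system",
    "Abnormality of the thoracic cavity",
    "Abnormality of the voice",
    "Constitutional symptom",
    "Growth abnormality",
    "Neoplasm",
)

#: Category roots by HPO id (the ids of the category terms in the released
#: ontology). Roots are configured by id, not by label matching, so label
#: edits in ontology releases do not break the mapping.
DEFAULT_CATEGORY_ROOTS: dict[str, str] = {
    "Abnormal cellular phenotype": "HP:0025354",
    "Abnormality of blood and blood-forming tissues": "HP:0001871",
    "Abnormality of head or neck": "HP:0000152",
    "Abnormality of limbs": "HP:0040064",
    "Abnormality of metabolism/homeostasis": "HP:0001939",
    "Abnormality of prenatal development or birth": "HP:0001197",
    "Abnormality of the breast": "HP:0000769",
    "Abnormality of the cardiovascular system": "HP:0001626",
    "Abnormality of the digestive system": "HP:0025031",
    "Abnormality of the ear": "HP:0000598",
    "Abnormality of the endocrine system": "HP:0000818",
    "Abnormality of the eye": "HP:0000478",
    "Abnormality of the genitourinary system": "HP:0000119",
    "Abnormality of the immune system": "HP:0002715",
    "Abnormality of the integument": "HP:0001574",
    "Abnormality of the musculoskeletal system": "HP:0033127",
    "Abnormality of the nervous system": "HP:0000707",
    "Abnormality of the respiratory system": "HP:0002086",
    "Abnormality of the thoracic cavity": "HP:0045027",
    "Abnormality of the voice": "HP:0001608",
    "Constitutional symptom": "HP:0025142",
    "Growth abnormality": "HP:0001507",
    "Neoplasm": "HP:0002664",
}


@dataclass(frozen=True)
class CategoryTable:
    """Ordered category names plus category-root HPO ids."""

    names: tuple[str, ...] = TOP_LEVEL_CATEGORIES
    hpo_roots: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_ROOTS))

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("category names must be unique")
        missing = [n for n in self.names if n not in self.hpo_roots]
        if missing:
            raise ValueError(f"categories without HPO roots: {missing}")

    def root_to_category(self) -> dict[str, str]:
        return {self.hpo_roots[name]: name for name in self.names}


class HpoHierarchy:
    """A minimal is-a DAG over HPO term ids.

    Built either programmatically from (child, parent) edges or from an
    OBO-like flat file containing ``[Term]`` stanzas with ``id:``, ``name:``
    and ``is_a:`` lines (other lines are ignored).
    """

    def __init__(self) -> None:
        self.parents: dict[str, set[str]] = {}
        self.names: dict[str, str] = {}

    def add_node(self, node: str, name: str = "") -> None:
        self.parents.setdefault(node, set())
        if name:
            self.names[node] = name

    def add_edge(self, child: str, parent: str) -> None:
        self.add_node(child)
        self.add_node(parent)
        self.parents[child].add(parent)

    def __contains__(self, node: str) -> bool:
        return node in self.parents

    def ancestors(self, node: str) -> set[str]:
        """All is-a ancestors of *node* (excluding itself)."""
        seen: set[str] = set()
        stack = list(self.parents.get(node, ()))
        while stack:
            cur = stack.pop()
            if cur in seen:
                continue
            seen.add(cur)
            stack.extend(self.parents.get(cur, ()))
        return seen

    @classmethod
    def from_obo(cls, path: str | Path) -> "HpoHierarchy":
        hier = cls()
        cur_id: str | None = None
        for raw in Path(path).read_text("utf-8").splitlines():
            line = raw.strip()
            if line == "[Term]":
                cur_id = None
            elif line.startswith("id:"):
                cur_id = line[3:].strip()
                hier.add_node(cur_id)
            elif line.startswith("name:") and cur_id:
                hier.names[cur_id] = line[5:].strip()
            elif line.startswith("is_a:") and cur_id:
                parent = line[5:].strip().split("!")[0].strip()
                hier.add_edge(cur_id, parent)
        return hier


@dataclass(frozen=True)
class StandardizedPhenotype:
    concept_id: str
    preferred_name: str
    source: str
    hpo_id: str | None = None
    top_level_category: str = "NA"

    @property
    def key(self) -> tuple[str, str]:
        return (self.concept_id, self.source)


def resolve_candidates(candidates: list[PhenotypeConcept]) -> PhenotypeConcept:
    """Pick the winning concept: best (lowest) source priority rank, ties by
    concept id. Total order, so invariant under input permutation."""
    if not candidates:
        raise ValueError("mention with no candidate concepts")
    return min(candidates, key=lambda c: (c.priority_rank, c.concept_id))


def top_level_category(
    hpo_id: str | None,
    hierarchy: HpoHierarchy,
    table: CategoryTable | None = None,
) -> str:
    """Category of the nearest category root above *hpo_id*, else "NA".

    Breadth-first traversal over is-a parents; the first depth at which any
    category root appears wins, ties broken by the table's category order.
    """
    table = table or CategoryTable()
    if not hpo_id:
        return "NA"
    if hpo_id not in hierarchy:
        logger.warning("unknown HPO id %s, category NA", hpo_id)
        return "NA"
    roots = table.root_to_category()
    order = {name: i for i, name in enumerate(table.names)}
    frontier = deque([hpo_id])
    seen = {hpo_id}
    while frontier:
        hits = [roots[n] for n in frontier if n in roots]
        if hits:
            return min(hits, key=order.__getitem__)
        nxt: deque[str] = deque()
        for node in frontier:
            for parent in sorted(hierarchy.parents.get(node, ())):
                if parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return "NA"


def standardize_mention(
    candidates: list[PhenotypeConcept],
    hierarchy: HpoHierarchy | None = None,
    table: CategoryTable | None = None,
) -> StandardizedPhenotype:
    """Resolve a mention's candidate set to one standardized phenotype."""
    winner = resolve_candidates(candidates)
    category = "NA"
    if winner.hpo_id and hierarchy is not None:
        category = top_level_category(winner.hpo_id, hierarchy, table)
    return StandardizedPhenotype(
        concept_id=winner.concept_id,
        preferred_name=winner.preferred_name,
        source=winner.source,
        hpo_id=winner.hpo_id,
        top_level_category=category,
    )


@dataclass(frozen=True)
class StandardizedPair:
    """One gene-phenotype co-mention from one target sentence."""

    article_id: str
    sentence_index: int
    gene: str
    phenotype: StandardizedPhenotype


def standardize_corpus(
    target_sentences: list[TargetSentence],
    lexicon: PhenotypeLexicon,
    hierarchy: HpoHierarchy | None = None,
    table: CategoryTable | None = None,
) -> list[StandardizedPair]:
    """Replace every phenotype mention with its standardized concept.

    Returns the sentence-level (gene, standardized phenotype) pair table the
    association module counts from.
    """
    cache: dict[tuple[str, ...], StandardizedPhenotype] = {}
    pairs: list[StandardizedPair] = []
    for target in target_sentences:
        for gene, mention in extract_pairs(target):
            ref = mention.lexicon_ref
            if ref not in cache:
                cands = [lexicon.concepts[tuple(r.split("|"))] for r in ref]
                cache[ref] = standardize_mention(cands, hierarchy, table)
            pairs.append(
                StandardizedPair(
                    article_id=target.sentence.article_id,
                    sentence_index=target.sentence.index,
                    gene=gene,
                    phenotype=cache[ref],
                )
            )
    return pairs
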