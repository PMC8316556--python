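"""Phenotype and gene lexicon construction.

The phenotype lexicon is built from UMLS-style RRF files by two-layer
filtering: first by source vocabulary (HPO, OMIM, DDB, SNOMED-CT US, MSH),
then by semantic type. Concepts from the non-HPO sources are kept only if
they carry at least one of the disease/symptom semantic types (by default
T047 Disease or Syndrome, T048 Mental or Behavioral Dysfunction, T184 Sign
or Symptom). HPO concepts are kept unless they carry one of a configurable
exclusion set of non-phenotype types (temporal, qualitative, spatial,
functional concepts and the like). ASDPTO terms arrive from a flat TSV term
list and bypass the semantic-type layer, since that vocabulary is
phenotype-only by construction.

Gene symbols come from a TSV of (symbol, risk class) rows, where the risk
class is a SFARI-style confidence tier: 1 (high confidence), 2 (strong
candidate), 3 (suggestive evidence), S (syndromic) or NA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "SOURCE_PRIORITY",
    "RRFColumns",
    "SemanticTypeFilter",
    "PhenotypeConcept",
    "GeneEntry",
    "PhenotypeLexicon",
    "GeneLexicon",
    "parse_concept_file",
    "parse_semantic_types",
    "parse_asdpto_terms",
    "build_phenotype_lexicon",
    "load_gene_list",
]

#: Source vocabularies in descending standardization priority (1 = highest).
SOURCE_PRIORITY: dict[str, int] = {
    "HPO": 1,
    "ASDPTO": 2,
    "OMIM": 3,
    "DDB": 4,
    "SNOMEDCT_US": 5,
    "MSH": 6,
}

#: RRF source vocabularies admitted by the first filtering layer.
RRF_SOURCES = frozenset({"HPO", "OMIM", "DDB", "SNOMEDCT_US", "MSH"})

VALID_RISK_CLASSES = frozenset({"1", "2", "3", "S", "NA"})


@dataclass(frozen=True)
class RRFColumns:
    """Column indices into pipe-delimited RRF rows.

    Defaults follow the public MRCONSO.RRF layout (CUI|LAT|TS|LUI|STT|SUI|
    ISPREF|AUI|SAUI|SCUI|SDUI|SAB|TTY|CODE|STR|...). Miniature fixtures may
    use compact layouts by overriding the indices.
    """

    cui: int = 0
    language: int = 1
    ispref: int = 6
    sab: int = 11
    code: int = 13
    string: int = 14
    # MRSTY.RRF: CUI|TUI|...
    sty_cui: int = 0
    sty_tui: int = 1


@dataclass(frozen=True)
class SemanticTypeFilter:
    """Second-layer semantic-type filter.

    ``include_codes`` applies to the non-HPO sources (a concept must carry at
    least one). ``hpo_exclude_codes`` applies to HPO (a concept must carry
    none). The HPO exclusion list is open-ended in practice; the default is
    the six commonly excluded non-phenotype types and further codes are
    user-supplied configuration.
    """

    include_codes: frozenset[str] = frozenset({"T047", "T048", "T184"})
    hpo_exclude_codes: frozenset[str] = frozenset(
        {"T045", "T077", "T079", "T080", "T082", "T169"}
    )

    def __post_init__(self) -> None:
        if self.include_codes & self.hpo_exclude_codes:
            raise ValueError("include_codes and hpo_exclude_codes must be disjoint")


@dataclass(frozen=True)
class ConceptRow:
    """One retained (English) row of the concept file."""

    cui: str
    source: str
    term: str
    code: str = ""
    is_preferred: bool = False


@dataclass
class PhenotypeConcept:
    """A vocabulary concept: id, preferred name, synonyms, source, types."""

    concept_id: str
    preferred_name: str
    synonyms: set[str]
    source: str
    semantic_types: frozenset[str] = frozenset()
    hpo_id: str | None = None

    def __post_init__(self) -> None:
        if not self.preferred_name:
            raise ValueError(f"concept {self.concept_id}: empty preferred name")
        self.synonyms = set(self.synonyms) | {self.preferred_name}

    @property
    def priority_rank(self) -> int:
        return SOURCE_PRIORITY[self.source]


@dataclass(frozen=True)
class GeneEntry:
    symbol: str
    risk_class: str = "NA"


@dataclass
class PhenotypeLexicon:
    """Filtered phenotype concepts keyed by (concept_id, source)."""

    concepts: dict[tuple[str, str], PhenotypeConcept] = field(default_factory=dict)

    def add(self, concept: PhenotypeConcept) -> None:
        key = (concept.concept_id, concept.source)
        if key in self.concepts:
            raise ValueError(f"duplicate concept {key}")
        self.concepts[key] = concept

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.ordered())

    def ordered(self) -> list[PhenotypeConcept]:
        """Concepts in the deterministic (concept_id, source) order."""
        return [self.concepts[k] for k in sorted(self.concepts)]

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "concept_id": c.concept_id,
                "preferred_name": c.preferred_name,
                "synonyms": sorted(c.synonyms),
                "source": c.source,
                "semantic_types": sorted(c.semantic_types),
                "hpo_id": c.hpo_id,
            }
            for c in self.ordered()
        ]
        Path(path).write_text(json.dumps(payload, indent=1), "utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeLexicon":
        lex = cls()
        for rec in json.loads(Path(path).read_text("utf-8")):
            lex.add(
                PhenotypeConcept(
                    concept_id=rec["concept_id"],
                    preferred_name=rec["preferred_name"],
                    synonyms=set(rec["synonyms"]),
                    source=rec["source"],
                    semantic_types=frozenset(rec["semantic_types"]),
                    hpo_id=rec.get("hpo_id"),
                )
            )
        return lex


@dataclass
class GeneLexicon:
    entries: dict[str, GeneEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def risk_class(self, symbol: str) -> str:
        entry = self.entries.get(symbol)
        return entry.risk_class if entry else "NA"

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.entries)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_concept_file(
    path: str | Path,
    columns: RRFColumns = RRFColumns(),
    language: str = "ENG",
) -> list[ConceptRow]:
    """Parse an MRCONSO-style pipe-delimited concept file.

    Rows in a language other than *language* are dropped; rows with too few
    fields are skipped and logged with their line number. A missing file is
    fatal.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    needed = max(columns.cui, columns.language, columns.sab, columns.code, columns.string)
    rows: list[ConceptRow] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("|")
            if len(fields) <= needed:
                logger.warning("%s:%d: malformed row (%d fields), skipped",
                               path.name, lineno, len(fields))
                continue
            if fields[columns.language] != language:
                continue
            ispref = fields[columns.ispref] == "Y" if columns.ispref < len(fields) else False
            rows.append(
                ConceptRow(
                    cui=fields[columns.cui],
                    source=fields[columns.sab],
                    term=fields[columns.string],
                    code=fields[columns.code],
                    is_preferred=ispref,
                )
            )
    return rows


def parse_semantic_types(
    path: str | Path, columns: RRFColumns = RRFColumns()
) -> dict[str, set[str]]:
    """Parse an MRSTY-style file into concept_id -> set of T-codes."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    needed = max(columns.sty_cui, columns.sty_tui)
    out: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("|")
            if len(fields) <= needed:
                logger.warning("%s:%d: malformed row, skipped", path.name, lineno)
                continue
            out.setdefault(fields[columns.sty_cui], set()).add(fields[columns.sty_tui])
    return out


def parse_asdpto_terms(path: str | Path) -> list[PhenotypeConcept]:
    """Parse an ASDPTO flat term list: TSV of id, name, synonyms ('|'-joined)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    concepts: list[PhenotypeConcept] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1]:
                logger.warning("%s:%d: malformed ASDPTO row, skipped", path.name, lineno)
                continue
            synonyms = set(filter(None, parts[2].split("|"))) if len(parts) > 2 else set()
            concepts.append(
                PhenotypeConcept(
                    concept_id=parts[0],
                    preferred_name=parts[1],
                    synonyms=synonyms,
                    source="ASDPTO",
                )
            )
    return concepts


# ---------------------------------------------------------------------------
# Lexicon construction
# ---------------------------------------------------------------------------

def build_phenotype_lexicon(
    rows: list[ConceptRow],
    semtype_map: dict[str, set[str]],
    semantic_filter: SemanticTypeFilter = SemanticTypeFilter(),
    asdpto_concepts: list[PhenotypeConcept] | None = None,
) -> PhenotypeLexicon:
    """Apply two-layer filtering and group synonym rows into concepts.

    Layer 1 keeps rows whose source vocabulary is one of HPO, OMIM, DDB,
    SNOMEDCT_US, MSH. Layer 2 keeps, for the non-HPO sources, only concepts
    whose semantic types intersect the include set; HPO concepts are kept
    unless their types intersect the exclusion set. A non-HPO concept with no
    semantic-type entry at all is excluded and logged. ASDPTO concepts are
    appended unfiltered under their own source.
    """
    grouped: dict[tuple[str, str], list[ConceptRow]] = {}
    for row in rows:
        if row.source not in RRF_SOURCES:
            continue
        grouped.setdefault((row.cui, row.source), []).append(row)

    lexicon = PhenotypeLexicon()
    for (cui, source), members in sorted(grouped.items()):
        types = frozenset(semtype_map.get(cui, ()))
        if source == "HPO":
            if types & semantic_filter.hpo_exclude_codes:
                continue
        else:
            if not types:
                logger.warning("concept %s (%s): no semantic-type entry, excluded", cui, source)
                continue
            if not types & semantic_filter.include_codes:
                continue
        preferred = next((m for m in members if m.is_preferred), members[0])
        hpo_id = preferred.code if source == "HPO" else None
        lexicon.add(
            PhenotypeConcept(
                concept_id=cui,
                preferred_name=preferred.term,
                synonyms={m.term for m in members},
                source=source,
                semantic_types=types,
                hpo_id=hpo_id,
            )
        )
    for concept in asdpto_concepts or []:
        lexicon.add(concept)
    return lexicon


def load_gene_list(path: str | Path, delimiter: str | None = None) -> GeneLexicon:
    """Load the gene list TSV/CSV of (symbol[, risk class]) rows.

    Exact duplicate rows collapse to one entry; the same symbol with two
    different risk classes is a fatal inconsistency. Unknown class labels map
    to NA with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    lexicon = GeneLexicon()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = delimiter or ("\t" if "\t" in line else ",")
            parts = [p.strip() for p in line.split(sep)]
            symbol = parts[0]
            if not symbol:
                logger.warning("%s:%d: empty gene symbol, skipped", path.name, lineno)
                continue
            risk = parts[1] if len(parts) > 1 and parts[1] else "NA"
            if risk not in VALID_RISK_CLASSES:
                logger.warning("%s:%d: unknown risk class %r for %s, using NA",
                               path.name, lineno, risk, symbol)
                risk = "NA"
            existing = lexicon.entries.get(symbol)
            if existing is not None:
                if existing.risk_class != risk:
                    raise ValueError(
                        f"{path.name}:{lineno}: gene {symbol} listed with conflicting "
                        f"classes {existing.risk_class!r} and {risk!r}"
                    )
                continue
            lexicon.entries[symbol] = GeneEntry(symbol, risk)
    return lexicon
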