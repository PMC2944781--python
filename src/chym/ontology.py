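"""Ontology parsing and normalization.

ChEBI-style ontologies arrive as OBO files with several relationship
types, some of them reciprocal (``is tautomer of`` and friends), plus
alternate ids and obsolete stanzas.  Semantic similarity needs a clean
rooted DAG, so this module normalizes the raw ontology into a single
child→parent relation, merges duplicate identifiers, drops obsolete
terms, and tags every node with the branches (structure / role /
subatomic) whose root it can reach.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .errors import CycleError, OboParseError, UnknownBranchError, UnknownTermError

log = logging.getLogger(__name__)

BRANCHES = ("structure", "role", "subatomic")

#: Reciprocal/cyclic ChEBI relationship types excluded during normalization.
#: The canonical offender is "is tautomer of"; the conjugate-pair and
#: enantiomer relations are symmetric in the same way.  Configurable.
DEFAULT_EXCLUDED_RELATIONS = frozenset(
    {
        "is_tautomer_of",
        "is_conjugate_base_of",
        "is_conjugate_acid_of",
        "is_enantiomer_of",
    }
)

_STRUCTURE_FORMATS = ("SMILES", "MDL", "InChI")


@dataclass(frozen=True)
class TermRecord:
    id: str
    name: str | None = None
    synonyms: tuple[str, ...] = ()
    structures: tuple[tuple[str, str], ...] = ()  # (format tag, text)
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()
    xrefs: tuple[str, ...] = ()


@dataclass
class RawOntology:
    """Parsed but unprocessed ontology content.

    ``relationships`` holds (child id, relation name, parent id) triples;
    ``is_a`` lines appear with relation name ``"is_a"``.
    """

    terms: list[TermRecord]
    relationships: list[tuple[str, str, str]]

    def __post_init__(self):
        ids = [t.id for t in self.terms]
        if len(ids) != len(set(ids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise OboParseError(f"duplicate term ids: {sorted(dupes)}")
        known = set(ids)
        for child, rel, parent in self.relationships:
            if child not in known or parent not in known:
                raise OboParseError(
                    f"relationship {child} {rel} {parent} references an undeclared term"
                )

    @property
    def term_index(self) -> dict[str, TermRecord]:
        return {t.id: t for t in self.terms}


class OntologyGraph:
    """Normalized acyclic term graph with child→parent edges.

    Nodes are canonical term ids; ``merges`` maps alias ids (alternate
    ids or duplicate-structure stanzas) to their canonical node.  Branch
    tags record, per node, which of the three sub-ontology roots the
    node reaches.  Ancestor sets are cached per node; results are
    identical with the cache disabled (it is a pure reachability
    closure).
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        merges: Mapping[str, str] | None = None,
        branch_tags: Mapping[str, frozenset[str]] | None = None,
        branch_roots: Mapping[str, str] | None = None,
    ):
        self.graph = graph
        self.merges = dict(merges or {})
        self.branch_tags = dict(branch_tags or {})
        self.branch_roots = dict(branch_roots or {})
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # -- resolution ---------------------------------------------------
    def resolve(self, term_id: str) -> str:
        """Map an id (possibly an alias) to its canonical node."""
        canonical = self.merges.get(term_id, term_id)
        if canonical not in self.graph:
            raise UnknownTermError(term_id)
        return canonical

    def __contains__(self, term_id: str) -> bool:
        return self.merges.get(term_id, term_id) in self.graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    # -- closures -----------------------------------------------------
    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive-transitive closure over child→parent edges."""
        node = self.resolve(term_id)
        cached = self._ancestor_cache.get(node)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, node)) | {node}
            self._ancestor_cache[node] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset[str]:
        """Reflexive set of nodes that have ``term_id`` as ancestor."""
        node = self.resolve(term_id)
        return frozenset(nx.ancestors(self.graph, node)) | {node}

    def topological_order(self) -> list[str]:
        """Nodes ordered children-before-parents."""
        return list(nx.topological_sort(self.graph))


# ---------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'^\s*"(.*)"')
_SMILES_KEY = re.compile(r"smiles", re.IGNORECASE)
_INCHI_KEY = re.compile(r"inchi(?!key)", re.IGNORECASE)
_MDL_KEY = re.compile(r"mdl|molfile", re.IGNORECASE)


def _prescan_stanzas(path: Path) -> None:
    """Raise OboParseError (with line number) for a [Term] stanza lacking an id."""
    stanza_start = None
    has_id = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("["):
                if stanza_start is not None and not has_id:
                    raise OboParseError(
                        f"[Term] stanza at line {stanza_start} has no id: line"
                    )
                stanza_start = lineno if stripped == "[Term]" else None
                has_id = False
            elif stanza_start is not None and stripped.startswith("id:"):
                has_id = True
    if stanza_start is not None and not has_id:
        raise OboParseError(f"[Term] stanza at line {stanza_start} has no id: line")


def _structure_records(node_data: Mapping) -> tuple[tuple[str, str], ...]:
    records = []
    for pv in node_data.get("property_value", []):
        m = re.match(r'^(\S+)\s+"(.*)"', pv)
        if not m:
            continue
        key, value = m.group(1), m.group(2)
        if _SMILES_KEY.search(key):
            records.append(("SMILES", value))
        elif _MDL_KEY.search(key):
            records.append(("MDL", value))
        elif _INCHI_KEY.search(key):
            records.append(("InChI", value))
    return tuple(records)


def parse_obo(path: str | Path, structures_tsv: str | Path | None = None) -> RawOntology:
    """Read an OBO 1.2 flat file into a :class:`RawOntology`.

    Honors ``id``, ``name``, ``synonym``, ``is_a``, ``relationship``,
    ``is_obsolete``, ``alt_id``, ``xref`` and ``property_value`` tags.
    Structure records are taken from property-value lines whose key names
    a structure format; an optional sidecar TSV
    ``term_id <TAB> format <TAB> structure_text`` supplies or extends them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_stanzas(path)
    graph = obonet.read_obo(path, ignore_obsolete=False)

    sidecar: dict[str, list[tuple[str, str]]] = {}
    if structures_tsv is not None:
        for lineno, line in enumerate(Path(structures_tsv).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise OboParseError(f"structures TSV line {lineno}: expected 3 columns")
            term_id, fmt, text = parts
            if fmt not in _STRUCTURE_FORMATS:
                raise OboParseError(
                    f"structures TSV line {lineno}: unknown format {fmt!r}"
                )
            sidecar.setdefault(term_id, []).append((fmt, text))

    terms = []
    relationships: list[tuple[str, str, str]] = []
    for node, data in graph.nodes(data=True):
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            synonyms.append(m.group(1) if m else raw)
        structures = _structure_records(data) + tuple(sidecar.get(node, ()))
        terms.append(
            TermRecord(
                id=node,
                name=data.get("name"),
                synonyms=tuple(synonyms),
                structures=structures,
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
                alt_ids=tuple(data.get("alt_id", [])),
                xrefs=tuple(data.get("xref", [])),
            )
        )
        for parent in data.get("is_a", []):
            relationships.append((node, "is_a", parent))
        for rel_line in data.get("relationship", []):
            parts = rel_line.split()
            if len(parts) >= 2:
                relationships.append((node, parts[0], parts[1]))

    known = {t.id for t in terms}
    relationships = [
        (c, r, p) for (c, r, p) in relationships if c in known and p in known
    ]
    return RawOntology(terms=terms, relationships=relationships)


# ---------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------

def _canon_relation(name: str) -> str:
    return name.strip().lower().replace(" ", "_")


def _merge_map(raw: RawOntology, active_terms: Sequence[TermRecord]) -> dict[str, str]:
    """alias id → canonical id.

    Two sources of aliases: alternate ids declared on a stanza, and pairs
    of stanzas carrying byte-identical canonical structure text (the
    duplicate-annotation case).  The canonical id of a merge group is the
    numerically lowest id (older entries tend to be better curated).
    """
    merges: dict[str, str] = {}
    for term in active_terms:
        for alias in term.alt_ids:
            merges[alias] = term.id

    by_structure: dict[tuple[str, str], list[str]] = {}
    for term in active_terms:
        for fmt, text in term.structures:
            if fmt in ("SMILES", "MDL"):
                by_structure.setdefault((fmt, text), []).append(term.id)
                break  # canonical structure = first usable record
    for group in by_structure.values():
        if len(group) > 1:
            canonical = min(group, key=_id_sort_key)
            for other in group:
                if other != canonical:
                    merges[other] = canonical
    # collapse alias chains
    for alias in list(merges):
        target = merges[alias]
        seen = {alias}
        while target in merges and target not in seen:
            seen.add(target)
            target = merges[target]
        merges[alias] = target
    return merges


def _id_sort_key(term_id: str):
    m = re.search(r"(\d+)", term_id)
    return (int(m.group(1)) if m else float("inf"), term_id)


def normalize(
    raw: RawOntology,
    excluded_relations: Iterable[str] | None = None,
    branch_roots: Mapping[str, str] | None = None,
    inverted_relations: Iterable[str] = (),
) -> OntologyGraph:
    """Collapse a raw ontology into a single acyclic child→parent relation.

    All relation types not in ``excluded_relations`` are merged into one
    "is a"-like relation oriented source→target (so for ``X has_part Y``
    the part Y becomes an ancestor of X, which is how a compound reaches
    the subatomic branch through its electrons).  ``inverted_relations``
    flips the orientation for any relation whose OBO direction runs the
    other way.  Obsolete terms are dropped; duplicate ids are merged.
    Residual cycles raise :class:`CycleError` rather than being broken
    silently.

    ``branch_roots`` maps branch names (⊆ {structure, role, subatomic})
    to root term ids; every node is tagged with each branch whose root
    it reaches.
    """
    excluded = {
        _canon_relation(r)
        for r in (DEFAULT_EXCLUDED_RELATIONS if excluded_relations is None else excluded_relations)
    }
    inverted = {_canon_relation(r) for r in inverted_relations}

    active = [t for t in raw.terms if not t.obsolete]
    active_ids = {t.id for t in active}
    merges = _merge_map(raw, active)

    def canon(term_id: str) -> str:
        return merges.get(term_id, term_id)

    graph = nx.DiGraph()
    graph.add_nodes_from(canon(t.id) for t in active)
    n_excluded = 0
    for child, rel, parent in raw.relationships:
        rel = _canon_relation(rel)
        if rel in excluded:
            n_excluded += 1
            continue
        if child not in active_ids or parent not in active_ids:
            continue  # endpoint obsolete
        if rel in inverted:
            child, parent = parent, child
        c, p = canon(child), canon(parent)
        if c != p:
            graph.add_edge(c, p)
    if n_excluded:
        log.debug("normalize: dropped %d edges from excluded relations", n_excluded)

    if not nx.is_directed_acyclic_graph(graph):
        cycle_edges = nx.find_cycle(graph)
        raise CycleError([e[0] for e in cycle_edges] + [cycle_edges[-1][1]])

    branch_roots = {k: canon(v) for k, v in (branch_roots or {}).items()}
    for branch in branch_roots:
        if branch not in BRANCHES:
            raise UnknownBranchError(f"unknown branch name: {branch!r}")
    tags: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for branch, root in branch_roots.items():
        if root not in graph:
            raise UnknownTermError(root)
        members = nx.ancestors(graph, root) | {root}  # nodes with a path to the root
        for n in members:
            tags[n].add(branch)
    return OntologyGraph(
        graph,
        merges=merges,
        branch_tags={n: frozenset(s) for n, s in tags.items()},
        branch_roots=branch_roots,
    )


def extract_branch(graph: OntologyGraph, branch: str) -> OntologyGraph:
    """Induced subgraph of one sub-ontology; ``"all"`` returns the input."""
    if branch == "all":
        return graph
    if branch not in BRANCHES:
        raise UnknownBranchError(f"unknown branch name: {branch!r}")
    members = [n for n in graph.graph.nodes if branch in graph.branch_tags.get(n, ())]
    sub = graph.graph.subgraph(members).copy()
    merges = {a: c for a, c in graph.merges.items() if c in sub}
    tags = {n: graph.branch_tags[n] for n in sub.nodes}
    roots = {b: r for b, r in graph.branch_roots.items() if b == branch}
    return OntologyGraph(sub, merges=merges, branch_tags=tags, branch_roots=roots)


def ancestors(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    """Anc(c): ancestors of ``term_id`` including the term itself."""
    return graph.ancestors(term_id)
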