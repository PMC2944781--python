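"""Information content from a pathway-annotation corpus.

A term's probability is the fraction of pathways in which the term or
any of its descendants appears; its information content is the negative
log of that probability.  Frequent (unspecific) terms therefore carry
low IC and specific terms high IC.  The corpus is a pathway → compound
mapping (the role the KEGG PATHWAY/COMPOUND databases play for ChEBI),
resolved onto ontology ids through cross-references; when a term has
several external references, all of them count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ChymError
from .ontology import OntologyGraph

log = logging.getLogger(__name__)

#: Sentinel returned by :func:`information_content` for p = 0 (a term
#: never observed in the corpus); such terms get weight 0 in simGIC sums.
UNANNOTATED = None


@dataclass(frozen=True)
class PathwayCorpus:
    """pathway id → set of ontology term ids annotated to it."""

    annotations: Mapping[str, frozenset[str]]

    def __post_init__(self):
        for pid, terms in self.annotations.items():
            if not terms:
                raise ValueError(f"pathway {pid!r} has an empty annotation set")

    def __len__(self) -> int:
        return len(self.annotations)

    def term_occurrences(self) -> dict[str, set[str]]:
        """term id → set of pathway ids where it directly appears."""
        occ: dict[str, set[str]] = {}
        for pid, terms in self.annotations.items():
            for t in terms:
                occ.setdefault(t, set()).add(pid)
        return occ


@dataclass
class ICTable:
    """Per-term probabilities and information-content weights.

    ``ic`` stores the weight used in simGIC sums: −log(p) in ``base``
    for annotated terms, 0.0 for unannotated ones (p = 0), with the
    ``annotated`` flag distinguishing true-zero IC (p = 1) from absence.
    """

    probability: dict[str, float]
    ic: dict[str, float]
    base: float = math.e

    def annotated(self, term_id: str) -> bool:
        return self.probability.get(term_id, 0.0) > 0.0

    def weight(self, term_id: str) -> float:
        return self.ic.get(term_id, 0.0)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("term_id\tprobability\tic\n")
            for term in sorted(self.probability):
                fh.write(f"{term}\t{self.probability[term]:.10g}\t{self.ic[term]:.10g}\n")


def resolve_corpus_ids(
    raw_corpus: Mapping[str, set[str] | frozenset[str]],
    xrefs: Mapping[str, set[str] | frozenset[str]],
) -> PathwayCorpus:
    """Resolve a pathway → external-compound-id corpus onto ontology ids.

    ``xrefs`` maps ontology ids to external ids and may be many-to-many
    in both directions: a term is annotated to a pathway iff *any* of
    its external references appears there.  External ids with no
    reverse mapping are skipped and counted in a log summary.
    """
    reverse: dict[str, set[str]] = {}
    for term, externals in xrefs.items():
        for ext in externals:
            reverse.setdefault(ext, set()).add(term)

    annotations: dict[str, frozenset[str]] = {}
    skipped = 0
    for pid, externals in raw_corpus.items():
        terms: set[str] = set()
        for ext in externals:
            hit = reverse.get(ext)
            if hit:
                terms.update(hit)
            else:
                skipped += 1
        if terms:
            annotations[pid] = frozenset(terms)
    if skipped:
        log.info("resolve_corpus_ids: %d external ids had no ontology mapping", skipped)
    return PathwayCorpus(annotations)


def term_probability(corpus: PathwayCorpus, graph: OntologyGraph, term_id: str) -> float:
    """Fraction of pathways containing ``term_id`` or any of its descendants."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    occ = corpus.term_occurrences()
    pathways: set[str] = set()
    for node in graph.descendants(term_id):
        pathways |= occ.get(node, set())
    return len(pathways) / len(corpus)


def information_content(p: float, base: float = math.e):
    """IC(p) = −log_base(p); returns :data:`UNANNOTATED` for p = 0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p}")
    if p == 0.0:
        return UNANNOTATED
    return -math.log(p) / math.log(base)


def build_ic_table(
    corpus: PathwayCorpus, graph: OntologyGraph, base: float = math.e
) -> ICTable:
    """IC for every node of ``graph`` from one bottom-up corpus pass.

    Occurrence sets are propagated child→parent in topological order, so
    a term's probability subsumes all its descendants' occurrences.
    Unannotated terms (p = 0) are recorded with weight 0 so they
    contribute nothing to simGIC sums.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    direct = corpus.term_occurrences()
    occ: dict[str, set[str]] = {}
    for node in graph.topological_order():  # children before parents
        s = set(direct.get(node, ()))
        for child in graph.graph.predecessors(node):
            s |= occ[child]
        occ[node] = s

    n = len(corpus)
    probability: dict[str, float] = {}
    ic: dict[str, float] = {}
    for node in graph.nodes:
        p = len(occ[node]) / n
        probability[node] = p
        value = information_content(p, base=base)
        ic[node] = 0.0 if value is UNANNOTATED else value
    return ICTable(probability=probability, ic=ic, base=base)


# ---------------------------------------------------------------------
# Flat-file readers (one pair per line, tab-separated)
# ---------------------------------------------------------------------

def read_pairs_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV into key → set-of-values (comments with #)."""
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ChymError(f"{path}, line {lineno}: expected 2 columns")
        mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping
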