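"""Semantic similarity between ontology terms: simUI and simGIC.

Both measures operate on the reflexive ancestor sets Anc(c) of the two
terms.  simUI is the Jaccard index of the two sets; simGIC weights each
ancestor by its information content, so similarity driven only by
abstract (low-IC) shared ancestors is discounted.  Branch restriction is
expressed by passing the branch subgraph: terms outside the branch have
no ancestor set there and cannot be scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import DegenerateICError, ScopedTermError, UnknownTermError
from .ic import ICTable
from .ontology import BRANCHES, OntologyGraph


@dataclass(frozen=True)
class SemanticSimilarityConfig:
    method: str  # "simUI" | "simGIC"
    branch: str  # "structure" | "role" | "subatomic" | "all"
    ic: ICTable | None = None

    def __post_init__(self):
        if self.method not in ("simUI", "simGIC"):
            raise ValueError(f"unknown semantic method: {self.method!r}")
        if self.branch not in BRANCHES + ("all",):
            raise ValueError(f"unknown branch: {self.branch!r}")
        if self.method == "simGIC" and self.ic is None:
            raise ValueError("simGIC requires an ICTable")


def sim_ui(graph: OntologyGraph, c1: str, c2: str) -> float:
    """|Anc(c1) ∩ Anc(c2)| / |Anc(c1) ∪ Anc(c2)| with reflexive Anc."""
    a1 = graph.ancestors(c1)
    a2 = graph.ancestors(c2)
    return len(a1 & a2) / len(a1 | a2)


def sim_gic(graph: OntologyGraph, ic: ICTable, c1: str, c2: str) -> float:
    """IC-weighted simUI: Σ IC over the intersection / Σ IC over the union.

    Unannotated terms have weight 0 and contribute nothing; if the whole
    union has zero IC the ratio is undefined and a
    :class:`DegenerateICError` is raised.
    """
    a1 = graph.ancestors(c1)
    a2 = graph.ancestors(c2)
    # summation in sorted term order so the result is exactly symmetric
    union_sum = sum(ic.weight(t) for t in sorted(a1 | a2))
    if union_sum == 0.0:
        raise DegenerateICError(
            f"zero IC over the ancestor union of {c1!r} and {c2!r}"
        )
    inter_sum = sum(ic.weight(t) for t in sorted(a1 & a2))
    return inter_sum / union_sum


def semantic_similarity(
    graph: OntologyGraph, config: SemanticSimilarityConfig, c1: str, c2: str
) -> float:
    """Dispatch on the configured method; ``graph`` must already be the
    branch subgraph matching ``config.branch``."""
    try:
        if config.method == "simUI":
            return sim_ui(graph, c1, c2)
        return sim_gic(graph, config.ic, c1, c2)
    except UnknownTermError as exc:
        if config.branch != "all":
            raise ScopedTermError(exc.term_id, config.branch) from exc
        raise


def write_similarity_matrix(
    path: str | Path,
    rows: Iterable[tuple[str, str, str, str, float]],
) -> None:
    """TSV writer: (id1, id2, method, branch, value) per row."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\tmethod\tbranch\tvalue\n")
        for id1, id2, method, branch, value in rows:
            fh.write(f"{id1}\t{id2}\t{method}\t{branch}\t{value:.10g}\n")
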