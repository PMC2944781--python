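"""The hybrid similarity metric and its parameter space.

A hybrid metric is identified by four parameters — fingerprint format,
semantic method, ontology branch and the mixing weight α — written in
the compact notation ``"LF,simGIC,all,0.29"``.  The similarity between
two compounds is the convex combination

    sim = α · tanimoto(fingerprints) + (1 − α) · semantic similarity,

so α = 1 degenerates to pure structural and α = 0 to pure semantic
comparison.  With 3 fingerprint formats, 2 semantic methods and 4 DAGs
the metric space holds 24 parameterized families.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import logging

from .errors import ChymError, ScoringError, UnknownTermError
from .fingerprints import (
    FINGERPRINT_FORMATS,
    LF_FORMAT,
    Fingerprint,
    builtin_pattern_set,
    choose_structure,
    linear_fragment_fingerprint,
    parse_structure,
    pattern_fingerprint,
    tanimoto,
)
from .ic import ICTable
from .ontology import OntologyGraph, extract_branch
from .semantic import SemanticSimilarityConfig, semantic_similarity

log = logging.getLogger(__name__)

SEMANTIC_METHODS = ("simUI", "simGIC")
BRANCH_NAMES = ("structure", "role", "subatomic", "all")

ALPHA_GRID_STEP = 0.01


@dataclass(frozen=True)
class MetricSpec:
    """(fingerprint format, semantic method, branch, α) — one hybrid metric."""

    fingerprint_format: str
    semantic_method: str
    branch: str
    alpha: float

    def __post_init__(self):
        if self.fingerprint_format not in FINGERPRINT_FORMATS:
            raise ValueError(f"unknown fingerprint format: {self.fingerprint_format!r}")
        if self.semantic_method not in SEMANTIC_METHODS:
            raise ValueError(f"unknown semantic method: {self.semantic_method!r}")
        if self.branch not in BRANCH_NAMES:
            raise ValueError(f"unknown branch: {self.branch!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha out of [0, 1]: {self.alpha}")

    def to_string(self) -> str:
        return f"{self.fingerprint_format},{self.semantic_method},{self.branch},{self.alpha:g}"

    @classmethod
    def from_string(cls, text: str) -> "MetricSpec":
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError(f"metric spec needs 4 comma-separated fields: {text!r}")
        return cls(parts[0], parts[1], parts[2], float(parts[3]))


def hybrid_similarity(s_struct: float, s_sem: float, alpha: float) -> float:
    """α·s_struct + (1 − α)·s_sem, all arguments in [0, 1]."""
    for name, v in (("s_struct", s_struct), ("s_sem", s_sem), ("alpha", alpha)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} out of [0, 1]: {v}")
    return alpha * s_struct + (1.0 - alpha) * s_sem


def enumerate_metric_space() -> list[tuple[str, str, str]]:
    """All 3 × 2 × 4 = 24 (format, method, branch) combinations, in order."""
    return list(itertools.product(FINGERPRINT_FORMATS, SEMANTIC_METHODS, BRANCH_NAMES))


def alpha_grid(step: float = ALPHA_GRID_STEP) -> list[float]:
    """Inclusive α grid from 0 to 1; the default step 0.01 gives 101 values."""
    n = round(1.0 / step)
    return [round(i * step, 10) for i in range(n + 1)]


class Resources:
    """Everything needed to score compounds: ontology, IC and fingerprints.

    ``fingerprints`` maps format tag → {compound id → Fingerprint}.  The
    IC table is computed on the full DAG and reused for every branch
    (sums in simGIC are restricted to branch ancestors implicitly,
    because ancestor sets are taken within the branch subgraph).
    Branch subgraphs are materialized lazily and cached.
    """

    def __init__(
        self,
        ontology: OntologyGraph,
        ic: ICTable | None,
        fingerprints: Mapping[str, Mapping[str, Fingerprint]],
    ):
        self.ontology = ontology
        self.ic = ic
        self.fingerprints = {k: dict(v) for k, v in fingerprints.items()}
        self._branch_cache: dict[str, OntologyGraph] = {"all": ontology}

    def branch_graph(self, branch: str) -> OntologyGraph:
        if branch not in self._branch_cache:
            self._branch_cache[branch] = extract_branch(self.ontology, branch)
        return self._branch_cache[branch]

    def fingerprint(self, compound_id: str, fmt: str) -> Fingerprint:
        try:
            return self.fingerprints[fmt][compound_id]
        except KeyError:
            raise ScoringError(
                f"compound {compound_id!r} has no fingerprint in format {fmt!r}"
            ) from None

    def semantic_config(self, method: str, branch: str) -> SemanticSimilarityConfig:
        return SemanticSimilarityConfig(
            method=method, branch=branch, ic=self.ic if method == "simGIC" else None
        )


def build_resources(
    ontology: OntologyGraph,
    structures: Mapping[str, tuple],
    ic: ICTable | None = None,
    formats: tuple[str, ...] = FINGERPRINT_FORMATS,
    strict: bool = True,
) -> Resources:
    """Compute every fingerprint format for every structured compound.

    ``structures`` maps compound id → structure record list; the record
    to use is chosen by the SMILES-over-MDL preference.  With
    ``strict=False`` unparseable compounds are skipped with a logged
    count (useful when ranking a whole noisy ontology); otherwise parse
    failures propagate.
    """
    fps: dict[str, dict[str, Fingerprint]] = {fmt: {} for fmt in formats}
    skipped = 0
    for cid in sorted(structures):
        try:
            fmt_rec, text = choose_structure(structures[cid])
            mol = parse_structure(text, fmt_rec)
        except ChymError:
            if strict:
                raise
            skipped += 1
            continue
        for fmt in formats:
            if fmt == LF_FORMAT:
                fps[fmt][cid] = linear_fragment_fingerprint(mol)
            else:
                fps[fmt][cid] = pattern_fingerprint(mol, builtin_pattern_set(fmt))
    if skipped:
        log.info("build_resources: skipped %d unparseable compounds", skipped)
    return Resources(ontology=ontology, ic=ic, fingerprints=fps)


def compound_similarity(
    c1: str, c2: str, spec: MetricSpec, resources: Resources
) -> float:
    """Hybrid similarity between two compounds under a metric spec."""
    fp1 = resources.fingerprint(c1, spec.fingerprint_format)
    fp2 = resources.fingerprint(c2, spec.fingerprint_format)
    s_struct = tanimoto(fp1, fp2)
    graph = resources.branch_graph(spec.branch)
    config = resources.semantic_config(spec.semantic_method, spec.branch)
    try:
        s_sem = semantic_similarity(graph, config, c1, c2)
    except UnknownTermError as exc:
        raise ScoringError(
            f"compound {exc.term_id!r} does not resolve in the ontology"
        ) from exc
    return hybrid_similarity(s_struct, s_sem, spec.alpha)
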