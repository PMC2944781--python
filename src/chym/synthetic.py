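"""Synthetic ontologies, corpora, molecules and labeled tasks.

Everything the pipeline consumes can be generated here, seeded and
reproducible, so the package builds and validates without any external
download.  The generator emulates the shape of a ChEBI-style resource:

* a rooted ontology with three partially overlapping branches
  (structure / role / subatomic) — compound leaves hang off a layered
  class scaffold in the structure branch, carry role parents with
  probability ``overlap`` and reach the subatomic branch through a
  ``has_part`` electron edge;
* a pathway corpus biased so sibling compounds co-occur, producing the
  specific-term-high-IC gradient a real annotation corpus shows;
* small valid SMILES molecules for the leaves;
* labeled activity tasks with controllable, independent structural and
  semantic signal: actives concentrate in one planted class subtree
  (semantic signal) and share a planted amide motif in their structures
  (structural signal), each with the configured probability; inactives
  carry each signal with the complementary probability.

What this emulates — and what it does not — is discussed in the methods
note; molecules are simple chains with spliced functional groups, not
realistic chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .classifier import ACTIVE, INACTIVE, LabeledSet
from .ic import PathwayCorpus
from .ontology import OntologyGraph, RawOntology, TermRecord, normalize

#: Pyridylmethyl-amide fragment spliced into motif-positive molecules;
#: large enough to contribute many linear fragments and several pattern
#: keys, so every fingerprint format can see the planted signal.
MOTIF_SMILES = "C(=O)NCc1ccncc1"

_DECOY_SMILES = "C(=O)OC"  # ester decoy so pattern keys stay non-trivial


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic world; defaults give a desk-scale ChEBI-like
    resource (≈250 terms, ≈200 compounds) suitable for full-grid runs."""

    seed: int = 0
    n_terms: int = 250
    overlap: float = 0.9          # fraction of compounds in all three branches
    mean_parents: float = 1.3     # >1 adds extra DAG parents inside a branch
    n_pathways: int = 40
    mean_pathway_size: float = 12.0
    n_active: int = 40
    n_inactive: int = 40
    structural_signal: float = 0.8
    semantic_signal: float = 0.8

    def __post_init__(self):
        if self.n_terms < 1 or self.n_pathways < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        for name in ("structural_signal", "semantic_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_active < 0 or self.n_inactive < 0:
            raise ValueError("class sizes must be non-negative")


@dataclass
class SyntheticOntology:
    """Generated ontology bundle: raw stanzas, normalized graph, structure
    records, cross-references and the class scaffold used for planting."""

    raw: RawOntology
    graph: OntologyGraph
    structures: dict[str, tuple[tuple[str, str], ...]]  # leaf → records
    xrefs: dict[str, frozenset[str]]                    # leaf → external ids
    branch_roots: dict[str, str]
    top_classes: tuple[str, ...]


@dataclass
class TaskFixture:
    """A labeled activity task plus its ground truth."""

    labels: LabeledSet
    structures: dict[str, tuple[tuple[str, str], ...]]  # overrides, all leaves
    subtree_root: str
    motif: str
    in_subtree: dict[str, bool]
    has_motif: dict[str, bool]


# ---------------------------------------------------------------------
# Molecules
# ---------------------------------------------------------------------

_CHAIN_ATOMS = ("C", "C", "C", "N", "O", "S")  # carbon-biased chain alphabet


def _random_chain(rng: np.random.Generator, lo: int = 4, hi: int = 10) -> str:
    n = int(rng.integers(lo, hi + 1))
    atoms = ["C"]  # start on carbon so splicing is always valence-safe
    for _ in range(n - 1):
        atom = _CHAIN_ATOMS[int(rng.integers(len(_CHAIN_ATOMS)))]
        atoms.append(atom)
        if atom == "C" and rng.random() < 0.2:
            atoms.append("(C)")  # methyl branch, only off carbon (valence-safe)
    return "".join(atoms)


def random_smiles(rng: np.random.Generator, motif: str | None = None) -> str:
    """A small valid molecule: chain [+ motif] + chain [+ benzene ring].

    Chains use single bonds over C/N/O, which is valence-safe by
    construction; the optional aromatic ring attaches to a carbon.
    """
    left = _random_chain(rng)
    right = _random_chain(rng)
    middle = motif or ""
    if motif is None and rng.random() < 0.3:
        middle = _DECOY_SMILES
    smiles = left + middle + right
    if rng.random() < 0.15:
        smiles = smiles + "C" + "c1ccccc1"  # carbon spacer then benzene
    return smiles


def _unique_smiles(
    rng: np.random.Generator, seen: set[str], motif: str | None = None
) -> str:
    # distinct text per compound: identical structure strings on two terms
    # would (correctly) be merged into one node by the normalizer
    while True:
        smiles = random_smiles(rng, motif=motif)
        if smiles not in seen:
            seen.add(smiles)
            return smiles


# ---------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------

def _term_id(i: int) -> str:
    return f"SYN:{i:04d}"


def generate_ontology(cfg: FixtureConfig) -> SyntheticOntology:
    """Random layered DAG with three overlapping branches and leaf SMILES.

    The structure branch holds a three-level class scaffold (top classes
    → subclasses → sub-subclasses) with compound leaves below it; extra
    in-branch parents (controlled by ``mean_parents``) create diamonds.
    A few reciprocal ``is_tautomer_of`` pairs, an obsolete term and an
    alternate id are included so the normalizer is exercised end to end.
    Deterministic: the same config yields an identical edge set.
    """
    rng = np.random.default_rng(cfg.seed)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return _term_id(counter[0])

    terms: list[TermRecord] = []
    rels: list[tuple[str, str, str]] = []

    def add_term(name: str, **kw) -> str:
        tid = new_id()
        terms.append(TermRecord(id=tid, name=name, **kw))
        return tid

    root = add_term("synthetic entity")
    if cfg.n_terms == 1:  # degenerate boundary: a lone root, no edges
        raw = RawOntology(terms=terms, relationships=[])
        graph = normalize(raw, branch_roots={})
        return SyntheticOntology(
            raw=raw, graph=graph, structures={}, xrefs={},
            branch_roots={}, top_classes=(),
        )
    b_struct = add_term("molecular structure")
    b_role = add_term("role")
    b_sub = add_term("subatomic particle")
    for b in (b_struct, b_role, b_sub):
        rels.append((b, "is_a", root))

    electron = add_term("electron")
    photon = add_term("photon")
    rels.append((electron, "is_a", b_sub))
    rels.append((photon, "is_a", b_sub))

    p_extra = min(max(cfg.mean_parents - 1.0, 0.0), 0.9)

    # structure scaffold: 4 top classes, each a depth-3 class hierarchy
    # (2 subclasses x 2 sub-subclasses); deep chains make within-class
    # leaves share most of their ancestry, as real chemical classes do
    top_classes = []
    subsubs_by_top: dict[str, list[str]] = {}
    sub_of: dict[str, str] = {}
    for t in range(4):
        top = add_term(f"class-{t}")
        rels.append((top, "is_a", b_struct))
        top_classes.append(top)
        subsubs_by_top[top] = []
        for s in range(2):
            sub = add_term(f"class-{t}.{s}")
            rels.append((sub, "is_a", top))
            for ss in range(2):
                subsub = add_term(f"class-{t}.{s}.{ss}")
                rels.append((subsub, "is_a", sub))
                subsubs_by_top[top].append(subsub)
                sub_of[subsub] = sub
        # occasional cross-link between top classes (diamond)
        if rng.random() < p_extra and t > 0:
            rels.append((subsubs_by_top[top][0], "is_a", top_classes[t - 1]))

    # role scaffold: 4 role families x 2 roles
    roles = []
    for r in range(4):
        fam = add_term(f"role-family-{r}")
        rels.append((fam, "is_a", b_role))
        for s in range(2):
            role = add_term(f"role-{r}.{s}")
            rels.append((role, "is_a", fam))
            roles.append(role)

    n_scaffold = counter[0]
    n_leaves = max(cfg.n_terms - n_scaffold, 1)

    structures: dict[str, tuple[tuple[str, str], ...]] = {}
    xrefs: dict[str, frozenset[str]] = {}
    leaves = []
    seen_smiles: set[str] = set()
    next_ext = [1]
    for i in range(n_leaves):
        leaf = add_term(f"compound-{i}", synonyms=(f"cmpd {i}",))
        leaves.append(leaf)
        top = top_classes[int(rng.integers(len(top_classes)))]
        pool = subsubs_by_top[top]
        # two class parents within the same top class (compounds typically
        # instantiate several related classes), optionally a third
        n_parents = 2 + (1 if rng.random() < p_extra else 0)
        picks = rng.choice(len(pool), size=min(n_parents, len(pool)), replace=False)
        for p in picks:
            rels.append((leaf, "is_a", pool[int(p)]))
        if rng.random() < cfg.overlap:
            rels.append((leaf, "is_a", roles[int(rng.integers(len(roles)))]))
        if rng.random() < cfg.overlap:
            rels.append((leaf, "has_part", electron))
        structures[leaf] = (("SMILES", _unique_smiles(rng, seen_smiles)),)
        ext_ids = {f"X:{next_ext[0]:05d}"}
        next_ext[0] += 1
        if rng.random() < 0.3:  # ambiguous cross-reference case
            ext_ids.add(f"X:{next_ext[0]:05d}")
            next_ext[0] += 1
        xrefs[leaf] = frozenset(ext_ids)

    # parser-exercise extras: tautomer pair, obsolete term, alternate id
    if len(leaves) >= 2:
        rels.append((leaves[0], "is_tautomer_of", leaves[1]))
        rels.append((leaves[1], "is_tautomer_of", leaves[0]))
    obsolete = new_id()
    terms.append(TermRecord(id=obsolete, name="withdrawn term", obsolete=True))
    # give the first leaf an alternate id pointing at a retired number
    first = terms[[t.id for t in terms].index(leaves[0])]
    terms[[t.id for t in terms].index(leaves[0])] = TermRecord(
        id=first.id,
        name=first.name,
        synonyms=first.synonyms,
        structures=first.structures,
        obsolete=first.obsolete,
        alt_ids=(f"SYN:{9000 + cfg.seed % 100:04d}",),
        xrefs=first.xrefs,
    )

    raw = RawOntology(terms=terms, relationships=rels)
    branch_roots = {"structure": b_struct, "role": b_role, "subatomic": b_sub}
    graph = normalize(raw, branch_roots=branch_roots)

    # attach structure records to the raw term stanzas for the writers
    terms_with_structures = [
        TermRecord(
            id=t.id,
            name=t.name,
            synonyms=t.synonyms,
            structures=structures.get(t.id, ()),
            obsolete=t.obsolete,
            alt_ids=t.alt_ids,
            xrefs=tuple(sorted(xrefs.get(t.id, ()))),
        )
        for t in terms
    ]
    raw = RawOntology(terms=terms_with_structures, relationships=rels)

    return SyntheticOntology(
        raw=raw,
        graph=graph,
        structures=structures,
        xrefs=xrefs,
        branch_roots=branch_roots,
        top_classes=tuple(top_classes),
    )


# ---------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------

def generate_corpus(
    syn: SyntheticOntology, cfg: FixtureConfig
) -> PathwayCorpus:
    """Pathways sampling compound leaves with a sibling bias.

    Each pathway anchors on one sub-subclass and draws most of its
    members from that class's leaves, the rest uniformly, so co-occurring
    compounds tend to be ontological siblings and IC increases with
    depth.  Deterministic from the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    graph = syn.graph
    compounds = sorted(syn.structures)
    # leaf members per sub-subclass
    by_class: dict[str, list[str]] = {}
    for leaf in compounds:
        for anc in graph.ancestors(leaf):
            if anc != leaf:
                by_class.setdefault(anc, []).append(leaf)
    anchors = sorted(c for c, members in by_class.items() if 3 <= len(members) <= 40)
    if not anchors:
        anchors = sorted(by_class)

    annotations: dict[str, frozenset[str]] = {}
    for p in range(cfg.n_pathways):
        anchor = anchors[int(rng.integers(len(anchors)))]
        pool = by_class[anchor]
        size = max(1, int(rng.poisson(cfg.mean_pathway_size)))
        members: set[str] = set()
        for _ in range(size):
            if pool and rng.random() < 0.7:
                members.add(pool[int(rng.integers(len(pool)))])
            else:
                members.add(compounds[int(rng.integers(len(compounds)))])
        annotations[f"path:{p:04d}"] = frozenset(members)
    return PathwayCorpus(annotations)


# ---------------------------------------------------------------------
# Labeled task
# ---------------------------------------------------------------------

def generate_task(
    syn: SyntheticOntology, corpus: PathwayCorpus, cfg: FixtureConfig
) -> TaskFixture:
    """Plant semantic and structural signal into a labeled set.

    Each signal strength is the probability that the plant is applied;
    otherwise the compound is drawn from the generic background.  An
    active is placed in the planted subtree with probability
    ``semantic_signal`` (else uniformly over all eligible leaves, which
    may land inside by chance) and gets the motif spliced into its
    structure with probability ``structural_signal`` (else a generic
    motif-free molecule).  An inactive avoids the subtree with
    probability ``semantic_signal`` (else uniform) and its molecules
    are generic, so it carries the motif only as often as the
    background does (essentially never).  At strength 0 a signal is
    therefore uninformative (labels independent of it); at strength 1
    the planting is deterministic.  Only compounds present in all three
    branches are eligible, so every metric family can score the task.
    Returns new structure records for the task compounds; non-task
    compounds keep their original structures.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    graph = syn.graph
    eligible = [
        leaf
        for leaf in sorted(syn.structures)
        if graph.branch_tags.get(graph.resolve(leaf), frozenset())
        >= {"structure", "role", "subatomic"}
    ]
    # planted subtree: the top class with the most eligible leaves
    def subtree_leaves(top: str) -> list[str]:
        members = graph.descendants(top)
        return [c for c in eligible if c in members]

    subtree_root = max(syn.top_classes, key=lambda t: (len(subtree_leaves(t)), t))
    inside = subtree_leaves(subtree_root)
    outside = [c for c in eligible if c not in set(inside)]

    def draw(pool: list[str], used: set[str]) -> str:
        for candidates in (pool, eligible):
            avail = [c for c in candidates if c not in used]
            if avail:
                choice = avail[int(rng.integers(len(avail)))]
                used.add(choice)
                return choice
        raise ValueError("not enough eligible compounds for the requested task size")

    s_sem, s_str = cfg.semantic_signal, cfg.structural_signal
    used: set[str] = set()
    structures = dict(syn.structures)
    in_subtree: dict[str, bool] = {}
    has_motif: dict[str, bool] = {}
    inside_set = set(inside)
    labels: dict[str, str] = {}
    plan = [ACTIVE] * cfg.n_active + [INACTIVE] * cfg.n_inactive
    for label in plan:
        if label == ACTIVE:
            pool = inside if rng.random() < s_sem else eligible
            motif = rng.random() < s_str
        else:
            pool = outside if rng.random() < s_sem else eligible
            motif = False  # inactives carry only the generic background
        cid = draw(pool, used)
        labels[cid] = label
        seen = {text for recs in structures.values() for _, text in recs}
        structures[cid] = (
            ("SMILES", _unique_smiles(rng, seen, motif=MOTIF_SMILES if motif else None)),
        )
        in_subtree[cid] = cid in inside_set
        has_motif[cid] = motif
    return TaskFixture(
        labels=LabeledSet(labels),
        structures=structures,
        subtree_root=subtree_root,
        motif=MOTIF_SMILES,
        in_subtree=in_subtree,
        has_motif=has_motif,
    )


# ---------------------------------------------------------------------
# Writers: emit fixtures in the formats the real pipeline reads
# ---------------------------------------------------------------------

def write_obo(
    path: str | Path,
    raw: RawOntology,
    structures: Mapping[str, tuple[tuple[str, str], ...]] | None = None,
) -> None:
    """OBO 1.2 writer; optional structure overrides replace stanza records."""
    overrides = structures or {}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        rels_by_child: dict[str, list[tuple[str, str]]] = {}
        for child, rel, parent in raw.relationships:
            rels_by_child.setdefault(child, []).append((rel, parent))
        for term in raw.terms:
            fh.write("\n[Term]\n")
            fh.write(f"id: {term.id}\n")
            if term.name:
                fh.write(f"name: {term.name}\n")
            for alias in term.alt_ids:
                fh.write(f"alt_id: {alias}\n")
            for syn in term.synonyms:
                fh.write(f'synonym: "{syn}" EXACT []\n')
            records = overrides.get(term.id, term.structures)
            for fmt, text in records:
                key = {"SMILES": "smiles", "MDL": "mdl", "InChI": "inchi"}[fmt]
                fh.write(f'property_value: http://example.org/chem/{key} "{text}" xsd:string\n')
            for xref in term.xrefs:
                fh.write(f"xref: {xref}\n")
            for rel, parent in rels_by_child.get(term.id, ()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")


def write_fixture_tree(
    outdir: str | Path,
    syn: SyntheticOntology,
    corpus: PathwayCorpus | None = None,
    task: TaskFixture | None = None,
) -> dict[str, Path]:
    """Write the whole fixture as the flat files the CLI consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    structures = task.structures if task else syn.structures
    paths["ontology"] = outdir / "ontology.obo"
    write_obo(paths["ontology"], syn.raw, structures=structures)

    paths["structures"] = outdir / "structures.tsv"
    with open(paths["structures"], "w") as fh:
        for cid in sorted(structures):
            for fmt, text in structures[cid]:
                fh.write(f"{cid}\t{fmt}\t{text}\n")

    paths["xrefs"] = outdir / "xrefs.tsv"
    with open(paths["xrefs"], "w") as fh:
        for cid in sorted(syn.xrefs):
            for ext in sorted(syn.xrefs[cid]):
                fh.write(f"{cid}\t{ext}\n")

    if corpus is not None:
        paths["corpus"] = outdir / "corpus.tsv"
        with open(paths["corpus"], "w") as fh:
            for pid in sorted(corpus.annotations):
                for cid in sorted(corpus.annotations[pid]):
                    ext = sorted(syn.xrefs[cid])[0]
                    fh.write(f"{pid}\t{ext}\n")

    if task is not None:
        paths["labels"] = outdir / "labeled.tsv"
        with open(paths["labels"], "w") as fh:
            for cid in sorted(task.labels.labels):
                fh.write(f"{cid}\t{task.labels.labels[cid]}\n")
    return paths
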