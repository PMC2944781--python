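"""Molecular structures, bit-vector fingerprints and Tanimoto similarity.

Two fingerprint families are provided:

* ``LF`` — a hashed linear-fragment fingerprint: every non-branched
  fragment (simple path or simple ring) of up to 7 atoms is canonicalized
  to a token string and hashed into a 1021-bit vector.  This is an
  explicit, reproducible dialect of the classic Daylight/OpenBabel-style
  path fingerprint: the hash is FNV-1a (32-bit) over the canonical token
  string, reduced modulo the bit count, and single-atom fragments are
  included.  It is not bit-compatible with any external toolkit.
* pattern fingerprints — one bit per SMARTS pattern from an ordered
  pattern file; two curated built-in sets (``PAT-A``, ``PAT-B``) play the
  roles of the two structural-key formats, and user files are accepted.

Structure parsing delegates to RDKit; similarity is the Jaccard-Tanimoto
coefficient over the bit vectors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    DegenerateFingerprintError,
    FingerprintComparisonError,
    NoUsableStructureError,
    PatternError,
    StructureParseError,
)

RDLogger.DisableLog("rdApp.*")  # parse failures are raised, not printed

LF_FORMAT = "LF"
LF_MAX_ATOMS = 7
LF_N_BITS = 1021

BUILTIN_PATTERN_SETS = ("PAT-A", "PAT-B")
FINGERPRINT_FORMATS = (LF_FORMAT,) + BUILTIN_PATTERN_SETS

_BOND_TOKEN = {1: "-", 2: "=", 3: "#", "ar": ":"}


@dataclass(frozen=True)
class Molecule:
    """Light wrapper over a parsed structure.

    ``atoms`` holds (element symbol, aromatic flag) per atom index and
    ``bonds`` holds ((i, j), order) with order in {1, 2, 3, "ar"}; the
    underlying RDKit molecule is kept for substructure matching.
    """

    atoms: tuple[tuple[str, bool], ...]
    bonds: tuple[tuple[tuple[int, int], object], ...]
    source_format: str
    rdmol: Chem.Mol = field(repr=False, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for (i, j), _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) has an invalid atom index")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add(key)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit vector with a tag identifying the generating method."""

    bits: frozenset[int]
    length: int
    format: str

    def __post_init__(self):
        if self.bits and max(self.bits) >= self.length:
            raise ValueError("bit index beyond fingerprint length")

    @property
    def n_on(self) -> int:
        return len(self.bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=bool)
        if self.bits:
            arr[list(self.bits)] = True
        return arr

    def to_hex(self) -> str:
        return np.packbits(self.to_array()).tobytes().hex()


# ---------------------------------------------------------------------
# Structure parsing and record selection
# ---------------------------------------------------------------------

def parse_structure(text: str, fmt: str) -> Molecule:
    """Parse a SMILES string or an MDL (V2000) molblock into a Molecule."""
    if not text:
        raise StructureParseError(text, fmt)
    if fmt == "SMILES":
        rdmol = Chem.MolFromSmiles(text)
    elif fmt == "MDL":
        rdmol = Chem.MolFromMolBlock(text)
    else:
        raise StructureParseError(text, fmt)
    if rdmol is None:
        raise StructureParseError(text, fmt)
    atoms = tuple((a.GetSymbol(), a.GetIsAromatic()) for a in rdmol.GetAtoms())
    bonds = []
    for b in rdmol.GetBonds():
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            order: object = "ar"
        else:
            order = int(b.GetBondTypeAsDouble())
        bonds.append(((b.GetBeginAtomIdx(), b.GetEndAtomIdx()), order))
    return Molecule(atoms=atoms, bonds=tuple(bonds), source_format=fmt, rdmol=rdmol)


def choose_structure(records: Sequence[tuple[str, str]]) -> tuple[str, str]:
    """Pick the structure record to use: first SMILES, else first MDL.

    InChI records are never used (for any compound carrying one there is
    normally another format as well); a record list with neither SMILES
    nor MDL raises :class:`NoUsableStructureError`.
    """
    if not records:
        raise NoUsableStructureError("empty structure record list")
    for fmt, text in records:
        if fmt == "SMILES":
            return (fmt, text)
    for fmt, text in records:
        if fmt == "MDL":
            return (fmt, text)
    raise NoUsableStructureError(
        f"no SMILES or MDL record among formats {[f for f, _ in records]}"
    )


# ---------------------------------------------------------------------
# Linear-fragment (hashed path) fingerprint
# ---------------------------------------------------------------------

def _fnv1a(data: bytes) -> int:
    h = 0x811C9DC5
    for byte in data:
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h


def _atom_token(atom: tuple[str, bool]) -> str:
    symbol, aromatic = atom
    return symbol.lower() if aromatic else symbol


def _path_string(mol_atoms, order_of, path: Sequence[int]) -> str:
    toks = [_atom_token(mol_atoms[path[0]])]
    for a, b in zip(path, path[1:]):
        toks.append(_BOND_TOKEN[order_of[(min(a, b), max(a, b))]])
        toks.append(_atom_token(mol_atoms[b]))
    return "".join(toks)


def _canonical_path(mol_atoms, order_of, path: Sequence[int]) -> str:
    fwd = _path_string(mol_atoms, order_of, path)
    rev = _path_string(mol_atoms, order_of, list(reversed(path)))
    return min(fwd, rev)


def _canonical_cycle(mol_atoms, order_of, cycle: Sequence[int]) -> str:
    # minimum over all rotations of both traversal directions, with the
    # ring-closure bond appended so the string determines the cycle
    best = None
    n = len(cycle)
    for seq in (list(cycle), list(reversed(cycle))):
        for shift in range(n):
            rot = seq[shift:] + seq[:shift]
            s = _path_string(mol_atoms, order_of, rot)
            a, b = rot[-1], rot[0]
            s += _BOND_TOKEN[order_of[(min(a, b), max(a, b))]]
            if best is None or s < best:
                best = s
    return "@" + best


def linear_fragments(mol: Molecule, max_atoms: int = LF_MAX_ATOMS) -> set[str]:
    """Canonical strings of all simple paths and simple rings of ≤ max_atoms atoms."""
    if not mol.atoms:
        raise ValueError("empty molecule")
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    order_of = {}
    for (i, j), order in mol.bonds:
        g.add_edge(i, j)
        order_of[(min(i, j), max(i, j))] = order

    fragments: set[str] = set()
    for start in g.nodes:
        stack = [[start]]
        while stack:
            path = stack.pop()
            fragments.add(_canonical_path(mol.atoms, order_of, path))
            if len(path) < max_atoms:
                for nbr in g.neighbors(path[-1]):
                    if nbr not in path:
                        stack.append(path + [nbr])
    for cycle in nx.simple_cycles(g, length_bound=max_atoms):
        fragments.add(_canonical_cycle(mol.atoms, order_of, cycle))
    return fragments


def linear_fragment_fingerprint(
    mol: Molecule, max_atoms: int = LF_MAX_ATOMS, n_bits: int = LF_N_BITS
) -> Fingerprint:
    """Hash each canonical fragment string into an ``n_bits``-wide vector."""
    fragments = linear_fragments(mol, max_atoms=max_atoms)
    bits = frozenset(_fnv1a(f.encode("utf-8")) % n_bits for f in fragments)
    return Fingerprint(bits=bits, length=n_bits, format=LF_FORMAT)


# ---------------------------------------------------------------------
# Pattern (structural-key) fingerprints
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PatternSet:
    """An ordered, compiled list of SMARTS patterns with a set name."""

    name: str
    smarts: tuple[str, ...]
    compiled: tuple[Chem.Mol, ...] = field(repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.smarts)


_COMMENT_RE = re.compile(r"(?:^|\s)#.*$")


def compile_patterns(lines: Iterable[str], name: str) -> PatternSet:
    """Compile one SMARTS pattern per line.

    A ``#`` at line start or preceded by whitespace begins a comment
    (``#`` inside a pattern, as in ``[#6]``, is untouched); blank lines
    are skipped.
    """
    smarts: list[str] = []
    compiled: list[Chem.Mol] = []
    for lineno, line in enumerate(lines, 1):
        text = _COMMENT_RE.sub("", line).strip()
        if not text:
            continue
        pat = Chem.MolFromSmarts(text)
        if pat is None:
            raise PatternError(text, lineno)
        smarts.append(text)
        compiled.append(pat)
    if not smarts:
        raise PatternError("<empty pattern set>", 0)
    return PatternSet(name=name, smarts=tuple(smarts), compiled=tuple(compiled))


def load_pattern_file(path: str | Path, name: str | None = None) -> PatternSet:
    path = Path(path)
    return compile_patterns(path.read_text().splitlines(), name or path.stem)


_builtin_cache: dict[str, PatternSet] = {}


def builtin_pattern_set(name: str) -> PatternSet:
    """One of the two shipped structural-key sets (``PAT-A`` / ``PAT-B``)."""
    if name not in BUILTIN_PATTERN_SETS:
        raise KeyError(f"unknown built-in pattern set: {name!r}")
    if name not in _builtin_cache:
        filename = {"PAT-A": "pattern_set_a.smarts", "PAT-B": "pattern_set_b.smarts"}[name]
        text = (
            importlib_resources.files("chym").joinpath("data", filename).read_text()
        )
        _builtin_cache[name] = compile_patterns(text.splitlines(), name)
    return _builtin_cache[name]


def pattern_fingerprint(mol: Molecule, patterns: PatternSet) -> Fingerprint:
    """Bit i set iff pattern i has at least one substructure match."""
    bits = frozenset(
        i
        for i, pat in enumerate(patterns.compiled)
        if mol.rdmol.HasSubstructMatch(pat)
    )
    return Fingerprint(bits=bits, length=len(patterns), format=patterns.name)


# ---------------------------------------------------------------------
# Tanimoto
# ---------------------------------------------------------------------

def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard-Tanimoto coefficient: shared on-bits / union of on-bits."""
    if a.format != b.format or a.length != b.length:
        raise FingerprintComparisonError(
            f"incompatible fingerprints: {a.format}/{a.length} vs {b.format}/{b.length}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        raise DegenerateFingerprintError("both fingerprints are all-zero")
    return len(a.bits & b.bits) / union


def write_fingerprints_tsv(path: str | Path, fps: dict[str, Fingerprint]) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tformat\tbits_hex\tlength\n")
        for cid in sorted(fps):
            fp = fps[cid]
            fh.write(f"{cid}\t{fp.format}\t{fp.to_hex()}\t{fp.length}\n")
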