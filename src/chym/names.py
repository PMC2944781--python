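"""Bag-of-words mapping of literature compound names onto ontology ids.

Literature activity lists usually carry names only, no structures.  A
name is reduced to a bag of words — maximal runs of letters or of
digits, case-folded, punctuation discarded — and matched against the
preferred names and synonyms of every ontology term that has a usable
structure record.  Several terms can share a bag (old duplicate
annotations); the numerically lowest id wins, older entries being the
better curated ones.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import NoUsableStructureError
from .fingerprints import choose_structure
from .ontology import RawOntology

_TOKEN_RE = re.compile(r"[a-z]+|[0-9]+")


def tokenize_name(name: str) -> frozenset[str]:
    """Bag of words: letter runs and digit runs, case-folded, no punctuation.

    Unicode is NFKD-normalized and combining marks stripped first, so
    Greek letters, primes and diacritics in chemical names reduce to
    plain ASCII where possible.  An all-punctuation name yields an
    empty bag, which no indexed term can match.
    """
    norm = unicodedata.normalize("NFKD", name)
    norm = "".join(ch for ch in norm if not unicodedata.combining(ch))
    return frozenset(_TOKEN_RE.findall(norm.casefold()))


@dataclass(frozen=True)
class IndexEntry:
    term_id: str
    source: str
    is_synonym: bool


@dataclass
class NameIndex:
    """token bag → entries, over structure-bearing terms only."""

    entries: Mapping[frozenset[str], tuple[IndexEntry, ...]]

    def lookup(self, bag: frozenset[str]) -> tuple[IndexEntry, ...]:
        return self.entries.get(bag, ())


def _id_numeric(term_id: str):
    m = re.search(r"(\d+)", term_id)
    return (int(m.group(1)) if m else float("inf"), term_id)


def build_name_index(raw: RawOntology) -> NameIndex:
    """Index preferred names and synonyms of terms with a SMILES/MDL record."""
    entries: dict[frozenset[str], list[IndexEntry]] = {}
    for term in raw.terms:
        if term.obsolete:
            continue
        try:
            choose_structure(term.structures)
        except NoUsableStructureError:
            continue
        sources = [(term.name, False)] if term.name else []
        sources.extend((syn, True) for syn in term.synonyms)
        for source, is_syn in sources:
            bag = tokenize_name(source)
            if bag:
                entries.setdefault(bag, []).append(
                    IndexEntry(term_id=term.id, source=source, is_synonym=is_syn)
                )
    return NameIndex(entries={k: tuple(v) for k, v in entries.items()})


UNMATCHED = "UNMATCHED"


def map_names(
    names: Iterable[str], index: NameIndex, mode: str = "exact"
) -> dict[str, str]:
    """name → ontology id (or :data:`UNMATCHED`).

    ``mode="exact"`` requires bag equality; ``mode="subset"`` also
    accepts indexed bags that contain the query bag (the loosest
    defensible reading of bag-of-words identity).  Ambiguity resolves
    to the numerically lowest id.  Deterministic and order-independent.
    """
    if mode not in ("exact", "subset"):
        raise ValueError(f"unknown matching mode: {mode!r}")
    result: dict[str, str] = {}
    for name in names:
        bag = tokenize_name(name)
        candidates = list(index.lookup(bag)) if bag else []
        if mode == "subset" and bag:
            for other_bag, entries in index.entries.items():
                if other_bag != bag and bag <= other_bag:
                    candidates.extend(entries)
        if candidates:
            result[name] = min((e.term_id for e in candidates), key=_id_numeric)
        else:
            result[name] = UNMATCHED
    return result


@dataclass(frozen=True)
class CoverageSummary:
    """Matched/total counts per label class."""

    per_label: Mapping[str, tuple[int, int]]  # label → (matched, total)

    @property
    def overall(self) -> tuple[int, int]:
        matched = sum(m for m, _ in self.per_label.values())
        total = sum(t for _, t in self.per_label.values())
        return matched, total


def map_labeled_names(
    labeled_names: Mapping[str, str], index: NameIndex, mode: str = "exact"
) -> tuple[dict[str, str], CoverageSummary]:
    """Map a name → label table; also report per-class coverage."""
    mapping = map_names(labeled_names.keys(), index, mode=mode)
    per_label: dict[str, list[int]] = {}
    for name, label in labeled_names.items():
        counts = per_label.setdefault(label, [0, 0])
        counts[1] += 1
        if mapping[name] != UNMATCHED:
            counts[0] += 1
    summary = CoverageSummary(
        per_label={k: (v[0], v[1]) for k, v in per_label.items()}
    )
    return mapping, summary


def write_mapping_tsv(
    path: str | Path, mapping: Mapping[str, str], labels: Mapping[str, str] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("name\tterm_id\tlabel\n")
        for name in sorted(mapping):
            label = labels.get(name, "") if labels else ""
            fh.write(f"{name}\t{mapping[name]}\t{label}\n")
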