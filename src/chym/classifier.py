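"""Similarity-threshold activity classification.

Training: every training compound gets an *activity coefficient* — its
unweighted mean similarity to the active training compounds, excluding
an active's comparison with itself (that value is always 1 and would
bias the average).  Every computed coefficient is then tried as a
threshold, and the one minimizing training misclassifications becomes
the threshold of activity τ.  Prediction: a compound is called active
iff its coefficient is ≥ τ.  Inactive training compounds influence only
τ, never the coefficients of new compounds.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .errors import ChymError, DegenerateTrainingError, ScoringError
from .metric import MetricSpec, Resources, compound_similarity

log = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"

SimilaritySource = Callable[[str, str], float]


@dataclass(frozen=True)
class LabeledSet:
    """compound id → binary activity label."""

    labels: Mapping[str, str]

    def __post_init__(self):
        bad = {v for v in self.labels.values()} - {ACTIVE, INACTIVE}
        if bad:
            raise ValueError(f"labels must be active/inactive, got {sorted(bad)}")

    @property
    def actives(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, l in self.labels.items() if l == ACTIVE))

    @property
    def inactives(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, l in self.labels.items() if l == INACTIVE))

    def subset(self, ids: Iterable[str]) -> "LabeledSet":
        return LabeledSet({c: self.labels[c] for c in ids})

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledSet":
        labels = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ChymError(f"{path}, line {lineno}: expected 2 columns")
            labels[parts[0]] = parts[1].strip().lower()
        return cls(labels)


@dataclass(frozen=True)
class ActivityModel:
    """Trained classifier: metric, active training set and threshold τ.

    ``training_coefficients`` is retained for audit; τ is always one of
    those coefficients.
    """

    spec: MetricSpec
    actives: tuple[str, ...]
    tau: float
    training_coefficients: Mapping[str, float]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"metric\t{self.spec.to_string()}\n")
            fh.write(f"tau\t{self.tau:.10g}\n")
            for cid in self.actives:
                fh.write(f"active\t{cid}\n")
            for cid, coeff in sorted(self.training_coefficients.items()):
                fh.write(f"coefficient\t{cid}\t{coeff:.10g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ActivityModel":
        spec = None
        tau = None
        actives: list[str] = []
        coeffs: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            parts = line.split("\t")
            if parts[0] == "metric":
                spec = MetricSpec.from_string(parts[1])
            elif parts[0] == "tau":
                tau = float(parts[1])
            elif parts[0] == "active":
                actives.append(parts[1])
            elif parts[0] == "coefficient":
                coeffs[parts[1]] = float(parts[2])
        if spec is None or tau is None:
            raise ChymError(f"malformed model file: {path}")
        return cls(spec=spec, actives=tuple(actives), tau=tau, training_coefficients=coeffs)


# ---------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------

def training_coefficients(
    sims: SimilaritySource, labeled: LabeledSet
) -> dict[str, float]:
    """Mean similarity of each training compound to the actives.

    For an active, its self-comparison is excluded; for an inactive, all
    actives count.  Requires at least two actives.
    """
    actives = labeled.actives
    if len(actives) < 2:
        raise DegenerateTrainingError(
            f"need at least 2 active compounds, got {len(actives)}"
        )
    coeffs: dict[str, float] = {}
    for cid in labeled.labels:
        others = [a for a in actives if a != cid]
        coeffs[cid] = sum(sims(cid, a) for a in others) / len(others)
    return coeffs


def select_threshold(coeffs: Mapping[str, float], labeled: LabeledSet) -> float:
    """Pick τ among the training coefficients.

    Each candidate classifies a compound active iff coefficient ≥
    candidate; the candidate with the fewest training misclassifications
    wins, ties going to the *largest* candidate (the most conservative
    choice toward calling "active").
    """
    if not coeffs:
        raise ValueError("empty coefficient map")
    missing = set(labeled.labels) - set(coeffs)
    if missing:
        raise ValueError(f"coefficients missing for {sorted(missing)}")
    best_tau = None
    best_miscls = None
    for candidate in coeffs.values():
        miscls = 0
        for cid, label in labeled.labels.items():
            predicted_active = coeffs[cid] >= candidate
            if predicted_active != (label == ACTIVE):
                miscls += 1
        if (
            best_miscls is None
            or miscls < best_miscls
            or (miscls == best_miscls and candidate > best_tau)
        ):
            best_tau, best_miscls = candidate, miscls
    return best_tau


def train(
    dataset: LabeledSet, spec: MetricSpec, resources: Resources
) -> ActivityModel:
    """Compose pairwise similarity, coefficients and threshold selection."""
    cache: dict[tuple[str, str], float] = {}

    def sims(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = compound_similarity(key[0], key[1], spec, resources)
        return cache[key]

    coeffs = training_coefficients(sims, dataset)
    tau = select_threshold(coeffs, dataset)
    return ActivityModel(
        spec=spec,
        actives=dataset.actives,
        tau=tau,
        training_coefficients=coeffs,
    )


# ---------------------------------------------------------------------
# Prediction and ranking
# ---------------------------------------------------------------------

def activity_coefficient(
    model: ActivityModel, compound: str, resources: Resources
) -> float:
    """Mean similarity of ``compound`` to the model actives.

    If the compound *is* one of the model actives its self-comparison is
    excluded, extending the training rule.
    """
    others = [a for a in model.actives if a != compound]
    if not others:
        raise DegenerateTrainingError("model has no other active to compare against")
    total = 0.0
    for a in others:
        total += compound_similarity(compound, a, model.spec, resources)
    return total / len(others)


def predict(
    model: ActivityModel, compound: str, resources: Resources
) -> tuple[str, float]:
    """(label, coefficient); active iff coefficient ≥ τ."""
    coeff = activity_coefficient(model, compound, resources)
    return (ACTIVE if coeff >= model.tau else INACTIVE, coeff)


def _id_sort_key(cid: str):
    m = re.search(r"(\d+)", cid)
    return (int(m.group(1)) if m else float("inf"), cid)


def rank_candidates(
    model: ActivityModel, candidates: Iterable[str], resources: Resources
) -> list[tuple[str, float]]:
    """Candidates ordered by descending coefficient (ties: ascending id).

    Unscoreable candidates are skipped with a logged count, so the whole
    ontology can be ranked even when some terms lack resources.
    """
    scored: list[tuple[str, float]] = []
    skipped = 0
    for cid in candidates:
        try:
            scored.append((cid, activity_coefficient(model, cid, resources)))
        except ScoringError:
            skipped += 1
    if skipped:
        log.info("rank_candidates: skipped %d unscoreable candidates", skipped)
    scored.sort(key=lambda pair: (-pair[1], _id_sort_key(pair[0])))
    return scored
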