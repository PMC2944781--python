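"""Validation machinery: MCC/accuracy, LMO25, repeated stratified k-fold
and the grid search over the hybrid-metric space.

The grid evaluates 24 (fingerprint format, semantic method, branch)
families × an inclusive α grid (step 0.01 → 101 values, 2424 candidate
metrics).  To make that tractable the pairwise structural and semantic
similarity matrices over the dataset are precomputed once per family;
the hybrid matrix for any α is then a convex combination, and each
train/test split is scored with a vectorized re-expression of the
threshold classifier.  A test in the suite pins the vectorized route to
the reference implementation in :mod:`chym.classifier`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import ACTIVE, LabeledSet
from .errors import (
    ChymError,
    DegenerateFingerprintError,
    DegenerateICError,
    DegenerateTrainingError,
    ScoringError,
)
from .ic import ICTable
from .metric import (
    MetricSpec,
    Resources,
    alpha_grid,
    enumerate_metric_space,
)

# ---------------------------------------------------------------------
# Confusion counts and scalar metrics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correctly classified compounds."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; zero-denominator convention → 0."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-repeat and mean performance for one metric and protocol."""

    spec: MetricSpec
    protocol: str
    seed: int
    per_repeat_accuracy: tuple[float, ...]
    per_repeat_mcc: tuple[float, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_repeat_accuracy))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.per_repeat_mcc))


# ---------------------------------------------------------------------
# Pairwise similarity cache
# ---------------------------------------------------------------------

class PairwiseCache:
    """Precomputed pairwise similarity components over a fixed id set.

    Structural matrices are built per fingerprint format from the bit
    vectors; semantic matrices per (method, branch) from ancestor
    incidence matrices (IC-weighted for simGIC).  ``hybrid_matrix``
    combines them for any α; ``sims_fn`` adapts a matrix to the
    callable interface of :mod:`chym.classifier`, guaranteeing both
    routes score identical numbers.
    """

    def __init__(self, resources: Resources, ids: Sequence[str]):
        self.resources = resources
        self.ids = tuple(ids)
        self.index = {cid: i for i, cid in enumerate(self.ids)}
        self._struct: dict[str, np.ndarray] = {}
        self._sem: dict[tuple[str, str], np.ndarray] = {}

    def struct_matrix(self, fmt: str) -> np.ndarray:
        if fmt not in self._struct:
            fps = [self.resources.fingerprint(cid, fmt) for cid in self.ids]
            length = fps[0].length
            bits = np.zeros((len(fps), length), dtype=bool)
            for row, fp in enumerate(fps):
                if fp.bits:
                    bits[row, list(fp.bits)] = True
            on = bits.sum(axis=1)
            inter = (bits.astype(np.int32) @ bits.T.astype(np.int32)).astype(float)
            union = on[:, None] + on[None, :] - inter
            if np.any(union == 0):
                raise DegenerateFingerprintError(
                    f"all-zero fingerprint pair in format {fmt!r}"
                )
            self._struct[fmt] = inter / union
        return self._struct[fmt]

    def sem_matrix(self, method: str, branch: str) -> np.ndarray:
        key = (method, branch)
        if key not in self._sem:
            graph = self.resources.branch_graph(branch)
            anc = [graph.ancestors(cid) for cid in self.ids]  # ScopedTerm via resolve
            terms = sorted(set().union(*anc))
            tindex = {t: j for j, t in enumerate(terms)}
            member = np.zeros((len(anc), len(terms)), dtype=bool)
            for row, aset in enumerate(anc):
                member[row, [tindex[t] for t in aset]] = True
            if method == "simUI":
                weights = np.ones(len(terms))
            else:
                ic: ICTable = self.resources.ic
                if ic is None:
                    raise ChymError("simGIC requires an IC table in resources")
                weights = np.array([ic.weight(t) for t in terms])
            weighted = member * weights
            inter = weighted @ member.T
            sums = weighted.sum(axis=1)
            union = sums[:, None] + sums[None, :] - inter
            if np.any(union == 0):
                raise DegenerateICError(
                    f"zero-weight ancestor union under {method}/{branch}"
                )
            self._sem[key] = inter / union
        return self._sem[key]

    def hybrid_matrix(self, spec: MetricSpec) -> np.ndarray:
        s = self.struct_matrix(spec.fingerprint_format)
        t = self.sem_matrix(spec.semantic_method, spec.branch)
        return spec.alpha * s + (1.0 - spec.alpha) * t

    def sims_fn(self, spec: MetricSpec):
        matrix = self.hybrid_matrix(spec)

        def sims(a: str, b: str) -> float:
            return float(matrix[self.index[a], self.index[b]])

        return sims


# ---------------------------------------------------------------------
# Vectorized split scoring
# ---------------------------------------------------------------------

def _split_confusion(
    H: np.ndarray, y: np.ndarray, train_idx: np.ndarray, test_idx: np.ndarray
) -> ConfusionCounts:
    """Train the threshold classifier on one split and score the test side.

    Vectorized equivalent of ``training_coefficients`` +
    ``select_threshold`` + ``predict`` (same self-exclusion and the same
    largest-minimizer tie-break for τ).
    """
    active_train = train_idx[y[train_idx]]
    if active_train.size < 2:
        raise DegenerateTrainingError("split has fewer than 2 active training compounds")
    n_act = active_train.size
    s = H[np.ix_(train_idx, active_train)].sum(axis=1)
    is_act = y[train_idx]
    diag = H[train_idx, train_idx]
    coeff = np.where(is_act, (s - diag) / (n_act - 1), s / n_act)

    act_c = coeff[is_act]
    inact_c = coeff[~is_act]
    miscls = (act_c[None, :] < coeff[:, None]).sum(axis=1) + (
        inact_c[None, :] >= coeff[:, None]
    ).sum(axis=1)
    best = miscls.min()
    tau = coeff[miscls == best].max()

    test_coeff = H[np.ix_(test_idx, active_train)].mean(axis=1)
    pred = test_coeff >= tau
    actual = y[test_idx]
    tp = int(np.sum(pred & actual))
    fp = int(np.sum(pred & ~actual))
    tn = int(np.sum(~pred & ~actual))
    fn = int(np.sum(~pred & actual))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------
# Split generation (shared between direct protocols and the grid)
# ---------------------------------------------------------------------

def _label_array(dataset: LabeledSet, ids: Sequence[str]) -> np.ndarray:
    return np.array([dataset.labels[c] == ACTIVE for c in ids], dtype=bool)


def _lmo_splits(
    y: np.ndarray, n_repeats: int, holdout_per_class: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    act = np.flatnonzero(y)
    inact = np.flatnonzero(~y)
    for name, pool in (("active", act), ("inactive", inact)):
        if pool.size <= holdout_per_class:
            raise ValueError(
                f"{name} class has {pool.size} compounds; "
                f"need more than {holdout_per_class}"
            )
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        test = np.concatenate(
            [
                rng.choice(act, size=holdout_per_class, replace=False),
                rng.choice(inact, size=holdout_per_class, replace=False),
            ]
        )
        mask = np.ones(y.size, dtype=bool)
        mask[test] = False
        splits.append((np.flatnonzero(mask), np.sort(test)))
    return splits


def _kfold_splits(
    y: np.ndarray, k: int, repeats: int, seed: int
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    n_act = int(y.sum())
    n_inact = int(y.size - n_act)
    for name, n in (("active", n_act), ("inactive", n_inact)):
        if n < k:
            raise ValueError(f"{name} class has {n} compounds; need at least k={k}")
    child_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    all_splits = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(child_seeds[r]))
        folds = [
            (train, test)
            for train, test in skf.split(np.zeros(y.size), y.astype(int))
        ]
        all_splits.append(folds)
    return all_splits


# ---------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------

def lmo25(
    dataset: LabeledSet,
    spec: MetricSpec,
    resources: Resources,
    n_repeats: int = 30,
    holdout_per_class: int = 25,
    seed: int = 0,
    cache: PairwiseCache | None = None,
) -> EvaluationResult:
    """Leave-multiple-out validation: hold out ``holdout_per_class``
    compounds per class, train on the remainder, repeat and average."""
    ids = sorted(dataset.labels)
    y = _label_array(dataset, ids)
    cache = cache or PairwiseCache(resources, ids)
    H = cache.hybrid_matrix(spec)
    accs, mccs = [], []
    for train_idx, test_idx in _lmo_splits(y, n_repeats, holdout_per_class, seed):
        counts = _split_confusion(H, y, train_idx, test_idx)
        accs.append(accuracy(counts))
        mccs.append(mcc(counts))
    return EvaluationResult(
        spec=spec,
        protocol="lmo25",
        seed=seed,
        per_repeat_accuracy=tuple(accs),
        per_repeat_mcc=tuple(mccs),
    )


def repeated_stratified_kfold(
    dataset: LabeledSet,
    spec: MetricSpec,
    resources: Resources,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    cache: PairwiseCache | None = None,
) -> EvaluationResult:
    """Repeated stratified k-fold CV; per-fold metrics are averaged
    within a repeat, then across repeats."""
    ids = sorted(dataset.labels)
    y = _label_array(dataset, ids)
    cache = cache or PairwiseCache(resources, ids)
    H = cache.hybrid_matrix(spec)
    accs, mccs = [], []
    for folds in _kfold_splits(y, k, repeats, seed):
        fold_accs, fold_mccs = [], []
        for train_idx, test_idx in folds:
            counts = _split_confusion(H, y, train_idx, test_idx)
            fold_accs.append(accuracy(counts))
            fold_mccs.append(mcc(counts))
        accs.append(float(np.mean(fold_accs)))
        mccs.append(float(np.mean(fold_mccs)))
    return EvaluationResult(
        spec=spec,
        protocol="kfold",
        seed=seed,
        per_repeat_accuracy=tuple(accs),
        per_repeat_mcc=tuple(mccs),
    )


# ---------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GridSearchResult:
    best_spec: MetricSpec
    best_result: EvaluationResult
    table: pd.DataFrame = field(compare=False)


def grid_search(
    dataset: LabeledSet,
    resources: Resources,
    alpha_step: float = 0.01,
    protocol: str = "kfold",
    seed: int = 0,
    k: int = 10,
    repeats: int = 3,
    n_repeats: int = 30,
    holdout_per_class: int = 25,
) -> GridSearchResult:
    """Evaluate every metric family × α on shared splits.

    Returns the argmax by mean MCC (ties: lower α, then enumeration
    order) and the full result table; families that cannot be scored for
    this dataset appear as failed rows with NaN performance.
    """
    ids = sorted(dataset.labels)
    y = _label_array(dataset, ids)
    cache = PairwiseCache(resources, ids)
    alphas = alpha_grid(alpha_step)

    if protocol == "kfold":
        repeat_splits = _kfold_splits(y, k, repeats, seed)
    elif protocol == "lmo25":
        repeat_splits = [[s] for s in _lmo_splits(y, n_repeats, holdout_per_class, seed)]
    else:
        raise ValueError(f"unknown protocol: {protocol!r}")

    rows = []
    best_key = None
    best = None  # (spec, per-repeat accs, per-repeat mccs)
    for enum_index, (fmt, method, branch) in enumerate(enumerate_metric_space()):
        try:
            s_mat = cache.struct_matrix(fmt)
            t_mat = cache.sem_matrix(method, branch)
        except (ScoringError, DegenerateFingerprintError, DegenerateICError) as exc:
            for alpha in alphas:
                rows.append(
                    {
                        "format": fmt,
                        "method": method,
                        "branch": branch,
                        "alpha": alpha,
                        "accuracy": float("nan"),
                        "mcc": float("nan"),
                        "error": str(exc),
                    }
                )
            continue
        for alpha in alphas:
            H = alpha * s_mat + (1.0 - alpha) * t_mat
            accs, mccs = [], []
            for folds in repeat_splits:
                fold_accs, fold_mccs = [], []
                for train_idx, test_idx in folds:
                    counts = _split_confusion(H, y, train_idx, test_idx)
                    fold_accs.append(accuracy(counts))
                    fold_mccs.append(mcc(counts))
                accs.append(float(np.mean(fold_accs)))
                mccs.append(float(np.mean(fold_mccs)))
            mean_mcc = float(np.mean(mccs))
            rows.append(
                {
                    "format": fmt,
                    "method": method,
                    "branch": branch,
                    "alpha": alpha,
                    "accuracy": float(np.mean(accs)),
                    "mcc": mean_mcc,
                    "error": "",
                }
            )
            key = (-mean_mcc, alpha, enum_index)
            if best_key is None or key < best_key:
                best_key = key
                best = (
                    MetricSpec(fmt, method, branch, alpha),
                    tuple(accs),
                    tuple(mccs),
                )
    if best is None:
        raise ChymError("no metric in the grid could be evaluated")
    best_spec, best_accs, best_mccs = best
    best_result = EvaluationResult(
        spec=best_spec,
        protocol=protocol,
        seed=seed,
        per_repeat_accuracy=best_accs,
        per_repeat_mcc=best_mccs,
    )
    table = pd.DataFrame(rows)
    return GridSearchResult(best_spec=best_spec, best_result=best_result, table=table)


def write_grid_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write the full grid table, best MCC first."""
    ordered = table.sort_values("mcc", ascending=False, kind="mergesort")
    cols = ["format", "method", "branch", "alpha", "accuracy", "mcc"]
    ordered.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")
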