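"""Threshold classifier: coefficients, τ selection, training, prediction."""

import itertools

import pytest

from chym.classifier import (
    ACTIVE,
    INACTIVE,
    LabeledSet,
    activity_coefficient,
    predict,
    rank_candidates,
    select_threshold,
    train,
    training_coefficients,
)
from chym.errors import DegenerateTrainingError, ScoringError
from chym.metric import MetricSpec


def sims_from(table):
    def sims(a, b):
        return table[(a, b)] if (a, b) in table else table[(b, a)]

    return sims


ABI = LabeledSet({"A": ACTIVE, "B": ACTIVE, "I": INACTIVE})
ABI_SIMS = sims_from({("A", "B"): 0.8, ("A", "I"): 0.2, ("B", "I"): 0.4,
                      ("A", "A"): 1.0, ("B", "B"): 1.0, ("I", "I"): 1.0})


def test_coefficients_with_self_exclusion():
    coeffs = training_coefficients(ABI_SIMS, ABI)
    assert coeffs == {"A": 0.8, "B": 0.8, "I": pytest.approx(0.3)}


def test_constant_similarity_gives_constant_coefficients():
    sims = lambda a, b: 1.0
    labeled = LabeledSet({"A": ACTIVE, "B": ACTIVE, "C": ACTIVE})
    assert set(training_coefficients(sims, labeled).values()) == {1.0}


def test_three_active_means():
    labeled = LabeledSet({"A": ACTIVE, "B": ACTIVE, "C": ACTIVE})
    sims = sims_from(
        {("A", "B"): 0.6, ("A", "C"): 0.6, ("B", "C"): 0.2}
    )
    coeffs = training_coefficients(sims, labeled)
    assert coeffs == {"A": pytest.approx(0.6), "B": pytest.approx(0.4), "C": pytest.approx(0.4)}


def test_single_active_is_degenerate():
    labeled = LabeledSet({"A": ACTIVE, "I": INACTIVE})
    with pytest.raises(DegenerateTrainingError):
        training_coefficients(ABI_SIMS, labeled)


# -------------------------------------------------------- select_threshold

def test_threshold_on_separable_example():
    coeffs = training_coefficients(ABI_SIMS, ABI)
    assert select_threshold(coeffs, ABI) == 0.8


def brute_force_threshold(coeffs, labeled):
    best = None
    for cand in coeffs.values():
        mis = sum(
            (coeffs[c] >= cand) != (labeled.labels[c] == ACTIVE) for c in coeffs
        )
        if best is None or mis < best[0] or (mis == best[0] and cand > best[1]):
            best = (mis, cand)
    return best


def test_threshold_on_inverted_data_matches_brute_force():
    labeled = LabeledSet({"A": ACTIVE, "B": ACTIVE, "I1": INACTIVE, "I2": INACTIVE})
    coeffs = {"A": 0.1, "B": 0.2, "I1": 0.8, "I2": 0.9}
    tau = select_threshold(coeffs, labeled)
    mis, expected = brute_force_threshold(coeffs, labeled)
    assert tau == expected
    # no candidate does better (exhaustive confirmation)
    for cand in coeffs.values():
        other = sum(
            (coeffs[c] >= cand) != (labeled.labels[c] == ACTIVE) for c in coeffs
        )
        assert other >= mis


def test_threshold_tie_breaks_to_largest_candidate():
    labeled = LabeledSet({"A": ACTIVE, "B": ACTIVE, "I": INACTIVE})
    # candidates 0.9 and 0.8 both misclassify exactly one compound
    # (B and I respectively); the tie goes to the larger candidate
    coeffs = {"A": 0.9, "B": 0.8, "I": 0.85}
    assert select_threshold(coeffs, labeled) == 0.9


# ------------------------------------------------------------------- train

def test_train_on_separable_fixture(small_world):
    _, _, _, task, _, resources = small_world
    spec = MetricSpec("LF", "simUI", "all", 0.5)
    model = train(task.labels, spec, resources)
    miscls = sum(
        (model.training_coefficients[c] >= model.tau)
        != (task.labels.labels[c] == ACTIVE)
        for c in task.labels.labels
    )
    assert miscls == 0
    assert model.tau in model.training_coefficients.values()


def test_train_with_actives_only_is_all_active(small_world):
    _, _, _, task, _, resources = small_world
    actives = LabeledSet({c: ACTIVE for c in task.labels.actives[:4]})
    model = train(actives, MetricSpec("LF", "simUI", "all", 0.5), resources)
    assert model.tau == min(model.training_coefficients.values())


def test_train_propagates_scoring_error(small_world):
    _, _, _, task, _, resources = small_world
    labels = dict(task.labels.labels)
    labels["SYN:ghost"] = INACTIVE
    with pytest.raises(ScoringError, match="ghost"):
        train(LabeledSet(labels), MetricSpec("LF", "simUI", "all", 0.5), resources)


def test_selected_tau_is_optimal_for_trained_models(small_world, world):
    for bundle, spec_text in [
        (small_world[3], "LF,simUI,all,0.5"),
        (world[2], "PAT-A,simGIC,structure,0.29"),
    ]:
        resources = small_world[5] if bundle is small_world[3] else world[4]
        model = train(bundle.labels, MetricSpec.from_string(spec_text), resources)
        coeffs = model.training_coefficients
        selected_mis = sum(
            (coeffs[c] >= model.tau) != (bundle.labels.labels[c] == ACTIVE)
            for c in coeffs
        )
        for cand in coeffs.values():
            mis = sum(
                (coeffs[c] >= cand) != (bundle.labels.labels[c] == ACTIVE)
                for c in coeffs
            )
            assert mis >= selected_mis


# ----------------------------------------------------------------- predict

def test_predict_at_threshold_is_active(small_world):
    _, _, _, task, _, resources = small_world
    model = train(task.labels, MetricSpec("LF", "simUI", "all", 0.5), resources)
    # the training compound whose coefficient equals tau must be active
    at_tau = [c for c, v in model.training_coefficients.items() if v == model.tau]
    label, coeff = predict(model, at_tau[0], resources)
    assert coeff == pytest.approx(model.tau)
    assert label == ACTIVE


def test_predict_model_active_excludes_self(small_world):
    _, _, _, task, _, resources = small_world
    model = train(task.labels, MetricSpec("LF", "simUI", "all", 0.5), resources)
    for cid in model.actives[:3]:
        assert activity_coefficient(model, cid, resources) == pytest.approx(
            model.training_coefficients[cid]
        )


def test_inactives_only_move_the_threshold():
    # perturbing inactive-set similarities must not change any coefficient
    # of other compounds, only (possibly) tau
    labeled = LabeledSet(
        {"A": ACTIVE, "B": ACTIVE, "C": ACTIVE, "I1": INACTIVE, "I2": INACTIVE}
    )
    base = {}
    for a, b in itertools.combinations(sorted(labeled.labels), 2):
        base[(a, b)] = 0.5
    base[("A", "B")] = base[("A", "C")] = base[("B", "C")] = 0.9
    perturbed = dict(base)
    perturbed[("A", "I1")] = 0.95
    perturbed[("B", "I2")] = 0.05
    c0 = training_coefficients(sims_from(base), labeled)
    c1 = training_coefficients(sims_from(perturbed), labeled)
    for cid in ("A", "B", "C"):
        assert c0[cid] == c1[cid]


# -------------------------------------------------------------------- rank

def test_rank_actives_matches_training_coefficients(small_world):
    _, _, _, task, _, resources = small_world
    model = train(task.labels, MetricSpec("LF", "simUI", "all", 0.5), resources)
    ranked = dict(rank_candidates(model, model.actives, resources))
    for cid in model.actives:
        assert ranked[cid] == pytest.approx(model.training_coefficients[cid])


def test_rank_single_candidate(small_world):
    _, _, _, task, _, resources = small_world
    model = train(task.labels, MetricSpec("LF", "simUI", "all", 0.5), resources)
    out = rank_candidates(model, [model.actives[0]], resources)
    assert len(out) == 1


def test_rank_ties_break_by_id_and_skips_unscoreable(small_world):
    _, _, _, task, _, resources = small_world
    model = train(task.labels, MetricSpec("LF", "simUI", "all", 0.5), resources)
    a, b = sorted(model.actives[:2])
    ranked = rank_candidates(model, [b, a, "SYN:ghost"], resources)
    assert len(ranked) == 2  # ghost skipped, not fatal
    if ranked[0][1] == ranked[1][1]:
        assert [r[0] for r in ranked] == sorted([a, b])
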