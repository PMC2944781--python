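"""Shared fixtures: one default synthetic world, built once per session."""

import pytest

from chym.evaluation import PairwiseCache
from chym.ic import build_ic_table
from chym.metric import build_resources
from chym.synthetic import (
    FixtureConfig,
    generate_corpus,
    generate_ontology,
    generate_task,
)


@pytest.fixture(scope="session")
def default_config():
    return FixtureConfig()


@pytest.fixture(scope="session")
def world(default_config):
    """(syn, corpus, task, ic, resources) under the default conditions."""
    syn = generate_ontology(default_config)
    corpus = generate_corpus(syn, default_config)
    task = generate_task(syn, corpus, default_config)
    ic = build_ic_table(corpus, syn.graph)
    resources = build_resources(syn.graph, task.structures, ic=ic)
    return syn, corpus, task, ic, resources


@pytest.fixture(scope="session")
def pairwise_cache(world):
    _, _, task, _, resources = world
    return PairwiseCache(resources, sorted(task.labels.labels))


@pytest.fixture(scope="session")
def small_world():
    """A separable toy task (both signals deterministic, 10+10 compounds)."""
    cfg = FixtureConfig(
        seed=5,
        n_terms=120,
        n_active=10,
        n_inactive=10,
        structural_signal=1.0,
        semantic_signal=1.0,
    )
    syn = generate_ontology(cfg)
    corpus = generate_corpus(syn, cfg)
    task = generate_task(syn, corpus, cfg)
    ic = build_ic_table(corpus, syn.graph)
    resources = build_resources(syn.graph, task.structures, ic=ic)
    return cfg, syn, corpus, task, ic, resources
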