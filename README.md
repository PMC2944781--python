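# chym

Hybrid structural/semantic similarity for chemical compounds, and a
similarity-threshold classifier for predicting compound activity
(blood–brain-barrier permeability, transporter substrates, receptor
binding and similar binary properties).

Purely structural comparison — fingerprints scored with the
Jaccard-Tanimoto coefficient — misses activity shared by structurally
dissimilar molecules. When compounds are annotated in a ChEBI-style
ontology, their *semantic* similarity (how much classification they
share) carries complementary information. `chym` implements the hybrid
metric

```
sim(c1, c2) = α · simstruct(c1, c2) + (1 − α) · simsem(c1, c2),   α ∈ [0, 1]
```

where

* `simstruct` is the Tanimoto coefficient `N(A∧B) / N(A∨B)` over bit-vector
  fingerprints — either a hashed linear-fragment fingerprint (`LF`: every
  non-branched fragment of ≤ 7 atoms hashed into 1021 bits) or one of two
  SMARTS structural-key sets (`PAT-A`, `PAT-B`);
* `simsem` is either **simUI** = `|Anc(c1) ∩ Anc(c2)| / |Anc(c1) ∪ Anc(c2)|`
  over the reflexive ancestor sets in a normalized ontology DAG, or
  **simGIC**, the same ratio with each ancestor term `t` weighted by its
  information content `IC(t) = −log p(t)`, where `p(t)` is the fraction of
  pathways in an annotation corpus containing `t` or any of its descendants.

The ontology is normalized into four DAGs (the structure, role and
subatomic branches, plus their merge), giving 3 formats × 2 methods ×
4 branches = **24 metric families**, each with the continuous weight α.

On top of the metric sits a threshold classifier: every training
compound receives an *activity coefficient* — its mean similarity to the
active training compounds, self-comparison excluded — and the
coefficient that minimizes training misclassifications becomes the
activity threshold τ. A compound is predicted active iff its
coefficient ≥ τ. Validation machinery includes leave-multiple-out
(LMO25: 25 + 25 held out, repeated), repeated stratified k-fold CV,
MCC/accuracy scoring and a full grid search over 24 × 101 candidate
metrics.

A first-class synthetic-fixture module generates ChEBI-like ontologies,
pathway corpora, molecules and labeled tasks with controllable
structural and semantic signal, so everything builds and validates with
no external downloads.

## Worked example

```python
from chym import (
    FixtureConfig, generate_ontology, generate_corpus, generate_task,
    build_ic_table, build_resources, MetricSpec, compound_similarity,
    train, predict, grid_search,
)

cfg = FixtureConfig(seed=0)          # ~250-term ontology, 40 actives / 40 inactives
syn = generate_ontology(cfg)
corpus = generate_corpus(syn, cfg)
task = generate_task(syn, corpus, cfg)
ic = build_ic_table(corpus, syn.graph)
resources = build_resources(syn.graph, task.structures, ic=ic)

spec = MetricSpec("LF", "simGIC", "all", 0.29)
a, b = task.labels.actives[:2]
print(f"sim({a}, {b}) = {compound_similarity(a, b, spec, resources):.3f}")

model = train(task.labels, spec, resources)
print(f"threshold tau = {model.tau:.3f}")
label, coeff = predict(model, task.labels.inactives[0], resources)
print(f"{task.labels.inactives[0]}: {label} (coefficient {coeff:.3f})")

result = grid_search(task.labels, resources, protocol="kfold", seed=0, repeats=3)
print(f"best metric: {result.best_spec.to_string()}")
print(f"mean MCC = {result.best_result.mean_mcc:.3f}, "
      f"mean accuracy = {result.best_result.mean_accuracy:.3f}")
```

prints

```
sim(SYN:0048, SYN:0049) = 0.211
threshold tau = 0.104
SYN:0051: inactive (coefficient 0.066)
best metric: PAT-B,simUI,all,0.34
mean MCC = 0.955, mean accuracy = 0.975
```

The pair similarity 0.211 combines Tanimoto and IC-weighted semantic
similarity at α = 0.29 (29 % weight on structure). The trained model
calls a compound active when its mean similarity to the training actives
reaches τ = 0.104. The grid search recovers the planted task signal:
the best metric mixes both components (α strictly between 0 and 1) and
reaches a mean Matthews correlation of 0.955 under 10-fold CV —
better than either the purely structural (α = 1) or purely semantic
(α = 0) ends of the same family.

The same pipeline is scriptable from the shell; `chym gen-fixtures`
writes a complete fixture tree (OBO ontology, structure/corpus/xref
TSVs, labeled set, YAML config) and the other subcommands (`sim`,
`train`, `classify`, `validate`, `grid`, `rank`, `map-names`,
`build-resources`) consume it or any real data in the same formats:

```
chym gen-fixtures --seed 0 --out fixtures/
chym grid --config fixtures/config.yaml --out grid.tsv --repeats 3
```

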