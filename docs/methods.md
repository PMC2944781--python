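# Methods

## The hybrid metric

`chym` scores a compound pair as the convex combination
`α·s_struct + (1−α)·s_sem` of two similarities that live on [0, 1].
α multiplies the *structural* component: α = 1 degenerates to pure
fingerprint comparison, α = 0 to pure ontology comparison. A metric is
fully identified by four parameters — fingerprint format, semantic
method, ontology branch, α — serialized as e.g. `PAT-A,simGIC,all,0.29`.
Because each component is bounded by [0, 1], the hybrid score is too,
and it is monotone in both components.

### Structural similarity

Structures are parsed with RDKit; when a compound carries several
records, SMILES is preferred over MDL (InChI records are never used —
in curated collections any compound with an InChI carries another
format too, so nothing is lost and one parser dialect is avoided).
Similarity is the Jaccard-Tanimoto coefficient over bit vectors; it is
defined only between fingerprints of the same format and length, and a
pair of all-zero fingerprints is an error rather than a silent 0.

Three formats are provided:

* **LF** — a hashed linear-fragment fingerprint. All non-branched
  fragments — simple paths and simple rings — of up to 7 atoms are
  enumerated, written as canonical token strings (element symbols,
  lower-cased when aromatic, joined by bond-order tokens `-`, `=`, `#`,
  `:`; paths take the lexicographically smaller traversal direction,
  rings the minimum over rotations and reflections with the closure
  bond appended and an `@` prefix), and each fragment sets bit
  `FNV1a32(string) mod 1021`. This is a deliberate, fully documented
  dialect of the classic Daylight-style path fingerprint: the hash, the
  canonicalization and the inclusion of single-atom fragments are
  pinned here so results are bit-reproducible across platforms, and no
  compatibility with any external toolkit's bit assignment is claimed.
* **PAT-A / PAT-B** — structural-key fingerprints: one bit per SMARTS
  pattern, set when the pattern matches at least once. The two shipped
  pattern files (`src/chym/data/*.smarts`) are curated in-house sets —
  set A covers broad functional groups, set B ring systems and
  heteroatom environments — standing in the roles the two classic
  pattern-file formats play; user-supplied pattern files are accepted
  anywhere a built-in set is.

### Ontology normalization

OBO input is parsed with `obonet` (plus a pre-scan that reports the
line number of a `[Term]` stanza lacking an id). Normalization then:

* drops obsolete terms;
* merges alternate ids, and stanzas whose canonical structure text is
  byte-identical, into one node (canonical id = numerically lowest, the
  older and typically better-curated entry);
* removes the symmetric/cyclic relationship types — by default
  `is tautomer of`, `is conjugate base of`, `is conjugate acid of`,
  `is enantiomer of` (configurable) — and merges every remaining
  relation into a single "is a"-like edge oriented source→target,
  child below parent. For `has part` this orientation already places
  the part above the whole (glucose *has part* electron ⇒ electron is
  an ancestor of glucose, so glucose reaches the subatomic branch); an
  `inverted_relations` hook exists for ontologies whose relation
  directions run the other way, and is empty by default.
* verifies acyclicity: a residual cycle raises an error naming one
  offending cycle rather than being broken silently.

Branch membership is reachability: a node belongs to the structure,
role or subatomic branch iff it reaches that branch's configured root.
`extract_branch` returns the vertex-induced subgraph; `all` is the
untouched merged DAG. Ancestor sets (`Anc(c)`, always reflexive) are
cached per graph; the cache is a pure memoization of the reachability
closure and changes no result.

### Semantic similarity

* **simUI** = |Anc(c1) ∩ Anc(c2)| / |Anc(c1) ∪ Anc(c2)|.
* **simGIC** = Σ IC over the intersection / Σ IC over the union.

Both are symmetric and bounded by [0, 1] since an intersection is a
subset of the union. Branch restriction is implemented by computing
ancestor sets inside the branch subgraph; scoring a term outside the
branch raises a scoped-term error, which the higher layers surface as a
scoring error naming the compound.

Information content comes from a pathway-annotation corpus: `p(t)` is
the fraction of pathways containing `t` or any descendant of `t`
(occurrences propagate child→parent in one topological pass), and
`IC(t) = −ln p(t)`. Conventions chosen where a choice had to be made:

* *Log base*: natural. simGIC is a ratio of IC sums, so any base change
  rescales numerator and denominator by the same constant — the choice
  is provably cosmetic and is covered by a test.
* *Unannotated terms* (`p = 0`): weight 0 in simGIC sums, equivalent to
  excluding them, instead of an infinite IC. If an entire ancestor
  union has zero weight the ratio is undefined (0/0) and a degenerate-IC
  error is raised; this includes the self-similarity of a term whose
  every ancestor is unannotated.
* *IC table scope*: computed once on the merged DAG and reused for
  branch-restricted metrics (the sums are restricted to branch
  ancestors implicitly). Recomputing per branch would only rescale
  occurrence counts that are identical on the shared nodes.
* Cross-reference resolution is deliberately permissive: a term is
  annotated to a pathway if *any* of its external references occurs
  there (references are many-to-many in both directions), and external
  ids with no reverse mapping are counted and logged, not fatal.
* A pathway counts once per term (set semantics), not once per
  occurrence.

## The activity classifier

Training on a labeled set (≥ 2 actives required, since an active's
self-comparison is excluded):

1. every training compound's *activity coefficient* is its unweighted
   mean similarity to the active training compounds — for an active,
   excluding itself (that comparison is always 1 and would bias the
   mean);
2. every computed coefficient (actives' and inactives') is tried as a
   threshold, classifying a compound active iff coefficient ≥
   candidate; the candidate minimizing *training* misclassifications is
   τ. Ties go to the largest minimizing candidate — the most
   conservative rule toward calling "active". The minimization is over
   the training set: minimizing over held-out data would leak labels
   into the model.
3. prediction: coefficient against the model's actives (a compound that
   is itself a model active keeps the self-exclusion), active iff
   coefficient ≥ τ — the boundary case is active by definition.

Inactive training compounds therefore influence only τ, never the
coefficient of any other compound; a test perturbs inactive-side
similarities and verifies exactly that. Ranking a candidate list orders
by descending coefficient with ties broken by ascending numeric id, and
skips (with a logged count) candidates that cannot be scored.

## Validation

* **LMO25**: per repeat, 25 actives + 25 inactives are removed as the
  test set, the model is trained on the remainder and scored on the
  holdout; 30 repeats by default, means reported.
* **Repeated stratified k-fold** (k = 10 default): fold assignment via
  scikit-learn's stratified splitter; per-fold accuracy/MCC are averaged
  within a repeat, then across repeats (10 repeats by default for a
  single metric).
* **MCC** uses the standard formula with the usual convention that a
  zero factor in the denominator yields 0.
* **Grid search** evaluates all 24 families × the inclusive α grid
  (step 0.01 → 101 values, 2424 candidates) on *shared* splits, reports
  the argmax by mean MCC (ties: lower α, then family enumeration order)
  and the full table, written sorted by MCC descending. Families that
  cannot be scored for a dataset (e.g. a branch without IC signal)
  appear as failed rows, not fatal errors. The grid default is 3
  repeats of 10-fold per candidate — grid selection is a ranking task
  and stabilizes quickly, while single-metric validation keeps the
  10-repeat default.

For speed the evaluator precomputes, per family, the pairwise
structural and semantic matrices over the dataset once (the hybrid
matrix for any α is then a linear blend) and scores each split with a
vectorized re-expression of the classifier. The vectorized route is
pinned to the reference classifier implementation by a test that runs
both on the same split and requires identical confusion counts; the
same τ tie-break is implemented in both. All stochastic procedures
draw from `numpy` generators seeded from their `seed` argument
(repeat-level seeds derived through `SeedSequence`) and are bitwise
reproducible.

## Name mapping

Literature activity lists carry names, not structures. A name is
reduced to a bag of words — maximal runs of letters or of digits after
NFKD normalization, diacritic stripping and case folding — and matched
against preferred names and synonyms of ontology terms that have a
usable structure record. The default predicate is exact bag equality
(the strictest defensible reading of bag-of-words identity); a subset
mode (query bag contained in an indexed bag) is available behind a
flag. Ambiguity resolves to the numerically lowest id, older entries
being the better curated. Coverage (matched/total per label class) is
always reported.

## Synthetic fixtures

The generator produces the whole study environment from one seeded
config and writes it in the exact formats the real pipeline reads, so
every parser is exercised without downloads:

* **Ontology** (~250 terms by default): one root; three branch roots;
  a structure scaffold of 4 top classes, each a depth-3 class hierarchy;
  ~190 compound leaves, each attached to two class parents inside one
  top class (plus occasionally a third); role parents and a `has part`
  electron edge with probability `overlap` (default 0.9, echoing the
  ~92 % three-branch overlap of real chemical ontologies); a reciprocal
  tautomer pair, an obsolete stanza and an alternate id to exercise the
  normalizer.
* **Molecules**: valence-safe SMILES — random C/N/O/S single-bond
  chains with occasional methyl branches, an ester decoy group, and a
  15 % benzene appendage. Every generated string is unique (duplicate
  structure text would be merged by the normalizer, correctly but
  confusingly for fixtures).
* **Corpus** (40 pathways, mean size 12): each pathway anchors on one
  class and draws 70 % of members from that class's leaves, the rest
  uniformly, giving the sibling co-occurrence that makes IC increase
  with depth.
* **Task** (40 actives / 40 inactives at signal strengths 0.8/0.8 by
  default): a signal strength is the probability that the plant is
  applied, otherwise the compound falls back to the generic background.
  Actives are drawn from the leaves of one planted top-class subtree
  (strength `semantic_signal`, else uniformly — which can land inside
  by chance) and get a pyridylmethyl-amide motif spliced into their
  structure (strength `structural_signal`, else a generic molecule).
  Inactives avoid the subtree with probability `semantic_signal` (else
  uniform) and always receive generic, motif-free molecules. At
  strength 0 a signal is thus exactly uninformative; at strength 1 the
  planting is deterministic. Only leaves present in all three branches
  are eligible, so all 24 metric families can score the task. The
  motif is large enough (amide + aromatic-nitrogen ring) to light up
  many linear fragments and several structural keys, so all three
  fingerprint formats can see the structural signal.

What the fixtures do **not** emulate: real chemistry (no valence-true
generative model, no stereochemistry, no tautomers with structures),
real ontology depth (ChEBI is two orders of magnitude larger and far
more unbalanced), real annotation sparsity, or name noise. Passing the
recovery tests therefore shows that the pipeline's inference machinery
works when the data contain the kind of signal the method assumes — it
does not certify performance on any real activity dataset.

## Problem sizes and numerical conventions

The default test fixture (≈250 terms, 80 task compounds) makes a full
24 × 101 grid with 3 repeats of 10-fold CV run in seconds, which is the
scale the test suite and the acceptance script use. Stated tolerances:
exact-arithmetic identities (oracle equivalence, base invariance,
symmetry) are checked at 1e-12; statistical outcomes (planted-signal
recovery, label-shuffle null) at the thresholds their tests state.
Degenerate inputs fail loudly by design: empty corpora, all-zero
fingerprint pairs, zero-IC unions, single-active training sets and
out-of-branch terms each have a dedicated error type rather than a
fallback value.
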