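# Methods

## Data model and assumptions

An ontology is a directed graph of classes (id, label, synonym list) with
parent→child edges. Well-formed inputs are DAGs, but nothing is assumed:
cycles and disconnected branches are tolerated in storage (BFS uses
visited sets), self-loops and duplicate edges are dropped on insertion.
Only subclass/development edges carry meaning; OWL axioms beyond named
subclass relations are ignored on read.

Window-W subgraph extraction performs two *separate* directed BFS sweeps —
ancestors within W and descendants within W — and unions them.
Mixed-direction paths are deliberately not followed: at W = 1 they would
already pull in siblings, inflating every subgraph beyond "upstream and
downstream relatives". Node order inside a subgraph is the generator
first, then ascending BFS distance, ties broken lexicographically by class
id; this fixes the adjacency matrices (and therefore every structure
score) across runs and platforms. The shortest path from a subgraph
member to its generator is its BFS distance in the orientation that
reached it, so it is always ≤ W; whether a descendant could reach the
generator more cheaply through paths outside the window is not considered.

## Name mapping

The edit distance is the classic unit-cost dynamic programme; the scaled
similarity 1 − lev/max(len) is computed on the post-preprocessing strings
(labels are lowercased there; the matcher itself is byte-exact on NFC
Unicode). Two empty strings are defined identical (similarity 1, logged).
With synonyms enabled, the maximum over all pairings of the two name lists
(label + synonyms) is used, which can only raise entries. The full a×b
matrix is materialised: local name confirmation later averages arbitrary
entries, so no pruning is possible. Bulk construction dispatches each
pair to edlib when importable (same values, C speed) and falls back to the
in-package DP; identical strings short-circuit to 1.

## Structure mapping

Generator nodes are exactly the classes left unassigned by name mapping,
on both sides.

**Vectorial (cosine / euclidean / pearson).** Adjacency rows of unequal
lengths are compared by sliding the shorter row over the longer one at all
nc = |a − b| + 1 offsets and keeping the best offset. Per-window
conventions chosen to keep all metrics on one [0,1] threshold scale:

* cosine — the cosine of the two binary vectors; two all-zero vectors
  score 1, exactly one all-zero scores 0;
* euclidean — converted by sim = 1 − d/√L (L = window length), since √L
  is the maximum distance between binary vectors of that length;
* pearson — the correlation coefficient clamped to [0,1]; zero-variance
  windows are undefined, so two identical constant windows score 1 and
  anything else 0.

The per-row-pair maxima p(k,l) are reduced to one subgraph score as the
average of the row-wise and column-wise means of maxima, restricted to
structure-bearing (non-all-zero) rows. The restriction matters: adjacency
rows of leaves are all zero, and counting their trivial agreement with
all-zero windows would score edgeless regions as perfect structure. Under
extraction, a subgraph with ≥ 2 members always has ≥ 1 edge, so both sides
all-zero means two single-node windows (score 1); one side all-zero
against real structure scores 0. This aggregation is symmetric in the two
subgraphs, equals 1 for identical subgraphs, and penalises size mismatch.
The reduction from per-row maxima to a scalar is a genuinely open design
point; the symmetric mean was chosen and is the one place where another
convention could defensibly differ.

**Constraint-based.** Assumes name matches are trustworthy. Every
A-subgraph node whose best name similarity against the B subgraph exceeds
θ_N contributes c = W + 1 − s (s = distance to the generator); the sum is
normalised by (min(|A_W|, |B_W|) − 1)·W — the value attained when every
non-generator node of the smaller subgraph matches at distance 1 — and
capped at 1. No matched pair at all gives 0.

**Blondel.** T_0 = all-ones, update
T ← (B̃ T Ã^t + B̃^t T Ã)/‖·‖_F, convergence checked only at even steps
(the raw iteration is 2-periodic in general) with tolerance 1e−6, cap 100
iterations; the returned score is the entry pairing the two generators
(both sit at index 0 of their node orders). Edgeless×edgeless degenerates
as in the vectorial case.

Structure-matrix entries are independent; `--threads N` computes rows in a
process pool with an order-preserving map, so parallel output is
bit-identical to serial.

## Alignment cascade and merging

Per A class: best name candidate (argmax over S, ties to the smallest B
id); strictly greater than θ_N ⇒ Name match. Otherwise the best structure
candidate among name-unmatched B classes; T ≥ θ_T *and* local-name mean
strictly greater than θ_LN ⇒ Structure match. When several B candidates
tie exactly at the maximal T (frequent for small isomorphic subgraphs),
they are tried in id order and the first to pass local-name confirmation
wins — a deterministic completion of the argmax that the confirmation step
makes meaningful. The inequality senses (strict for θ_N and θ_LN,
non-strict for θ_T) are intentional and tested.

Matching is greedy per A class and many-to-one: several A classes may
share one B partner. During merging each matched B class folds into its
single best-scoring A partner (ties by id) — replicating its relations
onto every partner would invent relations absent from both inputs. Labels
and synonyms of matched B classes become synonyms of the partner, which
makes re-fusion idempotent: fusing the merged result with B again adds
nothing. Unmatched B classes get fresh ids ("B:" + zero-padded counter,
collision-checked), and all B relations are re-expressed in merged ids and
added once. Class counts obey |merged| = |A| + |B| − |distinct matched B|.

## Parameters

| parameter | default | meaning |
|---|---|---|
| W | 4 | subgraph window, in edges; small W makes subgraphs isomorphic too easily, large W merges unrelated regions |
| θ_N | 0.85 | name-match threshold; at ~0.85 orthographic variants ("s" endings, apostrophes) still match |
| θ_T | 0.7 | structure-score threshold (no canonical value; aligned with θ_LN, user-set per run) |
| θ_LN | 0.7 | local-name confirmation threshold; below θ_N because neighbour labels vary more than the class's own |
| metric | cosine | the vectorial metrics are the fast choice; cosine and pearson behave near-identically, blondel is the slow reference |
| use_synonyms | true | maximise name similarity over synonym lists |

Blondel: tol 1e−6, max_iter 100 (even). Configuration files are flat
`key = value` text with `#` comments and comma-separated lists (the
original tool's format is not published; this dialect is this package's
own).

## Synthetic data

The generator emulates the situation the tool targets: two ontologies
sharing a conceptual backbone but diverging in names and local structure.
`generate_base` grows a rooted tree (Poisson child counts, mean 1.6 —
roughly the ~1.1 relations-per-class ratio of real cell-development
hierarchies) with globally unique 2–4-word labels from a cell-biology-like
vocabulary; ~30% of classes carry 1–2 synonyms. `derive_variant` perturbs
it with per-character label edits restricted to word-internal positions
(so token structure survives normalisation, like real orthographic
variation), class drops with parent→grandchild rewiring, grafted novel
subtrees, and label↔synonym swaps. Truth maps every surviving backbone
class to its twin; grafted classes never enter truth.

`standard_pair` fixes the benchmark conditions: 300 classes, edit rate
0.12 (measured mean label similarity between twins ≈ 0.88–0.89 — the
word-initial exclusion keeps the effective rate below nominal), grafts
≈ 10% of the backbone, swap rate 0.2, no drops. All randomness flows from
one seeded numpy generator; identical seed ⇒ byte-identical pair.

What passing on synthetic data does *not* show: real ontologies have
correlated, domain-structured label divergence (abbreviations, word-order
swaps, semantic synonyms), hub classes with very high degree, and
many-to-one concept granularity differences. The generator's uniform
character edits and tree-shaped backbones are easier than that, so
synthetic precision/recall (~0.95) should be read as an upper bound on
real-data behaviour, not an estimate of it.

## Problem sizes and budgets

Tests and the reproduction script run at 300-class pairs (seconds per
fusion) and 20–50 seed replicates — sizes chosen so the full suite stays
interactive while every stage (name matrix, structure matrix, cascade,
merge, evaluation) is exercised end-to-end. The packaged fixture pair has
60/62 classes.

## Known limitations

* No semantic resources (WordNet/UMLS): matching is purely orthographic
  plus structural, by design.
* Greedy per-node matching; no global one-to-one assignment optimisation.
* The merged graph is not repaired beyond de-duplication (no cycle
  breaking or consistency checking).
* ODS reading covers flat first-sheet string tables only.
* The HTML report's circular DAG is a static SVG with hover titles, capped
  at 2000 nodes (summary-only above).
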