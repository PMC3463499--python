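# Methods

## The network model

A regulatory network over genes (or microarray probes) is a mixed graph
stored as one square adjacency matrix. Entry (*i*, *j*) describes the
ordered pair (target *i*, source *j*): `+1` directed edge (*j* regulates
*i*), `-1` undirected interaction, `0` evidenced non-interaction, `NaN`
unknown. Two conventions follow from this encoding and are enforced as
invariants everywhere: undirected entries are stored symmetrically (one
undirected edge occupies two cells), and an ordered pair can never be
directed and undirected at once. The distinction between `0` and unknown is
load-bearing: assessment only scores pairs about which both networks make a
statement, so a model's *prediction count* is the number of pairs it commits
to, not the matrix size.

Self-regulation is excluded from gene-level networks: the knockdown designs
that produce the evidence cannot detect auto-regulation, so the diagonal is
forced to `0` in gold-standard construction and after probe collapse, and
the diagonal is excluded from path length, degrees, motifs and every
assessment domain. Probe-level matrices may carry diagonal entries
(the inference stages can propose them) but the combiners discard them.

## Knowledge-driven construction

`classify_evidence` maps one evidence record — perturbation Z-score
significance `sig`, fold-change magnitude `mag`, yeast one-hybrid count
`y1h`, signed genetic-interaction count `gen` — to an edge call, evaluating
the rule predicates in priority order (+1, then −1, then 0, else unknown).
A record can satisfy the directed and the undirected predicate
simultaneously (e.g. `gen = 3`); directed evidence is strictly more
informative, so the directed call wins. The same priority resolves the
reverse-pair conflict where pair (*i*, *j*) calls −1 while (*j*, *i*) calls
+1: the directed edge is kept and the undirected mark dropped with a
warning. The `gen` sign convention is positive = directional
expression-change reports, negative = non-directional synthetic-interaction
reports; the table reader also accepts split
`gen_directional`/`gen_nondirectional` columns. The one-hybrid clause is
read as "at least one hit" with a strict-equality switch (`y1h_exact`).
A missing evidence row leaves the pair unknown — an explicit all-zero record
is required for a non-interaction call.

Curated-model encoding (`encode_knowledge_model`) turns a directed edge
list plus phase and tissue annotations into a network where structurally
impossible pairs become explicit non-interactions: a gene of a later
expression phase cannot regulate one of an earlier phase, and
transcription-factor genes of opposite tissues (ectoderm vs mesoderm)
cannot regulate each other. An edge that is both asserted and blocked is a
contradiction and rejected.

## Data-driven inference

**Discretization.** Each probe is discretized independently into at most
*q* states (default *q* = 7, the value used for the motivating data set).
The default method is equal-frequency binning; when a probe has ≤ *q*
distinct values each value gets its own state in value order, which makes
discretization an exact inverse of the synthetic state-to-abundance map at
zero noise. Equal-width binning and single-link agglomerative merging of
value levels are selectable. Series are pooled into one binning by default
(`joint_series`), switchable to per-series bins.

**Transitions.** Consecutive time points within one series form
(input state vector, output state vector) pairs; transitions never cross a
series boundary, so *k* series of length *T* yield *k*(*T*−1) transitions.

**Minimal Sets Algorithm.** For a target, every pair of transitions with
different target outputs defines a *difference set* — the variables at
which the two inputs differ; any set of regulators able to explain the data
must intersect every difference set. The family of all subset-minimal
hitting sets is computed by incremental construction (absorb one difference
set at a time, extending the members that miss it and minimizing after each
step), which yields exactly the antichain of minimal hitting sets and is
verified in the tests against exhaustive subset enumeration. Identical
inputs with different outputs make the data inconsistent (possible after
discretization); the default is a hard error naming the colliding
transitions, with a lenient mode that drops the later transition.

**Model selection.** One candidate set per target is chosen by a
frequency-based score: the frequency of a variable is the fraction of the
target's minimal sets containing it, a set's raw score is the product of
its members' frequencies, normalized across the family. This scorer is a
reconstruction of the published frequency-scoring idea for minimal-sets
model selection (the original algorithm's exact definition was not
available); it is pluggable, and the provenance log records every family,
score and choice so a different scorer can be audited. Ties prefer smaller
sets; residual ties mean the data cannot distinguish the candidates at all
and are resolved uniformly at random from the pipeline seed (a lexicographic
fallback exists when no RNG is supplied). The seeded choice avoids
systematically concentrating arbitrary edges on low-index nodes, at the cost
of making the seed part of the experiment record. Before scoring, candidate
sets that violate the no-crosstalk constraint (an ectoderm variable
regulating a mesoderm target or vice versa) are discarded — unless every
candidate violates it, in which case the constraint is relaxed for that
target with a warning.

**Covariance coupling.** The sample variance-covariance matrix (*n*−1
divisor) is computed over all time points pooled across series; the
threshold is the median of the entire matrix including the diagonal, and
entries ≥ threshold become undirected couplings. Raw signed covariance is
compared by default (an absolute-value switch exists). The median threshold
necessarily marks at least half the matrix cells, so the covariance network
is dense by construction; its role in the pipeline is to couple probes that
move together (in particular multiple probes of one gene), not to be a
sparse estimator.

**Combination and collapse.** Both pipeline orders operate at probe level
and then collapse to genes. MSA-COV keeps every MSA directed edge and adds
an undirected coupling where covariance fires and neither direction is
claimed. COV-MSA lets covariance veto: a directed edge needs both the MSA
claim and the covariance coupling, hence its directed edges are always a
subset of MSA-COV's. Undirected self-loops are discarded in both. The
probe→gene collapse is by unanimity: a gene-pair entry is +1 (−1) only if
all probe-pair entries between the two probe sets are +1 (−1), else 0.

## Assessment

Confusion counting walks the ordered off-diagonal pairs of a domain,
skipping pairs unknown in either matrix. The core scheme: TP when the model
directs an edge the gold standard has (directed or undirected); TN when
both say non-interaction; HR ("half right") when the model leaves undirected
what the gold standard directs; FP for a claimed edge over a gold
non-interaction; FN for a missed gold edge. Two combinations are not fixed
by the core scheme and are policy-controlled, defaulting to: model −1 over
gold −1 is TP (both assert the same direction-free interaction) and model
−1 over gold 0 is FP; the alternative policy (`hr-halffp`) counts them HR
and half an FP. Counts are floats to keep fractional policies exact. An
unordered-pair mode merges the two cells of each pair by information
priority (+1 over −1 over 0 over unknown) and scores each pair once.

Rates use the half-right-weighted formulas above; a zero denominator yields
an explicit `None`, never a coerced number. Since each feature produces a
single classifier point rather than a curve, performance is the signed
perpendicular distance from the random-guess line: √2(TPR−FPR)/2 in ROC
space and √2(recall−1+precision)/2 in PR space, each bounded by ±√2/2 ≈
±0.707. The total distance sums both distances over the six feature domains
— Overall, P (pairs sourced at the designated master regulator), E(s)/M(s)
(both endpoints in the ectoderm/mesoderm module), E(w)/M(w) (at least one
endpoint) — with undefined points contributing 0 and flagged. The maximum
is 12/√2 ≈ 8.485, attained exactly by self-assessment of any gold standard
with at least one positive and one negative in every domain.

A caveat that matters for interpreting synthetic benchmarks: the PR
distance is signed against the anti-diagonal *y* = 1 − *x*, so a positive
contribution requires precision + recall > 1. Against a *fully known*
sparse gold standard (every non-edge an explicit 0), even a model far
better than random in ROC space tends to have negative PR distances,
because the dense scoreable negative set caps precision. Curated gold
standards that leave most pairs unknown restrict scoring to the
well-evidenced pairs and shift PR distances upward. Consequently the total
distance of a pipeline run against a fully-known synthetic truth is a
conservative measure and is frequently near or below zero even when the
directed predictions are substantially enriched for true edges; the test
suite documents the measured behavior rather than asserting an idealized
one.

## Synthetic ground truth

The generator emulates the study design the inference targets: a small
network (default module allotment 1 initiation / 3 ectoderm / 3 mesoderm /
2 mixed / 1 other at *n* = 10, scaled for other *n*) with independent
edge probability `density`, per-node update tables drawn uniformly over
*q*-state inputs of the node's parents, and a small number of independent
series (default 2, mirroring two genotypes profiled over one developmental
window) of *T* synchronous-update time points from random initial states.
States map affinely to abundances with configurable spacing plus Gaussian
noise. What it does *not* emulate: continuous kinetics, measurement-design
artifacts (dye bias, saturation), unequal series lengths, or missing
values. Passing tests therefore demonstrate algorithmic correctness and
recovery behavior under a clean finite-dynamics model, not robustness to
microarray noise structure.

Two practical properties of the dynamics are worth knowing. Nodes without
parents are constant after the first step, and sparse random-table systems
fall into fixed points within a few steps, so the informative portion of a
trajectory is its transient; at `density` = 0.15 the two default series
often contain only a handful of distinct states, which is the main driver
of variance in recovery benchmarks. The minimal-sets soundness guarantee
(some family member is always a subset of the true parent set on noise-free
data) holds regardless and is property-tested.

## Numerical and design choices

* Exact equality comparisons on adjacency entries (values are exactly
  representable); NaN marks unknown and is compared with `equal_nan`
  semantics in round-trips.
* Ties at the covariance median threshold are couplings (≥ comparison).
* Path length on mixed graphs traverses undirected edges both ways and
  excludes unreachable pairs from the mean by default (counting them as
  |nodes| is available); degrees count directed edges only by default, with
  undirected degrees reported separately and an opt-in to count them both
  ways. Hubs are nodes with out-degree strictly greater than half the node
  count.
* Motifs are enumerated over directed edges only: 2-cycles, feedforward
  loops (a→b→c with shortcut a→c, reported as the role-ordered triple) and
  3-node feedback loops (reported once, rotated to their lowest-index node).
* All randomness flows through `numpy.random.default_rng` seeds; every
  generator and the pipeline are bit-reproducible for a fixed seed, and the
  seed is recorded in provenance.
* Benchmarks in the test suite are sized to run on one CPU in seconds to a
  few minutes: oracle suites use networks of ≤ 21 nodes and hitting-set
  instances of ≤ 10 variables; recovery uses 50 replicates of the
  n = 10, T = 20, 2-series configuration.

## Known limitations

* The minimal-sets scorer is a reconstruction, not the published algorithm;
  rankings may differ on families where the product-of-frequencies score
  ties or disagrees with the original.
* The covariance stage has no sparsification beyond the median threshold;
  on single-probe-per-gene data it contributes many couplings, and the
  half of those landing on known non-edges dominates FPR (see the
  assessment caveat above).
* Unordered-pair assessment uses a priority merge of the two cells, which
  is one of several defensible conventions; counts in that mode should not
  be compared against ordered-mode counts.
* The evidence reader accepts spreadsheet workbooks only when spreadsheet
  support (openpyxl) is installed; delimited text is the canonical format.
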