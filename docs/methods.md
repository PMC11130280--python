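# Methods

## Scope and model

`hcicnet` ranks nodes of a simple undirected graph by combining a local
structural-hole score with a global shell-and-tenacity score, and
evaluates rankers by static targeted attack. Graphs are unweighted and
undirected; self-loops and duplicate edges in input files are normalized
away with a warning, because every formula below assumes
$a_{ii}=0,\;a_{ij}=a_{ji}\in\{0,1\}$. Node labels are opaque strings
(dataset files mix 0/1-based integer ids and names; nothing here should
depend on the spelling of a label).

## Local coefficient (WNCC)

The constraint coefficient sums, over neighbors $j$, the squared total
investment $p_{ij}+\sum_l p_{il}p_{lj}$ that node $i$ places in $j$
directly and through common neighbors ($p_{ij}=a_{ij}/k_i$). The
weak-tie weight of an edge,

$$w_{ij}=\frac{S_{ij}\sqrt{(k_i-1)(k_j-1)}+1}{|\Gamma(i)\cup\Gamma(j)|-1},$$

is defined for adjacent pairs only, is symmetric and strictly positive.
Two conventions needed fixing:

* **Union denominator.** $\Gamma$ is the open neighborhood, the union is
  taken literally, and exactly 1 is subtracted. For adjacent $i,j$ the
  union contains both endpoints, so the denominator is at least 1. This
  literal reading reproduces the full published worked-example WNCC
  column at 3 decimals; no alternative (subtracting both endpoints,
  excluding the endpoints from the union) is needed.
* **The $S_{ij}=0$ remark.** The source text asserts the numerator is 0
  when $S_{ij}=0$; it is in fact 1 (and must be, or every tie with no
  neighborhood overlap would zero out its constraint term). The formula
  is implemented as printed, numerator value 1.

**Isolated nodes.** $NCC$ and $WNCC$ are undefined at $k_i=0$; isolated
nodes receive the policy value 1.0 (the leaf / maximal-constraint value)
with a warning, so score tables stay total on the fragmented graphs that
attack experiments produce.

## Global coefficient (HTGC)

K-shell peeling is implemented directly (not delegated) because the
downstream KPD ranker needs per-sweep bookkeeping: within one KS round,
nodes of residual degree $\le KS$ are removed in recursive sweeps; a
node's strip order $l_i$ is the 1-based index of the sweep that removed
it, counted within its shell, and $l_{max}$ is the number of sweeps in
that shell. Within-sweep order is deliberately not broken — the
within-sweep sequence is not well defined, and sweep granularity is the
finest order that is. The networkx core-number routine serves as an
independent oracle in the tests.

The improved shell value uses the **original** degree $k_i$ and the
maximum **original** degree in the node's layer (both choices are forced
by the published worked-example IKS table, e.g. $3+6/7=3.857$ for the
core hub), with $KS_{i|next}$ the smallest larger shell present, or
$KS_i+1$ for the deepest layer. Shells can in principle skip integers;
the smallest-present-larger rule covers that case and is asserted by the
bracketing invariant $KS_i\le IKS_i<KS_{i|next}$.

Node tenacity counts isolated survivors as size-1 components (standard
component semantics; this is what makes $T=N$ for a leaf of a connected
$N$-node graph). Edge-set tenacity — a minimization over cut sets — is
provided only as a brute-force oracle guarded at 16 edges; the
minimization is NP-hard and the per-node form is what the ranking
pipeline uses. A cut set is a *minimal* disconnecting edge set;
minimality is checked on the maximal proper subsets only, which
suffices because deleting fewer edges can only be better connected.

**Printed-table rounding.** The published HTGC table divides tenacity by
the 3-decimal-rounded IKS (visible on the boundary nodes, where
$15/(17/7)=6.1765$ prints as 6.175, i.e. $15/2.429$). The library
computes the exact quotient; the transcription validator mirrors the
rounded-divisor convention when diffing against printed values. The two
agree within half an ulp of the printed precision everywhere else.

**Isolated nodes** have shell 0 and degree 0, hence $IKS=0$ and an
undefined quotient; they are assigned the largest finite HTGC in the
table (tying for least important), with a warning.

## Composite (HCIC)

Both coefficients are min–max normalized; a constant table maps to all
zeros (with a warning) rather than erroring, so vertex-transitive graphs
(cycles, cliques) still rank. The $1/(N-1)$ denominator factors are
implemented literally even though they cancel in ranking, for anyone
comparing raw values. Multiple nodes can legitimately share
$HCIC=0$ — any holder of a factor minimum; ties are preserved for the
monotonicity indicator and broken only for removal order, by ascending
node label.

## Benchmark rankers

DC, CI, WL, DWT, KPD, INCC and a seeded uniform-random ranker. Open
choices, each exposed as a knob:

* CI radius defaults to $l=2$, the smallest informative ball; the ball
  $set(i,l)$ contains nodes at distance $<l$ and excludes $i$ itself.
* DWT is oriented low-is-important: it is a constraint-style sum of
  $((1+S_{ij})/k_i)^2$ terms, structurally parallel to NCC.
* INCC is implemented with the inner sum over common neighbors nested
  inside the outer neighbor sum (the loose binding in the printed
  formula is resolved to the nested reading and not silently switched).

## Attack harness

The protocol is **static**: the ranking is computed once on the intact
graph; at each fraction $q$ the top $\lfloor qN\rfloor$ nodes (a
`round` variant is selectable — the convention is not standardized) are
removed from the original graph. Consequently $P_{Subset}$ and
$P_{Edges}$ are non-increasing along the grid, which the tests assert.
Sensitivity uses the susceptibility convention by default: the threshold
$\sigma$ equals the giant-component size, i.e. the sum runs over
non-giant components; a fixed integer $\sigma$ is accepted as well. The
default fraction grid is 0–0.5 in steps of 0.01.

## Fixtures and the synthetic generator

The two worked-example topologies are reconstructed from printed
constraints rather than copied from drawings: the per-node value tables
(constraint, tenacity, shell, improved shell), the stated degrees and
adjacencies, and the bridge/boundary roles pin the 15-node network's
edge set uniquely; the 17-node peeling example is pinned up to the
attachment of its degree-1 leaves (noted in the fixture file header).
`validate_transcription` gates each fixture on *standard* quantities
only — NCC, K-shell, tenacity — so a transcription error cannot be
masked by the novel metrics the fixtures exist to test. The cut-set
example graph is a synthetic stand-in built to satisfy the two stated
facts (one edge set is a minimal disconnecting set, the other leaves the
graph connected).

Synthetic test graphs come from seeded Erdős–Rényi, Barabási–Albert and
Watts–Strogatz generators — pure functions of (model, parameters,
seed). They exercise the metrics across sparse/dense, heavy-tailed and
clustered regimes, but they do not emulate the degree correlations,
community structure or bipartite motifs of real biological networks;
passing property tests shows formula correctness and invariance, not
field performance. Property tests run at modest sizes (10–60 nodes for
oracle agreement, 150–200 nodes for end-to-end attack runs), chosen so
the whole suite stays interactive while still covering multi-shell,
multi-component structure.

The seven large benchmark datasets are referenced only by an expected
$(N,M)$ manifest; nothing is bundled or downloaded. Given a
user-supplied edge-list or Matrix Market file, `hcicnet attack`
regenerates the published summary shape (indicator at 10% removal,
peak-sensitivity fraction, monotonicity) for any registry method.

## Known limitations

* Tenacity-based scores recompute components once per node ($O(N(N+M))$
  overall); fine up to a few $10^4$ edges, not tuned beyond that.
* Exact edge tenacity is exponential and guarded at 16 edges.
* Directed, weighted and multigraph inputs are out of scope.
* Single-node graphs cannot be ranked by the tenacity family.
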