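# Methods

## Model and definitions

All computations are on simple, unweighted, undirected graphs. Directed or
annotated inputs are reduced to this model before any metric runs:
reciprocal directed pairs collapse to one undirected edge, self-loops are
dropped (they never contribute to a geodesic between distinct nodes),
duplicate edges collapse, extra columns (edge weights, ratings,
timestamps) are ignored; every such decision is counted in a sanitize log.
Node labels are opaque strings preserved verbatim; a label→index map backs
the dense matrices internally and every output reports external labels.

**Distances.** The shortest-path distance matrix holds geodesic edge
counts from a breadth-first search at every source (`O(n·(n+m))` total).
Unreachable pairs carry an explicit marker, not a large sentinel value;
every consumer either excludes them (closeness, reciprocal connectivity)
or surfaces them (`inf` in text dumps).

**Global reciprocal connectivity.** `phi_c(G)` is half the sum of `1/d`
over ordered pairs of distinct nodes with finite distance. It is closely
related to the numerator of global network efficiency. The sum is
accumulated in exact rational arithmetic (`fractions.Fraction`), so a pair
at distance 3 contributes exactly 1/3; floats appear only at the API
boundary. This makes closed forms exact: on K_n the halved score is
n(n−1)/2, and dangling centrality on K_n is exactly 2/n.

**Dangling centrality.** `phi_c(i) = (phi_c(G) − phi_c(G_i)) / phi_c(G)`,
where `G_i` deletes the edges incident to node i but keeps the node. This
is observationally identical to node deletion for this score (a degree-0
node contributes no finite off-diagonal distances), but the
keep-the-node form matches the "degree forced to zero" framing and keeps
the node set stable across perturbations. Each perturbed graph gets a full
BFS recomputation — no incremental shortcuts in the reference path — and a
subset argument allows scoring only a prefix of nodes on large graphs.
Because the ratio is scale-free, the halving convention cancels between
numerator and denominator (asserted in the test suite). The metric is
undefined on an edgeless graph (division by zero) and raises explicitly.

## Classical-metric conventions

These deliberately differ from common library defaults; each choice is
pinned by a worked value in the test suite.

- **Degree**: raw incident-edge count, no normalization.
- **Closeness**: `1 / sum(finite distances)`, no `(n−1)` scaling.
  Unreachable pairs are excluded from the sum rather than zeroing the
  whole node — a documented extension, since the worked examples are all
  connected; a node with no finite distances scores 0.
- **Betweenness**: geodesic-fraction sums over *ordered* source–target
  pairs, endpoints excluded, unnormalized — exactly twice the Freeman
  value. Implemented as Brandes' two-pass BFS accumulation (each
  unordered pair is visited once per endpoint-as-source, which doubles
  the total automatically); an independent Brandes implementation
  (networkx, unnormalized) cross-checks at ×2 on random graphs.
- **Eigenvector**: power iteration from the all-ones vector, Euclidean
  normalization per step; λ is the Euclidean norm of the last
  pre-normalization product. A fixed-iteration mode exists to reproduce
  the tabulated iterates; the default mode iterates to a max-abs-change
  tolerance of 1e−10 with a 10,000-step cap and raises with diagnostics on
  non-convergence. Plain power iteration provably oscillates when the
  dominant eigenvalue is not strictly dominant in magnitude (bipartite
  spectra, tied components); convergence property tests therefore run on
  connected non-bipartite graphs, the method's mathematical domain, while
  the error path is tested on its own.
- **Katz**: direct solve of `(I − αAᵀ)x = β·1` (Aᵀ = A here). α ≥ 1/λ is
  rejected as divergent. The guard first applies the free bound
  λ ≤ max degree, so small α never triggers an eigen-computation; only
  borderline α consults the power method. Default α is 0.2 when
  0.2 < 1/λ (the worked choice), otherwise 0.85/λ, and the fallback is
  logged.

## Concordance

Pearson is the product-moment coefficient; Spearman is Pearson on
average ranks (ties share the mean of their rank positions); Kendall is
tau-b, `(C − D)/sqrt((n0 − t_x)(n0 − t_y))`. The tie conventions are not
arbitrary: on the five-node graph the degree/dangling Kendall value is
reproduced only by tau-b (7/√63 = 0.8819171), and the closeness/dangling
Spearman value is exactly 1 only with average ranks (nodes 1 and 2 tie in
both metrics). Coefficients are computed on raw metric values, never on
rounded displays; zero-variance input raises an explicit
undefined-coefficient error rather than returning NaN silently (the CLI
surfaces those per pair and keeps reporting the rest). Reports order
metrics DC, BC, CC, EVC, Katz with three methods each. Computation is
delegated to scipy.stats behind this interface; the tie-free closed
forms (1 − 6Σd²/(n(n²−1)); (C−D)/n0) are asserted as cross-checks.

## Synthetic graphs

The generator families (star, complete, path, cycle, Erdős–Rényi) exist
for property testing and closed-form checks, standing in for external
network datasets. The ER stream is fixed by contract: one uniform draw per
upper-triangle cell in row-major order from a seeded generator, so
(n, p, seed) identifies a graph byte-for-byte across runs. These graphs
exercise structure (hubs, leaves, regularity, disconnection, bipartite
spectra) but deliberately do not mimic the heavy-tailed degree
distributions of real co-purchasing or interaction networks — passing
tests demonstrate correctness of the algorithms, not field performance on
scale-free data.

## Numerical choices and problem sizes

- Printed-value comparisons use absolute tolerance 5e−5 against 4-decimal
  values and 5e−4 against λ; exact rationals remove float-accumulation
  concerns from the dangling path itself.
- Ranking breaks exact value ties by ascending node label for display;
  rank tables use average ranks so ranks always sum to n(n+1)/2.
- Oracle-equivalence testing runs the full pipeline against an
  independent double-loop BFS implementation on 200 seeded random graphs
  with n ≤ 12 at edge probability 0.3 — sizes chosen so the whole suite
  completes in a few seconds while still covering disconnected,
  tree-like and dense regimes. Exhaustive matrix-power distance checks
  run at n ≤ 7.

## Known limitations

- Weighted shortest paths are out of scope: edge weights in trust-network
  inputs are read and discarded; the graph is treated purely as a
  connectivity structure.
- The per-node perturbation recomputes all-pairs BFS from scratch, so
  scoring all nodes costs `O(n²(n+m))`; on large graphs use the subset
  argument (or the CLI's `--nodes` prefix) rather than a full sweep.
- Closeness on disconnected graphs uses the exclusion convention above;
  other conventions (harmonic centrality, component-size weighting) are
  deliberately not offered.
- The six-node fixture ships in two variants (10-edge matrix form and a
  9-edge variant missing edge 2-4) because published degree tables for
  the same figure disagree; the 10-edge matrix is canonical for every
  worked value in the tests.
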