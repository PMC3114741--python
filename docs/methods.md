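# Methods

## Model and assumptions

The method treats orthology inference as graph clustering. Vertices are
proteins; a directed arc `x → y` records a similarity hit of query `x`
against a protein `y` of another species, weighted by the alignment bit
score. Bit scores (not E-values) drive all retention decisions: the bit
score is the graph's designated edge weight and, unlike the E-value, does
not saturate at zero or depend on database-size conventions. E-values are
used only as an absolute inclusion filter. Because every species pair is
searched against per-species databases, E-values are comparable within a
pair but intentionally not across pairs — closely related proteomes are
implicitly held to a stricter standard, which substitutes for the global
score normalization other tools perform.

Assumptions inherited from the underlying heuristic:

- orthologous proteins produce alignments that pass the absolute filters
  (a missed alignment can only lose edges, never create wrong ones);
- within one query's hits against one species, true (co-)orthologs score
  within a factor `f` of the best hit, while paralogous background scores
  fall outside that band;
- sets of (co-)orthologs form dense, nearly complete multipartite
  subgraphs, and spurious inter-group edges are few enough to appear as
  low-weight cuts.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `e_cutoff` | 1e-10 | maximum E-value for a hit to enter the graph (inclusive) |
| `min_identity_pct` | 25 | minimum percent identity, 0–100 scale (inclusive) |
| `min_coverage_frac` | 0.5 | minimum fraction of the *query* covered by the aligned span (inclusive) |
| `sim_factor_f` | 0.95 | adaptive band: retain arcs with `bits ≥ f·best` per (query, species) |
| `conn_threshold` | 0.1 | minimum normalized algebraic connectivity `α₂/n` of a reported group |

Coverage is computed from the query-side aligned span
`(q_end − q_start + 1) / query_length`, not from the alignment-length
column, so subject-side gaps cannot inflate it. All threshold comparisons
are inclusive, so the printed defaults behave as advertised. When several
HSPs survive for one ordered protein pair, only the highest-scoring one is
kept (ties: lower E-value, then input order): one arc per ordered pair
keeps the best-arc and factor-f rules well defined.

`f` interpolates between classical reciprocal best hits (`f = 1`, where
tied maxima are still all retained) and progressively more permissive
co-ortholog recovery. The undirected edge weight is the arithmetic mean of
the two directed bit scores; weights are carried for reporting only.

## Spectral decomposition

Connected components are found by breadth-first search and processed
independently (this is also what makes multi-threaded runs trivially
reproducible: per-component results are merged in a canonical sort order).
Per recursion level:

1. **Tree pruning.** Degree-1 vertices are deleted iteratively (the unique
   2-core remains). Tree-like pieces usually stem from spurious reciprocal
   hits; they are dropped and recorded in the run summary. With exactly
   two species in the analysis nothing is pruned — a two-species group is
   itself a tree (edge or star) and no third species exists to corroborate
   or refute it.
2. **Connectivity test.** `α₂` is the second-smallest eigenvalue of the
   unweighted Laplacian `L = D − A` of the core. The normalization `α₂/n`
   maps a complete graph to exactly 1, so the default threshold 0.1 lives
   on a [0, 1] scale. A weighted Laplacian is deliberately not used: edge
   existence already encodes the factor-f decision, and binary adjacency
   makes the complete-multipartite closed form
   `α₂/n = (n − largest class)/n` hold exactly.
3. **Fiedler split.** Below-threshold cores are bipartitioned by the sign
   pattern of the Fiedler vector; entries with `|x| ≤ 1e-12` count as
   positive. Each side is re-split into connected components and recursed
   on. Every split strictly shrinks the part, so termination is
   guaranteed; a degenerate all-one-sign vector (possible only through
   rounding) falls back to a median split.

Groups are reported when they span ≥ 2 species and ≥ 2 proteins — an
orthology statement needs two species by definition. Pruned vertices are
dropped, not re-attached to a neighboring group.

### Eigensolver

For cores with n ≤ 64 a dense symmetric eigendecomposition is used
directly. Larger cores use power iteration on the spectrally shifted
operator `M = 2n·I − L` with the trivial all-ones eigenvector projected
out every step; since `λ_max(L) ≤ n < 2n`, the dominant surviving
direction of `M` is the Fiedler vector and `α₂ = 2n − μ`. The iteration
stops when the eigenpair residual `‖Mv − μv‖ ≤ 10·tol·|μ|` with
`tol = 1e-9`; for symmetric operators the residual norm bounds the
eigenvalue error directly, whereas a successive-difference test can stop
far from the answer when the spectral gap is small. On non-convergence
within `max_iter = 10000` the dense solver takes over. The starting vector
comes from a seeded PRNG (default seed 42), and the Fiedler vector is
sign-normalized (first nonzero entry positive), making runs byte-for-byte
reproducible.

## Synthetic planted-truth generator

`orthograph.synthetic.generate` plants families across species and writes
exactly the artifacts the pipeline consumes. Defaults describe the regimes
the method targets:

- ortholog hits: reciprocal, bit score ~ Normal(300, 15), identity
  uniform in 80–95 %, full query coverage; one score draw per protein pair
  (both directions report the same alignment);
- duplication: with probability `dup_prob` a present family carries two
  co-ortholog copies in that species. Copies subfunctionalize: copy 0 and
  copy 1 of two *duplicated* species pair like-with-like, and unlike-copy
  arcs between two duplicated species are scaled by `co_ortho_penalty`
  (default 0.9) — the divergent co-ortholog situation the adaptive band
  exists to handle. A species that retained a single copy is treated as an
  unbiased ortholog of both copies elsewhere. Penalizing instead every arc
  that touches a second copy would push lone duplicates outside the
  f = 0.95 band almost surely (0.9 < 0.95 with σ = 15) and make even
  noise-light duplication regimes unrecoverable by construction, which is
  not the regime duplication is meant to model;
- spurious hits: directed, independent per ordered pair with probability
  `spurious_prob`, bit score ~ Normal(60, 8), identity ~30 %, coverage
  0.6. With the default E-value transform `E = 10^(−bits/10)` these fall
  above the 1e-10 cutoff and are removed by the absolute filter; spectral
  bridge-severing is exercised separately by constructed low-connectivity
  fixtures;
- E-values are a deterministic monotone transform of bit scores. Only
  ordering and thresholds matter downstream, so realism here would buy
  nothing and cost reproducibility. Sequences are placeholders: the
  pipeline reads only ids and lengths.

What passing planted-data tests shows — and what it does not: the
generator produces alignment-level data directly, so it validates the
graph construction and decomposition stages, not the upstream search. Real
BLAST output adds length-dependent score variance, asymmetric HSPs,
low-complexity artifacts and incomplete annotation, none of which are
modeled; recovery rates on planted data are therefore upper bounds.

The exhaustive edit-distance oracle (`edit_oracle`, n ≤ 8) enumerates all
vertex-set partitions and scores each block against the complete
multipartite graph on its species classes (insertions = absent
cross-species pairs, deletions = cross-block edges). It exists purely as
an independent ground truth for tiny graphs; the production path never
calls it.

## Problem sizes used in the bundled checks

The test suite and `scripts/acceptance.py` run planted projects of up to
10 species × 200 families (idealized) and 20 × (10 species × 50 families)
replicates (robust regime), 100 random hit tables for the RBH-equivalence
check, and 200 random connected graphs with n ≤ 64 for eigensolver
agreement. These sizes fully exercise every code path (including the
iterative eigensolver branch) while keeping a full run in tens of seconds;
the method itself has no size-dependent switches beyond the documented
n ≤ 64 dense cutoff.

## Known limitations

- In-paralogs are not explicitly tagged or collapsed; recent duplicates
  simply co-occur inside a group.
- Pruned (tree-like) vertices are discarded rather than reassigned, so a
  true ortholog attached by a single surviving edge is lost in analyses
  with ≥ 3 species; two-member groups cannot be reported at all there,
  because any two-vertex component is a tree.
- The connectivity threshold acts on the unweighted topology; a bridge of
  many parallel weak edges can hold two groups together even when their
  bit scores are low.
- Hit tables are trusted as given: the package never runs or verifies the
  underlying similarity search, and only the fixed 12-column tabular
  dialect is accepted.
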