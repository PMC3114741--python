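# orthograph

Detection of (co-)ortholog groups across many species from pairwise
sequence-similarity searches, using an adaptive generalization of the
reciprocal best alignment heuristic followed by spectral graph
partitioning.

## The problem

Orthologs — genes in different species descending from a single gene in
their last common ancestor through speciation — are the backbone of
comparative genomics, genome annotation and molecular phylogenetics.
The standard way to predict them between two proteomes is the reciprocal
best hit (RBH) rule: `x ∈ A` and `y ∈ B` are predicted orthologs iff each
is the other's best-scoring alignment. Gene duplications break this rule:
a pair of divergent co-orthologs can have *no* reciprocal best alignment at
all, while simply taking the k best hits pulls in distant paralogs.
At scale there is a second problem: holding all pairwise alignments for
hundreds of proteomes in memory is infeasible.

## The method

`orthograph` works on the directed graph whose vertices are proteins and
whose arcs `x → y` are similarity hits weighted by the alignment bit score
(E-value, percent identity and query-coverage cutoffs are applied first;
defaults E ≤ 1e-10, identity ≥ 25 %, coverage ≥ 50 %).

1. **Adaptive near-best arcs.** For each query `x` and each target species
   `B`, keep every arc with `bits(x→y) ≥ f · max_{y'∈B} bits(x→y')`.
   With `f = 1` this is classical RBH; the default `f = 0.95` also retains
   slightly weaker hits, which recovers divergent co-orthologs without
   admitting distant paralogs. Each species-pair hit table is reduced on
   the fly, so only a sparse `n × k` structure is ever stored.
2. **Symmetrization.** An undirected edge `{x, y}` survives iff both arcs
   were retained; ortholog groups now appear as dense, nearly complete
   multipartite subgraphs (classes ≈ species / co-ortholog sets).
3. **Spectral decomposition.** Each connected component Ξ is tested via its
   normalized algebraic connectivity `α₂(Ξ)/n`, where `α₂` is the
   second-smallest eigenvalue of the unweighted graph Laplacian
   `L = D − A`. Components scoring at or above the threshold (default 0.1)
   are reported as single groups; the rest are split along the sign pattern
   of the Fiedler vector (the eigenvector of `α₂`) and the pieces are
   processed recursively. Tree-like protrusions — usually false-positive
   edges — are removed by iterated deletion of degree-1 vertices before
   each eigencomputation, except when exactly two species are compared.

Finding the true minimum edge-edit decomposition into complete multipartite
subgraphs is NP-complete; an exhaustive edit-distance oracle
(`orthograph.edit_oracle`) is included for cross-checking the heuristic on
tiny graphs, and a planted-truth generator (`orthograph.synthetic`) builds
complete synthetic projects — FASTA files, hit tables, ground truth — for
end-to-end validation.

## Worked example

The package consumes per-species FASTA files plus one 12-column tabular
hit file (`blast -outfmt 6` layout) per ordered species pair, named
`<query>__vs__<subject>.tsv`. Here we let the bundled generator plant a
4-species, 6-family dataset with a 40 % duplication rate and then cluster
it:

```bash
$ cat plant.yaml
n_species: 4
n_families: 6
dup_prob: 0.4
seed: 11
$ orthograph fixtures --spec plant.yaml --out data
4 species, 35 proteins -> data
$ orthograph cluster --hits data/hits --project run data/*.fasta
proteins        35
species         4
retained_arcs   113
reciprocal_edges        49
connected_components    6
groups  6
6 groups -> run.groups.tsv
$ cat run.groups.tsv
# Species	Genes	Alg.-Conn.	s01	s02	s03	s04
4	7	0.104	s01_g0004	s02_g0004,s02_g0004b	s03_g0004,s03_g0004b	s04_g0004,s04_g0004b
4	5	0.317	s01_g0000	s02_g0000	s03_g0000	s04_g0000,s04_g0000b
4	5	0.317	s01_g0002	s02_g0002	s03_g0002,s03_g0002b	s04_g0002
4	5	0.400	s01_g0003	s02_g0003	s03_g0003,s03_g0003b	s04_g0003
4	4	1.000	s01_g0001	s02_g0001	s03_g0001	s04_g0001
4	4	0.500	s01_g0005	s02_g0005	s03_g0005	s04_g0005
```

Each row is one (co-)ortholog group: the number of species covered, the
number of proteins, the group's normalized algebraic connectivity, then the
member ids per species (`*` marks an absent species). A perfect one-per-
species group is a complete graph and scores 1.000; groups that absorbed
co-ortholog duplicates (`…b` ids) are still dense enough to pass the 0.1
threshold but score lower. The run summary also reports 5 pruned vertices:
duplicate copies whose few remaining edges left them as tree-like pendants.

The cumulative presence census (how many groups span at least x species —
the core-genome curve) of the same run:

```bash
$ orthograph census run.groups.tsv
# min_species	cumulative_groups
4	6
3	6
2	6
```

Equivalent library calls: `orthograph.generate_project`,
`orthograph.run_project`, `orthograph.coverage_census`.

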