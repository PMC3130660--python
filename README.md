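# mmm2

Exact detection of coevolving protein pairs from phylogenetic distance
matrices. Given two families of homologues with pairwise distance matrices
(PHYLIP square format, e.g. `protdist` output), `mmm2` finds all largest
sets of one-to-one A-to-B protein pairings whose ratios of paired
distances (RPDs) agree within a tolerance `alpha` — the size of the
largest such *match* is the coevolution score of the family pair.

The search is exact: every edge of a *compatibility graph* (vertices =
candidate pairings, edges = pairings that can coexist) is treated in turn
as the minimum-RPD edge of a candidate match; the forward-compatible
neighbourhood forms a small subgraph whose maximum cliques are found with
an Östergård-style branch-and-bound, modified to enumerate all maximum
cliques (with a faster single-solution mode, `--maxtrees 1`).

## CLI

Score one pair of matrices (default `alpha = 0.1`; `alpha = 0.108` is a
documented alternative that compensates for the strictness of the
pairwise match criterion relative to the legacy triplet-based one):

```sh
mmm2 run --matrix-a famA.phy --matrix-b famB.phy \
     --alpha 0.1 --species-delim '|:0' --format json
```

Species handling is optional: give either `--species-delim CHAR:FIELD`
(species = that field of each label) or `--species-map map.tsv`
(two-column `protein<TAB>species`). Without a rule, all pairings are
admissible.

Batch mode over a manifest (TSV rows `pair_id <TAB> path_a <TAB> path_b`;
failures are logged and skipped):

```sh
mmm2 batch --manifest pairs.tsv --species-delim '|:0' \
     --min-shared-species 30 --outdir results/
```

Generate a synthetic fixture pair with a planted coevolving subset
(one matrix contains a scaled, optionally noised, copy of a submatrix of
the other):

```sh
echo '{"n_a": 6, "n_b": 7, "shared_species": 5, "planted_size": 5,
       "scale": 2.0, "noise": 0.0, "seed": 11}' > spec.json
mmm2 synth --spec spec.json --outdir fixtures/
```

## Library

```python
from mmm2 import (read_phylip_square, build_compatibility_graph,
                  Tolerance, solve)

a = read_phylip_square("famA.phy")
b = read_phylip_square("famB.phy")
g = build_compatibility_graph(a, b)
result = solve(g, Tolerance(0.1), maxtrees="all")
result.score            # coevolution score
result.matches          # every maximum match
```

`mmm2.oracle_synth.brute_force_solve` is a definitionally correct
reference solver (full subset enumeration, guarded to small graphs) used
throughout the tests, and `mmm2.mmm_solver.legacy_mmm_match_test`
implements the older triplet-based match criterion as a comparator.

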