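# dcjswarm

Ancestral gene-order inference with a discrete quantum-behaved particle
swarm. The package computes double-cut-and-join (DCJ) distances between
signed gene orders, solves the DCJ genome median problem with a
sorting-path-based swarm search, simulates rearrangement datasets, and
scores/searches phylogenetic trees with the median solver in an iterative
(GRAPPA-style) framework.

## What is inside

| module | contents |
| --- | --- |
| `dcjswarm.genome` | signed gene orders, adjacency/telomere sets, gene-order file IO |
| `dcjswarm.dcj` | adjacency graphs, DCJ distance `n − (C + I/2)`, DCJ operations, sorting-path sampling |
| `dcjswarm.median` | the swarm median solver (36·M sorting-path initialization, two-average mean-best selection, sorting-based position updates, lower-bound stopping) |
| `dcjswarm.simulate` | seeded inversion/transposition simulators for median triplets and trees |
| `dcjswarm.phylo` | neighbor joining, circular-ordering lower bound, tree scoring, bounded topology search, Robinson-Foulds error, Newick IO |
| `dcjswarm.metrics` | adjacency accuracy (intersection over union), distance to the true ancestor, batch reports |
| `dcjswarm.cli` | `dcjswarm` command-line front end |

Genomes may be multichromosomal, linear or circular. Hot paths (component
counting and sorting-step sampling) are JIT-compiled with numba when it is
available and fall back to pure Python otherwise.

## Command line

```sh
# pairwise DCJ distance matrix of a gene-order file
dcjswarm distance genomes.txt

# simulate a median triplet (identity ancestor, 200 inversions per edge)
dcjswarm simulate --out data/ --n-genes 1000 -r 200 --seed 1

# solve the median of three genomes
dcjswarm median data/leaves.txt --out run/ --population 20 --seed 1

# compare an inferred median with the true ancestor
dcjswarm eval run/median.txt data/true_ancestor.txt

# simulate a 6-leaf tree dataset and search tree space
dcjswarm simulate --kind tree --out tree_data/ --n-leaves 6 --n-genes 200 -r 10 --seed 1
dcjswarm search tree_data/leaves.txt --out tree_run/ --population 20 --max-generations 500
```

Gene-order files are plain text: a `>name` header per genome, signed
integers for genes, `$` ending a linear chromosome, `@` a circular one, and
`#` starting comments.

Every command writes a `manifest.json` (command, config, seed, version)
sufficient to replay the run.

## Notes

- The solver's iteration cap is `min(max_generations, ceil(1.5 × medianLB))`
  and the search stops early when the best score reaches `ceil(medianLB)`,
  where `medianLB = (d12 + d13 + d23)/2`.
- Unrestricted DCJ is implemented: circular intermediates may appear while
  sorting linear genomes.
- Sorting-path sampling fixes unmet target adjacencies in uniformly random
  order (then telomere cuts), which keeps every sample on an optimal
  sorting path; the solver's diversification walk additionally draws
  general component-splitting operations, which can create adjacencies
  present in none of the three input genomes — optimal medians routinely
  need such adjacencies.
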