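# stemloop

Stem/loop-partitioned phylogenetics for ribosomal-RNA alignments.

Paired (stem) regions of rRNA evolve by compensatory substitutions —
the two columns of a base pair covary and do not carry independent
phylogenetic signal — while unpaired (loop) regions evolve as independent
sites, often fast enough to reach substitutional saturation.  A standard
DNA model counts every stem pair's signal twice; a paired-site RNA model
counts it once, which increases the relative weight of the loops.  When
the loops are homoplastic noise, that reweighting can swamp the reliable
stem signal and mislead the tree.  `stemloop` is a toolkit for studying
and diagnosing exactly this trade-off, aimed at molecular systematists
working with structure-annotated rRNA alignments.

It provides:

* **Structure partitioning** — bind a Vienna dot-bracket consensus
  structure (the format structural aligners emit) to an aligned FASTA,
  honor a column-exclusion mask, and split the matrix into loop sites and
  stem doublets.
* **Models** — GTR+Γ for loops, and the 13 paired-site RNA models
  (RNA6A–D on 6 states, RNA7A–F on 7, RNA16/RNA16A/RNA16B on 16), with
  the one-step/two-step compensatory-substitution constraint (two-step
  models set every double substitution AU↔GC to rate zero) and the
  family-specific mismatch policies (ignored / lumped into one MM state /
  modelled individually).
* **Likelihood engine** — partitioned Felsenstein pruning over mixed
  4-state and doublet data with shared branch lengths, per-partition rate
  multipliers and discrete-gamma rates; branch-length and model-parameter
  optimization; exhaustive quartet search and NNI hill climbing; AICc
  model comparison within classes: AICc = −2 logL + 2k + 2k(k+1)/(n−k−1).
* **Saturation testing** — the entropy-based index of substitution
  saturation, Iss = mean per-site entropy / full-saturation entropy, with
  critical values Iss.c estimated by seeded simulation on balanced
  (symmetric) and pectinate (asymmetric) reference topologies; a
  partition is called saturated when Iss exceeds the asymmetric Iss.c.
* **Tree metrics** — Robinson–Foulds distances on shared leaf sets and
  config-driven benchmark-clade monophyly checks relative to a declared
  outgroup.
* **Synthetic rRNA generator** — covarying stem doublets plus loop sites
  with a saturation dial λ, calibration of λ to a target saturation
  verdict, and a Felsenstein-zone experiment comparing quartet recovery
  of the DNA setup against the mixed RNA/DNA setups.
* **Pipeline + CLI** — `stemloop pipeline` runs the whole design
  (partition → saturation tests → 14 setups → restricted loop-only /
  stem-only analyses → RF tables → benchmark grid) deterministically
  under one master seed.

## Worked example

Generate a small structured alignment with saturated loops, test each
partition for saturation, and compare the DNA setup against a mixed
setup on the Felsenstein-zone quartet:

```python
import numpy as np
from stemloop import (SimulationConfig, simulate, iss_test,
                      felsenstein_zone_experiment)
from stemloop.trees import balanced_tree

tree = balanced_tree(16, 0.05)           # 16 taxa, moderate depth
cfg = SimulationConfig(tree=tree, n_stem_pairs=300, n_loop_sites=600,
                       loop_rate_multiplier=5.4, seed=7)
aln, truth = simulate(cfg)

loops = aln.matrix[:, truth["loop_columns"]]
stems = aln.matrix[:, sorted(c for p in truth["stem_pairs"] for c in p)]
for name, sl in [("loops", loops), ("stems", stems), ("combined", aln.matrix)]:
    r = iss_test(sl, partition=name, seed=1)
    print(f"{name:9s} Iss={r.iss:.3f}  Iss.c(asym)={r.issc_asym:.3f}  {r.verdict}")

table = felsenstein_zone_experiment(0.7, 0.05, 5.4, 30,
                                    setups=("GTR", "RNA6A"), seed=17)
print(table["recovery"])
```

prints (seeds as above):

```
loops     Iss=0.635  Iss.c(asym)=0.581  saturated
stems     Iss=0.430  Iss.c(asym)=0.581  not_saturated
combined  Iss=0.545  Iss.c(asym)=0.574  not_saturated
setup
GTR      0.733333
RNA6A    0.533333
Name: recovery, dtype: float64
```

Reading the output: the loop partition alone is diagnosed as saturated
(its Iss exceeds the asymmetric critical value), the stems are not, and —
the reason partition-wise testing matters — the concatenated matrix hides
the loop saturation entirely.  On the long-branch quartet with those
saturated loops, the DNA setup (which double-counts the informative
stems) recovers the true topology more often than the mixed RNA6A setup
(which downweights them); with informative loops (λ ≈ 1) the two setups
are comparable.

The same stages are available from the shell:

```
stemloop simulate  --config sim.yaml --out data/toy
stemloop partition --aln data/toy.fasta --struct data/toy.db
stemloop saturation --aln data/toy.fasta --struct data/toy.db --by-partition
stemloop ml        --aln data/toy.fasta --struct data/toy.db --model RNA6A
stemloop compare   tree1.nwk tree2.nwk
stemloop pipeline  --aln data/toy.fasta --struct data/toy.db --outdir report/
```

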