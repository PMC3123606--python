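# Methods

## The problem

Ribosomal-RNA genes are the workhorse markers of metazoan phylogenetics,
but their two structural compartments evolve under different rules.
Helical (stem) regions evolve by compensatory substitutions that preserve
base pairing, so the two columns of a pair do not carry independent
signal; single-stranded (loop) regions evolve as independent sites but
often at much higher rates, to the point of substitutional saturation.
Treating stem columns as independent sites under a DNA model effectively
counts their signal twice; modelling them as covarying doublets under a
paired-site RNA model counts them once, which *downweights* stems relative
to loops.  When loops are homoplastic noise, that reweighting can let the
noise dominate and degrade the tree.  This package implements the full
analysis needed to study that trade-off: structure-aware partitioning,
the 14 model setups, per-partition saturation testing, tree comparison,
and a synthetic generator that reproduces the mechanism.

## Substitution models

Loops (and the whole alignment in the DNA setup) use GTR+Γ: a reversible
4-state generator `Q_ij = s_ij π_j` with 5 free exchangeabilities, 3 free
frequencies, and discrete-gamma rate variation (4 equal-probability
categories, each represented by its conditional quartile mean, normalized
to mean 1).

Stems in the 13 mixed setups use paired-site models on doublet states:

* **6-state** (RNA6A–D): states are the canonical pairs AU, GU, GC, UA,
  UG, CG; non-canonical doublets carry no information (full ambiguity).
* **7-state** (RNA7A–F): the 6 canonical pairs plus a single lumped
  mismatch state MM.
* **16-state** (RNA16, RNA16A, RNA16B): every ordered nucleotide pair is
  a distinct state with its own frequency.

Two structural constraints distinguish the families.  *One-step* models
(RNA6A–D, RNA7A, RNA7B, RNA7D, RNA16A) allow compensatory double
substitutions (AU↔GC) directly; *two-step* models (RNA7C, RNA7F, RNA16,
RNA16B) set every double-substitution rate to exactly zero, so pair
changes must pass through an intermediate state.  RNA7E appears in
neither published class list; this implementation classifies it two-step
with lumped mismatches and tied pair↔MM rates, and flags the
classification as an implementation default in the spec registry
(`class_source`).

Within a family the lettered variants tie parameters:

| variant | exchangeabilities | frequencies |
|---|---|---|
| A (and RNA16, RNA16A) | fully general (each allowed transition free) | free |
| B | tied into transition classes {single change, double change, pair↔MM} | free |
| C | as B | tied across reverse-complement pairs (π_AU = π_UA, …) |
| D / F (and RNA16B) | single class (equal rates) | free |

The exact intra-family tying of the lettered variants is not fully
printed in the primary literature (it defers to the PHASE manual); the
registry above is this package's documented default and every tying is
overridable by constructing a `ModelSpec` directly.  On 16 states there
are 48 single-change and 72 double-change unordered state pairs (direct
enumeration); RNA16 therefore has 48 free transition rates and 72
structural zeros, and RNA16A additionally frees the 11 canonical↔canonical
doubles.

All generators are reversible, built as `Q_ij = s_ij π_j` with symmetric
`s`, and calibrated to one expected substitution per unit branch length
(`-Σ π_i Q_ii = 1`).  Transition matrices come from the symmetric
similarity transform (`eigh`), which is exact for reversible generators
and fast enough to recompute per branch and rate category.

## Likelihood engine

Felsenstein pruning over partitions that share one set of branch lengths;
each partition carries its own model, gamma shape, and rate multiplier
(the first partition's multiplier is fixed to 1).  Ambiguity — gaps, N,
IUPAC codes, and mismatch doublets under 6-state models — enters as
partial-likelihood masks at the tips; a gap or N in either member of a
pair makes the whole doublet uninformative.  Site patterns are compressed
with weights (ambiguity-distinct patterns stay distinct), and per-node
rescaling keeps partial likelihoods in range for trees of hundreds of
taxa.

Optimization alternates (a) bracketed one-dimensional search per branch
length and (b) bounded L-BFGS-B over log-transformed exchangeabilities,
gamma shapes, and rate multipliers, until the round gain falls below a
tolerance (default 1e-3, max 20 rounds); the log-likelihood is asserted
never to decrease.  State frequencies are empirical by default (counts
from the tip masks, projected onto the model's tied groups), matching
common practice in partitioned ML tools; they are still counted as free
parameters in `k`.

Tree search enumerates all three topologies exhaustively for quartets;
otherwise it hill-climbs with nearest-neighbor interchanges from a
neighbor-joining start (distances pooled over partitions with a
Jukes-Cantor-type correction per state space).  NNI neighbors are scored
with branch lengths only, re-using the current model parameters; the
winner gets a full re-optimization.  The search is deterministic given
its inputs.

AICc is `-2 logL + 2k + 2k(k+1)/(n-k-1)` with `n` the number of
observation columns in the setup's *own* representation: loop columns
plus stem doublets for mixed setups, all columns for the DNA setup.
Consequently AICc is comparable only within a model class on the same
representation — which is exactly how the within-class model test is
used.  When `n ≤ k+1` the AICc is undefined and the code refuses to fall
back to AIC silently.

## Saturation testing

The observed index of substitution saturation is

    Iss = mean per-column Shannon entropy / H_FSS,

with entropies in bits, gaps and ambiguity codes excluded per column,
constant columns removed first ("accounting for invariant sites"), and
`H_FSS` the entropy of the global nucleotide frequencies — the expected
per-site entropy at full saturation.  A constant alignment has Iss = 0;
an i.i.d. uniform alignment approaches Iss = 1 from below (finite-sample
entropy bias of order (K−1)/(2N ln 2)).

Critical values Iss.c are estimated by seeded simulation rather than
imported from published tables, so they are self-contained and
versionable.  Jukes-Cantor sequences are evolved over a geometric grid of
tree depths on two reference shapes:

* **symmetric**: an equal-branch fully balanced tree (ultrametric);
* **asymmetric**: a pectinate (caterpillar) tree with short internal
  edges and pendant branches alternating long/short at a fixed 8:1
  ratio, so consecutive long branches are non-adjacent.

The asymmetric branch-length profile is a deliberate design choice: a
pectinate *topology* with equal or ultrametric branch lengths places long
branches next to each other and is actually easier to recover than a
balanced tree at small taxon counts, so no threshold ordering would
emerge.  Rate asymmetry with interleaved long branches is the regime in
which saturation first misleads reconstruction (long-branch attraction),
which is what an asymmetric critical value is meant to capture.

At each depth the mean Iss and the mean fraction of true internal edges
recovered by neighbor joining on *uncorrected* p-distances are recorded
(saturation is precisely the regime where uncorrected distances compress
and stop increasing with depth).  Iss.c is the Iss interpolated at the
point where recovery, searched only after its peak and isotonically
smoothed, crosses one half.  Starting the search at the peak prevents
shallow-depth resolution failures (too few substitutions, not too many)
from masquerading as saturation.  With this construction
Iss.c(symmetric) > Iss.c(asymmetric) at every supported taxon count
(4, 8, 16, 32) and reference length.

`iss_test` bins the observed slice's column count to a fixed length grid
(50 … 10000) before the Iss.c lookup so that the simulation cache is
shared across replicates, subsamples taxon-rich alignments down to the
largest supported reference size, and reports both critical values with
two-tailed t-test p-values (standard error from the per-site entropy
spread).  The verdict is **exceedance of the asymmetric threshold** —
Iss > Iss.c(asym) — not p-value significance; the symmetric threshold
and the p-values are advisory.  Partitions with fewer than 10 variable
sites are inconclusive.

## Synthetic data

The generator emulates the statistical structure of a structure-aligned
rRNA matrix: stem doublets evolve as covarying units under a chosen
paired-site model (default RNA6A with heterogeneous transition rates and
GC-rich pair frequencies); loop sites evolve independently under GTR+Γ
(default shape 0.5) with a rate multiplier λ that drives them from frozen
(λ = 0) through informative (λ ≈ 1) to saturated.  Doublets are written
into paired columns of a nested hairpin layout interleaved with loop
blocks (a blocked layout is available; no statistic may depend on the
layout, which is tested by permutation).  The lumped MM state of 7-state
models is written as a uniformly drawn mismatch doublet.  A single master
seed makes every output bit-reproducible.

`calibrate_saturation` bisects over λ until the loop partition's verdict
matches a target in ≥80% of probe replicates, returning the *onset*
multiplier.  The "saturated" study condition then uses 1.5× the onset:
empirical saturated loop partitions sit well above their critical
threshold, not at it, and the margin keeps all three verdict rates (loops
saturated, stems not, concatenation masked) simultaneously stable.
Saturation is induced purely by rate scaling on a fixed tree; alignment
error, the other mechanism sometimes invoked for noisy loops, is
deliberately not modelled — so passing tests here say nothing about
misalignment artefacts in real data, only about multiple-substitution
homoplasy.  Likewise the generator is stationary and homogeneous: base
compositional heterogeneity across lineages is out of scope.

The Felsenstein-zone experiment uses a quartet with two non-adjacent long
branches (p) against short ones (q), defaults p = 0.7, q = 0.05, 75 stem
pairs and 300 loop sites, and scores each analysis setup by exhaustive
3-topology ML.  Substitution parameters are fixed at their generating
values (the loop multiplier included) and only branch lengths are
optimized per topology — standard practice for simulation studies that
isolates topology choice from estimation noise and keeps the experiment
within desk-scale budgets.  λ for the saturated condition is calibrated
on a 16-taxon balanced reference alignment, not on the quartet itself: a
4-taxon slice compresses the Iss scale (every variable column carries
≥0.81 bits) and makes quartet-level calibration degenerate.

The mechanism the experiment reproduces: both setups see the same loop
noise, but the DNA setup counts every stem pair twice and therefore
carries roughly double the coherent stem signal into the zone.  With
saturated loops the DNA setup recovers the true quartet at least as often
as the mixed setup; with informative loops the two are comparable and the
mixed setup is often slightly better (its stem covariation model is the
correct one).

## Pipeline

`run_pipeline` executes the full design on one structured alignment:
partition → saturation tests on loops, stems and the concatenation → all
14 setups (failures of one setup are recorded and do not abort others) →
loop-only and stem-only DNA fits → Robinson-Foulds tables (combined vs
each restricted tree, per setup) → benchmark-clade verdicts against a
declared outgroup.  Monophyly is always evaluated relative to the
outgroup (unrooted trees have no clades otherwise); polytomies are left
unresolved and the RF distance uses whatever bipartitions exist.  Reports
(JSON, TSVs, a pass/fail setup grid, and an increased/decreased/unchanged
RF-delta grid) embed the resolved configuration, and a rerun under the
same master seed is byte-identical.

## Numerical choices and problem sizes

* Branch-length bounds [1e-8, 20]; log-rate bounds e^±7; gamma shape in
  [0.02, 50].
* Transition matrices clipped at zero after eigendecomposition
  (round-off can produce −1e-17 entries).
* Rate-matrix eigendecompositions are cached per parameter vector;
  pattern compression keys on the full ambiguity mask.
* Iss.c simulations default to 240 total replicates across a 12-point
  depth grid and are cached by (taxa, length, topology, reps, seed).
* The test suite and the acceptance script run everything at deliberately
  modest sizes — quartet oracles at 24 columns, saturation batteries at
  16 taxa × 1200 columns, zone experiments at 60–100 replicates, AICc
  recovery at 1500 doublets — chosen to give decisive margins (e.g.
  within-class ΔAICc of the generating model is ~200) while keeping a
  full run on one CPU in the minutes range.

## Known limitations

* The lettered-variant parameter tyings are this package's defaults, not
  a bit-exact transcription of PHASE's; AICc comparisons across
  differently-tied registries will differ.
* Iss.c values are internally consistent but not numerically
  interchangeable with DAMBE's (different simulation engine, reference
  trees, and recovery criterion); an externally supplied critical value
  can be passed by comparing against `IssResult` fields directly.
* No bootstrap, no Bayesian inference, no indel or alignment-error
  simulation, no non-stationary base composition.
* The NNI search is a hill climber; on low-signal data it can stop in a
  local optimum (as any single-start NNI search can).
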