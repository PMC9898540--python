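# Methods

## Quantification model

A sorted sample (one mouse, one blood population, one time point) yields
barcode read counts and three flow-cytometry fractions: the population's
share of white blood cells (`pop_frac_wbc`), the donor chimerism of that
population (`donor_frac`) and the GFP+ (barcode-carrying) share of donor
cells (`gfp_frac`).  Clonal abundance in %WBC is

```
abundance[b, s] = 100 × pop_frac × donor_frac × gfp_frac × reads[b, s] / Σ_b reads[b, s]
```

Because read fractions sum to one, per-sample abundance totals equal
`100 × pop × donor × gfp` exactly; the tests assert this conservation law at
1e-9 relative tolerance.  Abundance is therefore invariant to sequencing
depth (homogeneity: scaling a sample's counts leaves it unchanged).  A
sample with zero total reads produces zero abundance with a warning rather
than an error — late bleeds can legitimately drop out.

A clone is identified by `(barcode, mouse)`: barcodes mark independent
transduction events, so the same sequence in two mice is two clones, and all
per-clone rules are evaluated within a mouse.  Clone membership in a mouse
requires at least one read there, so a zero flow fraction cannot silently
drop clones.

### Spike-artifact filter

A clone whose abundance exceeds 0.5 %WBC in exactly one
(cell type, time point) cell of a mouse while being absent in every other
cell of that mouse is treated as a single-cell sorting/PCR artifact and
removed.  "Absent" is not quantified in the defining rule; we reuse the
0.01 %WBC measurability floor the classifiers use, keeping a single notion
of "detected" throughout (both thresholds are configurable).  The decision
is per clone, so the filter is idempotent; a clone above 0.5 % in two cells
is retained, since multi-cell presence contradicts "absent elsewhere".

## Classification

All classifiers share `BiasParameters`:

| parameter | default | units | role |
|---|---|---|---|
| `fold_threshold` | cot 22.5° = 1 + √2 ≈ 2.4142 | fold | bias rule |
| `detect_floor` | 0.01 (inclusive ≥) | %WBC | measurability / production |
| `high_abundance_floor` | 0.05 (exclusive >) | %WBC | high-abundance flag |
| `early_timepoint`, `late_timepoint` | 2.5, 6.5 | months | temporal references |
| `relative` | True | — | bias on relative copy numbers vs raw %WBC |

The floor is inclusive and the high-abundance and fold rules strict, per
their definitions ("below 0.01" defines absence; "above 0.05"; "greater
than 2.4142").  Boundary cases (ratio exactly 1, ratio exactly at the fold
threshold) fall to the non-extreme class — they are measure-zero under
continuous noise, and the strict inequalities leave the boundary open.

**Relative copy number.**  The bias rule compares a clone's standing in the
myeloid compartment (Gr, the only sorted myeloid type) with its standing in
the lymphoid compartment (B + CD4 T + CD8 T, aggregated by summation).  Raw
%WBC values are not comparable across compartments of different absolute
size, so the clone's lineage abundance is normalized by the mouse's total
lineage abundance at that time point.  This makes the 2.4142-fold rule
scale-free: multiplying a mouse's abundances by any constant leaves bias
labels unchanged.  Setting `relative=False` compares raw summed %WBC
instead.

**Precedence.**  Specialization is decided before the fold rule: a clone
measurable in exactly one lineage is that lineage's `*_specialized`
regardless of copy numbers; a clone measurable in neither is `undetected`.
The B-vs-T axis applies the same machinery to {B} vs {CD4 T, CD8 T} with
`not_applicable` for clones measurable in neither.

**Merging CD4/CD8 T.**  T cells are merged only where the analysis merges
them: cell-type-combination labels and B-vs-T bias.  Temporal and dynamics
classes keep CD4 T and CD8 T separate.

**Temporal and dynamics.**  The reference months are 2.5 and 6.5 (blood
production was similar at 5.5 and 6.5 months, so 6.5 represents long-term
output).  `persisted` = produced at both references, `early`/`late` = only
one, `neither` otherwise; "produced" can be read per cell type or as
any-cell-type (both provided).  For clones persisted in a T-cell
population, the 6.5:2.5 abundance ratio labels them `expanded` (> 1) or
`shrunken` (< 1); an exact tie is reported separately as `tie`.

## Clustering

Clones from all mice and both groups are pooled (raw clone profiles, no
cross-mouse normalization) and featurized as
`log2(abundance + pseudocount)` over 4 cell types × 3 analysis time points
(2.5, 5.5, 6.5 months; month 3.5 is collected but not analyzed).  The
pseudocount, 1e-4 %WBC, sits two decades below the detection floor: it
keeps undetected cells far from detected ones without producing −∞.
Clones with zero abundance in all twelve cells are dropped.

Features are centered and unit-scaled per column, then rotated by PCA (12
components of 12 features — a full-rank rotation, kept configurable).  The
decomposition is made deterministic by fixing each component's sign so its
largest-magnitude loading is positive.  Clustering operates on PC scores,
never on the 2-D UMAP embedding, which is computed only for display.

The graph is a shared-nearest-neighbor graph: an edge joins i and j when
either is among the other's k nearest neighbors (k = 20, capped at ⌈n/3⌉),
weighted by the Jaccard overlap of their neighborhoods.  Each neighborhood
includes the point itself, so coincident profiles share weight 1 (the
Seurat convention).  Louvain community detection with a fixed seed
partitions the graph; cluster ids are relabeled by decreasing size with
ties broken by smallest member, and clones are sorted into a canonical
order first, so permuting the input permutes the output without changing
the partition.

The `resolution` parameter selects granularity.  The default 1.0 resolves
fine substructure — the regime in which the original workflow reports ~10
clusters.  The planted-structure recovery experiment instead asks whether
the three coarse archetypes (short-only, middle-only, long-term
multilineage) are recovered; they form three disconnected components of the
kNN graph, and the recovery protocol clusters at resolution 0.05, where
modularity optimization returns exactly the components.  This choice is
part of the recovery protocol, not of the default pipeline.

Clusters are categorized by a majority rule: a cluster is `long_term` when
at least half its members are detected (any cell type ≥ floor) at 6.5
months; otherwise `short_term` when at least half are detected at 2.5;
otherwise `middle_term` when at least half are detected at 5.5; any
remaining cluster is labeled by its argmax time point.  The defining
descriptions are qualitative; majority vote is the simplest testable rule.

## Statistics

Group comparisons use the one-tailed two-sample unequal-variance (Welch)
t-test, `t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b)` with Welch–Satterthwaite
degrees of freedom, significance tagged `*` at p ≤ 0.05 and `**` at
p < 0.01.  The mouse is the unit of replication — per-mouse summaries are
formed before testing, never clone-level pseudo-replicates.  The direction
of the alternative is a required explicit argument; inferring it from the
data would invalidate a one-tailed p value.  When both groups have zero
variance and equal means, p = 0.5 by convention with a warning.  No
multiple-testing correction is applied; reports carry the number of tests.

Shannon diversity is `H = −Σ p_i ln p_i` over a sample's clone shares, in
nats by default (the convention of the vegan package), with a configurable
base.  `H` is scale-invariant and bounded by `ln(number of detected clones)`.

## Synthetic data

The generator emulates the measurement chain the quantification model
inverts.  Per mouse:

1. each of 200 clones draws an archetype from its group's mixture;
2. its true trajectory is the archetype's mean (cell type × time point)
   profile times i.i.d. lognormal noise `exp(N(0, σ))` per cell (σ = 0.5 by
   default; recovery experiments use σ = 0.3).  Cells with zero mean stay
   exactly zero;
3. in the HSC+MPP group, CD4/CD8 T means at ≥ 5.5 months are multiplied by
   `mpp_effect` (default 2.0), and the mixture weights shift from the
   short-term archetype toward middle/long-term and expanding-T phenotypes —
   together the planted group effect.  `SimulationConfig.null_variant()`
   removes both for null calibration;
4. spike artifacts (Binomial(200, 0.02) extra clones, 0.6–1.5 %WBC in one
   random cell, zero elsewhere) are injected, exactly matching the filter's
   removal clause so filter recall is a sharp test;
5. per sample, reads are drawn `Multinomial(depth, true shares)` at
   depth 100,000, so count totals equal the depth exactly;
6. flow fractions are emitted consistently with the planted totals:
   population and donor fractions get Beta noise around nominal blood
   values, and the GFP fraction is solved from
   `total = 100 × pop × donor × gfp` (with pop/donor adjusted when gfp
   would exceed 0.95), so quantification reconstructs the planted
   trajectories up to multinomial noise only;
7. barcodes are unique random 27-mers (length is a toy default, not a claim
   about any real library).

The seven default archetypes span short-term multilineage, middle-term,
long-term balanced, myeloid-specialized, lymphoid-specialized, T-biased and
persisted-expanding-T phenotypes.  Their means (0.02–0.12 %WBC) are sized
so that a 200-clone mouse yields realistic per-sample totals of a few %WBC
while every intentionally produced cell stays at least twice the detection
floor, and so that the pooled myeloid and lymphoid compartments are of
comparable relative size (making "balanced" archetypes genuinely balanced
under relative copy numbers).  Persisted archetypes are given T-cell trends
of at least ~2.5-fold so their expanded/shrunken truth is not a coin flip
at the ratio-1 boundary.

**Ground truth for recovery tests.**  Reference labels are obtained by
running the classifiers on the pre-sequencing true trajectories of the
non-spike clones.  Recovery then measures robustness to the measurement
chain (multinomial sampling) alone, while the correctness of the label
definitions themselves is established independently by brute-force oracle
tests that loop over the definitions literally.  Nominal per-archetype
annotations are additionally verified to match classification of a
noise-free (σ = 0) simulation exactly.

**What the simulator does not model:** PCR amplification bias and
sequencing substitution errors in the main generator (the toy-FASTQ module
models substitutions only), barcode collisions between clones, cell-cycle
or niche dynamics, and clone-count or depth figures from any real dataset —
no raw data are publicly deposited, so clone numbers, depths and effect
magnitudes are plausibility choices, documented here, not estimates.
Passing recovery tests therefore demonstrates correctness of the pipeline
under the stated noise model, not performance on any particular real
dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run the full study design (12 mice × 200
clones × 16 samples at depth 100,000) for conservation, filter-recall,
label-recovery and power experiments; cluster recovery uses 4 mice × 150
clones of the three planted archetypes over 10 seeds; Welch calibration
uses 10,000 null replicates at n = 5 vs 7; the end-to-end determinism check
runs a 4-mouse pipeline (including UMAP) twice and compares serialized
bytes.  Floating-point tolerances: conservation 1e-9 relative; Welch vs
reference 1e-10; PCA distance preservation 1e-9; abundance round-trip
through TSV at 12 significant digits, 1e-9.

## Known limitations

* The abundance formula assumes the three flow fractions are measured
  without error; no uncertainty is propagated to abundance.
* The SNN/Louvain implementation is a generic equivalent of the Seurat
  workflow, not a re-implementation of its exact pruning constants or
  Leiden refinement; cluster counts at default resolution are therefore
  not expected to match any specific published clustering.
* Barcode matching in the toy FASTQ path is Hamming (substitution-only) on
  fixed-length barcodes; indels are out of scope.
* One-tailed tests are reported exactly as specified, without
  multiple-testing correction; consumers should weigh the annotated number
  of tests.
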