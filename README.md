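# clonetrace

Clonal lineage tracking of genetically barcoded hematopoietic stem cells
(HSCs) after transplantation.

In a cellular-barcoding experiment, HSCs are lentivirally tagged with unique
DNA barcodes and transplanted; each barcode then marks one *clone* — the set
of blood cells descended from one stem cell.  Sorted blood populations
(granulocytes Gr, B cells, CD4 T and CD8 T cells) are sequenced at several
time points, and the barcode read counts are combined with flow-cytometry
fractions to quantify every clone's contribution to the blood.  `clonetrace`
implements the full analysis for such experiments, including the comparison
of HSC-only recipients with recipients co-transplanted with multipotent
progenitors (MPPs):

1. **Quantification** — clonal abundance in percent of white blood cells:

   `abundance = 100% × (population %WBC) × (donor %) × (GFP %) × reads / total reads`

   followed by removal of single-cell spike artifacts (clones above
   0.5 %WBC in exactly one cell-type/time-point cell and absent everywhere
   else in the mouse).

2. **Classification** — per-clone categorical labels:
   * *lineage bias*: a clone is myeloid- or lymphoid-**biased** when its
     relative copy number in one lineage exceeds cot(22.5°) = 1 + √2 ≈ 2.4142
     times the other's, **specialized** when it is measurable
     (≥ 0.01 %WBC) in only one lineage, and *balanced* otherwise; the same
     rule applies to B-vs-T bias;
   * *cell-type combinations* ({Gr, B, T} subsets, CD4/CD8 T merged as T);
   * *high-abundance* flags (> 0.05 %WBC);
   * *temporal* classes — **early** / **late** / **persisted** by production
     at 2.5 and/or 6.5 months post-transplantation;
   * *dynamics* — persisted T-cell clones are **expanded** or **shrunken**
     by their 6.5:2.5 production ratio.

3. **Clustering** — clones pooled across mice are described by log2
   abundance over 4 cell types × 3 time points, rotated by PCA, linked in a
   shared-nearest-neighbor graph and partitioned by Louvain community
   detection (the generic equivalent of the Seurat
   FindNeighbors/FindClusters workflow); clusters are categorized as
   long-/middle-/short-term by when their members produce blood.  A UMAP
   embedding is provided for display only.

4. **Statistics** — one-tailed unequal-variance (Welch) t-tests between the
   HSC and HSC+MPP groups with the mouse as the replicate (\*P ≤ 0.05,
   \*\*P < 0.01), and Shannon clonal diversity per sample.

5. **Simulation** — a ground-truthed generator of complete in-silico
   experiments (read counts, flow fractions, optional toy FASTQ) built from
   clone archetypes, with a planted increase of late T-cell output in the
   HSC+MPP group.  Every pipeline stage is testable against known truth.

## Worked example

```python
from clonetrace import (
    SimulationConfig, generate_dataset, compute_clonal_abundance,
    filter_spurious_clones, classify_all, per_mouse_total_abundance,
    compare_groups,
)

config = SimulationConfig(sigma=0.3)          # 5 HSC + 7 HSC+MPP mice, 200 clones each
counts, flow, truth = generate_dataset(config, seed=1)
matrix = compute_clonal_abundance(counts, flow)
filtered, removed = filter_spurious_clones(matrix)
print(f"clones: {matrix.n_clones}, removed as spikes: {len(removed)}")

labels = classify_all(filtered)
print(labels.lineage_bias[6.5].value_counts().to_string())

pm = per_mouse_total_abundance(filtered, "CD4T", 6.5)
res = compare_groups(pm, "donor CD4T %WBC at 6.5 months", "greater", "HSC+MPP", "HSC")
print(res.summary())
```

prints

```
clones: 2458, removed as spikes: 58
balanced                748
undetected              699
myeloid_specialized     351
lymphoid_specialized    253
lymphoid_biased         231
myeloid_biased          118
donor CD4T %WBC at 6.5 months: HSC+MPP 14.54 ± 0.5922 (n=7) vs HSC 5.189 ± 0.2266 (n=5); one-tailed Welch t=14.747, df=7.64, p=3.454e-07 **
```

All 58 injected spike artifacts were removed (and nothing else); the
6.5-month bias tally mixes the seven simulated clone archetypes; and the
planted two-fold increase of late T-cell production in the co-transplanted
group is detected as a highly significant one-tailed Welch test (mean ± SEM
per group, mouse as the replicate).

The same pipeline is available from the shell:

```sh
clonetrace simulate --out-dir sim/ --seed 1
clonetrace quantify --counts sim/counts.tsv --flow sim/flow.csv --out abundance.tsv
clonetrace classify --abundance abundance.tsv --out labels.tsv
clonetrace cluster  --abundance abundance.tsv --out clusters.tsv
clonetrace compare  --abundance abundance.tsv --cell-type CD4T --timepoint 6.5 \
                    --direction greater --out comparison.tsv
clonetrace diversity --abundance abundance.tsv --out shannon.tsv
```

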