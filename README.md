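# cnaforest

Biomarker discovery from segment-level chromosomal microarray (CMA) data
in adult B-cell acute lymphoblastic leukemia (B-ALL). The package asks:
which gene-level copy-number alterations (gains, losses, mosaic losses)
and copy-neutral loss-of-heterozygosity (cnLOH) events separate patients
with MRD-positive remission after induction therapy from those who clear
MRD — and which of those events are disease-specific rather than common
population variants?

It is a library first (importable modules plus narrative scripts in
`examples/`), with a thin `cnaforest` CLI for batch runs. Intended users
are hematology-genomics analysts who have segment tables exported from
array-analysis software and per-sample clinical labels.

## The analysis

1. **QC filtering.** A call is valid when its SNP-marker support meets
   the platform minimum (>= 50 for cnLOH and gains, >= 20 for losses) and,
   for dosage events, |mean log2-ratio| > 0.25. A separate size filter
   (> 500 kb CNV, > 5 Mb cnLOH) is used only for genome-wide landscape
   reporting.
2. **Encoding.** QC-passed segments become a binary samples x features
   matrix; a feature is a `GENE:event` pair (mosaic losses merged into
   `loss`), set to 1 when any segment of that event overlaps the gene by
   >= 1 bp.
3. **Ranking.** A random forest scored by stratified 10-fold
   cross-validation; features ranked by Gini (mean impurity-decrease)
   importance, each annotated as a risk or favorable factor from group
   frequencies.
4. **Significance.** A label-permutation test: B = 1000 shuffles of the
   MRD labels, recomputing the CV accuracy each time;
   p = (1 + #{null >= observed}) / (B + 1).
5. **Validation.** Per-feature two-sided Fisher exact tests with odds
   ratios (Haldane–Anscombe corrected) and Benjamini–Hochberg adjustment.
6. **Clusters.** Top-ranked features chained into co-localized same-event
   region clusters (gap <= 1 Mb, >= 5 genes), labeled by cytoband span.
7. **Reference comparison.** Each patient matched to 3 same-sex,
   nearest-age healthy references; carrier frequencies compared between
   cohorts to flag somatic, disease-associated events.

A seeded synthetic-data module generates the full study layout (35
labeled patients, a 105-member matched pool, a gene catalog, and segment
calls with three planted region clusters plus background noise), so the
entire pipeline is testable end to end without any data download. See
`docs/methods.md` for model details and design rationale.

## Worked example

```python
from cnaforest import (ModelConfig, SimulationConfig, encode, mrd_labels,
                       permutation_test, qc_filter, rank_features,
                       detect_clusters, simulate_study)

study = simulate_study(SimulationConfig(seed=1))
ids = [p.sample_id for p in study.patients]
matrix = encode(qc_filter(study.patient_segments), study.catalog, ids)
labels = mrd_labels(study.patients, ids)

config = ModelConfig(n_folds=5, n_trees=150, n_permutations=49,
                     top_k=200, seed=1)
ranking = rank_features(matrix, labels, config)
result = permutation_test(matrix, labels, config)
print(f"observed CV accuracy {result.observed_accuracy:.3f}, "
      f"p = {result.p_value:.4f}")
for c in detect_clusters(ranking, study.catalog):
    print(c.label, c.canon_event, len(c.feature_ids), "genes")
```

prints

```
observed CV accuracy 0.800, p = 0.0200
16q13 loss 16 genes
19q13.2-19q13.31 cnLOH 12 genes
```

The observed accuracy is well above the ~0.51 majority-class rate, and
p = 0.02 is the smallest value attainable with 49 permutations — the
whole null distribution lies below the observed accuracy. The recovered
clusters are planted ones: a cnLOH run over the PSG-like gene tiling on
19q13 and the 16q13 mosaic-loss region. (The third planted cluster on
7p22.3 drew only 2 of 17 MRD-positive carriers at this seed — binomial
luck — and stays below the detector at this interactive model size; the
default 500-tree configuration used by the tests recovers it from most
seeds.) The same
analysis as a single call, with all interface files written to disk:

```sh
cnaforest run --seed 1 --out-dir results/
```

Each `examples/NN_*.py` script walks one capability (simulation, QC and
encoding, ranking and permutation, Fisher validation and clusters,
matched-reference comparison, full pipeline) and prints what the numbers
mean.

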