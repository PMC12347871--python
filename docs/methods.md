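# Methods

`cnaforest` implements a biomarker-discovery analysis for segment-level
chromosomal microarray (CMA) data in adult B-cell acute lymphoblastic
leukemia (B-ALL). The question it addresses: which gene-level copy-number
alterations (CNAs) and copy-neutral loss-of-heterozygosity (cnLOH) events
distinguish patients who remain minimal-residual-disease (MRD) positive
after induction therapy from those who clear MRD, and which of those
events are disease-specific rather than common constitutional variants.

## Input model and QC

A CMA call is a segment: a 1-based closed interval with an event type
(`gain`, `loss`, `loss_mosaic`, `cnLOH`), a SNP-marker support count, a
mean log2-ratio (absent for cnLOH, which is copy-neutral by definition),
and an optional mosaic fraction (the estimated fraction of cells carrying
the event). Validity filtering follows array-analysis practice:

| rule | default | note |
|---|---|---|
| cnLOH marker minimum | 50 | inclusive (`>= 50`) |
| gain marker minimum | 50 | inclusive |
| loss / mosaic-loss marker minimum | 20 | inclusive |
| dosage validity | \|mean log2R\| > 0.25 | strict; positive for gains, negative for losses |
| landscape CNV size | > 500 kb | strict ("exceeding"); reporting only |
| landscape cnLOH size | > 5000 kb | strict; reporting only |

Marker thresholds are read as minimum valid counts (inclusive at the
boundary); the size thresholds, used only for genome-wide landscape
reporting, are strict. The landscape subset never feeds the encoding.

Gene catalogs are 5-column BED-like files (chrom, start, end, symbol,
cytoband); the 0-based half-open disk convention converts to internal
1-based closed coordinates at the file boundary. Strand is ignored
throughout — copy-number events are strandless.

## Gene x event encoding

Each feature is a `SYMBOL:event` pair with mosaic losses merged into
`loss` (a subclonal and a clonal deletion of a gene are the same risk
variable), so the canonical event vocabulary is {gain, loss, cnLOH}. A
sample scores 1 on a feature when any of its QC-passed segments of that
canonical event shares at least one base with the gene. Design choices:

* Any >= 1 bp overlap sets the entry — no reciprocal-overlap fraction.
  The events of interest here are large (often arm-scale) relative to
  genes, so partial-overlap refinements would change almost nothing while
  adding a parameter.
* Presence is binary; the mosaic fraction does not weight the entry.
* A gene hit by both a loss and a cnLOH in one sample sets both columns:
  the variable is the (gene, event) pair, not the gene.
* Only pairs observed in at least one sample become columns; columns are
  ordered lexicographically by feature id, and the classifier additionally
  canonicalizes column order internally, so every downstream result is
  invariant to input ordering.

## Classifier and significance

A random forest (default 500 trees) is scored by mean accuracy over
stratified 10-fold cross-validation. Stratification matters: with a
17-versus-18 cohort, unstratified 10-fold splitting can produce test
folds containing a single class. Feature importances are mean impurity
decreases from one forest fit on all samples (a full-data fit, not
per-fold averaging), normalized to sum to 1; ties break lexicographically
by feature id. Because impurity importance is unsigned, each top feature
is annotated as a *risk* factor (more frequent among MRD-positive
samples) or *favorable* (otherwise) from the raw group frequencies.

Significance of the cross-validated accuracy uses a label-permutation
test: the labels are shuffled B times (default 1000) with the feature
matrix fixed — preserving class balance exactly — and the full CV
accuracy is recomputed per shuffle. The p-value is the add-one estimator

    p = (1 + #{null >= observed}) / (B + 1),

which is never zero and attains its minimum 1/(B+1) when the entire null
distribution lies below the observed accuracy (with B = 1000 that minimum
prints as 0.001). The add-one convention is chosen deliberately: a plain
proportion of exceedances would report p = 0 in exactly the situation
where the printed value of an empirical permutation p should be 1/(B+1).

## Univariate validation

Each feature's 2x2 table (carriers vs non-carriers by MRD group) is
tested with the two-sided Fisher exact test in the point-probability
convention (the two-sided p sums hypergeometric point probabilities not
exceeding the observed table's); two-sided exact tests are
convention-dependent, so this is stated explicitly and pinned by an
exhaustive-enumeration oracle in the test suite for every table with
total n <= 40. Odds ratios are (ad)/(bc) with the Haldane–Anscombe +0.5
correction applied to all cells whenever any cell is zero. Multiple
testing uses Benjamini–Hochberg by default (FDR is the appropriate
error rate for tens of thousands of correlated gene-event features;
Bonferroni and Holm are available behind a flag).

## Cluster detection and region reporting

Large CMA events hit runs of neighboring genes, so informative features
arrive in co-localized blocks. Among the top-k ranked features (default
k = 200), genes sharing a canonical event on one chromosome are sorted by
position and chained while consecutive gene intervals are separated by at
most `max_gap` (default 1 Mb); chains with at least `min_genes` genes
(default 5) are reported as region clusters labeled by their spanned
cytobands. The gap and minimum-size rules are artifact-level choices: 1 Mb
comfortably bridges intergenic distance inside a band without merging
bands across arms, and 5 genes suppresses coincidental pairs.

A region's group frequency is the mean of member-gene carrier fractions
per group (per-gene values are also reported). Region summaries give
min/median/max of segment size, marker count and overlapped-gene count
per group, over segments of the region's event type overlapping it.

## Matched reference comparison

To separate disease-associated events from constitutional variants, each
patient is assigned exactly three same-sex references from a healthy pool
(3x the cohort), minimizing absolute age difference, without replacement.
The default policy is deterministic greedy assignment in sorted patient
order with ties broken by reference id; a globally optimal mode solves
the assignment problem over all patient slots (each patient contributing
three) with `scipy`'s Hungarian solver. Matching uses demographics only,
never aberration data, so it cannot leak outcome information. Both
per-patient assignment and cohort-level frequency comparison are
supported; cohort-level carrier frequencies with per-feature Fisher tests
are the reporting default, since a 3x pool matched at cohort level is the
more conservative interpretation.

## Synthetic-data generator

No patient-level data are distributed, so the generator emulates the
study's structure for testing and demonstration:

* 17 MRD-positive and 18 MRD-negative patients; a 3x (105-member)
  reference pool with each patient's sex copied and age jittered by at
  most 2 years, making exact-sex nearest-age triple matching feasible by
  construction. Ages are uniform integers on 18–58; sex is
  Bernoulli(0.55 male).
* Three planted region clusters: a 19q13-like cnLOH region tiled with a
  PSG-family-like run of 12 genes (carrier frequencies 0.70 MRD+ / 0.16
  MRD- / 0.47 reference; a `table1` preset uses the raw carrier counts
  13/17 and 3/18 instead — the rounded headline rate and the raw carrier
  counts differ slightly, so both are exposed as presets rather than
  reconciled), and
  7p22.3-like and 16q13-like mosaic-loss regions (6/17 vs 1/18, absent
  from the reference pool). Each sample carries each planted event
  independently at its group rate; planted losses are subclonal
  (mosaic fraction uniform on [0.2, 0.8]) and all planted segments pass
  default QC by construction.
* Background noise: 1000 background genes tiled genome-wide
  (length-weighted across 22 autosome-scale chromosomes) and a
  Poisson(30) count of background segments per sample with log-uniform
  sizes on 100 kb – 10 Mb — spanning both landscape-filter regimes — and
  random event types. These counts are scaled down from genome scale
  (a real cohort of this kind yields ~10^3 aberrations per sample and
  ~10^4–10^5 observed gene-event variables) so a full analysis runs in
  seconds; the planted-signal-to-noise structure, not the absolute count,
  is what the downstream stages are sensitive to.
* One seed fans out to independent sub-streams in a fixed draw order
  (catalog, patients, patient segments, reference pool), so enlarging the
  catalog never perturbs cohort labels, and every artifact is
  byte-reproducible for a fixed seed.

What the generator does *not* model: realistic breakpoint distributions,
SNP-level marker placement, allele-specific states, recurrent focal
hotspots beyond the planted regions, or correlation between background
events and disease status. Passing tests therefore demonstrate that the
pipeline recovers region-level planted structure under independent noise
— not that it would rank any particular real-world gene list.

## Numerical and degeneracy choices

* Permutation p is never 0 (add-one estimator); a permutation result with
  p outside (0, 1] is rejected as invalid.
* `cv_accuracy` refuses single-class labels, and refuses fold counts
  exceeding the smallest class (stratified folds would otherwise be
  single-class), with an explanatory error.
* Constant feature columns are permitted and flagged, not dropped: a
  planted event carried by every sample is still a reportable finding
  even though it cannot split a tree.
* Odds ratios are always finite (Haldane–Anscombe); empty 2x2 margins
  give p = 1.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; derived seeds are masked below 2^31 for
  scikit-learn compatibility.

## Known limitations

* Recovery of a planted cluster is limited by the binomial draw of its
  carriers: at a 6/17-vs-1/18 contrast, roughly one run in ten draws a
  near-null realization (e.g. 2 carriers in each group) in which the
  cluster is statistically invisible; joint recovery of all three planted
  regions across repeated runs is correspondingly capped (empirically
  ~16/20 across fixed seeds). This is a property of small-cohort binomial
  sampling, not of the detector.
* Mean-of-folds CV accuracy on 35 samples moves by ±0.02 with the fold
  seed; worked-example comparisons therefore average a few fold seeds.
* The encoder is dense; at genuinely genome-scale feature counts
  (~10^5 columns) a sparse backing store would be the next step.
* The matching quality metric is integer-year age difference only;
  no covariate-rich or propensity matching is attempted.
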