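# Methods

`gpmatch` links gene presence/absence to phenotypes across a panel of
bacterial strains. This note records the model, the parameters that matter,
the synthetic-data generator's assumptions, and the design choices made
where the procedure was genuinely open.

## The matching model

The unit of association is a *phenotype*: one class of one experiment (e.g.
"growth level 0 on melibiose"). Each phenotype defines a binary
one-vs-rest classification task — the strains of that class against the
experiment's other retained strains — with the OG × strain occurrence
matrix as the feature space. The premise is that a trait caused by the
presence (or absence) of a gene cluster is predictable from occurrence
bits, and that genes that help the classifier are candidate causes.

### Phenotype preparation

* Continuous readouts are discretized into **equal-frequency terciles**
  (stable rank order, `numpy.array_split` sizing) and the middle tercile is
  excluded; the outer bins become classes "low" and "high". Rank-based
  bins are scale-free, which matters because readouts are incomparable
  across assay types (an API score of 2 means no growth; the same number in
  a growth curve means growth). Equal-width bins would be dominated by
  outliers on unbounded assays.
* Binary and ordinal readouts pass through, one class per observed level,
  labelled by the level digit.
* An experiment is **unusable** when fewer than two classes remain or any
  retained class has fewer than `min_class_size` (default 3) strains — the
  same support level the selection rule uses. The exclusion reason is
  logged per experiment.
* **Bags**: class imbalance is reduced by building `bags` (default 100)
  subsamples, each containing every minority-class strain plus an
  equal-size without-replacement sample of the majority class.

### Genotype preparation

* **Homogeneity filter**: an OG is removed when its population variance
  p(1−p) < `var_min` (default 0.05), p being the presence fraction.
  Population rather than n/(n−1)-corrected variance is used deliberately:
  only p(1−p) makes "present in ≥36 of 38 strains" fall exactly below the
  0.05 threshold (0.0499 vs 0.0513 corrected), giving the closed form
  {count ≤ 2 or ≥ 36} at n = 38. The filter is idempotent.
* **Correlation collapse**: OGs are grouped by single linkage (connected
  components) over pairwise Pearson r ≥ `corr_threshold` (default 0.95) of
  occurrence vectors; the lexicographically smallest member represents the
  group. Single linkage is required for consistency with top-list
  augmentation, which must re-add *any* gene correlated to *any* selected
  gene. Perfectly co-occurring operon members therefore enter
  classification once and re-emerge together in the output.
* Missing genotype calls are treated as absent (calls are binary upstream);
  the count is logged.

### Forest training and contribution scores

One forest of `trees` decision trees is grown per bag (scikit-learn trees
under an in-package bagging loop, so per-tree bootstrap membership, votes
and leaf estimates are all accessible). `max_features` is ⌊√m⌋. For a
tree, out-of-bag (OOB) strains are all retained strains not drawn into its
bootstrap — including strains left out of the bag entirely.

* **Accuracy** is the fraction of strains whose OOB majority vote (over all
  trees of all bags) matches their class; vote ties break toward the
  negative class (conservative for relation calling); strains never OOB are
  excluded with a warning.
* **Contribution score** c(g, s): casewise permutation importance. For
  each tree and OOB strain s, the margin of s's true class (p_true −
  p_other from the tree's leaf estimate) is computed before and after
  permuting g's values among the tree's OOB strains; c(g, s) is the mean
  decrease over all OOB occurrences of s. Trees that never split on g
  contribute exactly zero. Positive c(g, s) means g helps classify s. The
  margin-decrease form was chosen over raw vote-count decrease because it
  is smoother at small OOB sizes and preserves the sign convention the
  support rule needs.

### Iterative selection, gate, top list

Per phenotype: `replicates` (default 3) independent forests are trained;
a gene is *consistent* when it has c(g, s) > 0 for at least `min_support`
(default 3) positive-class strains in **every** replicate (intersection —
the strictest reading, which is what curbs spurious relations).
Inconsistent genes are removed and the loop repeats until at most
`stop_removals` (default 5) genes are removed in an iteration. Removal is
per phenotype; a gene dropped for one phenotype stays active for others.

* **Accuracy gate**: phenotypes classified below `gate` (default 0.60,
  boundary kept) are dropped from all downstream outputs. The gating
  accuracy is the mean OOB accuracy of the **first** iteration's
  replicates, i.e. of forests trained on the full pre-selection gene set.
  This is a deliberate choice: accuracy measured after label-informed gene
  removal is inflated by feature-selection bias — on label-permuted data
  the post-selection OOB accuracy reaches 0.8–0.96, so a gate on it would
  reject nothing, while the pre-selection estimate stays near or below
  chance (0.25–0.58 measured) and cleanly rejects null phenotypes. The
  last iteration's accuracy is kept as a diagnostic field.
* **Ranking**: phenotype importance I(g) sums c(g, s) over positive-class
  strains only ("the strains exhibiting the phenotype"). The top `topk`
  (default 50) genes are kept, with all genes tied at the k-th value
  included so membership never depends on tie order; then every member of a
  correlation group whose representative was selected is appended carrying
  the representative's importance, with provenance recorded.

### Relation classification and gene clusters

For each selected gene and phenotype, the presence fraction f over the
phenotype's positive strains gives the presence state: f ≥ 0.75
predominantly present, f ≤ 0.25 predominantly absent (the complement of
"absent in at least 75%"), otherwise subset. Subset states are flagged
*partial* (analogous-gene signature, drawn black). The importance level is
high/low around the per-phenotype **median** of selected importances
(configurable); a two-level factor is the smallest that yields the 6-colour
scheme, and the median makes the split scale-free across phenotypes.
Inverse relations are not computed separately — they surface as
predominantly-absent states for a positive class and are simply tagged.

Genes annotated with any of the keywords `transposase`, `integrase`,
`phage` (case-insensitive substring, configurable) are removed before
cluster extraction, as such relations are likely spurious. Remaining
related genes of one reference strain are sorted by start position per
replicon and chained whenever consecutive starts differ by ≤ `proximity_bp`
(default 2500 nt, inclusive); chains of ≥2 genes are reported as clusters,
the rest as singletons in genomic order. Strand is ignored — the rule uses
start positions only, so divergently transcribed neighbours chain
naturally.

### Strain clustering from phenotypes

Per experiment category, strains are clustered by UPGMA (unweighted
average linkage, `scipy.cluster.hierarchy`) over Euclidean distances
computed from the raw measurements of experiments with data for every
strain. Measurements are fed unstandardized within a category (readouts in
one category share a scale; a z-score flag exists but is off by default).
A category is skipped, with the reason logged, when fewer than
`min_complete` (default 6) complete experiments remain — one more than the
five that justified skipping the smallest category in the motivating
panel. Merge heights on a metric input are non-decreasing; the dendrogram
is exported as an ultrametric newick tree (leaf depth = half the root merge
height).

## The synthetic-data generator

`gpmatch.synth` emulates the data a pan-genome CGH panel study produces.
Defaults mirror a 38-strain panel: 4026 OGs of which 149 are single plasmid
genes, 4 reference strains, and 130 experiments over 5 categories (sugar 29
ordinal, antibiotic 32 continuous, metal 30 ordinal, milk/polysaccharide 20
continuous, other 19 binary).

* **Background matrix**: each OG's presence frequency is drawn once from
  U(0.25, 0.85) (plasmid OGs U(0.10, 0.50)) and strains sample
  independently, which puts per-strain presence counts in the ~2100–2250
  range, inside the 1903–2563 band such panels show.
* **Genomes**: one circular chromosome per reference strain (plus one
  plasmid replicon for the first two), genes laid left-to-right with
  lengths U(300, 1500) bp and intergenic gaps U(50, 400) bp. Only start
  positions matter downstream (the 2500-nt rule), so richer structure would
  be untestable decoration.
* **Planted relations**: a *direct* cluster's genes share one carrier-set
  occurrence pattern and the target phenotype is positive iff the cluster
  is present, flipped with probability 1 − `penetrance`; *inverse* inverts
  the indicator; a *partial* pair plants two disjoint-carrier clusters
  whose union explains the trait. Continuous targets draw from
  class-conditional Gaussians 3 sd apart (configurable — the study gives no
  readout distributions, so separation is a power knob, not a claim).
  Occurrence bits of planted genes flip with probability `label_noise`
  (CGH call errors), except in the home reference strain so coordinates
  stay meaningful.
* **Missingness** is two-level: a fraction (default 0.4) of experiments is
  missing-prone, and their cells go missing at `missing_rate` (default
  0.10). Uniform cell-level missingness would leave almost no complete
  experiment at 38 strains, which real panels do not show.
* **Probe signals**: each reference gene is tiled with probes; present
  genes draw log-normal intensities around a base level, absent genes 3
  doublings lower, so log2 query/reference ratios centre at 0 and −3 and a
  deleted cluster appears as a contiguous low segment. The default
  segment-absence call is median log-ratio ≤ −1.
* **Annotations**: a 5% decoy fraction of background genes gets
  transposase/integrase/phage annotations to exercise the mobile-element
  filter; planted genes never do.

What the generator does **not** emulate: phylogenetic relatedness between
strains (occurrence bits are independent given frequency, so there is no
population structure to confound associations), linkage between background
genes, hybridization physics, or dose-response structure within ordinal
assays. Passing recovery tests therefore shows the machinery is correct
and powered under the stated noise model — not that real panels are free of
confounding by shared ancestry.

## Problem sizes and numerical choices

* Tests and the acceptance script run forests of 5–10 trees per bag
  (500–1000 trees per replicate across 100 bags) for recovery and null
  studies, and 2 trees per bag for the full-scale end-to-end run; these
  sizes were chosen once as the package's scaled-down study sizes and give
  stable results across seeds. `ForestConfig.n_trees` defaults to 500 per
  bag for production use.
* All randomness flows from one master seed through named
  `numpy.random.SeedSequence` spawn keys (stage, phenotype id, replicate,
  iteration), so identical seeds give bit-identical outputs and any
  phenotype can be recomputed in isolation.
* Degenerate inputs: empty matrices, all-missing experiments, single-class
  experiments, zero-probe regions, zero reference intensities and empty
  keyword lists are handled explicitly (error or no-op as documented in the
  API).
* Outputs are written via write-then-rename, so an aborted run leaves no
  truncated tables.

## Known limitations

* No multiple-testing correction across phenotypes (none is applied in the
  procedure this implements); the accuracy gate is the only
  false-positive control.
* The contribution score's exact form (margin decrease) is one defensible
  realization of casewise importance; raw vote-count decrease would rank
  similarly but is coarser at small OOB counts.
* With ~38 strains, partial relations are intrinsically hard to detect
  (few strains per analogous cluster); the generator can plant them, but
  recovery is not guaranteed at that sample size.
* Strain relatedness is not modelled; on real panels, associations can
  reflect shared ancestry rather than causation.
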