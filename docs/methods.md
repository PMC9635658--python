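# Methods

## Model and assumptions

`eqtg` treats causal-gene prioritization as highly imbalanced binary
classification over a gene-by-feature table. The working assumptions are:

* causal genes (eQTGs) share measurable gene-level properties — more
  protein-interaction partners, more variable expression, more and more
  diverse protein domains, more introns — that generalise from the known
  positive set to unseen eQTL regions;
* the genes of one eQTL region are exchangeable apart from those
  properties, so ranking within a ±1 Mbp window by classifier probability
  is meaningful;
* negatives are "everything not known positive", i.e. the negative pool is
  contaminated with undiscovered causal genes at a low rate. The
  resampling ensemble is the mitigation: each of the M members sees all
  positives but a different negative draw, so no single mislabeled gene
  dominates, and the mean over members smooths out draw-specific
  artifacts.

Forest members are standard scikit-learn random forests; a member's
probability for a gene is the fraction of trees voting positive, and no
calibration is applied — only the *ranking* of mean probabilities is ever
consumed, and every rank statistic in the package is invariant under
strictly monotone transforms of the scores.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `pos_neg_ratio` | 200 | negatives drawn per positive for each member; approximates the causal fraction of a real eQTL region. Grid-searched in tuning (1, 5, 10, 50). |
| `M` (ensemble size) | 5,000 | production default; guarantees every pool gene is drawn at least once with high probability at small ratios. Examples and tests use M = 50–100, which already stabilises the mean score. |
| `n_trees` | 200 | per-member forest size; grid {100, 200, 500}. |
| `min_samples_split` | 2 | grid {2, 5, 10}. |
| `max_features_rule` | `sqrt` | per-split feature subsampling; conventional forest default, grid also offers fractions 0.25 and 0.5. |
| CV design | 50 × 50 | positive 4:1 re-splits × negative re-draws = 2,500 paired evaluations; validation negatives are drawn at the same ratio as training and disjointly from that repetition's training negatives. |
| window `half_width` | 1,000,000 bp | 1 Mbp up- and downstream of the candidate's span; upstream/downstream are genomic left/right regardless of strand (the window is symmetric, so strand cannot matter). |
| recall cutoffs | 5, 10, 20 % | strict `<` comparison, matching the rank definition ("rank 10%" = 10% of the region scores higher). |
| correlation-cluster threshold | r ≥ 0.6 | inclusive, signed Pearson; an `absolute` switch thresholds |r| instead. |

### Seed scheme

All randomness descends from one master seed. Ensemble member k's seed is
derived by `SeedSequence(master).spawn()[k]`, so any member is
reconstructible in isolation and scores are invariant to member order.
Cross-validation streams are keyed by `(master_seed, tag, split_index[,
sampling_index])` and deliberately do **not** depend on the
hyperparameters or the feature set: every grid point, and every reduced
model in the leave-one-out importance analysis, sees the identical
positive splits and negative draws, making AUC differences paired and
sharply reducing their variance.

## Negative-demand cap

With the production ratio (1:200) and a positive set of ~200 genes, the
requested 40,000 negatives exceed the ~27,000 genes available outside the
positive set. `sample_negatives` therefore samples without replacement
capped at the pool size and logs a warning: at the cap every member trains
on the whole pool and members differ only through tree randomness; at
smaller ratios the member negative sets differ materially, which is where
the resampling design actually earns its keep.

## Feature construction choices

* **PPI count** — partners over edges with STRING combined score ≥ 700
  ("below 700" removed, so 700 itself is kept); undirected duplicates are
  collapsed keeping the maximum score, self-loops dropped. A gene absent
  from the network counts 0 (absence is informative, not missing).
* **Expression variability** — samples sharing a group label (tissue,
  accession, or experiment) are averaged first; the features are the mean
  and sample standard deviation (ddof = 1) across the group means. This
  gives "across tissues/accessions" semantics that are robust to
  unbalanced replicate counts. Values are used untransformed by default;
  a `log2(x+1)` switch exists because the appropriate scale is
  data-dependent, and the choice is recorded in output metadata.
* **Structural features** — intron count is exon count − 1 on the
  *representative transcript*, defined as the transcript with the greatest
  summed exon length, ties broken by lexicographically smallest transcript
  id. This is a reproducible proxy for "the representative gene model" of
  an annotation release. Splice variants = number of mRNA records; domain
  counts come straight from the (gene, domain) annotation rows (total) and
  their distinct domain ids (unique).
* **Missing values** — outer-join assembly imputes absent cells to 0 and
  records them in an explicit boolean mask. Zero-fill keeps every gene
  scorable genome-wide and matches the count-like semantics of most
  features; all descriptive statistics (medians, correlations, rank-sum
  tests) are computed on the unimputed view so imputation never leaks into
  inference.
* **Correlations** — pairwise-complete Pearson; a zero-variance feature
  has *undefined* (missing) correlations rather than 0, so it can never
  join a correlation cluster spuriously. Clusters are connected components
  of the thresholded graph — the simplest transitive closure of the
  pairwise rule — so chains of pairwise-correlated features merge.

## Numerical conventions and degenerate inputs

* AUC is the tie-aware rank statistic (ties count ½); a single-class
  validation set is an error, not a default value.
* Rank percent counts strictly greater scores; ties are not "higher". A
  mid-rank alternative exists but is off by default.
* Training rows are assembled in sorted gene-id order, making member
  training invariant to the row order of the feature table.
* The permuted-label control re-deals the positive label uniformly over
  the combined gene universe once per positive-split repetition (not once
  globally), so the control has the same resampling variance structure as
  the signal run it calibrates.
* Grid-search ties are broken toward fewer trees, then smaller ratio.
* Genome-wide score summaries break score ties by gene id, making tail
  gene lists deterministic.

## What the synthetic data does and does not emulate

`eqtg.simulate` generates: feature tables whose informative columns are
location-shifted by `effect_size` standard deviations for positives, with
correlated blocks built from shared latent factors (expected within-block
correlation = `block_corr`) and optional uniform missingness; toy genomes
of non-overlapping gene spans arranged in windows separated by more than
the 2 Mbp query window, one planted positive-like gene per window; and raw
PPI/expression/GFF3/domain files in the exact dialects the feature readers
consume, with ground-truth values recorded alongside. Defaults (200
positives, 5,000-gene pool, 20 features, 3 informative) mirror the shape
of the real problem — ~200 positives against ~27,000 genes — at a scale
that keeps full test runs in minutes.

Deliberately *not* emulated: linkage disequilibrium and the block
correlation structure of real genotypes, eQTL-mapping noise, the skewed
and heavy-tailed marginals of most real features (a negative-binomial
mode exists for count-like columns but the default is Gaussian), label
contamination of the negative pool, and any relationship between a gene's
position and its features. Passing tests therefore demonstrate that the
machinery is correct and calibrated — chance-level control AUC, planted
signal recovered by importance analysis and window ranking — not that any
particular real-data AUC or recall will be achieved.

## Problem sizes used in the shipped tests

The test suite and acceptance script run the full algorithms at reduced
scale chosen as the package's own CI sizes: the calibration check uses the
default 200/5,000 table with a 10 × 10 CV and 100-tree members; the
2,500-repetition bookkeeping check uses 10-tree members at ratio 1 on a
100/2,000 table; the planted-causal benchmark uses 20 windows × 100 genes
with an M = 100 ensemble at ratio 5 (ratio ≥ 10 would hit the pool cap on
a toy genome and collapse the resampling diversity).

## Known limitations

* The ensemble reports no uncertainty on a gene's mean probability;
  member-level spread is available but not summarised.
* Leave-one-out importance understates features that have correlated
  twins; cluster-mode importance mitigates but depends on the 0.6
  threshold.
* The negative pool is assumed clean; contamination biases AUC estimates
  slightly downward but is not modelled.
* Legacy features are consumed as given — no recomputation or
  normalisation is attempted, and their provenance is the caller's
  responsibility.
* Window construction needs a gene annotation with the same gene ids as
  the feature table; no id mapping beyond optional STRING prefix/alias
  handling is provided.
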