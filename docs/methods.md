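# Methods

## Clone definition and assembly

A clone is the set of rearrangements within one sequencing library that
share identical TRBV and TRBJ gene calls and CDR3 amino-acid sequence.
Gene calls are normalized before keying: ambiguous comma-separated calls
keep the first listed gene, and the IMGT allele suffix (`*NN`) is stripped
at the default gene-level granularity (allele-level keying is available
via `gene_level=False`). A unique sequence must be detected at least
twice (`min_copies=2`) to be called a clone; this suppresses spurious
singletons created by per-read errors. The evidence threshold is applied
per library by default; `donor_min_copies_filter` offers the alternative
scope in which copies are pooled across all of a donor's libraries before
thresholding, for workflows that treat detection "within an individual"
donor-wide.

The abundance filter used before TRBV-usage and overlap analyses removes
clones whose copy number lies strictly below 50% of the sample's mean
copy number (`total_copies / n_clones`). The threshold is computed once
on the input table and applied in a single pass — it is not recomputed on
the survivors, which would change the mean. Ties at exactly half the mean
survive ("below" is read strictly). Frequencies are renormalized over the
survivors.

## Diversity statistics

Clonality of a sample with clone frequencies `p(x)` over `L` unique
clones is `1 − H(p)/log₂L`, with `H` the Shannon entropy in bits: 0 for a
uniform repertoire, 1 for a monoclonal one. For `L = 1` the ratio is 0/0
and clonality is defined as 1 (a monoclonal sample is maximally clonal);
the case is logged. Clonality is invariant to rescaling all counts and
strictly increases when copies move from a smaller clone to a larger one.
It is *not* monotone under merging two clones: merging lowers both `H`
and the `log₂L` normalizer, and e.g. counts (1,1,2) → (2,2) drop
clonality from 0.054 to 0. The test suite asserts the grouping property
that does hold (merging never increases `H`).

Top-N summaries rank clones by copies descending (ties broken by CDR3,
then V/J, lexicographically, so results are order-invariant) and report
the fraction of copies in rank bands, by default top 10 / 11–100 /
101–1000 / >1000.

Clonality-vs-age uses ordinary least squares per lineage × subset cell,
pooling all tissue sites and treating every sample as one point (matching
how such scatter plots are usually drawn; no within-donor weighting).
Groups with fewer than 3 samples or constant age are skipped with a
warning; a constant response returns slope 0 with p = 1 rather than the
0/0 t-statistic.

Diversity analyses use replicate 1 only by default, which normalizes cell
input across samples; overlap analyses use replicates 1 and 2.

## TRBV usage

Usage is computed on unique clones (each clone counts once regardless of
copy number) after the 50%-of-mean cutoff, as percentages over the genes
present. In the gene × sample matrix, genes absent from a sample are 0%.
"Centered and scaled" for heatmap/PCA input is implemented as per-gene
standardization across samples — the only reading that makes samples
comparable — with the sample-SD (`ddof=1`) convention; zero-variance
genes map to z = 0 rather than NaN. PCA and hierarchical clustering of
the scaled matrix are delegated to standard routines; this package
guarantees a deterministic input matrix. The CD4-vs-CD8 comparison
reports per-gene means ± SE and raw two-sided two-sample t-test p-values,
with an optional statsmodels multiple-testing adjustment
(the raw-star convention is common in this literature, so raw is the
default).

## Overlap

Cosine similarity is computed between clone-frequency vectors over the
union of clone keys. A sample-pair value is the mean of the four
replicate pairings cos(A1,B1), cos(A1,B2), cos(A2,B1), cos(A2,B2), with
the copy cutoff applied to each replicate table separately; if a
replicate is missing the mean degrades to the available pairs and
records how many were used. Per-donor, per-lineage matrices over
subset × tissue populations are symmetric with unit diagonal, and a
complete-linkage leaf ordering is provided for heatmap rendering.

Compiled summaries classify within-donor, within-lineage pairs into three
designs — same subset in two sites, different subsets within one site,
different subsets in different sites — and pool pairs across donors
(`pool_level="donor"` first averages within donor). The optional
between-subject normalization is within-donor centering with grand-mean
restoration (value − donor mean + grand mean), a standard within-subject
SE correction for repeated measures; raw means are always reported
alongside and single-pair groups carry SEM 0 with a `sem_defined=False`
flag.

## Sequence distances and the stratum hierarchy

Before any distance work, non-productive rearrangements are removed and
any clone key present in more than one sample is removed from all samples
(so every analyzed clone is private to one sample and clone size cannot
leak into sequence similarity). From each cleaned table, `n` clones
(default 500; 250 for embedding input) are drawn uniformly without
replacement with a seeded generator after canonical key sorting, so draws
are machine- and order-independent; undersampled tables take all clones
and are flagged.

Levenshtein distance is the unit-cost edit distance, computed with edlib;
the tests verify it exhaustively against an independent
dynamic-programming implementation on short strings and check the metric
axioms. Hamming distance is defined only for equal-length strings; pairs
of unequal length are skipped (excluded from means) under the default
policy. The symmetrized Kullback–Leibler divergence between two samples'
TRBV usage adds a pseudocount of 1 to every gene of the cohort-union
support in both samples, normalizes to frequencies, and uses the natural
log; the entropy in clonality deliberately stays in log₂ — both scales
follow the conventional definitions of their respective statistics.

Sample pairs are classified by the finest metadata level at which the two
samples differ: replicate (same donor/lineage/tissue/subset), then
subset, tissue, lineage, donor. The strata partition the pair set. For
edit/Hamming metrics the unit of analysis is the mean cross-clone
distance of a sample pair — clone pairs are averaged within the sample
pair first, then sample pairs within a stratum, so unequal sampling depth
cannot dominate a stratum. For the KL metric the per-pair divergence is
the unit. Neighboring strata are compared with two-sided unpaired
Student's t tests (pooled variance; Welch via `equal_var=False`). tSNE or
any other 2-D embedding of the clone × clone matrix is out of scope; the
package emits the symmetric distance matrix with aligned tissue/subset
labels.

## Clone tracking

For one donor (optionally one lineage), clones are ranked by copies
summed over all samples, replicates summed within a sample by default
(a replicate-1-only switch exists). A clone's track reports copies per
site, each site's subset composition (fractions summing to 1 where the
site total is positive), and the clone's share of the site's total
copies — both framings of "size" used in line-circle figures.

## Synthetic cohorts

The generator emits AIRR-format tables plus a sample sheet and a ground
truth bundle, from a single integer seed through one deterministic
`numpy` generator (same seed ⇒ byte-identical output). Per
donor × lineage × subset it draws a clone pool:

* **Clone sizes** follow a geometric rank-frequency law `wᵢ ∝ (1−d)ⁱ`
  (the printed rank-abundance bands suggest no particular parametric
  law; geometric is the simplest with a tunable concentration). Default
  pools — TEMRA (400 clones, d=0.05), TEM (1200, 0.008), TRM (1200,
  0.0065), TCM (2500, 0.0008) — give pool clonality 0.34 / 0.18 / 0.15 /
  0.02, the observed subset hierarchy. An optional per-subset
  `age_decay_slope` grows `d` exponentially with donor age (default on
  for TEM and TEMRA, off for TRM/TCM), emulating age-associated clonal
  expansion of circulating subsets.
* **Tissue structure**: each clone has a home tissue and joins each other
  tissue with the subset's sharing probability (defaults TEMRA 0.8 > TEM
  0.5 > TRM 0.2 > TCM 0.05, the observed overlap hierarchy).
* **TRBV usage** is drawn from lineage-level Dirichlet weights multiplied
  by a per-donor log-normal signature shared across that donor's lineages
  (sd 0.8, so between-donor usage divergence exceeds half the
  between-lineage divergence and donor remains the top KL stratum).
  TRBJ is uniform.
* **CDR3s** are `C` + interior + `F` with one shared interior length
  distribution (7 + Binomial(10, ½)) across all groups, so edit-distance
  effects cannot be length artifacts. Nested positional imprints place an
  entity-preferred residue at reserved interior positions with
  probability equal to the imprint strength: donor 0.9 (positions 1–2),
  lineage 0.6 (3–4), tissue 0.4 (5–6), subset 0.0. Preferred residues are
  distinct across entities of a level, so the expected between-entity
  mismatch excess at a position is the squared strength — giving
  separable strata ordered donor > lineage > tissue > subset ≈ replicate.
  Only the tissue-vs-subset contrast is an empirically documented
  phenomenon; the donor/lineage imprints are the generator's own device
  for making the full hierarchy testable.
* **Libraries**: each sample yields two replicate multinomial draws of
  `depth` cells (default 20 000) from the same tissue-restricted pool.
  An error process emits `Binomial(depth, error_rate)` singleton records
  (default rate 0.005) whose CDR3 carries one random substitution of a
  frequency-weighted parent clone; a small non-productive background
  (rate 0.01) with random CDR3s exercises productivity filtering.

Ground truth records per-sample pool clonality and top-10 mass, realized
per-tissue-pair Jaccard sharing, injected error keys, and the imprint
assignments.

### Study presets and problem sizes

Four presets pin the conditions used by the tests and
`scripts/acceptance.py`:

* `clonality_study_config` — 2 donors × 2 lineages × 3 tissues, default
  pools, for subset-hierarchy recovery.
* `sharing_study_config(s)` — 1 donor, one CD8 TEM pool over two tissues
  at sharing `s`, depth 8 000, error-free, for the overlap-vs-sharing
  calibration (20 values of `s`).
* `aging_study_config` — 6 donors aged 28–63, CD8 TEM/TRM pools of 500
  clones with decay 0.003 at depth 30 000. These pools keep the rarest
  clone well covered, which matters: with the default (larger, steeper)
  pools the plug-in clonality estimator is biased in a decay-dependent
  way and attenuates the age slope, whereas under full coverage the
  estimate converges to pool truth (|error| < 0.002 at 10⁵ cells) and
  OLS recovers the generative slope within 1 SE.
* `hierarchy_study_config` — 3 donors × 2 lineages × 3 tissues × 2
  subsets × 2 replicates, pools of 4 000 clones at depth 4 000. Detection
  is deliberately incomplete so each replicate retains private clones
  after overlapping-clone removal, as in real repertoires; 60 clones per
  sample are then drawn for the distance work, which keeps the full
  72-sample hierarchy (≈ 9 × 10⁶ clone-pair distances) under a minute on
  one CPU.

### What the generator does not emulate

Clone pools are disjoint across subsets, so cross-subset overlap is 0 by
construction — the generator models the tissue-sharing axis only, and
compiled cross-subset overlap summaries on synthetic data are not
informative about real TEM–TRM lineage relationships. There is no VDJ
recombination mechanics (no D segment, no nucleotide junctions, no
convergent recombination), no thymic selection, no CMV-like
antigen-driven expansions, and PCR/sequencing error is reduced to
single-substitution singletons. Passing recovery tests therefore
demonstrates that the statistics measure what they claim under known
structure, not that real repertoires satisfy these generative
assumptions.

## Numerical and degenerate-input conventions

Empty clone tables pass through filters unchanged; an all-filtered
assembly returns an empty table with a warning rather than an error.
Cosine is undefined (error) for zero vectors; self-pairs are excluded
from pair classification. Frequencies sum to 1 within 1e-9; usage
columns to 100 within 1e-6. Unparseable rearrangement rows are skipped
and counted (`rows_in = rows_out + skipped`), never silently dropped.
Distance matrices are float32 (the hierarchy cohort's pooled matrix is
≈ 75 MB at float64 but ≈ 37 MB at float32; distances are small integers,
exactly representable). Levenshtein of an empty string is the other
string's length, handled before calling edlib.
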