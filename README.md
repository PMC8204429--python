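# tcrtissue

Analysis of bulk TCR-β repertoires sorted by donor, lineage (CD4/CD8),
memory subset (TCM, TEM, TRM, TEMRA), tissue site and biological
replicate. The package is aimed at immunologists asking how memory T cell
clones are distributed and maintained across blood and tissues: which
subsets are clonally expanded, how widely clones are shared between
anatomic sites, whether TRBV gene usage segregates by lineage, and whether
sequence-similar clones track with tissue or with subset.

It consumes AIRR-community rearrangement TSVs (one per sequencing library)
plus a sample sheet, and implements the full downstream pipeline:

| stage | statistic |
|---|---|
| clone assembly | clones = identical TRBV + TRBJ gene calls + CDR3 amino-acid sequence, detected ≥ 2 times |
| diversity | clonality `1 − H(p)/log₂L` (Shannon entropy in bits over `L` clones), top-N clone proportions, clonality-vs-age OLS |
| TRBV usage | % of unique clones per gene after a 50%-of-mean copy-number cutoff; per-gene z-scores for heatmaps/PCA; CD4-vs-CD8 t tests |
| overlap | cosine similarity `Σaᵢbᵢ/(‖a‖‖b‖)` of clone-frequency vectors, averaged over the four replicate pairings |
| sequence distance | CDR3 Levenshtein/Hamming distances and symmetrized TRBV KL divergence `Σᵥ pᵢln(pᵢ/pⱼ)+pⱼln(pⱼ/pᵢ)` (pseudocount 1) between non-overlapping clones, stratified by replicate / subset / tissue / lineage / donor |
| clone tracking | per-clone copies per site with subset composition (line-circle plot data) |
| simulation | seeded multi-donor, multi-tissue synthetic cohorts with ground truth |

## Worked example

```python
from tcrtissue import simulate, diversity, overlap

# a synthetic two-donor cohort with the default subset clone-size pools
cohort = simulate.generate_cohort(simulate.clonality_study_config(), seed=7)
tables = simulate.cohort_clone_tables(cohort, replicate_1_only=True)

frame = diversity.clonality_frame(
    [diversity.clonality_of_table(t) for t in tables if t.n_clones]
)
print(frame.groupby("subset")["clonality"].mean().round(3))
```

```
subset
TCM      0.026
TEM      0.115
TEMRA    0.198
TRM      0.114
```

Clonality runs from 0 (maximally diverse) to 1 (monoclonal). The estimates
reproduce the configured subset hierarchy — TEMRA is by far the most
clonally expanded, TEM and TRM sit together at intermediate clonality, and
TCM is nearly maximally diverse. The same tables feed the other analyses,
e.g. the top-N clone bands of one TEMRA library
(`diversity.top_n_fraction`): the 10 largest clones hold 42.6% of all
copies. Replicate-averaged cosine overlap between two sites:

```python
pair = overlap.sample_pair_cosine(bld_replicates, spl_replicates)
print(pair.cosine_mean)   # 0.814 for TEMRA, 0.331 for TRM (Bld vs Spl)
```

— widely circulating TEMRA clones give high between-site overlap while
tissue-resident TRM clones overlap far less, each value being the mean of
the four replicate-pair comparisons after the per-replicate copy cutoff.

A command-line layer mirrors the library
(`tcrtissue simulate|assemble|clonality|topn|age-regression|usage|overlap|hierarchy|track`);
every subcommand reads the AIRR TSV + sample-sheet directory layout that
`tcrtissue simulate --seed 3 --out cohort/` writes and emits tidy TSVs.

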