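# equomgs

Marker-gene metagenomic species (MGS) profiling, ANI-based genomospecies
delineation and equol-pathway genotyping for gut-microbiome cohort studies.

## The problem

Shotgun-metagenomic cohort studies repeatedly find that the gut commensal
*Adlercreutzia equolifaciens* is depleted in patients with metabolic liver
disease, with prevalence and abundance falling as severity increases, and
that its genomes split into two geography-linked genomospecies that differ
in carriage of the four-enzyme equol biosynthesis pathway (daidzein
reductase *dzr*, dihydrodaidzein reductase *ddr*, tetrahydrodaidzein
reductase *tdr*, and a racemase). `equomgs` re-implements the full
computational chain behind such findings as a tested, reusable library —
and pairs every stage with a synthetic-data generator that plants known
ground truth, so the whole pipeline is exercisable and verifiable without
multi-gigabyte downloads.

The stages, in the order they run:

1. **Quantification** — filter read alignments at ≥95% nucleotide identity,
   count genes with two-step multi-mapper allocation (unique counts first,
   then proportional redistribution), convert to coverage depth
   (count × read length / gene length), and quantify an MGS as the mean
   coverage of its 100 marker genes, nulled when <10% of markers are seen.
   Undetected samples get the artificial log10 sentinel −10 ("M10").
2. **Cohort statistics** — per-group prevalence; Fisher's exact test
   (probability-mass two-sided); Mann–Whitney U with AUC = U/(n₁n₂);
   tie-corrected Kruskal–Wallis; exact two-sample Kolmogorov–Smirnov; and a
   combined Wilcoxon+KS screen for discriminating MGS with
   Benjamini–Hochberg correction. Plus the HOMA-IR and Friedewald clinical
   formulas.
3. **Population genomics** — genome QC (completeness ≥80%, contamination
   ≤5%), fragment-based k-mer ANI (identity = 100·m^(1/k)), UPGMA on
   1 − ANI/100 with flat clusters at the 95% ANI species cutoff, non-metric
   MDS ordination, and chi-squared cluster×metadata association.
4. **Pathway genotyping** — six-frame translated search (BLOSUM62, affine
   gaps, seeded with exact amino-acid 4-mers), detection at identity ≥90%
   and query coverage ≥90%, producer call when ≥75% of the four proteins
   are detected.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate a healthy-vs-cirrhosis cohort (102/112 samples, planted carriage
probabilities 0.57/0.16, one-decade depth depletion), profile it, and test
the association:

```python
from equomgs import (CohortSpec, simulate_cohort, mgs_abundance,
                     log10_with_sentinel, prevalence_by_group,
                     fisher_exact, mann_whitney_auc)
from equomgs.synthetic import cohort_mgs_model

spec = CohortSpec(seed=1)
coverage, metadata, truth = simulate_cohort(spec)
profile = mgs_abundance(coverage, cohort_mgs_model(spec))
profile["log10"] = log10_with_sentinel(profile)

prev, table = prevalence_by_group(profile["detected"], metadata["group"],
                                  spec.groups)
print(prev)
fr = fisher_exact(table.to_numpy())
mw = mann_whitney_auc(profile.loc[metadata["group"] == "healthy", "log10"],
                      profile.loc[metadata["group"] == "cirrhosis", "log10"])
print(f"Fisher p = {fr.p_value:.3g}  AUC = {mw.effect:.3f}  p = {mw.p_value:.3g}")
```

Output:

```
healthy      0.656863
cirrhosis    0.151786
Name: prevalence, dtype: float64
Fisher p = 2.2e-14  AUC = 0.773  p = 5.63e-15
```

The estimated prevalences (65.7% and 15.2%) recover the planted carriage
probabilities up to binomial sampling noise; the AUC of 0.77 says a random
healthy sample out-ranks a random cirrhotic sample 77% of the time, driven
jointly by the prevalence gap and the planted abundance shift.

The genome side runs the same way from a simulated population
(`GenomePopulationSpec` → `build_ani_matrix` → `upgma` → `cut_clusters` →
`genotype_genome`), or end to end:

```bash
equomgs run --seed 1 --outdir results/run1     # all stages, all artifacts
equomgs simulate --seed 1 --outdir results/sim # synthetic data only
equomgs ani --genomes-dir results/sim/genomes --outdir results/ani
```

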