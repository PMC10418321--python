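# Methods

This note documents the models, rules and numerical choices behind
`equomgs`, and what the synthetic-data generators do and do not emulate.

## Quantification model

Reads aligned to a gene catalog arrive as records `(read_id, read_length,
[(gene_id, nucleotide identity %), ...])`. Candidates with identity below
95% are discarded (the threshold absorbs intra-species nucleotide
variability against a non-redundant catalog); records left without
candidates are dropped. Optional subsampling draws a uniform
without-replacement sample of records to a per-sample target; samples
already below the target are kept with a warning rather than dropped, since
per-sample targets are user-supplied.

Gene counts use two-step allocation: uniquely mapping reads are counted
first; each multi-mapped read then distributes weight 1 across its
candidates proportionally to the unique counts, or equally when every
candidate has zero unique evidence (the equal split keeps exact mass
conservation in a degenerate case the rule itself does not address).
A single proportional pass is used; no iterative (EM-like) re-normalisation
(`sharing=single_pass` in the config records this choice).

Coverage is computed as mean sequencing depth, `count x read_length /
gene_length`. The alternative normalisation `count / (gene_length x
read_length)` is available as `coverage_formula=normalized`; depth is the
default because downstream the quantity is treated as an estimated
sequencing coverage.

A metagenomic species (MGS) is quantified as the arithmetic mean coverage
of its marker genes — canonically 100 species-specific core genes — with
zeros included in the mean. "Seen" means coverage strictly greater than 0.
If fewer than 10% of the markers are seen, the abundance is set to null and
the species is called not detected. For plotting and rank statistics,
undetected samples receive the artificial sentinel −10 on the log10 scale
("M10"); if data ever place a real value at or below the sentinel, the
sentinel is lowered (floor of minimum − 1) with a warning.

## ANI estimation and genomospecies delineation

Genomes pass QC when completeness ≥ 80% and contamination ≤ 5% (both
inclusive); isolate genomes without QC values pass with a flag.

Directed ANI splits the query into non-overlapping 3,000-bp fragments
(whole contigs when the genome is shorter than one fragment) and matches
each fragment's 16-mers against an index of reference k-mers that occur
exactly once in the reference. Matched k-mers vote for the alignment
diagonal (reference position − query offset); the winning diagonal, summed
over a ±5 bp band to tolerate small indels, must collect strictly more than
5 votes for the fragment to count as mapped. The per-fragment identity
inverts the expected intact-k-mer fraction: if the per-site identity is
`p`, a k-mer survives with probability `p^k`, so `identity = 100 · m^(1/k)`
with `m` the matched fraction. ANI is the mean identity over mapped
fragments; the symmetric ANI of a pair is the arithmetic mean of the two
directions (one direction is used if only one maps; fully unalignable pairs
receive a floor of 70% — below any species threshold — and are flagged, so
the matrix stays complete for clustering). An exact per-fragment
global-alignment mode (`mode="alignment"`) exists and serves as the oracle
in tests. Fragment length, k, the vote threshold and the floor are all
configurable.

On 200-kb uniform-substitution genomes the estimator recovers planted
divergences of 1–8% to within 0.5 percentage points; the inversion's
Jensen bias is O(Var(m)) and negligible at these fragment sizes. Known
limitation: per-fragment diagonals assume local collinearity, so dense
indels (or rearrangement breakpoints inside a fragment) split the vote and
bias identity downward; the synthetic generator defaults to indel-free
genomes.

Clustering is classic UPGMA on the distance `1 − ANI/100`: merge the
closest pair; inter-cluster distance is the size-weighted average of member
distances. Ties are broken by the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest member id), which
makes dendrograms bit-reproducible. Genomospecies are flat clusters cut at
distance 0.05 (95% ANI); membership uses strict `height < cutoff`, so a
merge exactly at the cutoff separates clusters — consistent with reading
"95% cutoff" as delineating species below 95% ANI. Cluster labels are
ordered by decreasing size.

Ordination is non-metric MDS (SMACOF majorization with isotonic
regression) on the same distance matrix: 8 random restarts plus one
classical-scaling start, 500 iterations maximum, tolerance 1e-6 on the
stress change, reporting Kruskal stress-1 of the best restart. The
embedding is deterministic given the seed.

Cluster–metadata association (e.g. phylogroup × host geography) uses the
Pearson chi-squared test on the r×c contingency table, with a flag raised
when any expected count falls below 5.

## Equol-pathway genotyping

The pathway comprises four enzymes — daidzein reductase (dzr),
dihydrodaidzein reductase (ddr), tetrahydrodaidzein reductase (tdr) and a
racemase. Each protein is searched against all six reading frames of every
contig (bacterial genetic code, table 11), with frames split at stop codons
and each stop-free segment searched separately, mirroring how translated
search tools treat stops. Segments sharing at least two exact amino-acid
4-mers with the query are aligned locally (BLOSUM62, affine gaps open 11 /
extend 1); queries shorter than twice the seed word force exhaustive
alignment, and an `exhaustive` flag disables seeding entirely. The
maximum-scoring hit decides detection; partial hits are not merged across
segments (conservative).

Identity is computed over aligned columns (gap columns excluded from the
denominator); coverage is aligned query residues over query length — the
common convention for translated-search outputs. A protein is detected when
identity ≥ 90% and coverage ≥ 90% (inclusive); a genome is an equol
producer when at least 75% of the four proteins are detected, i.e. 3 of 4.

The four bundled queries are synthetic stand-ins of realistic enzyme
lengths (450/300/380/250 aa) generated from a fixed seed; real pathway
proteins exist in public databases under their accessions and can be
supplied as a FASTA via the `equol` subcommand.

## Cohort statistics

All tests are two-sided. Fisher's exact test uses the probability-mass
two-sided rule: sum hypergeometric probabilities of all tables (fixed
margins) no more probable than the observed one, with a 1+1e-7 relative
slack against floating-point artefacts. Mann–Whitney U uses midranks; the
effect size AUC = U/(n₁n₂) is the probability a random case value exceeds a
random control value, ties counting half. Its p-value is exact
(null-distribution enumeration via the Gaussian-binomial recurrence) for
untied samples with n₁+n₂ ≤ 20, otherwise a tie-corrected normal
approximation with continuity correction — the common statistical-package
default. Kruskal–Wallis uses the tie-corrected H with a chi-squared
reference. The two-sample KS test computes D on the integer lattice and an
exact p-value by lattice-path counting (vectorised cumulative-sum
recursion) whenever the samples are untied and n₁n₂ ≤ 10,000, otherwise
the Kolmogorov asymptotic with the standard small-sample correction.

The discriminating-MGS screen runs a Wilcoxon rank-sum and a KS test per
MGS, adjusts each family with Benjamini–Hochberg, and flags an MGS when
both adjusted p-values fall below α = 0.05 (the conservative reading of a
"combined approach"; `either` and Fisher's combination are config
options). The screen's KS p-values are asymptotic, which keeps the
vectorised screen fast; at the screen's sample sizes the exact/asymptotic
difference is immaterial for ranking.

Calibration caveat: with equal group sizes n=m the KS statistic is discrete
on a 1/n grid, so its attainable test sizes near a nominal α are quantised
(at n=50: 0.039 and 0.067 bracket 0.05). This is a property of the
statistic, not of the implementation, and the rank tests do not share it.

Clinical formulas: HOMA-IR = fasting glucose (mmol/L) × fasting insulin
(mU/L) / 22.5; Friedewald LDL = TC − HDL − TG/2.2 (mmol/L), rejected when
TG ≥ 4.6 mmol/L per the formula's own validity constraint.

## Synthetic-data generators

The generators are pure functions of a spec and a seed and define the
conditions all tests run under.

**Genome populations.** A uniform-composition ancestor (default GC 0.64,
typical of the organism family modelled; 100 kb default length) spawns one
base genome per phylogroup; the per-lineage substitution rate is solved
from `2r(1−r) + (2/3)r²  = b` so the realized base–base divergence matches
the between-group target (default 0.09). Members mutate from their base at
the within-group rate (default 0.02), making member–member within-group
divergence ≈ 0.04 and between-group ≈ 0.13 — comfortably straddling the
0.05 species cut. Substitutions are i.i.d. per site with no
transition/transversion bias (ANI depends only on the substituted-site
count); indels default to zero. Equol operons are planted per-phylogroup
with carriage probabilities (0.60, 0.088); reverse translation uses seeded
uniform codon choice (codon bias is irrelevant to protein-level search),
and planted genes are flanked by stop codons. Host geography is drawn from
per-phylogroup profiles over {Asia, Europe, North America, other} (0.82
Asia in group 1; 0.92 Europe+North America in group 2); host species and
MAG/isolate status follow the 154:10:1 and 154:11 proportions of the
genome collection modelled. Realized pairwise divergences are recorded on
the substitution-only sequences, before operon planting.

**Cohorts.** A zero-inflated lognormal: per sample, carriage ~
Bernoulli(group prevalence); carriers draw an MGS depth `10^N(μ_g, σ_g)`
and spread it over the marker genes through per-marker multiplicative
log-normal noise (σ = 0.5 natural log) and Poisson read sampling;
non-carriers are zero on all markers. Defaults model a healthy-vs-cirrhosis
contrast: groups of 102/112, prevalences 0.57/0.16, log10 depth means
−1.0/−1.8 with SD 0.7 (about a one-decade depletion). Carriers are
guaranteed at least ⌈0.1·n_markers⌉ nonzero markers (one read is added to
leading zero markers if Poisson sampling leaves fewer), so the 10% rule
never misclassifies a planted carrier; background genes carry independent
lognormal-Poisson noise.

**Read assignments.** Per-gene read counts are Poisson with the requested
expected depths; a configurable fraction of reads receives 1–3 extra
candidate genes, and identities are uniform in [95, 100].

What the generators do *not* emulate: sequencing error profiles, real
read-mapping ambiguity structure (multi-mapping here is uniform across
genes rather than homology-driven), compositionality of relative
abundances, correlated marker dropout, horizontal transfer or
rearrangement, and real phylogenetic depth beyond the two-level divergence
construction. Passing tests therefore demonstrate correctness of the
algorithms under the stated models, not performance on real cohorts.

## Problem sizes

The test and acceptance workloads are scaled for a laptop-class single
core: ANI recovery uses 200-kb genome pairs (20 seeds × 4 divergences),
delineation uses 20-genome populations over 20 seeds, genotyping uses 40
60-kb genomes, the screen uses 900 MGS × 60 samples over 100 replicates,
and null calibrations use 10⁴ replicates. The acceptance script runs a
60-genome population and a full default cohort.
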