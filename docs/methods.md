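# Methods

This note records the models, conventions and numerical choices behind
`heterogroup`, and what the synthetic-data tests do and do not establish
about real panels.

## Genotype representation and quality control

Genotypes are stored as alternate-allele dosages in {0, 1, 2} with a single
missing sentinel; positions stay 1-based as in HapMap and VCF. QC rules are
applied marker-first, each marker tallied under the first rule it fails:
(1) biallelic / no-indel, (2) marker call rate ≥ 0.90, (3) MAF ≥ 0.05;
then samples with missing fraction > 0.20 are dropped. "Call rate" is a
per-marker quantity and "missing rate" per-sample — the reading under
which the two thresholds are not redundant, matching common SNP-QC
tooling. A VCF GQ field, when present, masks calls below 20 before any
other rule; HapMap input carries no GQ, so the rule is a no-op there. All
downstream statistics use pairwise-complete denominators; no imputation,
liftover or multi-allelic decomposition is attempted. The VCF writer emits
records in matrix order rather than coordinate-sorted order so that a
write/read round-trip reproduces the marker map exactly.

## Synthetic structured panels

`popsim.simulate_panel` collapses an inbred panel's breeding history into
four statistical knobs:

- **Differentiation.** Ancestral frequencies p ~ Uniform(0.1, 0.5);
  subpopulation frequencies follow Balding–Nichols,
  Beta(p(1−F)/F, (1−p)(1−F)/F), so F plays the role of Fst. Default
  F = 0.10 (moderate differentiation); the default ancestral-MAF range
  yields a panel mean MAF near 0.29.
- **Homozygosity.** Latent genotypes are Hardy–Weinberg draws; each
  heterozygote is retained with probability residual_het / E[het] and
  otherwise collapsed to a random homozygote, hitting a target observed
  heterozygosity (default 0.02, i.e. S7-level inbreeding) without
  simulating the selfing pedigree explicitly. Downstream statistics
  consume only frequencies and heterozygosity, so pedigree depth adds
  nothing at far greater cost. If the target exceeds the Hardy–Weinberg
  expectation a warning is raised and heterozygosity stays at the HW
  level.
- **Admixture.** A fraction of lines (default 0.10) draw per-individual
  Dirichlet(α = 1) ancestry proportions and a per-locus origin from them.
  The ground-truth label of an admixed line is its majority ancestry —
  the only meaningful "true" assignment for a mixed genome.
- **Map.** Markers are assigned round-robin to 10 chromosomes with
  increasing positions. Loci are independent: no linkage disequilibrium,
  recombination map, selection, or genotyping-error model beyond optional
  uniform missingness. Every statistic the pipeline computes is an
  unlinked-marker statistic, so this sacrifices no relevant structure —
  but it means the generator cannot exercise LD-sensitive workflows, and
  passing tests say nothing about them.

Defaults (376 lines as 180/137/59 from three founders, 1904 SNPs, F = 0.10,
OH 0.02, 10% admixed) emulate an elite early-maturing maize inbred panel.
Identical config including seed gives bit-identical output.

## Diversity indices

OH is the fraction of heterozygous calls; EH = 2p(1−p). PIC defaults to
Botstein's form, 1 − Σp² − Σ_{i<j} 2p_i²p_j² (≤ 0.375 for a biallelic
marker); the gene-diversity form 1 − Σp² (≤ 0.5) is available as
`method="gene_diversity"`, and summaries name the method used — published
panel means above 0.375 imply the gene-diversity form. Shannon H, inverse
Simpson 1/D and richness S need a unit of counting; per chromosome and
genome-wide we count **distinct multilocus genotype classes** (unique
dosage rows restricted to the chromosome), the only reading that produces
index values far above 1 on a several-hundred-line panel. Output metadata
records this choice (`attrs["abundance_unit"]`). Hill-number ordering
(1 ≤ 1/D ≤ S, exp(H) ≤ S) is enforced by property tests.

## Distance matrices

All four metrics use pairwise-complete loci. IBS distance is the fraction
of non-shared alleles: per locus the unordered genotype pairs share
2 − |x_i − x_j| of 2 compared alleles, so d = Σ|x_i − x_j| / (2·m_ij).
Gower treats dosage as numeric with per-marker observed range (the
canonical Gower definition; a `fixed` mode uses the theoretical range 2) —
on fully homozygous data both coincide with the mismatching-locus
fraction. Euclidean is unscaled by default with an optional missing-data
rescaling. Jaccard binarizes to alternate-allele presence (configurable to
minor-allele presence); pairs with an empty union get distance 0 by
convention. Distance summaries break ties at the extremes by lexicographic
label order.

## Agglomerative clustering and the CCC

All seven linkages run through the Lance–Williams update. Centroid, median
and Ward.D2 apply their coefficients to squared dissimilarities and report
square-rooted heights, so all merge heights live on the input distance
scale; Ward follows the ".D2" convention (squared input, sqrt
back-transform), which matches both R's `ward.D2` and scipy's `ward`.
Ties at the minimal merge distance are broken by the smallest (row, col)
index pair — trees are deterministic. Centroid/median height inversions
are permitted and flagged (`has_inversions`), not corrected; cophenetic
distances take the lowest containing merge regardless, so they remain
well-defined under inversions. Cutting into k groups removes the k−1 last
merges in merge order (for monotone trees, exactly the k−1 highest) and
numbers groups by first-leaf appearance. The implementation is verified
two ways: against scipy's `linkage` on Euclidean inputs, and against a
naive first-principles agglomerator (cross-pair extremes/means, recursive
WPGMA/WPGMC formulas, the pairwise-sum centroid identity) on hundreds of
random matrices.

The CCC is the Pearson correlation between the n(n−1)/2 input distances
and their cophenetic counterparts; zero variance in either vector yields
NaN (undefined), never 0. The metric × linkage grid picks its arg-max.

## K selection and membership

PCA centers (optionally unit-scales) mean-imputed dosages, excludes
zero-variance markers, and fixes component signs (largest-magnitude
loading positive). Partitions come from k-means with 10 restarts and a
fixed seed. Elbow takes the K with maximal second difference of the
within-cluster sum of squares; silhouette maximizes mean silhouette width
(K = 1 skipped with a warning); the gap statistic uses a uniform draw over
the bounding box of the scores, B = 50 references, and the standard
"smallest K with gap(K) ≥ gap(K+1) − s(K+1)" rule. Evanno ΔK is
|L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over replicate log-probabilities,
defined for interior K; it is invariant to constant shifts, needs ≥ 2
replicates per K, and zero replicate variance is flagged rather than
divided by.

Ancestry-fraction thresholds (default 0.80) assign each line to its
arg-max group or designate it admixed. When no external ancestry matrix is
supplied, fractions are derived from the K-partition with a Gaussian
kernel, f_ik ∝ exp(−½ (d_ik/σ_k)²), where σ_k is the mean centroid
distance of cluster k's own members; this scale-aware choice sends
well-embedded lines toward fraction 1 and splits lines between clusters.
It is a deterministic geometric proxy, not a probabilistic ancestry model;
on default synthetic panels it designates ~12% admixed against a simulated
10%.

## AMOVA, Φ_PT and gene flow

The one-level AMOVA uses squared distances: SS_total = Σ_{i<j} δ²/N,
SS_within = Σ_g Σ_{i<j∈g} δ²/n_g, df = (k−1, N−k),
n0 = (N − Σn_g²/N)/(k−1), V_w = MS_within,
V_a = (MS_among − MS_within)/n0 and Φ_PT = V_a/(V_a+V_w). The default
input is squared Euclidean dosage distance (the codominant-data
convention); any matrix can be passed with a flag declaring its scale.
Negative V_a is reported raw and truncated at zero only inside Φ_PT. The
permutation p-value uses the (b+1)/(m+1) estimator with labels shuffled
under a mandatory seed; the comparison statistic is the *untruncated* Φ,
which keeps the null distribution of p approximately uniform (truncation
would pile permuted values onto the observed zero). Pairwise Φ_PT applies
the same machinery to each group pair's sub-matrix.

Gene flow uses Nm = (1 − Φ)/(2Φ). The haploid-style constant 2 (rather
than 4) is adopted because it reproduces all four published (Φ, Nm) pairs
of the motivating study to ≈1% once the 3-decimal rounding of Φ is
accounted for. Differentiation bins follow the conventional scale: ≤ 0.05
low, ≤ 0.15 moderate, ≤ 0.25 high, above that very high.

## Problem sizes and what the tests show

Recovery studies run on 20 seeded panels of 300 lines × 1000 SNPs (three
founders at F = 0.10, OH 0.02): elbow, silhouette and gap each recover
K = 3 in ≥ 90% of seeds, and mean Φ_PT lands within ±0.03 of 0.10. At the
full default scale (376 × 1904) the complete pipeline runs in about half a
minute. Estimator-recovery tests across F ∈ {0.05, 0.10, 0.20} use
unadmixed panels, where the generating F is the estimand; with the default
10% admixed fraction Φ_PT is genuinely diluted (to ≈ 0.083 at F = 0.10 and
≈ 0.166 at F = 0.20) — a property of admixture, not estimator bias.

Known limitations: on a minority of admixed panels the k = 3 cut of the
average-linkage tree isolates a few admixed outliers as a splinter cluster
instead of separating two founder groups (median adjusted Rand index
against truth ≥ 0.9 across seeds; unadmixed lines recover at ARI 1.0).
This mirrors breeding practice, where admixed lines are designated by the
membership threshold rather than trusted to the tree. Dataset-level
numbers of any particular real panel (mean PIC, mean distance, a specific
CCC value, hybrid counts, group sizes) depend on that panel's genotypes
and are not targets of the synthetic tests; only structural findings
(number of groups, differentiation level, dominance of average linkage in
the CCC grid) are expected to transfer.
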