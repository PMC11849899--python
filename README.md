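# heterogroup

Genotype-based heterotic grouping for inbred breeding panels.

Hybrid breeding programs cross inbred lines from complementary *heterotic
groups* — sets of lines that combine well with other groups but not among
themselves. Given a diploid biallelic SNP genotype matrix for a panel of
inbreds (HapMap or VCF), this package:

1. applies marker/sample quality control (biallelic, no indels, call rate,
   MAF, per-sample missingness);
2. computes per-marker and per-chromosome diversity indices — observed and
   expected heterozygosity, MAF, polymorphism information content (PIC),
   Shannon *H*, inverse Simpson *1/D*, and richness;
3. builds four genetic distance matrices — identity-by-state (IBS), Gower,
   Euclidean, and Jaccard;
4. clusters under seven agglomerative linkage rules (single, complete,
   average/UPGMA, McQuitty/WPGMA, centroid, median, Ward.D2) and scores
   every distance × linkage combination by its **cophenetic correlation
   coefficient** (CCC) — the Pearson correlation between input distances
   d(i,j) and the dendrogram heights c(i,j) at which pairs first merge —
   selecting the combination that best preserves the distance structure;
5. chooses the number of subpopulations K from PCA scores (elbow,
   silhouette, gap statistic) or from a STRUCTURE-style log-probability
   table via the Evanno ΔK = |L″(K)| / sd(L(K)) statistic, and designates
   lines with maximum ancestry fraction < 80% as admixed;
6. cuts the selected tree into heterotic groups, summarizes within-group
   distances, and enumerates candidate hybrids: cross-group pairs with
   distance ≥ a dissimilarity benchmark (default 0.35);
7. quantifies group differentiation with a distance-based AMOVA:

       Φ_PT = V_a / (V_a + V_w),   V_a = (MS_among − MS_within) / n0,
       n0 = (N − Σ n_g² / N) / (k − 1),

   with permutation p-values, pairwise Φ_PT, and gene flow
   Nm = (1 − Φ) / (2Φ).

Because real elite panels are rarely public, a **synthetic-panel
generator** (`heterogroup.popsim`) draws structured, near-homozygous
panels under the Balding–Nichols model with known ground truth, so every
stage is testable end to end.

## Worked example

Simulate a 376-line panel (three founder populations of 180/137/59, 1904
SNPs on 10 chromosomes, F = 0.10, 2% residual heterozygosity, 10% admixed)
and run the whole pipeline:

```bash
heterogroup simulate --n-per-subpop 180,137,59 --n-markers 1904 --seed 1 --out panel
cat > cfg.yaml <<EOF
input_path: panel.hmp.txt
input_format: hapmap
k_range: [1, 2, 3, 4, 5, 6]
k_method: silhouette
n_permutations: 999
seed: 1
out_dir: out
EOF
heterogroup run --config cfg.yaml
```

prints (28 s on a laptop-class core):

```json
{
  "best_metric": "jaccard",
  "best_linkage": "average",
  "best_ccc": 0.8611085475406982,
  "k_used": 3,
  "group_sizes": { "1": 126, "2": 193, "3": 57 },
  "n_hybrids": 42501,
  "phi_pt": 0.090143529662938
}
```

Reading the output: after QC 1870 of 1904 markers survive; the panel shows
mean MAF 0.293 and observed heterozygosity 0.021, as simulated. Average
linkage dominates the CCC grid (here paired with the Jaccard matrix,
CCC 0.86); silhouette on PCA scores recovers K = 3, matching the three
founder populations; 11.7% of lines fall below the 80% membership
threshold and are designated admixed, close to the simulated 10%; and the
AMOVA attributes 9% of squared-distance variation to differences among the
three heterotic groups (Φ_PT = 0.090, "moderate"), with pairwise gene flow
Nm ≈ 4.8–5.3 migrants per generation. `out/` additionally holds the QC
report, per-marker and per-chromosome diversity tables, the full CCC grid,
PCA scores, the membership table, the dendrogram in newick, the hybrid
list and the AMOVA tables.

Every stage is also available on its own (`heterogroup qc | diversity |
distance | cluster | structure | heterotic | amova`) and as plain library
functions.

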