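# Methods

## The model

Translation elongation is treated as a sequence of per-codon waiting
times: the time to synthesise protein *j* is `t_j = Σ_i S_ij τ_i`, with
`S_ij` the count of codon *i* in gene *j* and `τ_i` the mean time to
place the cognate amino acid — a quantity set by the concentration of
the cognate tRNA and by proofreading against near-cognates. Protein
dynamics follow

    d[P]_j/dt = (ρ_R / t_j) · [mRNA]_j − (k_d + μ) · [P]_j

where `ρ_R` is the number of ribosomes per mRNA, `k_d` the protein
degradation rate constant and `μ` the growth (dilution) rate; the
synthesis rate constant is written as ribosomes per mRNA divided by the
time each ribosome needs per protein. At steady state, and assuming
only `t_j` differs between proteins while `ρ_R`, `k_d`, `μ` differ only
between conditions, fold changes between two conditions obey

    f_P = C · T_j · f_R,
    C   = (ρ_R2/ρ_R1) · (k_d1 + μ1)/(k_d2 + μ2),
    T_j = t_j(1)/t_j(2).

`T_j` is the codon-composition-dependent part of the amplification
factor; `C` is shared by all genes in a dataset. The analysis variable
is `x_j = log2(f_P/f_R) = log2(C) + log2(T_j) + noise`, so clustering
genes by codon frequency groups genes of similar `T_j`, and the share
of variance of `x` lying between clusters measures how much of the
protein–mRNA decoupling codon usage explains.

## Sequence layer

Coding sequences are read from FASTA in frame 0 (inputs are declared
CDSs; there is no ORF scanning or strand resolution). A record is
dropped, and logged, if its length is not a positive multiple of 3 or
if more than `max_ambiguous_fraction` (default 0.05) of its bases are
non-ACGT; within retained genes, individual ambiguous triplets are
skipped rather than dropping the gene. The default codon alphabet is
the 61 sense codons in alphabetical order — elongation involves only
sense codons — with a flag restoring all 64. The amino-acid alternative
translates sense codons under the standard nuclear code (no alternative
codes) and normalises over the 20 amino acids. Frequency rows are
counts divided by the gene's total codon content and sum to 1 within
1e-9.

## Clustering

The SOM is a batch Kohonen map on a rectangular sheet, default 5×4 = 20
units. Twenty clusters is the operating point used for genome-scale
yeast codon data; grid shape, epochs and radii are configurable. Per
epoch every gene is assigned to its nearest codebook vector (Euclidean
distance, ties broken toward the lowest unit index) and each codebook
vector is replaced by the Gaussian-neighborhood-weighted mean of the
assigned rows; the neighborhood radius (in grid-distance units) decays
geometrically from `sigma_initial` (default 2.5) to `sigma_final`
(default 0.25) over the epochs (default 30). Batch updates make
training deterministic given the initial codebook; the default
`pca_linear` initialisation spreads codebook vectors along the data's
first two principal axes with SVD signs fixed, so whole runs are
bit-reproducible. A `random` init (seeded sampling of data rows) is
kept for robustness checks.

Epoch updates are *monotone-guarded*: if the smoothed batch update
would raise the quantization error (possible while the neighborhood is
wide, since the update optimises the neighborhood-weighted distortion
rather than the quantization error itself), the codebook is kept
unchanged for that epoch and training proceeds with the next, smaller
radius. The guard triggers rarely, changes results at the 1e-6 level
when it does, and makes the per-epoch error trace non-increasing by
construction.

Empty units are allowed; they are reported with size 0 and drop out of
the variance partition. The U-matrix is the mean codebook distance to
the 4-neighborhood; the "PCA-like" companion view projects codebook
vectors onto the data's first two principal axes.

## Variance partition

For each fold-change dataset, genes with nonpositive or missing `f_P`
or `f_R` are excluded with logged reasons (never imputed). Then

    SS_within  = Σ_c Σ_j (x_jc − x̄_c)²
    SS_between = Σ_c n_c (x̄_c − x̄)²

and `SS_total = SS_within + SS_between` holds to 1e-9 relative by
construction (the within-cluster formula is the standard one; a
published variant placing the inner sum inside the square does not
satisfy the additivity identity and is treated as a typographical
slip). The F statistic is `(SS_between/df1)/(SS_within/df2)` with
`df = (k−1, N−k)` over nonempty clusters, upper-tail p from the F
distribution. Degenerate inputs are flagged rather than erroring:
`SS_total = 0` reports undefined fractions with an `all_x_identical`
flag; `SS_within = 0` with signal reports F = ∞, p = 0 and a
`zero_within` flag. Singleton clusters are retained and contribute 0 to
SS_within. Because log2 fold-change data are only approximately normal,
a permutation p-value (label shuffling, add-one correction
`(r+1)/(n_perm+1)`) is provided alongside the F-test.

## Enrichment

Per (cluster, term) pair with at least one annotated member, the
upper-tail hypergeometric probability `P(X ≥ k)` is computed for `k`
annotated genes in a cluster of `n` universe members, with `K` carriers
among `N` universe genes, then adjusted by Benjamini–Hochberg step-up.
The correction is applied jointly across all (cluster, term) tests by
default — the more conservative choice — with a `per_cluster` switch.
The default significance cutoff is 0.01. Annotations come from a
two-column TSV or GAF 2.x (gene column 2, term column 5, `!` comments
skipped) and are taken as given: ontology structure is not modelled, so
terms are not propagated up a DAG — a known limitation relative to
GO-aware tools.

## Synthetic data generator

The generator draws `τ_1` per codon lognormal (log-mean 0, log-sd 0.5);
`τ_2` equals `τ_1` in the *null world* (every `T_j = 1`) or is redrawn
independently in the *alternative world*. Cluster archetypes are
Dirichlet over the 61 sense codons with concentration 0.3 — sparse
enough to give clusters distinct codon profiles of the kind selection
produces. Defaults are 20 clusters × 100 genes at 500 codons/gene:
desk-scale but genome-like (a yeast-genome-scale run is 20 × 300).
Per gene, counts are multinomial at the archetype frequencies, `f_R` is
lognormal (log2-sd 1), and `f_P = C·T_j·f_R·ε` with `log2 ε ~
N(0, σ)`; noise enters multiplicatively on `f_P` only, consistent with
the log2 analysis variable. `C` is a single scalar per dataset
(default 1). Gene length is fixed per simulation; a realism knob for
length jitter was considered and omitted since `T_j` is scale-free in
the counts.

The noise solver inverts the generator's own variance accounting: the
between-cluster variance of `x` is the size-weighted variance of
`log2(C·T_c)` over archetypes, and the within-cluster variance is `σ²`
plus the delta-method multinomial sampling variance of `log2 T_j`
(`Var(ln t1 − ln t2)` from multinomial moments, order 1/n in gene
length). Solving `f* = V_b/(V_b + σ² + V_sampling)` for σ makes the
realised between-fraction land on the target within sampling error;
ignoring the sampling term biases it low by ≈ 0.03 at 500 codons/gene.

What the generator does *not* emulate: ribosome traffic and initiation
limitation, wobble-pairing kinetics, mRNA secondary structure,
dataset-specific missingness, and correlated measurement error between
`f_P` and `f_R`. Passing the recovery tests therefore shows the
statistical machinery is correct and calibrated under the model's own
assumptions — not that real proteome datasets satisfy those
assumptions.

## Pipeline

The pipeline clusters the genome once and evaluates any number of
fold-change tables against that shared clustering. Every exclusion
(frame, ambiguity, nonpositive fold change, unannotated gene) is
counted in the report. Numbers are written at full precision in JSON;
the human-readable summary rounds to 4 significant digits. All
stochastic steps derive from a single config seed, so a rerun with the
same config is byte-identical apart from timestamps. Stage failures
abort with the stage name; a MANIFEST marks incomplete outputs.

## Numerical and design notes

- Ties in best-matching-unit search break toward the lowest unit index
  (fixed, arbitrary).
- The SOM has no theoretically preferred grid; 5×4 with a Gaussian
  4-neighborhood kernel was chosen for determinism and simplicity.
  Published cluster memberships from other SOM implementations are not
  reproducible without their (unstated) hyperparameters, so cluster
  size distributions are treated qualitatively.
- `partition_variance` re-indexes labels over nonempty clusters, so
  `k_used` counts only clusters that kept ≥ 1 retained gene.
- Problem sizes in the test-suite simulations (e.g. 1,000 null
  replicates at 2,000 genes; 20 recovery replicates at 2,000 genes ×
  500 codons; one 6,000-gene end-to-end run) were chosen as the
  smallest sizes at which the calibration and recovery properties are
  statistically sharp.
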