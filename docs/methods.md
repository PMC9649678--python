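# Methods

This note documents the models and procedures `lnmet` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Quality control

Cells pass three filters, computed per sample (patient × tissue), in this
order and before anything else touches the counts:

1. detected genes (log10) ≥ sample median − `mad_multiplier` × MAD;
2. mitochondrial count fraction ≤ sample median + `mad_multiplier` × MAD;
3. total UMIs ≥ `umi_floor`.

Defaults: `mad_multiplier = 3`, `umi_floor = 300`. The MAD is the raw median
absolute deviation — no 1.4826 consistency constant — because the filters are
defined directly in MAD units, not as robust standard deviations. When every
cell in a sample is identical the MAD is 0 and the band collapses onto the
median, removing nothing. Mitochondrial genes are identified by the
case-insensitive symbol prefix `MT-`. A cell failing several rules is counted
under each rule in the report; the removal is the union.

The doublet rule operates on clusters, not cells: a cluster is removed when
its mean doublet score exceeds 0.6 or it expresses markers of more than one
cell type. "Expresses a marker" means more than 25% of the cluster's cells
have at least one count of some marker of that type; 25% mirrors the
`min.pct` conventions used elsewhere in the pipeline. Doublet scores are
consumed as input (per-cell column), not computed — simulation-based doublet
scoring is out of scope.

## Ambient contamination

The model is additive: each observed cell is a mixture of (1 − ρ) of its own
transcripts and ρ drawn from a pooled ambient profile b (per-gene proportions
of the whole channel). Without empty droplets, b is taken from the pooled
filtered matrix. For a marker gene set G_s and clusters C_s declared unable
to express it, all observed counts are ambient, so

    ρ̂_s = Σ_{c∈C_s, g∈G_s} x_cg / ( Σ_{c∈C_s} N_c · Σ_{g∈G_s} b_g ),

and the channel-level ρ̂ pools numerators and denominators over sets, clipped
to [0, 0.5]. Correction is the expected-value subtraction
x′ = max(0, round(x − ρ·N_c·b_g)): zero entries stay zero, totals never
increase, and ρ = 0 is the identity. This is a deliberately simple estimator
of the channel contamination; it does not model per-cell ρ variation or
re-distribute removed counts.

QC ordering: all cell/cluster filters run before ambient estimation, so the
ambient profile is built from surviving cells only. The UMI floor is applied
to raw (pre-correction) counts.

## Log-normalization

y = ln(1 + scale · x / N_c) with `scale = 1e4` (counts per ten thousand).
Zero-total cells are dropped with a warning. Downstream log2 fold changes
de-log via expm1 before forming group-mean ratios (pseudocount 1e-9), so a
planted k-fold count difference reports ≈ log2(k) rather than a compressed
log-scale ratio.

## CNV inference and malignancy calling

Genes are ordered by genomic start within each chromosome (ties broken by
symbol); genes without positions are excluded. Relative expression is
r = clamp(y − mean over reference cells, ±3); clamping precedes windowing so
single extreme genes cannot dominate a window mean. The reference defaults
to all non-epithelial cells and is configurable — using a designated normal
subset is equally valid and exposed via `CnvParams.reference_cells`.

CNV_i(c, w) is the mean of r over W = 100 consecutive genes (stride 1);
windows never cross chromosome boundaries, chromosomes with fewer than W
positioned genes are excluded and reported, and edge windows are dropped
rather than padded (padding would bias chromosome ends toward zero).
CNV_f = exp(CNV_i − median_w CNV_i) re-centers each cell on its own median
window, making the profile invariant to per-cell additive shifts and putting
copy-neutral windows at ≈ 1.

Scores: S(c) = Σ_w CNV_f² and M(c) = mean_w (CNV_f − 1)². The parse of the
malignancy score as mean((CNV_f − 1)²) — rather than mean(CNV_f²) − 1 — is
required for a non-negative score that is 0 exactly for a neutral profile;
the alternative can go negative. S is computed and reported but only M is
used for calling: note S is non-zero (≈ number of windows) even for a
perfectly neutral cell, which is why it is unsuitable for thresholding.

The threshold is the minimum of a Gaussian KDE (Silverman bandwidth,
512-point grid) between the two highest local maxima; maxima need a
prominence of at least 5% of the peak density as a noise guard (both
configurable). A unimodal density returns no threshold and flags every cell
non-malignant with a warning rather than inventing a cut. CNV clones are
Ward/Euclidean hierarchical clusters of the CNV_f vectors of malignant
cells, cut at k.

## TCR repertoire

Productive TRA/TRB contigs are grouped per barcode (10x "-1" style suffixes
stripped to join the expression cells). The (n_TRA, n_TRB) multiset maps to
single pair (1,1), orphan α (1,0), orphan β (0,1), extra α (2,1), extra β
(1,2), two full chains (2,2) and multichain (> 2 of either chain). The
combinations (2,0)/(0,2) are not covered by the seven-type enumeration; they
are mapped to extra α / extra β (a doubled chain without a full pair). Cells
with no productive chains are excluded and reported.

Only single-pair cells form clonotypes, keyed on (patient, TRA CDR3-nt,
TRB CDR3-nt) by exact match — the conservative AND reading consistent with
the single-pair restriction; an OR variant (either chain shared merges
clones, via union-find within a patient) is available as
`chain_match="any"`.

Clonal size fractions are cell-weighted shares of cells in clonotypes of
size 1, 2 and ≥ 3 within each group; a clonotype-weighted alternative (count
clones, not cells) would give smaller expanded fractions and is not
reported.

STARTRAC-expansion per (patient, tissue, cluster) group: with clonotype
frequencies p over n_ct clonotypes, evenness = H(p)/ln(n_ct) and expansion =
1 − evenness. Natural logs; the normalization cancels the base. Monoclonal
groups with ≥ 2 cells score 1 (the vanishing-evenness limit); groups with a
single cell are undefined (0/0) and reported missing.

STARTRAC-transition per (patient, tissue) stratum with K ≥ 2 clusters: each
clonotype's transition is H(q)/ln(K) over its cluster distribution q (0 if
confined to one cluster); the cluster-level index averages these over the
clonotypes present in the cluster, weighted by each clone's cell count
within that cluster. Strata with K < 2 are undefined.

Matched T cells: a cell is matched iff its clonotype has at least one cell
in each tissue of the same patient; patients contributing a single tissue
are excluded and reported. Low-capture patients can be excluded upstream by
a minimum T-cell count.

Differential expression: per-gene two-sided Wilcoxon rank-sum on the
log-normalized layer, Benjamini–Hochberg adjustment, log2 fold change of
de-logged group means; significance = q < 0.05 and |log2FC| above the
analysis-specific cut (0.25 for matched-T comparisons, 0.5 for cluster
comparisons). Both groups need at least 3 cells.

## Ligand–receptor permutation test

Clusters are downsampled to at most 1000 cells (without replacement,
seeded). Complex expression is the minimum over subunits (limiting-subunit
convention; the expression filter applies to the complex value, not the
subunits individually). For ordered clusters (A, B) and pair (L, R):
strength = (mean_A(L) + mean_B(R)) / 2; the record passes the filter when
more than 30% of A's cells have L > 0 and more than 30% of B's cells have
R > 0. p-values come from `n_perm = 1000` global permutations of the cluster
label vector: p = #(permuted strength ≥ observed)/n_perm, without the +1
correction (a `add_one` flag provides the (c+1)/(n+1) variant); permutation
is global, not within-patient (a stratified variant would condition on
patient composition and is a natural extension). kept = p < 0.05 and both
fraction filters. The marker-gene pre-filter retains genes with one-vs-rest
log2FC > 0.5 and expressing fraction > 0.25 in the focal cluster (the
Wilcoxon p is reported alongside but the retention rule is the printed
fold-change/fraction criterion), then restricts records to pairs touching
the retained set.

## Composition and signatures

Scaled composition: scaled_tk = n_tk / N_k removes category size;
share_tk = scaled_tk / Σ_k′ scaled_tk′ sums to 1 across categories within a
type and is invariant to uniformly replicating a category's cells. The
per-sample fraction test compares n_ts/N_s across two categories with the
unpaired two-sided Wilcoxon rank-sum by default; a paired signed-rank
variant keyed on patient is available, since the study design pairs tissues
within patients. Types with fewer than 3 samples per category report NaN.

Signature scores are unweighted means over the resolvable member genes
(each gene contributes with weight 1/|sig|; unresolved symbols are
reported); ratios are per-unit score quotients with zero denominators
flagged NaN rather than infinite. Quantile grouping uses linear-interpolated
(type-7) quantiles: high = score > Q(0.55), low = score < Q(0.45), the
middle decile excluded; constant score vectors exclude everything with a
warning. Survival modeling on the grouped table is left to dedicated
packages (lifelines, r-survival).

## Synthetic data generator

The generator emulates the study design: `n_patients` patients × paired
PT/LNMT samples × `cells_per_sample` cells (defaults 2 × 2 × 250 = 1000
cells), 2000 genes on five autosome-like chromosomes (equal gene counts,
strictly increasing starts) plus 10 `MT-` genes on chrM holding ~7% of
counts. Six clusters model epithelial, CD4 T, CD8 T, B, myeloid and CAF
populations. Counts are negative-binomial (gamma–Poisson) with per-gene
dispersion ~ U(0.05, 0.25), per-cell depth lognormal around 3000 UMIs, and
cluster-specific profiles: a shared lognormal baseline, mild cluster effects
on 10% of genes (σ = 0.4 in log space — strong enough to make clusters
distinguishable, weak enough that window averages of neutral cells stay
near zero), three exclusive marker genes per cluster at a fixed moderate
weight, and two very highly expressed exclusive "hallmark" genes per
cluster (jointly 4% of the transcriptome, emulating secretoglobin /
immunoglobulin dominance).

Malignant cells (default 30%, assigned to the epithelial cluster) have the
mean expression of genes inside each CNV block multiplied by the copy ratio
before sampling — the default blocks are a 200-gene ratio-2.0 amplification
on chr1 and a 150-gene ratio-0.5 deletion on chr2 — without renormalizing,
since dosage changes total mRNA. Doublets (default 5%) replace sampled
cells with the sum of two random singlet draws binomially thinned to the
slot's own depth, carry high doublet scores (Beta(16, 4) vs Beta(2, 18) for
singlets), and sit in their own extra cluster label, standing in for the
over-clustering step that isolates doublets in real analyses. Ambient
contamination applies the additive model verbatim:
x′ = round((1 − ρ)x + ρ·N_c·b) with b the pooled pre-mixing profile. The
per-entry rounding means genes whose expected ambient count is below 0.5
contribute no ambient signal — which is precisely why the estimator's
marker sets are the hallmark genes (expected ambient counts well above 1)
and why the doublet rule's marker map uses the moderate-weight markers
(expected ambient counts well below 0.5). The small residual biases of the
rounding are visible in the recovered ρ̂ (≈ 0.107 at ρ = 0.10).

TCR tables cover T-lineage cells (clusters 1–2): per patient, clone sizes
are drawn from a long-tailed distribution (P(1)=0.70, P(2)=0.15, P(3)=0.09,
P(4)=0.04, P(6)=0.02 — roughly the singleton-dominated shape of real tumor
repertoires) and a `shared_clone_fraction` of clonotypes (default 0.2) is
split across both tissues with at least one cell in each. The
`clonal_profile` is a single size distribution applied to every cluster and
tissue; per-cluster/per-tissue profiles are not modeled. CDR3 strings are
synthetic (unique per patient); 5% of T cells are perturbed into non
single-pair configurations and a sprinkle of non-productive contigs is
added, both to exercise the pairing classifier. Two ligand–receptor
interactions are planted (source/target-exclusive expression, one
two-subunit receptor) along with ubiquitously expressed decoy pairs.

What the generator does **not** emulate: pathway co-expression structure,
batch effects, per-cell ambient variation, UMI saturation, V/D/J segment
biology, spatial data. Passing recovery tests therefore demonstrates the
correctness of the estimators under their own model assumptions, not
robustness to everything real droplet data contains.

## Problem sizes and determinism

The default conditions (1000 cells × 2000 genes) run the full pipeline in a
few seconds; tests use these defaults or smaller constructed fixtures, and
every stochastic step takes an explicit seed (`SimConfig.seed`,
`InteractionParams.seed`, `numpy.random.default_rng`), making all outputs
reproducible bit-for-bit. `scripts/acceptance.py` derives all of its seeds
from the single `--seed` argument.

## Known limitations

* The ambient estimator returns a single channel-level ρ; datasets with
  strongly cell-type-dependent contamination violate its assumptions.
* The bimodal threshold assumes two density modes; gradual malignancy-score
  continua yield the unimodal fallback (no calls) rather than a cut.
* Clonotype identity ignores convergent TCRs across patients by design.
* The permutation test treats cells as exchangeable across clusters under
  the null; patient structure can be handled only by pre-stratifying the
  input.
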