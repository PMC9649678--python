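# lnmet

Analysis toolkit for paired primary-tumor (PT) / lymph-node-metastasis
(LNMT) single-cell RNA + TCR studies. It re-implements, as a tested and
reusable library, the bespoke computations such a study needs between the
count matrix and the biology:

* **QC** — three per-sample cell filters (detected genes on a log10 scale
  below median − 3×MAD; mitochondrial fraction above median + 3×MAD; fewer
  than 300 UMIs), followed by cluster-level doublet removal (mean doublet
  score > 0.6, or markers of more than one cell type expressed).
* **Ambient mRNA** — a marker-set contamination estimator: for gene sets a
  cluster cannot biologically express (e.g., secretoglobins outside the
  epithelium, immunoglobulins outside B cells), observed counts must be
  ambient, giving ρ̂ = Σx / (ΣN_c · Σb_g); counts are corrected by
  x′ = max(0, round(x − ρ·N_c·b_g)).
* **CNV malignancy calling** — relative expression clamped to [−3, 3],
  averaged over 100-gene sliding windows per chromosome (CNV_i), re-centered
  and exponentiated per cell (CNV_f = exp(CNV_i − median)); per-cell CNV
  score S = Σ_w CNV_f², malignancy score M = mean_w (CNV_f − 1)²; cells above
  the valley between the two modes of the KDE of M are called malignant.
* **TCR repertoire** — the seven chain-pairing categories (single pair,
  orphan α/β, extra α/β, two full chains, multichain); clonotypes from
  single-pair cells keyed on (patient, TRA, TRB) CDR3 nucleotides;
  STARTRAC-expansion = 1 − normalized Shannon entropy of clonotype
  frequencies; STARTRAC-transition = clone-size-weighted normalized entropy
  across clusters; matched T cells = clonotypes spanning both tissues of a
  patient; Wilcoxon + Benjamini–Hochberg differential expression.
* **Ligand–receptor testing** — CellPhoneDB-style: downsample to 1000 cells
  per cluster, strength = mean(ligand in A, receptor in B), a >30%
  expressing-fraction filter, p from 1000 global label permutations,
  multi-subunit complexes via the limiting (minimum) subunit, and a
  marker-gene (log2FC > 0.5, min.pct > 0.25) pre-filter.
* **Composition & signatures** — sample-size-scaled composition shares
  (n_tk/N_k, renormalized per type), per-sample fraction Wilcoxon tests,
  mean-expression signature scores, signature ratios, and 55th/45th
  percentile high/low grouping.

A first-class synthetic-data generator (`lnmet.simulate`) produces
multi-patient paired-tissue cohorts with planted ground truth — malignant
cells carrying chromosome-block dosage changes, a known ambient fraction,
labeled doublets, clonally expanded and tissue-shared TCR repertoires, and
planted ligand–receptor interactions — so every stage is testable without
any downloads.

## Worked example

```bash
python examples/01_simulate_and_qc.py
python examples/02_cnv_malignancy.py
```

prints (seed 1):

```
generated 1000 cells x 2000 genes (true ambient rho = 0.1)
QC report: {'n_input': 1000, 'removed_low_genes': 42, 'removed_high_mito': 43,
            'removed_low_umi': 0, 'n_removed': 82, 'n_kept': 918}
doublet-cluster rule removed clusters [6]; 875 cells remain
estimated rho = 0.1069 (per marker set: {'epithelial_secreted': 0.0966, 'ig_like': 0.1306})
counts: 2793013 -> 2636737 after ambient subtraction

1495 windows across 5 chromosomes (excluded: ['chrM'])
bimodal threshold = 0.0246
called 290 malignant cells; accuracy vs planted truth = 0.998
median M: neutral = 0.0059, malignant = 0.0490
```

Reading: the generator planted 10% ambient contamination, 5% doublets (all
assigned to the over-clustered cluster 6) and 30% malignant cells. QC
removes ~8% of cells, the doublet rule removes cluster 6, the estimator
recovers ρ ≈ 0.107, and the CNV stage separates malignant from neutral
cells by an order of magnitude in malignancy score, calling them with
99.8% accuracy. Further examples cover the TCR repertoire
(`03_tcr_repertoire.py`), interaction testing (`04_interactions.py`) and
composition/signature statistics (`05_composition_signatures.py`).

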