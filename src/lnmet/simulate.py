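"""Synthetic paired-tissue single-cell datasets with planted ground truth.

The generator emulates the study design the pipeline targets: multiple
patients, each contributing a primary-tumor (PT) and a paired lymph-node
metastasis (LNMT) sample; clustered cell populations including an epithelial
cluster that harbours malignant cells with chromosome-block dosage changes;
ambient mRNA contamination mixed in at a known fraction; doublets with known
labels; clonally expanded TCR repertoires with tissue-shared clonotypes; and
planted ligand-receptor interactions between specific clusters.

Counts follow a negative-binomial model (gamma-Poisson) with per-gene
dispersion and cluster-specific expression profiles. Each cluster carries a
handful of exclusive marker genes plus one very highly expressed "hallmark"
gene (emulating transcripts such as secretoglobins or immunoglobulins that
dominate ambient contamination in real droplet data); these drive both the
doublet marker rule and the marker-set contamination estimator downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite

from .containers import CellTable

TISSUES = ("PT", "LNMT")
AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"


class ConfigurationError(ValueError):
    """SimConfig references invalid chromosomes, spans or clusters."""


@dataclass(frozen=True)
class PlantedLR:
    """A planted ligand-receptor interaction between two clusters."""

    pair_id: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]
    source_cluster: int
    target_cluster: int
    effect: float


@dataclass
class SimConfig:
    """Generator settings. Defaults define the standard study conditions:

    2 patients x 2 tissues x 250 cells = 1,000 cells, 2,000 genes on five
    autosome-like chromosomes plus a small chrM block, 6 clusters
    (0 = epithelial, 1 = CD4 T, 2 = CD8 T, 3 = B, 4 = myeloid, 5 = CAF),
    30% malignant cells carrying one 200-gene amplification (copy ratio 2.0)
    and one 150-gene deletion (copy ratio 0.5), 10% ambient contamination,
    5% doublets, a long-tailed clone-size distribution with 20% of
    clonotypes shared across the two tissues of a patient, and two planted
    ligand-receptor interactions (one with a two-subunit receptor complex).
    """

    n_patients: int = 2
    cells_per_sample: int = 250
    n_genes: int = 2000
    n_clusters: int = 6
    n_chromosomes: int = 5
    cluster_means: Sequence[float] | None = None  # relative depth per cluster
    malignant_fraction: float = 0.30
    cnv_blocks: Sequence[tuple[str, tuple[int, int], float]] = (
        ("chr1", (100, 300), 2.0),
        ("chr2", (50, 200), 0.5),
    )
    ambient_rho: float = 0.10
    doublet_rate: float = 0.05
    clonal_profile: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.70, 2: 0.15, 3: 0.09, 4: 0.04, 6: 0.02}
    )
    shared_clone_fraction: float = 0.20
    planted_lr: Sequence[PlantedLR] | None = None  # None -> built-in defaults
    seed: int = 0

    # secondary knobs (not part of the headline study conditions)
    mean_depth: float = 3000.0
    depth_sigma: float = 0.25  # lognormal sd of per-cell depth
    n_mito: int = 10
    markers_per_cluster: int = 3
    marker_weight: float = 4.0  # absolute profile weight of exclusive markers
    hallmarks_per_cluster: int = 2
    hallmark_share: float = 0.04  # joint transcriptome share of hallmark genes
    epithelial_cluster: int = 0
    t_clusters: tuple[int, ...] = (1, 2)
    b_cluster: int = 3
    nonpair_fraction: float = 0.05  # T cells with non single-pair chains
    n_decoy_lr: int = 8

    def validate(self) -> None:
        if self.n_patients < 1 or self.cells_per_sample < 1 or self.n_genes < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_clusters < 2:
            raise ConfigurationError("need at least 2 clusters")
        for p, name in [
            (self.malignant_fraction, "malignant_fraction"),
            (self.doublet_rate, "doublet_rate"),
            (self.shared_clone_fraction, "shared_clone_fraction"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        if not 0.0 <= self.ambient_rho < 0.5:
            raise ConfigurationError("ambient_rho must be in [0, 0.5)")
        per_chrom = (self.n_genes - self.n_mito) // self.n_chromosomes
        chrom_names = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for chrom, (lo, hi), ratio in self.cnv_blocks:
            if chrom not in chrom_names:
                raise ConfigurationError(f"cnv block references unknown {chrom}")
            if not (0 <= lo < hi <= per_chrom):
                raise ConfigurationError(
                    f"cnv block span ({lo},{hi}) outside {chrom} (0..{per_chrom})"
                )
            if ratio <= 0:
                raise ConfigurationError("copy ratio must be positive")
        if self.cluster_means is not None and len(self.cluster_means) != self.n_clusters:
            raise ConfigurationError("cluster_means length must equal n_clusters")
        probs = np.array(list(self.clonal_profile.values()), float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError("clonal_profile must be a probability distribution")


@dataclass
class TruthBundle:
    """Ground truth of a generated dataset (consumed only by tests/reports)."""

    malignant_labels: pd.Series  # bool, indexed by cell id
    true_rho: float
    doublet_labels: pd.Series  # bool, indexed by cell id
    clonotype_truth: pd.Series  # clonotype id (or <NA>), indexed by cell id
    planted_lr: tuple[PlantedLR, ...]


@dataclass
class SyntheticDataset:
    """Everything :func:`generate_dataset` produces."""

    cells: CellTable  # layer="raw"
    genes: pd.DataFrame  # gene annotation: symbol index, chromosome, start
    tcr: pd.DataFrame  # contig records (barcode, chain, cdr3, cdr3_nt, productive)
    lr_pairs: pd.DataFrame  # pair_id, ligand_subunits, receptor_subunits
    truth: TruthBundle
    marker_map: dict[str, list[str]]  # cell type -> exclusive markers
    ambient_marker_sets: dict[str, list[str]]  # estimator marker sets
    nonexpressing_clusters: dict[str, set[int]]  # per set: clusters not expressing it


# --------------------------------------------------------------------------- #
# gene annotation


def _build_gene_annotation(cfg: SimConfig) -> pd.DataFrame:
    n_auto = cfg.n_genes - cfg.n_mito
    per_chrom = n_auto // cfg.n_chromosomes
    rows = []
    g = 0
    for c in range(cfg.n_chromosomes):
        n_here = per_chrom if c < cfg.n_chromosomes - 1 else n_auto - per_chrom * (
            cfg.n_chromosomes - 1
        )
        for j in range(n_here):
            rows.append((f"G{g + 1:05d}", f"chr{c + 1}", 1000 * (j + 1)))
            g += 1
    for j in range(cfg.n_mito):
        rows.append((f"MT-{j + 1}", "chrM", 1000 * (j + 1)))
    df = pd.DataFrame(rows, columns=["symbol", "chromosome", "start"])
    return df.set_index("symbol")


def _block_gene_indices(cfg: SimConfig, genes: pd.DataFrame) -> list[tuple[np.ndarray, float]]:
    out = []
    for chrom, (lo, hi), ratio in cfg.cnv_blocks:
        on_chrom = np.flatnonzero((genes["chromosome"] == chrom).to_numpy())
        out.append((on_chrom[lo:hi], float(ratio)))
    return out


# --------------------------------------------------------------------------- #
# expression model


def _default_planted_lr(special: dict[str, list[str]]) -> tuple[PlantedLR, ...]:
    lig, rec = special["lr_genes"][:4], special["lr_genes"][4:8]
    return (
        PlantedLR("LRP1", (lig[0],), (rec[0],), source_cluster=4, target_cluster=2, effect=5.0),
        PlantedLR("LRP2", (lig[1],), (rec[1], rec[2]), source_cluster=5, target_cluster=1, effect=5.0),
    )


def _cluster_profiles(
    cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, list[str]], tuple[PlantedLR, ...]]:
    """Per-cluster expression profiles (n_clusters x n_genes, rows sum to 1)."""
    n_genes = len(genes)
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)

    # mitochondrial genes get a fixed joint share of ~7%
    mito = genes["chromosome"].to_numpy() == "chrM"
    if mito.any():
        base[mito] = 0.07 * base[~mito].sum() / mito.sum()

    # reserve special genes on the last autosome, away from the default blocks
    last_chrom = f"chr{cfg.n_chromosomes}"
    pool = np.flatnonzero((genes["chromosome"] == last_chrom).to_numpy())
    need = (
        cfg.n_clusters * (cfg.hallmarks_per_cluster + cfg.markers_per_cluster)
        + 8
        + 2 * cfg.n_decoy_lr
    )
    picked = rng.choice(pool, size=min(need, len(pool)), replace=False)
    it = iter(picked.tolist())
    hallmark = [
        [next(it) for _ in range(cfg.hallmarks_per_cluster)] for _ in range(cfg.n_clusters)
    ]
    markers = [
        [next(it) for _ in range(cfg.markers_per_cluster)] for _ in range(cfg.n_clusters)
    ]
    lr_genes = [next(it) for _ in range(8)]
    decoy_genes = [next(it) for _ in range(2 * cfg.n_decoy_lr)]

    syms = genes.index.to_numpy()
    special = {
        "hallmark": [[syms[i] for i in row] for row in hallmark],
        "markers": [[syms[i] for i in row] for row in markers],
        "lr_genes": [syms[i] for i in lr_genes],
        "decoy_genes": [syms[i] for i in decoy_genes],
    }
    planted = (
        tuple(cfg.planted_lr) if cfg.planted_lr is not None else _default_planted_lr(special)
    )
    for p in planted:
        for k in (p.source_cluster, p.target_cluster):
            if not 0 <= k < cfg.n_clusters:
                raise ConfigurationError(f"planted LR references unknown cluster {k}")
        for s in (*p.ligand, *p.receptor):
            if s not in genes.index:
                raise ConfigurationError(f"planted LR references unknown gene {s}")

    profiles = np.tile(base, (cfg.n_clusters, 1))
    # mild cluster-specific effects on 10% of genes
    for k in range(cfg.n_clusters):
        affected = rng.random(n_genes) < 0.10
        profiles[k, affected] *= rng.lognormal(0.0, 0.4, size=int(affected.sum()))
    # exclusive markers (moderate, fixed weight: safe from ambient rounding)
    # and hallmark genes (very high weight: the ambient drivers)
    for k in range(cfg.n_clusters):
        for i in markers[k]:
            profiles[:, i] = 0.0
            profiles[k, i] = cfg.marker_weight
        for i in hallmark[k]:
            profiles[:, i] = 0.0
    # decoy LR genes: ubiquitous, moderately high (pass the 30% filter everywhere)
    gidx = genes.index.get_indexer(special["decoy_genes"])
    profiles[:, gidx] = base[gidx] * 8.0
    # planted LR genes: strong in their own cluster, near-absent elsewhere
    for p in planted:
        for s in p.ligand:
            i = genes.index.get_loc(s)
            profiles[:, i] = base[i] * 0.02
            profiles[p.source_cluster, i] = base[i] * 8.0 * p.effect
        for s in p.receptor:
            i = genes.index.get_loc(s)
            profiles[:, i] = base[i] * 0.02
            profiles[p.target_cluster, i] = base[i] * 8.0 * p.effect
    # hallmark genes take a fixed joint transcriptome share, set last
    for k in range(cfg.n_clusters):
        row = profiles[k]
        other = row.sum() - row[hallmark[k]].sum()
        per_gene = cfg.hallmark_share / (1 - cfg.hallmark_share) * other
        row[hallmark[k]] = per_gene / max(cfg.hallmarks_per_cluster, 1)

    if cfg.cluster_means is not None:
        profiles *= np.asarray(cfg.cluster_means, float)[:, None]
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles, special, planted


def _sample_counts(
    cfg: SimConfig,
    profiles: np.ndarray,
    clusters: np.ndarray,
    depths: np.ndarray,
    malignant: np.ndarray,
    block_idx: list[tuple[np.ndarray, float]],
    dispersion: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    mu = profiles[clusters] * depths[:, None]
    for idx, ratio in block_idx:
        mu[np.ix_(malignant, idx)] *= ratio
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=np.broadcast_to(shape, mu.shape), scale=mu * dispersion)
    return rng.poisson(lam)


# --------------------------------------------------------------------------- #
# TCR repertoire


def _random_cdr3(rng: np.random.Generator, length: int = 12) -> tuple[str, str]:
    aa = "C" + "".join(rng.choice(list(AA), size=length - 2)) + "F"
    nt = "".join(rng.choice(list(NT), size=3 * length))
    return aa, nt


def _draw_clone_size(profile: Mapping[int, float], rng: np.random.Generator) -> int:
    sizes = np.array(list(profile.keys()))
    probs = np.array(list(profile.values()), float)
    return int(rng.choice(sizes, p=probs / probs.sum()))


def _generate_tcr(
    cfg: SimConfig,
    cell_meta: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Contig table + per-cell truth clonotype assignment."""
    is_t = cell_meta["cluster"].isin(cfg.t_clusters) & ~cell_meta["is_doublet"]
    truth = pd.Series(pd.NA, index=cell_meta.index, dtype="object")
    records: list[tuple[str, str, str, str, bool]] = []

    for patient, pat_meta in cell_meta.loc[is_t].groupby("patient", sort=True):
        pools = {
            t: list(rng.permutation(pat_meta.index[pat_meta["tissue"] == t].to_numpy()))
            for t in TISSUES
        }
        seen_nt: set[tuple[str, str]] = set()
        ct = 0
        while any(pools.values()):
            size = _draw_clone_size(cfg.clonal_profile, rng)
            both = all(len(pools[t]) > 0 for t in TISSUES)
            shared = both and size >= 2 and rng.random() < cfg.shared_clone_fraction
            members: list[str] = []
            if shared:
                n_pt = 1 + int(rng.binomial(size - 2, 0.5)) if size > 2 else 1
                want = {"PT": n_pt, "LNMT": size - n_pt}
                for t in TISSUES:
                    take = min(want[t], len(pools[t]))
                    members += [pools[t].pop() for _ in range(take)]
            else:
                weights = np.array([len(pools[t]) for t in TISSUES], float)
                t = TISSUES[int(rng.choice(2, p=weights / weights.sum()))]
                take = min(size, len(pools[t]))
                members += [pools[t].pop() for _ in range(take)]
            while True:
                tra_aa, tra_nt = _random_cdr3(rng)
                trb_aa, trb_nt = _random_cdr3(rng, length=13)
                if (tra_nt, trb_nt) not in seen_nt:
                    seen_nt.add((tra_nt, trb_nt))
                    break
            ct += 1
            cid = f"{patient}_ct{ct:04d}"
            for cell in members:
                truth.loc[cell] = cid
                barcode = f"{cell}-1"
                records.append((barcode, "TRA", tra_aa, tra_nt, True))
                records.append((barcode, "TRB", trb_aa, trb_nt, True))

    df = pd.DataFrame(
        records, columns=["barcode", "chain", "cdr3", "cdr3_nt", "productive"]
    )

    # perturb a fraction of T cells into non single-pair chain configurations
    t_cells = truth.index[truth.notna()].to_numpy()
    n_odd = int(round(cfg.nonpair_fraction * len(t_cells)))
    if n_odd and len(df):
        odd = rng.choice(t_cells, size=n_odd, replace=False)
        variants = rng.choice(
            ["orphan_alpha", "orphan_beta", "extra_alpha", "extra_beta", "multichain"],
            size=n_odd,
        )
        drop_rows: list[int] = []
        extra_rows: list[tuple[str, str, str, str, bool]] = []
        for cell, variant in zip(odd, variants):
            barcode = f"{cell}-1"
            rows = df.index[df["barcode"] == barcode]
            if variant == "orphan_alpha":
                drop_rows += list(rows[df.loc[rows, "chain"] == "TRB"])
            elif variant == "orphan_beta":
                drop_rows += list(rows[df.loc[rows, "chain"] == "TRA"])
            else:
                n_extra = 2 if variant == "multichain" else 1
                chain = "TRB" if variant == "extra_beta" else "TRA"
                for _ in range(n_extra):
                    aa, nt = _random_cdr3(rng)
                    extra_rows.append((barcode, chain, aa, nt, True))
            truth.loc[cell] = pd.NA
        df = df.drop(index=drop_rows)
        if extra_rows:
            df = pd.concat(
                [df, pd.DataFrame(extra_rows, columns=df.columns)], ignore_index=True
            )

    # sprinkle non-productive contigs; the pipeline must ignore them
    if len(df):
        n_junk = max(1, len(t_cells) // 20)
        junk_cells = rng.choice(t_cells, size=min(n_junk, len(t_cells)), replace=False)
        junk = []
        for cell in junk_cells:
            aa, nt = _random_cdr3(rng)
            junk.append((f"{cell}-1", "TRA", aa, nt, False))
        df = pd.concat([df, pd.DataFrame(junk, columns=df.columns)], ignore_index=True)

    df = df.sort_values(["barcode", "chain", "cdr3_nt"], kind="stable").reset_index(drop=True)
    return df, truth


# --------------------------------------------------------------------------- #
# main entry points


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _build_gene_annotation(config)
    profiles, special, planted = _cluster_profiles(config, genes, rng)
    block_idx = _block_gene_indices(config, genes)
    dispersion = rng.uniform(0.05, 0.25, size=len(genes))

    # --- cell sheet -------------------------------------------------------
    cell_rows = []
    for p in range(config.n_patients):
        patient = f"P{p + 1}"
        for tissue in TISSUES:
            for i in range(config.cells_per_sample):
                cell_rows.append((f"{patient}_{tissue}_{i + 1:04d}", patient, tissue))
    meta = pd.DataFrame(cell_rows, columns=["cell_id", "patient", "tissue"]).set_index(
        "cell_id"
    )
    n_cells = len(meta)

    # doublets and malignant cells, stratified per sample for balance
    is_doublet = np.zeros(n_cells, dtype=bool)
    malignant = np.zeros(n_cells, dtype=bool)
    clusters = np.zeros(n_cells, dtype=int)
    for _, idx in meta.groupby(["patient", "tissue"], sort=True).indices.items():
        idx = np.asarray(idx)
        n = len(idx)
        n_dbl = int(round(config.doublet_rate * n))
        dbl = rng.choice(idx, size=n_dbl, replace=False)
        is_doublet[dbl] = True
        rest = np.setdiff1d(idx, dbl)
        n_mal = int(round(config.malignant_fraction * n))
        n_mal = min(n_mal, len(rest))
        mal = rng.choice(rest, size=n_mal, replace=False)
        malignant[mal] = True
        clusters[mal] = config.epithelial_cluster
        normal = np.setdiff1d(rest, mal)
        clusters[normal] = rng.integers(0, config.n_clusters, size=len(normal))
    clusters[is_doublet] = config.n_clusters  # over-clustered doublet cluster

    depths = rng.lognormal(np.log(config.mean_depth), config.depth_sigma, size=n_cells)

    # --- counts -----------------------------------------------------------
    singlet_clusters = np.where(is_doublet, 0, clusters)
    X = _sample_counts(
        config, profiles, singlet_clusters, depths, malignant, block_idx, dispersion, rng
    )
    dbl_pos = np.flatnonzero(is_doublet)
    singlet_pos = np.flatnonzero(~is_doublet)
    if len(dbl_pos) and len(singlet_pos) >= 2:
        a = rng.choice(singlet_pos, size=len(dbl_pos))
        b = rng.choice(singlet_pos, size=len(dbl_pos))
        summed = X[a] + X[b]
        tot = summed.sum(axis=1, keepdims=True).clip(min=1)
        p_keep = np.clip(depths[dbl_pos, None] / tot, 0.0, 1.0)
        X[dbl_pos] = rng.binomial(summed, p_keep)
        malignant[dbl_pos] = False

    # --- ambient mixing: x' = round((1 - rho) x + rho N_c b) ----------------
    rho = config.ambient_rho
    if rho > 0:
        totals = X.sum(axis=1).astype(float)
        b = X.sum(axis=0).astype(float)
        b /= b.sum()
        X = np.rint((1.0 - rho) * X + rho * totals[:, None] * b[None, :]).astype(np.int64)

    meta["cluster"] = clusters
    meta["is_doublet"] = is_doublet
    meta["doublet_score"] = np.where(
        is_doublet, rng.beta(16, 4, size=n_cells), rng.beta(2, 18, size=n_cells)
    ).round(4)
    meta["total_umi"] = X.sum(axis=1)

    tcr, clonotype_truth = _generate_tcr(config, meta, rng)

    # --- LR pair list (planted + decoys) -----------------------------------
    lr_rows = [
        (p.pair_id, ";".join(p.ligand), ";".join(p.receptor)) for p in planted
    ]
    dg = special["decoy_genes"]
    for j in range(config.n_decoy_lr):
        lr_rows.append((f"DECOY{j + 1}", dg[2 * j], dg[2 * j + 1]))
    lr_pairs = pd.DataFrame(
        lr_rows, columns=["pair_id", "ligand_subunits", "receptor_subunits"]
    )

    cell_meta = meta.drop(columns=["is_doublet"])
    table = CellTable(
        counts=sp.csr_matrix(X),
        cell_meta=cell_meta,
        gene_meta=genes.copy(),
        layer="raw",
    )

    truth = TruthBundle(
        malignant_labels=pd.Series(malignant, index=meta.index, name="malignant"),
        true_rho=float(rho),
        doublet_labels=pd.Series(is_doublet, index=meta.index, name="doublet"),
        clonotype_truth=clonotype_truth,
        planted_lr=planted,
    )

    ec, bc = config.epithelial_cluster, config.b_cluster
    marker_map = {
        f"type{k}": list(special["markers"][k]) for k in range(config.n_clusters)
    }
    ambient_sets = {
        "epithelial_secreted": list(special["hallmark"][ec]),
        "ig_like": list(special["hallmark"][bc]),
    }
    nonexpr = {
        "epithelial_secreted": set(range(config.n_clusters)) - {ec},
        "ig_like": set(range(config.n_clusters)) - {bc},
    }
    return SyntheticDataset(
        cells=table,
        genes=genes,
        tcr=tcr,
        lr_pairs=lr_pairs,
        truth=truth,
        marker_map=marker_map,
        ambient_marker_sets=ambient_sets,
        nonexpressing_clusters=nonexpr,
    )


# --------------------------------------------------------------------------- #
# fixtures on disk


def write_fixtures(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the plain-text dialects the readers consume.

    Files: ``matrix.mtx`` (cells x genes integer triplets), ``genes.tsv``,
    ``cells.tsv``, ``contigs.csv``, ``lr_pairs.tsv``, ``truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    m = dataset.cells.counts.tocoo()
    paths["matrix"] = directory / "matrix.mtx"
    mmwrite(paths["matrix"], sp.coo_matrix((m.data.astype(np.int64), (m.row, m.col)), shape=m.shape))

    paths["genes"] = directory / "genes.tsv"
    dataset.genes.reset_index().to_csv(paths["genes"], sep="\t", index=False)

    paths["cells"] = directory / "cells.tsv"
    dataset.cells.cell_meta.reset_index().to_csv(paths["cells"], sep="\t", index=False)

    paths["contigs"] = directory / "contigs.csv"
    dataset.tcr.to_csv(paths["contigs"], index=False)

    paths["lr_pairs"] = directory / "lr_pairs.tsv"
    dataset.lr_pairs.to_csv(paths["lr_pairs"], sep="\t", index=False)

    truth = dataset.truth
    paths["truth"] = directory / "truth.json"
    payload = {
        "true_rho": truth.true_rho,
        "malignant_labels": {k: bool(v) for k, v in truth.malignant_labels.items()},
        "doublet_labels": {k: bool(v) for k, v in truth.doublet_labels.items()},
        "clonotype_truth": {
            k: (None if pd.isna(v) else v) for k, v in truth.clonotype_truth.items()
        },
        "planted_lr": [
            {
                "pair_id": p.pair_id,
                "ligand": list(p.ligand),
                "receptor": list(p.receptor),
                "source_cluster": p.source_cluster,
                "target_cluster": p.target_cluster,
                "effect": p.effect,
            }
            for p in truth.planted_lr
        ],
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
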