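"""Synthetic paired snATAC/snRNA generator with known ground truth.

The generator emulates the statistical structure that drives peak-gene link
inference in real multiome data:

* K cell types of unequal abundance (multinomial assignment);
* cell-type-specific peaks: a latent Bernoulli "open" state per cell with
  per-peak Beta-distributed open probabilities, high in the owner type and
  leaky elsewhere;
* a per-cell TF-program activity that co-opens a type's own peaks and
  co-raises its marker genes — the within-type co-accessibility whose
  detectability grows with the type's cell count, and the mechanism behind
  bimodal matched-null distributions in datasets with a dominant cell type;
* continuous cell-state factors loading on every peak and gene, smearing
  trans correlations into wide smooth null distributions;
* trans peaks placed on dedicated chromosomes that carry no genes, so the
  "different chromosome" null pool is always well defined;
* sparse counts: ATAC is zero unless open, then Poisson with lognormal
  per-peak strengths; RNA is negative binomial with lognormal per-gene
  baselines and a log-linear mean;
* a shared lognormal cell size factor for both modalities, inducing the
  coverage confounding the matched-null method is designed to remove;
* known true cis links: a gene's mean is multiplied by exp(effect) in cells
  where its linked peak is open, with lognormal per-gene effect sizes.

See docs/methods.md for the full parameterization and its rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    ConfigError,
    GeneAnnotation,
    GenomicInterval,
    MultiomeDataset,
    PeakAnnotation,
    write_mtx_triplet,
)

SHARED = "shared"

PEAK_WIDTH = 500          # bp; typical ATAC peak width scale
GENE_SPACING = 1_200_000  # bp between TSSs, > 2x the cis window so windows do not overlap
CIS_OFFSET_MAX = 450_000  # bp; cis peaks placed within this offset of the TSS
TRANS_SPACING = 2_000     # bp between trans peaks on their dedicated chromosomes


@dataclass
class SimulationConfig:
    """Study conditions for one simulated multiome experiment.

    Defaults describe a 2,000-cell experiment with one dominant (60%) and one
    rare (5%) cell type, leaky cell-type-specific accessibility (mean open
    probability 0.6 in the owner type vs 0.1 elsewhere), TF-program-driven
    within-type co-accessibility, and true cis links with a 1.5-unit
    log-fold effect on expression.
    """

    n_cells: int = 2000
    celltype_proportions: dict[str, float] = field(
        default_factory=lambda: {"typeA": 0.60, "typeB": 0.20, "typeC": 0.15, "typeD": 0.05}
    )
    n_genes: int = 120
    n_cis_peaks_per_gene: int = 5
    n_trans_peaks: int = 1200
    frac_celltype_specific_peaks: float = 0.5
    open_prob_in_type: float = 0.6
    open_prob_out_type: float = 0.1
    # per-peak heterogeneity: open probabilities are Beta-distributed around
    # the two means above (higher concentration = more uniform peaks), and
    # each peak's count mean carries a lognormal multiplier. Real peak sets
    # vary widely in specificity and strength; without this, within-group
    # trans correlations are nearly identical and any secondary group reads
    # as a separate mode.
    open_prob_concentration: float = 10.0
    atac_mean_sigma: float = 1.2
    atac_count_mean: float = 1.5
    rna_baseline_mean: float = 0.5
    rna_mean_sigma: float = 1.5   # lognormal spread of per-gene baseline means
    rna_dispersion: float = 0.5   # NB theta: var = mu + mu^2/theta
    celltype_effect: float = 0.3  # log-FC of a marker gene in its owner type
    link_effect: float = 1.5      # median log-FC of a gene's mean when its true peak is open
    link_effect_sigma: float = 0.6  # lognormal spread of per-gene link effects
    frac_true_links: float = 0.8  # fraction of genes receiving one true cis link
    # continuous cell-state covariation shared between modalities: each cell
    # carries latent factors that shift peak open probabilities (logit scale)
    # and gene means (log scale) through random per-feature loadings. This
    # smears trans correlations into the wide, smooth null distributions seen
    # in real data instead of leaving them a spike at zero.
    n_latent_factors: int = 10
    latent_peak_sd: float = 0.3
    latent_gene_sd: float = 0.3
    # shared TF-program activity: cells of a type express the type's
    # regulatory program with varying intensity, co-opening its peaks (logit
    # scale) and co-raising its marker genes (log scale). The resulting
    # same-type trans correlations scale with the type's abundance — the
    # power mechanism behind multimodal nulls in dominant cell types.
    program_peak_sd: float = 2.0
    program_gene_sd: float = 1.0
    gc_beta_params: tuple[float, float] = (10.0, 10.0)
    libsize_lognormal_params: tuple[float, float] = (0.0, 0.3)
    n_chromosomes: int = 4        # gene-bearing chromosomes; trans peaks get chrT1/chrT2
    link_distance_decay_bp: float | None = None   # if set, link_effect *= exp(-d/decay)
    true_link_distance_scale_bp: float | None = None  # if set, true peaks drawn near the TSS
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.celltype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cell-type proportions must sum to 1, got {total}")
        for name, p in self.celltype_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"proportion for {name} out of [0,1]: {p}")
        for name in ("open_prob_in_type", "open_prob_out_type", "frac_celltype_specific_peaks",
                     "frac_true_links"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.open_prob_in_type <= self.open_prob_out_type:
            raise ConfigError("open_prob_in_type must exceed open_prob_out_type")
        for name in ("n_cells", "n_genes", "n_cis_peaks_per_gene", "n_trans_peaks",
                     "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("atac_count_mean", "rna_baseline_mean", "rna_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass
class GroundTruth:
    """Truth labels for power/ROC evaluation of the simulated dataset."""

    true_links: set[tuple[str, str]]               # (peak_id, gene_id)
    peak_owner_type: dict[str, str]                # peak_id -> cell type or "shared"
    gene_marker_type: dict[str, str]               # gene_id -> cell type or "shared"


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial via the gamma-Poisson mixture; var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam)


def simulate_multiome(config: SimulationConfig) -> tuple[MultiomeDataset, GroundTruth]:
    """Generate a paired ATAC/RNA dataset plus its ground truth, reproducibly
    from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    types = list(config.celltype_proportions)
    props = np.array([config.celltype_proportions[t] for t in types])

    # --- cells ---------------------------------------------------------
    cell_types = rng.choice(types, size=config.n_cells, p=props)
    size_factors = rng.lognormal(*config.libsize_lognormal_params, size=config.n_cells)
    barcodes = [f"cell{i:05d}" for i in range(config.n_cells)]

    # --- genes: spread over gene chromosomes, isolated cis windows ------
    genes: list[GeneAnnotation] = []
    for g in range(config.n_genes):
        chrom = f"chr{g % config.n_chromosomes + 1}"
        tss = CIS_OFFSET_MAX + 100_000 + (g // config.n_chromosomes) * GENE_SPACING
        genes.append(GeneAnnotation(f"gene{g:04d}", chrom, tss))
    # marker types uniform across cell types: marker genes are a property of a
    # type, not of its sampling depth
    gene_marker: dict[str, str] = {}
    marker_flags = rng.random(config.n_genes) < config.frac_celltype_specific_peaks
    for g, gene in enumerate(genes):
        gene_marker[gene.gene_id] = (
            types[rng.integers(len(types))] if marker_flags[g] else SHARED
        )

    # --- true links: one designated cis peak per selected gene ----------
    linked = rng.random(config.n_genes) < config.frac_true_links
    true_peak_slot: dict[str, int] = {}
    cis_offsets = rng.integers(
        -CIS_OFFSET_MAX, CIS_OFFSET_MAX, size=(config.n_genes, config.n_cis_peaks_per_gene)
    )
    for g, gene in enumerate(genes):
        if not linked[g]:
            continue
        if config.true_link_distance_scale_bp is not None:
            d = np.abs(cis_offsets[g])
            w = np.exp(-d / config.true_link_distance_scale_bp)
            slot = int(rng.choice(config.n_cis_peaks_per_gene, p=w / w.sum()))
        else:
            slot = int(rng.integers(config.n_cis_peaks_per_gene))
        true_peak_slot[gene.gene_id] = slot

    # --- peaks -----------------------------------------------------------
    peak_ids: list[str] = []
    intervals: list[GenomicInterval] = []
    peak_owner: dict[str, str] = {}
    true_links: set[tuple[str, str]] = set()
    link_peak_col: dict[str, int] = {}   # gene_id -> ATAC column of its true peak
    link_dist: dict[str, float] = {}

    for g, gene in enumerate(genes):
        for k in range(config.n_cis_peaks_per_gene):
            start = int(gene.tss + cis_offsets[g, k])
            iv = GenomicInterval(gene.chrom, start, start + PEAK_WIDTH,
                                 id=f"{gene.chrom}-{start}-{start + PEAK_WIDTH}")
            col = len(peak_ids)
            peak_ids.append(iv.id)
            intervals.append(iv)
            if true_peak_slot.get(gene.gene_id) == k:
                owner = gene_marker[gene.gene_id]
                true_links.add((iv.id, gene.gene_id))
                link_peak_col[gene.gene_id] = col
                link_dist[gene.gene_id] = abs(float(cis_offsets[g, k]))
            elif rng.random() < config.frac_celltype_specific_peaks:
                # unlinked specific peaks follow detection power, like trans peaks
                owner = types[rng.choice(len(types), p=props)]
            else:
                owner = SHARED
            peak_owner[iv.id] = owner

    # trans peaks: dedicated chromosomes, ownership proportional to abundance
    # (detection power for a type's peaks grows with its cell count)
    for j in range(config.n_trans_peaks):
        chrom = f"chrT{j % 2 + 1}"
        start = 10_000 + (j // 2) * TRANS_SPACING
        iv = GenomicInterval(chrom, start, start + PEAK_WIDTH,
                             id=f"{chrom}-{start}-{start + PEAK_WIDTH}")
        peak_ids.append(iv.id)
        intervals.append(iv)
        if rng.random() < config.frac_celltype_specific_peaks:
            peak_owner[iv.id] = types[rng.choice(len(types), p=props)]
        else:
            peak_owner[iv.id] = SHARED

    n_peaks = len(peak_ids)
    owners = np.array([peak_owner[p] for p in peak_ids], dtype=object)

    # --- ATAC: latent open state, then Poisson counts --------------------
    nu = config.open_prob_concentration
    p_in = rng.beta(config.open_prob_in_type * nu,
                    (1 - config.open_prob_in_type) * nu, size=n_peaks)
    p_out = rng.beta(config.open_prob_out_type * nu,
                     (1 - config.open_prob_out_type) * nu, size=n_peaks)
    peak_strength = rng.lognormal(0.0, config.atac_mean_sigma, size=n_peaks)
    in_type = (owners[None, :] == cell_types[:, None]) | (owners[None, :] == SHARED)
    open_prob = np.where(in_type, p_in[None, :], p_out[None, :])
    # latent cell-state factors perturb accessibility on the logit scale
    factors = rng.standard_normal((config.n_cells, config.n_latent_factors))
    peak_loadings = rng.normal(0.0, config.latent_peak_sd,
                               size=(config.n_latent_factors, n_peaks))
    logit = np.log(open_prob / (1 - open_prob)) + factors @ peak_loadings
    # shared TF-program activity: cells of a type express that type's
    # regulatory program with varying intensity, co-opening the type's own
    # peaks. This is the within-type co-accessibility whose detectability
    # grows with the number of cells of the type.
    program = rng.standard_normal(config.n_cells)
    own_type = owners[None, :] == cell_types[:, None]
    logit = logit + config.program_peak_sd * program[:, None] * own_type
    open_prob = 1.0 / (1.0 + np.exp(-logit))
    open_state = rng.random((config.n_cells, n_peaks)) < open_prob
    lam = config.atac_count_mean * peak_strength[None, :] * size_factors[:, None]
    atac = np.where(open_state, rng.poisson(lam, size=(config.n_cells, n_peaks)), 0)
    # ensure strictly positive counts where open (a "detected open" peak has
    # at least one read); keeps open state identifiable at small count means
    atac = np.where(open_state & (atac == 0), 1, atac)

    # --- RNA: log-linear NB mean ----------------------------------------
    mu = np.empty((config.n_cells, config.n_genes))
    gene_loadings = rng.normal(0.0, config.latent_gene_sd,
                               size=(config.n_latent_factors, config.n_genes))
    latent_rna = factors @ gene_loadings
    # per-gene baseline expression spans orders of magnitude, as in real data
    gene_base = rng.lognormal(math.log(config.rna_baseline_mean),
                              config.rna_mean_sigma, size=config.n_genes)
    for j, gene in enumerate(genes):
        log_mu = math.log(gene_base[j]) + np.log(size_factors) + latent_rna[:, j]
        owner = gene_marker[gene.gene_id]
        if owner != SHARED:
            # program term is centered on the multiplicative scale (−σ²/2) so
            # it adds within-type covariance without shifting the type mean
            log_mu = log_mu + (cell_types == owner) * (
                config.celltype_effect
                + config.program_gene_sd * program
                - config.program_gene_sd**2 / 2.0
            )
        if gene.gene_id in link_peak_col:
            # per-gene effect sizes are lognormal around the configured median
            eff = config.link_effect * rng.lognormal(0.0, config.link_effect_sigma)
            if config.link_distance_decay_bp is not None:
                eff *= math.exp(-link_dist[gene.gene_id] / config.link_distance_decay_bp)
            log_mu = log_mu + eff * open_state[:, link_peak_col[gene.gene_id]]
        mu[:, j] = np.exp(log_mu)
    rna = _nb_sample(rng, mu, config.rna_dispersion)

    # --- annotations ------------------------------------------------------
    gc = rng.beta(*config.gc_beta_params, size=n_peaks)
    all_types = frozenset(types)
    atac_sp = sp.csc_matrix(atac)
    peaks = []
    for j, iv in enumerate(intervals):
        owner = peak_owner[iv.id]
        called = all_types if owner == SHARED else frozenset({owner})
        peaks.append(
            PeakAnnotation(
                iv,
                gc=float(gc[j]),
                log_coverage=float(np.log1p(atac[:, j].sum())),
                called_in=called,
            )
        )

    dataset = MultiomeDataset(
        atac=atac_sp,
        rna=sp.csc_matrix(rna),
        peaks=peaks,
        genes=genes,
        barcodes=barcodes,
        cell_types=np.asarray(cell_types, dtype=object),
    )
    truth = GroundTruth(true_links, peak_owner, gene_marker)
    return dataset, truth


def downsample_celltype(
    dataset: MultiomeDataset,
    celltypes: set[str] | list[str] | str,
    n_keep: int,
    seed: int = 0,
) -> MultiomeDataset:
    """Retain all cells outside ``celltypes`` plus a uniform random sample of
    ``n_keep`` cells within them; peak and gene annotations (including the
    matching covariates) are unchanged."""
    if isinstance(celltypes, str):
        celltypes = {celltypes}
    celltypes = set(celltypes)
    member = np.isin(dataset.cell_types, list(celltypes))
    available = int(member.sum())
    if n_keep > available:
        raise ConfigError(
            f"cannot keep {n_keep} cells: only {available} labeled {sorted(celltypes)}"
        )
    rng = np.random.default_rng(seed)
    member_idx = np.flatnonzero(member)
    keep_member = rng.choice(member_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(~member), keep_member]))
    return MultiomeDataset(
        atac=sp.csc_matrix(dataset.atac[keep]),
        rna=sp.csc_matrix(dataset.rna[keep]),
        peaks=list(dataset.peaks),
        genes=list(dataset.genes),
        barcodes=[dataset.barcodes[i] for i in keep],
        cell_types=dataset.cell_types[keep],
    )


def write_fixture(dataset: MultiomeDataset, truth: GroundTruth | None,
                  out_dir: str | Path) -> None:
    """Write the fixture directory layout: atac/ and rna/ MTX triplets,
    peaks.bed, genes.tsv, labels.tsv, peak_annotations.tsv and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mtx_triplet(dataset.atac, dataset.peak_ids, dataset.barcodes, out / "atac")
    write_mtx_triplet(dataset.rna, dataset.gene_ids, dataset.barcodes, out / "rna")
    with open(out / "peaks.bed", "w") as fh:
        for p in dataset.peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in dataset.genes],
            "chrom": [g.chrom for g in dataset.genes],
            "tss": [g.tss for g in dataset.genes],
            "strand": [g.strand for g in dataset.genes],
        }
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"barcode": dataset.barcodes, "cell_type": dataset.cell_types}
    ).to_csv(out / "labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "peak_id": dataset.peak_ids,
            "gc": [p.gc for p in dataset.peaks],
            "called_in": [",".join(sorted(p.called_in)) for p in dataset.peaks],
        }
    ).to_csv(out / "peak_annotations.tsv", sep="\t", index=False)
    if truth is not None:
        rows = sorted(truth.true_links)
        pd.DataFrame(
            {
                "peak_id": [r[0] for r in rows],
                "gene_id": [r[1] for r in rows],
                "peak_owner_type": [truth.peak_owner_type[r[0]] for r in rows],
                "gene_marker_type": [truth.gene_marker_type[r[1]] for r in rows],
            }
        ).to_csv(out / "truth.tsv", sep="\t", index=False)
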