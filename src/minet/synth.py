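"""Synthetic paired miRNA/gene expression data with known ground truth.

Generates every input the pipeline consumes — expression matrices,
genomic coordinates, a miRNA-target flat file and a PPI edge list —
from a single seeded configuration, so that each downstream stage can be
checked against planted signal.

The generative model: miRNA expression is blockwise-exchangeable
Gaussian (a shared latent factor per block gives within-block Pearson
correlation ``block_rho``); gene expression is a sparse linear response
to miRNA expression plus Gaussian noise that itself carries gene-block
structure.  Planted miRNA->gene effects are graph-smooth: genes of one
co-expression block perturbed by the same miRNA share the sign and
approximate magnitude of their coefficients, which is exactly the
structure the graph-fusion penalties of the multitask model reward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from minet import io

CIS_WINDOW = 1_000_000  # bp; the pipeline-wide cis definition

_MIRNA_LEN = 80  # hairpin arm footprint, bp
_GENE_LEN = 5_000
_ANCHOR_SPACING = 10_000_000  # bp between miRNA anchors on one chromosome


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults are a desk-scale rendition of a tumor expression cohort:
    200 samples, 60 mature miRNAs (30 hairpins x 2 arms), 300 genes,
    20 planted cis eQTL pairs with standardized effect 1.0 against
    noise SD 0.5, and co-expression blocks correlated at rho = 0.8.
    The PPI default (3000 edges, mean degree ~20) mirrors the density
    of aggregate interaction resources; a degree-conditioned
    permutation null only has power when the planted module's inflated
    degrees are shared by enough background nodes.
    """

    n_samples: int = 200
    n_mirnas: int = 60
    n_genes: int = 300
    n_true_eqtls: int = 20
    effect_size: float = 1.0
    noise_sd: float = 0.5
    mirna_block_sizes: list[int] = field(default_factory=lambda: [4] * 10)
    gene_block_sizes: list[int] = field(default_factory=lambda: [5] * 12)
    block_rho: float = 0.8
    cis_fraction: float = 0.8
    ppi_edges: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_mirnas", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_true_eqtls < 0 or self.ppi_edges < 0:
            raise ValueError("counts must be non-negative")
        if any(s <= 0 for s in self.mirna_block_sizes + self.gene_block_sizes):
            raise ValueError("block sizes must be positive")
        if sum(self.mirna_block_sizes) > self.n_mirnas:
            raise ValueError("miRNA block sizes exceed n_mirnas")
        if sum(self.gene_block_sizes) > self.n_genes:
            raise ValueError("gene block sizes exceed n_genes")
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if not 0 <= self.cis_fraction <= 1:
            raise ValueError("cis_fraction must be in [0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if self.n_true_eqtls > self.n_mirnas * self.n_genes:
            raise ValueError("more true eQTLs than miRNA-gene pairs")


@dataclass
class GroundTruth:
    """Planted structure underlying one synthetic cohort."""

    true_eqtl_pairs: set[tuple[str, str]]
    true_coefficients: pd.DataFrame  # miRNAs x genes
    mirna_blocks: list[list[str]]
    gene_blocks: list[list[str]]
    target_records: set[tuple[str, str]]

    def to_jsonable(self) -> dict:
        nz = self.true_coefficients.to_numpy()
        rows, cols = np.nonzero(nz)
        return {
            "true_eqtl_pairs": sorted(list(p) for p in self.true_eqtl_pairs),
            "true_coefficients": [
                [
                    str(self.true_coefficients.index[r]),
                    str(self.true_coefficients.columns[c]),
                    float(nz[r, c]),
                ]
                for r, c in zip(rows, cols)
            ],
            "mirna_blocks": self.mirna_blocks,
            "gene_blocks": self.gene_blocks,
            "target_records": sorted(list(p) for p in self.target_records),
        }


def _mirna_ids(n: int) -> list[str]:
    # hairpins contribute a -3p and a -5p arm; both appear in the matrix
    ids = []
    for i in range(n):
        hairpin = 1000 + i // 2
        arm = "-3p" if i % 2 == 0 else "-5p"
        ids.append(f"syn-mir-{hairpin}{arm}")
    return ids


def _gene_ids(n: int) -> list[str]:
    return [f"SYNG{i:04d}" for i in range(n)]


def _partition(ids: list[str], sizes: list[int]) -> list[list[str]]:
    blocks, pos = [], 0
    for size in sizes:
        blocks.append(ids[pos : pos + size])
        pos += size
    return blocks


def _block_factor_matrix(
    ids: list[str], blocks: list[list[str]], rho: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian matrix (features x samples) with
    exchangeable correlation rho inside each block."""
    values = rng.standard_normal((len(ids), n))
    if rho > 0:
        index = {fid: i for i, fid in enumerate(ids)}
        for block in blocks:
            factor = rng.standard_normal(n)
            for fid in block:
                i = index[fid]
                values[i] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * values[i]
    return values


def _plant_coefficients(
    cfg: SynthConfig,
    mirna_ids: list[str],
    gene_ids: list[str],
    gene_blocks: list[list[str]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose the planted miRNA->gene effects, one gene per pair.

    Gene blocks are consumed one at a time, each paired with a distinct
    miRNA, so the genes of a perturbed block share their miRNA, the sign
    of its effect and (up to 10% jitter) its magnitude.
    """
    coef = pd.DataFrame(
        np.zeros((len(mirna_ids), len(gene_ids))), index=mirna_ids, columns=gene_ids
    )
    blocked = {g for block in gene_blocks for g in block}
    singleton_genes = [g for g in gene_ids if g not in blocked]
    block_order = list(rng.permutation(len(gene_blocks)))
    mirna_order = list(rng.permutation(mirna_ids))
    remaining = cfg.n_true_eqtls

    gene_groups: list[list[str]] = [gene_blocks[b] for b in block_order]
    gene_groups.append(singleton_genes)
    for group in gene_groups:
        if remaining == 0:
            break
        take = group[: min(len(group), remaining)]
        if not take:
            continue
        mirna = mirna_order.pop() if mirna_order else rng.choice(mirna_ids)
        sign = rng.choice([-1.0, 1.0])
        for gene in take:
            jitter = 1.0 + 0.1 * rng.uniform(-1, 1)
            coef.loc[mirna, gene] = sign * cfg.effect_size * jitter
        remaining -= len(take)
    if remaining > 0:
        # gene universe exhausted group-wise; spread the rest over fresh pairs
        free = [
            (m, g)
            for m in mirna_ids
            for g in gene_ids
            if coef.loc[m, g] == 0.0
        ]
        for m, g in [free[i] for i in rng.permutation(len(free))[:remaining]]:
            coef.loc[m, g] = rng.choice([-1.0, 1.0]) * cfg.effect_size
    return coef


def generate_expression(
    cfg: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the paired miRNA and gene expression matrices.

    Returns (miRNA matrix, gene matrix, ground truth); both matrices are
    features x samples with shared sample IDs.  Identical configurations
    (including the seed) yield byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    mirna_ids = _mirna_ids(cfg.n_mirnas)
    gene_ids = _gene_ids(cfg.n_genes)
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    mirna_blocks = _partition(mirna_ids, cfg.mirna_block_sizes)
    gene_blocks = _partition(gene_ids, cfg.gene_block_sizes)

    x = _block_factor_matrix(mirna_ids, mirna_blocks, cfg.block_rho, cfg.n_samples, rng)
    coef = _plant_coefficients(cfg, mirna_ids, gene_ids, gene_blocks, rng)
    noise = _block_factor_matrix(gene_ids, gene_blocks, cfg.block_rho, cfg.n_samples, rng)
    y = coef.to_numpy().T @ x + cfg.noise_sd * noise

    pairs = {
        (mirna_ids[r], gene_ids[c])
        for r, c in zip(*np.nonzero(coef.to_numpy()))
    }
    # target DB ground truth: every true pair, plus decoy interactions
    decoys = set()
    n_decoys = cfg.n_true_eqtls
    while len(decoys) < n_decoys:
        m = mirna_ids[rng.integers(cfg.n_mirnas)]
        g = gene_ids[rng.integers(cfg.n_genes)]
        if (m, g) not in pairs:
            decoys.add((m, g))
    truth = GroundTruth(
        true_eqtl_pairs=pairs,
        true_coefficients=coef,
        mirna_blocks=mirna_blocks,
        gene_blocks=gene_blocks,
        target_records=pairs | decoys,
    )
    mirna_df = pd.DataFrame(x, index=mirna_ids, columns=sample_ids)
    gene_df = pd.DataFrame(y, index=gene_ids, columns=sample_ids)
    return mirna_df, gene_df, truth


def generate_coordinates(
    cfg: SynthConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place every feature on a genome so cis structure is controlled.

    Each miRNA block lives on its own chromosome, with anchors spaced
    10 Mb apart.  Exactly round(cis_fraction * n_true) of the true pairs
    put the gene within the 1 Mb cis window of its miRNA; the remaining
    true pairs place the gene ~2-5 Mb away on the same chromosome (well
    outside the window).  Genes not in any true pair are scattered:
    half inside some miRNA's window (null cis pairs for calibration),
    half outside every window.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mirna_ids = list(truth.true_coefficients.index)
    gene_ids = list(truth.true_coefficients.columns)

    block_of = {}
    for b, block in enumerate(truth.mirna_blocks):
        for fid in block:
            block_of[fid] = b
    n_blocks = len(truth.mirna_blocks)
    singles = [m for m in mirna_ids if m not in block_of]
    for k, fid in enumerate(singles):
        block_of[fid] = n_blocks + k  # one chromosome per unblocked miRNA

    chrom, anchor = {}, {}
    per_chrom_count: dict[int, int] = {}
    for fid in mirna_ids:
        b = block_of[fid]
        k = per_chrom_count.get(b, 0)
        per_chrom_count[b] = k + 1
        chrom[fid] = f"chr{b + 1}"
        anchor[fid] = _ANCHOR_SPACING * (k + 1)

    mirna_bed = pd.DataFrame(
        {
            "chrom": [chrom[m] for m in mirna_ids],
            "start": [anchor[m] for m in mirna_ids],
            "end": [anchor[m] + _MIRNA_LEN for m in mirna_ids],
            "name": mirna_ids,
            "score": 0,
            "strand": "+",
        }
    )

    ordered_pairs = sorted(truth.true_eqtl_pairs)
    perm = rng.permutation(len(ordered_pairs))
    n_cis = int(round(cfg.cis_fraction * len(ordered_pairs)))
    cis_flags = {ordered_pairs[perm[i]]: i < n_cis for i in range(len(ordered_pairs))}
    mirna_of_gene = {g: m for m, g in ordered_pairs}

    gene_rows = []
    free_slot = 0
    for gid in gene_ids:
        if gid in mirna_of_gene:
            m = mirna_of_gene[gid]
            near = cis_flags[(m, gid)]
        else:
            m = mirna_ids[free_slot % len(mirna_ids)]
            near = free_slot % 2 == 0
            free_slot += 1
        if near:
            # gap in (10 kb, 900 kb]: safely inside the 1 Mb window
            gap = int(rng.integers(10_000, 900_000))
        else:
            # 2-5 Mb downstream: outside every window on this chromosome
            gap = int(rng.integers(2_000_000, 5_000_000))
        start = anchor[m] + _MIRNA_LEN + gap
        gene_rows.append(
            {
                "chrom": chrom[m],
                "start": start,
                "end": start + _GENE_LEN,
                "name": gid,
                "score": 0,
                "strand": "+",
            }
        )
    gene_bed = pd.DataFrame(gene_rows)
    return mirna_bed, gene_bed


def generate_target_db(
    truth: GroundTruth, ambiguous_fraction: float, seed: int = 0
) -> pd.DataFrame:
    """Write the planted miRNA-target records as a flat file table.

    ``ambiguous_fraction`` of the records (rounded to a count) have the
    arm suffix (-3p/-5p) stripped from the miRNA name, emulating target
    databases that name the hairpin rather than the mature arm.
    """
    if not 0 <= ambiguous_fraction <= 1:
        raise ValueError("ambiguous_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = sorted(truth.target_records)
    n_strip = int(round(ambiguous_fraction * len(records)))
    strip = set(rng.permutation(len(records))[:n_strip].tolist())
    rows = []
    for i, (m, g) in enumerate(records):
        name = m
        if i in strip:
            for suffix in ("-3p", "-5p"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
                    break
        rows.append({"mirna_name": name, "gene_id": g})
    return pd.DataFrame(rows)


def generate_ppi(cfg: SynthConfig, seed_genes: list[str]) -> nx.Graph:
    """Scale-free-ish PPI over the gene universe with a planted module.

    Backbone: Barabasi-Albert preferential attachment with mean degree
    ~2 * ppi_edges / n_genes.  On top, the designated seed genes are
    wired into a clique, giving them the excess direct connectivity the
    permutation test is meant to detect.
    """
    gene_ids = _gene_ids(cfg.n_genes)
    unknown = set(seed_genes) - set(gene_ids)
    if unknown:
        raise ValueError(f"seed genes outside the gene universe: {sorted(unknown)[:5]}")
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(gene_ids)
    if cfg.ppi_edges == 0:
        return graph
    m = max(1, int(round(cfg.ppi_edges / cfg.n_genes)))
    backbone = nx.barabasi_albert_graph(
        cfg.n_genes, m, seed=int(np.random.default_rng(cfg.seed + 2).integers(2**31))
    )
    graph.add_edges_from(
        (gene_ids[a], gene_ids[b]) for a, b in backbone.edges() if a != b
    )
    seeds = sorted(set(seed_genes))
    for i, a in enumerate(seeds):
        for b in seeds[i + 1 :]:
            graph.add_edge(a, b)
    return graph


def generate_all(
    cfg: SynthConfig, outdir: str | Path, ambiguous_fraction: float = 0.25
) -> GroundTruth:
    """Generate and write every pipeline input under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirna, gene, truth = generate_expression(cfg)
    mirna_bed, gene_bed = generate_coordinates(cfg, truth)
    targets = generate_target_db(truth, ambiguous_fraction, seed=cfg.seed + 3)
    seed_genes = sorted({g for _, g in truth.true_eqtl_pairs})
    ppi = generate_ppi(cfg, seed_genes)
    if ppi.number_of_edges() == 0:
        warnings.warn("generated PPI network has no edges")

    io.write_expression_tsv(mirna, outdir / "mirna_expression.tsv")
    io.write_expression_tsv(gene, outdir / "gene_expression.tsv")
    io.write_bed(mirna_bed, outdir / "mirnas.bed")
    io.write_bed(gene_bed, outdir / "genes.bed")
    io.write_target_db(targets, outdir / "targets.tsv")
    io.write_ppi(ppi, outdir / "ppi.tsv")
    io.write_json(truth.to_jsonable(), outdir / "ground_truth.json")
    return truth
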