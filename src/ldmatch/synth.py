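"""Synthetic phased haplotype panels with controllable LD structure.

The generator uses a founder-mosaic model: each chromosome carries K founder
haplotypes with per-SNP minor-allele probabilities drawn from a rescaled
Beta distribution, and each sampled haplotype is a mosaic of founders.
Walking along the chromosome, the founder index is redrawn between adjacent
SNPs with probability 1 - exp(-c' * d), where d is the physical gap and c'
the local switch rate — a direct recombination analogue, so one parameter
controls the LD decay length (~1/c base pairs).  Inside genic regions the
switch rate is multiplied by gamma <= 1: gamma = 1 gives a null genome whose
genic and non-genic SNPs follow the identical LD process, gamma < 1 plants
an LD excess in genes (less shuffling between founders).

Gene placement is an alternating renewal process (exponential gaps,
gamma-distributed gene lengths) hitting the configured genic fraction in
expectation; SNP positions follow Poisson processes with class-specific
densities, emulating the denser SNP coverage usually seen in genic regions
on array panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import HaplotypePanel, MarkerMap, write_phased_vcf
from .regions import Interval


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the founder-mosaic genome simulator.

    Defaults are the calibration fixture scale used throughout the test
    suite: 2 chromosomes of 1 Mbp, 100 haploid haplotypes, ~40 eligible
    genic regions, and candidate pools comfortably above the 50-window
    eligibility rule.
    """

    n_haplotypes: int = 100
    n_chromosomes: int = 2
    chromosome_length_bp: int = 2_000_000
    genic_fraction: float = 0.12
    mean_gene_length_bp: float = 8_000.0
    snp_density_genic: float = 1.6  # SNPs per kbp
    snp_density_nongenic: float = 1.2  # SNPs per kbp
    n_founders: int = 8
    switch_rate: float = 5e-5  # per bp; LD decay length ~ 1/rate
    genic_ld_multiplier: float = 1.0  # gamma; 1 = null, <1 = genic LD excess
    maf_beta_a: float = 0.8
    maf_beta_b: float = 0.8
    min_maf: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.genic_fraction < 1.0):
            raise SimulationError("genic_fraction must be in (0, 1)")
        if not (0.0 < self.genic_ld_multiplier <= 1.0):
            raise SimulationError("genic_ld_multiplier must be in (0, 1]")
        for name in (
            "n_haplotypes", "n_chromosomes", "chromosome_length_bp",
            "mean_gene_length_bp", "snp_density_genic",
            "snp_density_nongenic", "n_founders", "switch_rate",
        ):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.mean_gene_length_bp >= self.chromosome_length_bp:
            raise SimulationError("mean gene length exceeds chromosome length")
        if self.n_haplotypes < 2 or self.n_founders < 2:
            raise SimulationError("need >= 2 haplotypes and >= 2 founders")


@dataclass
class SyntheticDataset:
    """A simulated panel with its marker map, gene annotation and ground
    truth (passes default genotype QC unchanged by construction)."""

    panel: HaplotypePanel
    marker_map: MarkerMap
    genes: list[Interval]
    truth: dict


def _place_genes(rng: np.random.Generator, cfg: SimConfig, chrom: str) -> list[Interval]:
    """Alternating renewal process: Exp gaps, Gamma(shape 4) gene lengths."""
    gf = cfg.genic_fraction
    mean_gap = cfg.mean_gene_length_bp * (1 - gf) / gf
    genes: list[Interval] = []
    cursor = 0
    L = cfg.chromosome_length_bp
    while True:
        gap = rng.exponential(mean_gap)
        start = cursor + max(1, int(np.ceil(gap)))
        length = max(2, int(np.ceil(rng.gamma(4.0, cfg.mean_gene_length_bp / 4.0))))
        end = start + length - 1
        if end >= L:
            break
        genes.append(Interval(chrom, start, end))
        cursor = end
    return genes


def _poisson_positions(
    rng: np.random.Generator, start: int, end: int, density_per_kbp: float
) -> np.ndarray:
    length = end - start + 1
    if length <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(density_per_kbp * length / 1000.0)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = start + np.unique(rng.integers(0, length, size=n))
    return pos.astype(np.int64)


def _simulate_chromosome(
    rng: np.random.Generator, cfg: SimConfig, chrom: str
) -> tuple[np.ndarray, np.ndarray, list[Interval], np.ndarray]:
    """Returns (alleles N x M, positions, genes, genic flags)."""
    genes = _place_genes(rng, cfg, chrom)

    pos_parts = []
    prev_end = 0
    for g in genes:
        pos_parts.append(
            _poisson_positions(rng, prev_end + 1, g.start - 1, cfg.snp_density_nongenic)
        )
        pos_parts.append(
            _poisson_positions(rng, g.start, g.end, cfg.snp_density_genic)
        )
        prev_end = g.end
    pos_parts.append(
        _poisson_positions(
            rng, prev_end + 1, cfg.chromosome_length_bp, cfg.snp_density_nongenic
        )
    )
    pos = np.concatenate(pos_parts)
    pos = np.unique(pos)
    M = pos.size
    if M < 2:
        raise SimulationError(
            "chromosome received fewer than 2 SNPs; increase density or length"
        )

    genic = np.zeros(M, dtype=bool)
    if genes:
        starts = np.array([g.start for g in genes])
        ends = np.array([g.end for g in genes])
        k = np.searchsorted(starts, pos, side="right") - 1
        genic = (k >= 0) & (pos <= ends[np.clip(k, 0, len(ends) - 1)])

    K = cfg.n_founders
    N = cfg.n_haplotypes
    q = cfg.min_maf + (0.5 - cfg.min_maf) * rng.beta(cfg.maf_beta_a, cfg.maf_beta_b, M)
    founders = (rng.random((K, M)) < q).astype(np.uint8)

    gaps = np.diff(pos).astype(float)
    local_rate = np.where(
        genic[:-1] & genic[1:],
        cfg.genic_ld_multiplier * cfg.switch_rate,
        cfg.switch_rate,
    )
    with np.errstate(over="ignore"):
        p_switch = 1.0 - np.exp(-local_rate * gaps)

    fidx = np.empty((N, M), dtype=np.int32)
    fidx[:, 0] = rng.integers(K, size=N)
    U = rng.random((N, M - 1))
    fresh = rng.integers(K, size=(N, M - 1)).astype(np.int32)
    for k in range(1, M):
        sw = U[:, k - 1] < p_switch[k - 1]
        fidx[:, k] = np.where(sw, fresh[:, k - 1], fidx[:, k - 1])

    alleles = founders[fidx, np.arange(M)]

    # guarantee post-QC stability: redraw founder alleles at columns whose
    # sample MAF fell below min_maf (drift or monomorphic founders)
    for attempt in range(60):
        f = alleles.mean(axis=0)
        maf = np.minimum(f, 1.0 - f)
        bad = np.flatnonzero(maf < cfg.min_maf)
        if bad.size == 0:
            break
        if attempt < 10:
            q_bad = cfg.min_maf + (0.5 - cfg.min_maf) * rng.beta(
                cfg.maf_beta_a, cfg.maf_beta_b, bad.size
            )
        else:  # force common variants so the loop terminates quickly
            q_bad = rng.uniform(0.3, 0.5, bad.size)
        founders[:, bad] = rng.random((K, bad.size)) < q_bad
        alleles[:, bad] = founders[fidx[:, bad], bad]
    else:
        raise SimulationError("could not make all columns polymorphic")

    return alleles, pos, genes, genic


def simulate(config: SimConfig) -> SyntheticDataset:
    """Simulate a phased haploid panel with annotations and ground truth.

    Deterministic under ``config.seed``: per-chromosome generators are
    spawned from one seed sequence, so each chromosome is reproducible in
    isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chromosomes)
    allele_blocks = []
    chrom_names = []
    pos_all = []
    genes_all: list[Interval] = []
    per_chrom = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        rng = np.random.default_rng(children[c])
        alleles, pos, genes, genic = _simulate_chromosome(rng, config, chrom)
        allele_blocks.append(alleles)
        chrom_names.extend([chrom] * pos.size)
        pos_all.append(pos)
        genes_all.extend(genes)
        per_chrom.append(
            {
                "chromosome": chrom,
                "n_snps": int(pos.size),
                "n_genes": len(genes),
                "n_genic_snps": int(genic.sum()),
            }
        )
    panel = HaplotypePanel(
        alleles=np.concatenate(allele_blocks, axis=1),
        sample_ids=[f"H{i}" for i in range(config.n_haplotypes)],
        ploidy_mode="haploid",
    )
    pos_cat = np.concatenate(pos_all)
    f = panel.alleles.mean(axis=0)
    mmap = MarkerMap(
        chrom=np.asarray(chrom_names, dtype=object),
        pos=pos_cat,
        maf=np.minimum(f, 1.0 - f),
    )
    truth = {
        "gamma": config.genic_ld_multiplier,
        "seed": config.seed,
        "n_founders": config.n_founders,
        "switch_rate": config.switch_rate,
        "chromosomes": per_chrom,
    }
    return SyntheticDataset(panel=panel, marker_map=mmap, genes=genes_all, truth=truth)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Emit the dataset as phased VCF + BED + truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf = outdir / "panel.vcf"
    bed = outdir / "genes.bed"
    truth = outdir / "truth.json"
    write_phased_vcf(dataset.panel, dataset.marker_map, vcf)
    with open(bed, "w") as fh:
        for g in dataset.genes:
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\n")
    with open(truth, "w") as fh:
        json.dump(dataset.truth, fh, indent=1)
    return {"vcf": vcf, "bed": bed, "truth": truth}


def planted_effect_suite(
    config: SimConfig,
    gammas,
    n_replicates: int | dict,
    seed: int,
    alpha: float = 0.05,
    min_snps: int = 10,
    min_candidates: int = 50,
    measure: str = "median_r2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full-pipeline calibration/power harness.

    For each genic LD multiplier gamma, simulates ``n_replicates`` genomes
    (``n_replicates`` may be a dict keyed by gamma), runs partition ->
    matching -> genome-wide paired comparison on the chosen measure, and
    records the rejection decision at ``alpha`` and the mean percentage
    difference.  Returns ``(per-gamma summary, per-replicate records)``.
    """
    from .pipeline import run_pipeline  # deferred: pipeline imports synth types

    rng = np.random.default_rng(seed)
    rep_rows = []
    for gamma in gammas:
        n_rep = n_replicates[gamma] if isinstance(n_replicates, dict) else n_replicates
        rep_seeds = rng.integers(0, 2**31 - 1, size=n_rep)
        for r in range(n_rep):
            cfg = replace(
                config, genic_ld_multiplier=float(gamma), seed=int(rep_seeds[r])
            )
            ds = simulate(cfg)
            result = run_pipeline(
                ds.panel, ds.marker_map, ds.genes,
                min_snps=min_snps, min_candidates=min_candidates,
                alpha=alpha, measures=(measure,), scopes=("genome",),
                comparisons=("G_vs_IG",),
            )
            row = result.comparisons
            row = row[
                (row["scope"] == "genome")
                & (row["measure"] == measure)
                & (row["comparison"] == "G_vs_IG")
            ].iloc[0]
            rep_rows.append(
                {
                    "gamma": float(gamma),
                    "replicate": r,
                    "seed": int(rep_seeds[r]),
                    "n_pairs": int(row["n_pairs"]),
                    "mean_pct_diff": float(row["mean_pct_diff"]),
                    "p_value": float(row["p_value"]),
                    "reject": bool(row["p_value"] < alpha),
                }
            )
    reps = pd.DataFrame(rep_rows)
    summary = (
        reps.groupby("gamma")
        .agg(
            n_replicates=("replicate", "size"),
            rejection_rate=("reject", "mean"),
            mean_delta=("mean_pct_diff", "mean"),
            mean_n_pairs=("n_pairs", "mean"),
        )
        .reset_index()
    )
    return summary, reps
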