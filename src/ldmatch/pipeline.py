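"""End-to-end orchestration: partition -> matching -> summaries -> tests."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import HaplotypePanel, MarkerMap
from .ld import summarize_region_fast
from .matching import ExclusionRecord, MatchedTriple, select_matched_triples
from .paired_tests import PairedSample, compare
from .regions import (
    Interval,
    Region,
    eligible_reference_sets,
    merge_overlapping_genes,
    partition_markers,
    regions_to_dataframe,
)

MEASURES = ("median_r2", "median_r2s", "mean_r2", "mean_r2s", "H")
COMPARISONS = ("G_vs_IG", "IG_vs_IGprime")


@dataclass
class PipelineResult:
    marker_map: MarkerMap
    genic_regions: list[Region]
    nongenic_segments: list[Region]
    eligible: list[Region]
    triples: list[MatchedTriple]
    exclusions: list[ExclusionRecord]
    summaries: pd.DataFrame  # one row per (triple, role)
    comparisons: pd.DataFrame  # one row per (scope, measure, comparison)
    counts: dict


def _summaries_table(
    panel: HaplotypePanel,
    mmap: MarkerMap,
    triples: list[MatchedTriple],
    diversity_mode: str,
) -> pd.DataFrame:
    rows = []
    for t_id, t in enumerate(triples):
        for role, region in (("G", t.G), ("IG", t.IG), ("IG_prime", t.IG_prime)):
            s = summarize_region_fast(panel, region, mmap, diversity_mode)
            rows.append(
                {
                    "triple": t_id,
                    "role": role,
                    "chrom": region.chromosome,
                    "start": region.span[0] if region.span else -1,
                    "end": region.span[1] if region.span else -1,
                    "n_snps": region.n_snps,
                    "n_pairs": s.n_pairs,
                    "median_r2": s.median_r2,
                    "median_r2s": s.median_r2s,
                    "mean_r2": s.mean_r2,
                    "mean_r2s": s.mean_r2s,
                    "H": s.H,
                }
            )
    return pd.DataFrame(rows)


def _comparison_table(
    summaries: pd.DataFrame,
    triples: list[MatchedTriple],
    measures,
    comparisons,
    scopes,
    alpha: float,
    delta_mode: str,
    bonferroni: bool = False,
) -> pd.DataFrame:
    if summaries.empty:
        return pd.DataFrame(
            columns=[
                "scope", "measure", "comparison", "n_pairs", "mean_ref",
                "mean_ctrl", "mean_pct_diff", "se_pct_diff",
                "wilcoxon_statistic", "p_value", "significant", "testable",
            ]
        )
    wide = summaries.pivot(index="triple", columns="role")
    chrom_of = summaries[summaries["role"] == "G"].set_index("triple")["chrom"]
    chroms = list(dict.fromkeys(chrom_of))
    scope_list = []
    if scopes is None:
        scope_list = chroms + ["genome"]
    else:
        for s in scopes:
            scope_list.extend(chroms if s == "chromosome" else [s])
    rows = []
    for scope in scope_list:
        sel = (
            wide.index
            if scope == "genome"
            else chrom_of.index[chrom_of == scope]
        )
        if len(sel) == 0:
            continue
        for measure in measures:
            for comp in comparisons:
                ref_role, ctrl_role = (
                    ("G", "IG") if comp == "G_vs_IG" else ("IG", "IG_prime")
                )
                sample = PairedSample(
                    ref=wide.loc[sel, (measure, ref_role)].to_numpy(),
                    ctrl=wide.loc[sel, (measure, ctrl_role)].to_numpy(),
                    measure=measure,
                    comparison=comp,
                    scope=str(scope),
                )
                res = compare(sample, alpha=alpha, delta_mode=delta_mode)
                if bonferroni and scope != "genome" and res.testable:
                    res.p_value = min(1.0, res.p_value * len(chroms))
                    res.significant = bool(res.p_value < alpha)
                rows.append(
                    {
                        "scope": res.scope,
                        "measure": res.measure,
                        "comparison": res.comparison,
                        "n_pairs": res.n_pairs,
                        "mean_ref": res.mean_ref,
                        "mean_ctrl": res.mean_ctrl,
                        "mean_pct_diff": res.mean_pct_diff,
                        "se_pct_diff": res.se_pct_diff,
                        "wilcoxon_statistic": res.wilcoxon_statistic,
                        "p_value": res.p_value,
                        "significant": res.significant,
                        "testable": res.testable,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(
    panel: HaplotypePanel,
    mmap: MarkerMap,
    gene_intervals: list[Interval],
    min_snps: int = 10,
    min_candidates: int = 50,
    step: int = 1,
    pool: dict | None = None,
    alpha: float = 0.05,
    diversity_mode: str = "sample_corrected",
    delta_mode: str = "per_pair",
    measures=MEASURES,
    comparisons=COMPARISONS,
    scopes=None,
    bonferroni: bool = False,
) -> PipelineResult:
    """Run partition -> eligibility -> matching -> summaries -> paired tests
    on an in-memory panel.  ``scopes`` may list chromosome ids, "genome" or
    the shorthand "chromosome" (all chromosomes); default is all chromosomes
    plus genome-wide.  ``bonferroni`` multiplies chromosome-scope p-values
    by the number of chromosomes (off by default: each chromosome is
    interpreted at its own 5% level)."""
    merged = merge_overlapping_genes(gene_intervals)
    mmap, genic_regions, nongenic_segments = partition_markers(mmap, merged)
    eligible = eligible_reference_sets(genic_regions, min_snps=min_snps)
    small = [g for g in genic_regions if g.n_snps < min_snps]
    exclusions = [
        ExclusionRecord(
            chromosome=g.chromosome, span=g.span, n_snps=g.n_snps,
            reason="too few SNPs",
        )
        for g in small
    ]
    triples, match_excl = select_matched_triples(
        eligible, mmap, nongenic_segments,
        min_candidates=min_candidates, step=step, pool=pool,
    )
    exclusions.extend(match_excl)
    summaries = _summaries_table(panel, mmap, triples, diversity_mode)
    comparisons_df = _comparison_table(
        summaries, triples, measures, comparisons, scopes, alpha, delta_mode,
        bonferroni,
    )
    n_genic = int((mmap.region_class == "genic").sum())
    counts = {
        "n_snps": len(mmap),
        "n_genic_snps": n_genic,
        "n_nongenic_snps": len(mmap) - n_genic,
        "n_merged_genic_intervals": len(merged),
        "n_genic_regions_with_snps": len(genic_regions),
        "n_eligible": len(eligible),
        "n_matched_triples": len(triples),
        "n_excluded": len(exclusions),
    }
    return PipelineResult(
        marker_map=mmap,
        genic_regions=genic_regions,
        nongenic_segments=nongenic_segments,
        eligible=eligible,
        triples=triples,
        exclusions=exclusions,
        summaries=summaries,
        comparisons=comparisons_df,
        counts=counts,
    )


def _config_hash(config: dict) -> str:
    return hashlib.md5(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_report(result: PipelineResult, outdir, config: dict) -> dict:
    """Write the TSV report bundle (regions, matches, exclusions,
    comparisons) with a provenance header on every file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# ldmatch {__version__} config={_config_hash(config)}\n"
    paths = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        paths[name] = path

    emit("regions.tsv", regions_to_dataframe(result.genic_regions + result.nongenic_segments))
    match_rows = []
    for t_id, t in enumerate(result.triples):
        match_rows.append(
            {
                "triple": t_id,
                "chrom": t.G.chromosome,
                "g_start": t.G.span[0] if t.G.span else -1,
                "g_end": t.G.span[1] if t.G.span else -1,
                "m_snps": t.G.n_snps,
                "ig_start": t.IG.span[0],
                "ig_end": t.IG.span[1],
                "igp_start": t.IG_prime.span[0],
                "igp_end": t.IG_prime.span[1],
                "a_maf": t.score_IG.a_maf,
                "a_delta": t.score_IG.a_delta,
                "a_pwd": t.score_IG.a_pwd,
                "total": t.score_IG.total,
                "n_candidates": t.n_candidates,
            }
        )
    emit("matches.tsv", pd.DataFrame(match_rows))
    emit(
        "exclusions.tsv",
        pd.DataFrame(
            [
                {
                    "chrom": e.chromosome,
                    "start": e.span[0] if e.span else -1,
                    "end": e.span[1] if e.span else -1,
                    "n_snps": e.n_snps,
                    "reason": e.reason,
                    "n_candidates": e.n_candidates,
                }
                for e in result.exclusions
            ],
            columns=["chrom", "start", "end", "n_snps", "reason", "n_candidates"],
        ),
    )
    emit("summaries.tsv", result.summaries)
    emit("comparisons.tsv", result.comparisons)
    return paths
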