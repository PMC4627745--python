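"""Shared fixtures and helpers for the ldmatch test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ldmatch import HaplotypePanel, MarkerMap


def make_panel(rows, ploidy_mode: str = "haploid") -> HaplotypePanel:
    """Panel from a list of 0/1 haplotype rows."""
    A = np.asarray(rows, dtype=np.uint8)
    return HaplotypePanel(
        alleles=A,
        sample_ids=[f"H{i}" for i in range(A.shape[0])],
        ploidy_mode=ploidy_mode,
    )


def make_map(pos, maf=None, chrom: str = "chr1") -> MarkerMap:
    """Single-chromosome marker map; MAF defaults to 0.25 everywhere."""
    pos = np.asarray(pos, dtype=np.int64)
    if maf is None:
        maf = np.full(pos.size, 0.25)
    return MarkerMap(
        chrom=np.asarray([chrom] * pos.size, dtype=object), pos=pos, maf=maf
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    """8 haplotypes x 4 SNPs with all columns polymorphic."""
    A = np.array(
        [
            [1, 0, 1, 0],
            [1, 0, 1, 1],
            [0, 1, 0, 0],
            [0, 1, 1, 0],
            [1, 0, 0, 1],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 1, 0],
        ],
        dtype=np.uint8,
    )
    return make_panel(A)


@pytest.fixture(scope="session")
def calibration_suite():
    """Full-pipeline calibration/power runs shared by the statistical
    acceptance tests: 1000 null genomes plus 200 genomes at each planted
    effect level (gamma = 0.5, 0.25) under the default study conditions."""
    from ldmatch import SimConfig, planted_effect_suite

    summary, reps = planted_effect_suite(
        SimConfig(),
        gammas=[1.0, 0.5, 0.25],
        n_replicates={1.0: 1000, 0.5: 200, 0.25: 200},
        seed=0,
    )
    return summary, reps
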