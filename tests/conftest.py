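"""Shared fixtures: one small and one full-size synthetic methylome.

The full-size dataset (16 Mb, ~65k PMD CpGs at 30x coverage) is generated
once per session and shared by the model-recovery, attenuation, null and
MNase tests; the small dataset serves the cheaper unit tests.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pmdseq as pq
from pmdseq import core

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

GT_SEED = 11
CALLS_SEED = 12
REPLICATE_SEED = 77
FIT_SEED = 5


def small_config() -> pq.SimConfig:
    return pq.SimConfig(
        chrom_lengths={"chr1": 800_000, "chr2": 400_000},
        pmd_length_range=(120_000, 250_000),
        gap_length_range=(60_000, 150_000),
        island_spacing_mean=80_000,
        dhs_spacing_mean=150_000,
        repeat_coverage=0.3,
        duplication_lengths=(8_000,),
    )


def null_config(intercept: float = 0.5, chrom_len: int = 210_000) -> pq.SimConfig:
    """Single all-PMD chromosome with a flat coefficient matrix."""
    return pq.SimConfig(
        chrom_lengths={"chr1": chrom_len},
        pmd_length_range=(chrom_len, chrom_len + 1),
        gap_length_range=(2, 4),
        island_spacing_mean=10 * chrom_len,
        dhs_spacing_mean=10 * chrom_len,
        repeat_coverage=0.0,
        duplication_lengths=(),
        intercept=intercept,
        cg_inner=0.0,
        cg_band=0.0,
        cg_outer=0.0,
        flank_left={},
        flank_right={},
        periodic_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def small_gt() -> pq.GroundTruth:
    return pq.make_ground_truth(small_config(), seed=7)


@pytest.fixture(scope="session")
def default_gt() -> pq.GroundTruth:
    return pq.make_ground_truth(pq.SimConfig(), seed=GT_SEED)


def preprocess(gt: pq.GroundTruth, seed: int) -> pd.DataFrame:
    """Simulate one methylome and run the standard filtering pipeline."""
    calls = pq.simulate_methylome(gt, seed=seed)
    cpgs = core.combine_strands(calls)
    cpgs = core.apply_filters(
        cpgs, gt.regions["CpG_island"], dhs=gt.regions["DHS"], min_cov=10
    )
    return core.annotate_intervals(cpgs, gt.regions["PMD"], gt.regions["repeat"])


@pytest.fixture(scope="session")
def default_cpgs(default_gt) -> pd.DataFrame:
    return preprocess(default_gt, CALLS_SEED)


@pytest.fixture(scope="session")
def pmd_cpgs(default_cpgs) -> pd.DataFrame:
    return default_cpgs[default_cpgs["pmd"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def pmd_design(pmd_cpgs, default_gt) -> pq.ContextDesign:
    return pq.encode_contexts(pmd_cpgs, default_gt.genome)


@pytest.fixture(scope="session")
def main_fit(pmd_design):
    """The reference model-recovery experiment: 50k PMD CpGs, 40k/10k split."""
    rng = np.random.default_rng(FIT_SEED)
    sub = pmd_design.subset(np.sort(rng.choice(pmd_design.n_sites, 50_000, replace=False)))
    coeffs, ev = pq.fit_dinuc_model(sub, n_train=40_000, n_test=10_000, seed=FIT_SEED)
    return sub, coeffs, ev


def attach_truth(cpgs: pd.DataFrame, gt: pq.GroundTruth) -> pd.DataFrame:
    """Merge the generator's true per-CpG probability into an observed table."""
    return cpgs.merge(gt.cpgs[["chrom", "pos", "p"]], on=["chrom", "pos"], how="left")
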