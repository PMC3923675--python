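"""Allele-specific validation of the positional dinucleotide effects.

A homozygous CpG flanked by exactly one heterozygous SNP measures, through
the methylation difference between its two alleles, the effect of swapping
one dinucleotide: dm = m_alt - m_ref = s_d(alt) - s_d(ref).  Because an
arbitrary constant per block leaves all dm unchanged, the per-block
regression is singular; the TT coefficient is fixed to zero as reference,
leaving 15 free variables per block, solved independently per block with
no intercept.  For display the coefficients (with TT's zero reinserted)
are mean-centered per block, which removes the gauge entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .sequence import (
    FLANK,
    Genome,
    N_BLOCKS,
    TT_CODE,
    block_codes,
    block_of_offset,
    window_codes,
)

log = logging.getLogger(__name__)

N_STATES = 16


@dataclass
class AllelicFit:
    """Per-block dinucleotide coefficients inferred from allelic differences.

    ``matrix[b, d]`` is NaN where dinucleotide d never occurs in block b's
    equations or where a block had too few sites; ``centered`` subtracts
    each block's mean over its defined states.
    """

    blocks: np.ndarray  # block indices fitted (subset of 0..77)
    matrix: np.ndarray  # (78, 16), NaN = missing
    n_sites: np.ndarray  # (78,) equations per block

    def centered(self) -> np.ndarray:
        out = self.matrix.copy()
        for b in range(out.shape[0]):
            ok = ~np.isnan(out[b])
            if ok.any():
                out[b, ok] -= out[b, ok].mean()
        return out


def blocks_in_window(window: int) -> np.ndarray:
    """Block indices whose two bases both lie within +-window bp of the C."""
    out = []
    for b in range(N_BLOCKS):
        left = -FLANK + 2 * b if b < N_BLOCKS // 2 else 2 + 2 * (b - N_BLOCKS // 2)
        if left >= -window and left + 1 <= window + 1:
            out.append(b)
    return np.asarray(out)


def select_allelic_cpgs(
    ref_table: pd.DataFrame,
    alt_table: pd.DataFrame,
    snps: pd.DataFrame,
    genome: Genome,
    window: int = 40,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Select CpGs with exactly one heterozygous SNP in the +-window.

    Keeps CpGs present on both alleles with coverage >= ``min_cov`` on
    each, whose window (taken in whole blocks: offsets -window..-1 and
    +2..window+1) contains exactly one heterozygous SNP not hitting the
    CpG dinucleotide itself.  Returns one row per site with the ref and
    alt dinucleotide of the SNP's block and the allelic difference
    dm = m_alt - m_ref.
    """
    if "heterozygous" in snps.columns:
        het = snps[snps["heterozygous"].astype(bool)]
    else:
        het = snps
    merged = ref_table.merge(
        alt_table, on=["chrom", "pos"], suffixes=("_ref", "_alt")
    )
    merged = merged[
        (merged["total_ref"] >= min_cov) & (merged["total_alt"] >= min_cov)
    ]
    rows = []
    for chrom, sub in merged.groupby("chrom", sort=True):
        codes = genome[chrom]
        spos = np.sort(het.loc[het["chrom"] == chrom, "pos"].to_numpy())
        salt = het.loc[het["chrom"] == chrom].set_index("pos")["alt_base"]
        base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
        for row in sub.itertuples(index=False):
            pos = int(row.pos)
            lo = np.searchsorted(spos, pos - window)
            hi = np.searchsorted(spos, pos + window + 2)
            hits = spos[lo:hi]
            hits = hits[(hits != pos) & (hits != pos + 1)]
            # exclude SNPs in the +-window corners outside whole blocks
            hits = hits[(hits - pos >= -window) & (hits - pos <= window + 1)]
            in_cpg = np.any((spos[lo:hi] == pos) | (spos[lo:hi] == pos + 1))
            if in_cpg or len(hits) != 1:
                continue
            snp = int(hits[0])
            off = snp - pos
            block = block_of_offset(off)
            if block is None:
                continue
            win, valid = window_codes(codes, np.array([pos]))
            if not valid[0]:
                continue
            bcodes = block_codes(win)[0]
            d_ref = int(bcodes[block])
            b_left = -FLANK + 2 * block if block < N_BLOCKS // 2 else 2 + 2 * (block - N_BLOCKS // 2)
            alt_code = base_code[str(salt.loc[snp])]
            first = alt_code if off == b_left else int(codes[pos + b_left])
            second = alt_code if off == b_left + 1 else int(codes[pos + b_left + 1])
            d_alt = 4 * first + second
            if d_alt == d_ref:
                continue
            m_ref = row.meth_ref / row.total_ref
            m_alt = row.meth_alt / row.total_alt
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "snp_pos": snp,
                    "offset": off,
                    "block": block,
                    "d_R": d_ref,
                    "d_A": d_alt,
                    "m_R": m_ref,
                    "m_A": m_alt,
                    "dm": m_alt - m_ref,
                    "cov_R": int(row.total_ref),
                    "cov_A": int(row.total_alt),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "snp_pos", "offset", "block", "d_R", "d_A",
            "m_R", "m_A", "dm", "cov_R", "cov_A",
        ],
    )


def allelic_design(sites: pd.DataFrame) -> np.ndarray:
    """Signed incidence rows (+1 at d_A, -1 at d_R) over the 15 non-TT states."""
    free = [d for d in range(N_STATES) if d != TT_CODE]
    col = {d: j for j, d in enumerate(free)}
    X = np.zeros((len(sites), len(free)))
    for i, (da, dr) in enumerate(zip(sites["d_A"], sites["d_R"])):
        if da != TT_CODE:
            X[i, col[da]] += 1.0
        if dr != TT_CODE:
            X[i, col[dr]] -= 1.0
    return X


def fit_allelic_positionwise(
    sites: pd.DataFrame, min_sites_per_block: int = 50
) -> AllelicFit:
    """Per-block least squares for the allelic dinucleotide contributions.

    Each site contributes one equation dm = s(d_A) - s(d_R); TT is fixed
    to zero (reference), there is no intercept, and every block is solved
    independently.  Dinucleotides appearing in no equation of a block are
    reported missing (NaN), not zero; blocks with fewer than
    ``min_sites_per_block`` equations are skipped entirely.
    """
    matrix = np.full((N_BLOCKS, N_STATES), np.nan)
    n_sites = np.zeros(N_BLOCKS, dtype=np.int64)
    fitted_blocks = []
    free = [d for d in range(N_STATES) if d != TT_CODE]
    for block, sub in sites.groupby("block"):
        block = int(block)
        n_sites[block] = len(sub)
        if len(sub) < min_sites_per_block:
            log.info("block %d: only %d sites, skipped", block, len(sub))
            continue
        X = allelic_design(sub)
        y = sub["dm"].to_numpy(dtype=np.float64)
        present = np.zeros(N_STATES, dtype=bool)
        present[TT_CODE] = True
        for d in np.concatenate([sub["d_A"].to_numpy(), sub["d_R"].to_numpy()]):
            present[int(d)] = True
        used_cols = [j for j, d in enumerate(free) if present[d]]
        sol = np.full(len(free), np.nan)
        if used_cols:
            Xu = X[:, used_cols]
            fit, *_ = scipy.linalg.lstsq(Xu, y, cond=1e-10)
            sol[used_cols] = fit
        matrix[block, TT_CODE] = 0.0
        for j, d in enumerate(free):
            if present[d]:
                matrix[block, d] = sol[j]
        fitted_blocks.append(block)
    return AllelicFit(
        blocks=np.asarray(fitted_blocks, dtype=np.int64),
        matrix=matrix,
        n_sites=n_sites,
    )


def concordance(
    fit: AllelicFit, truth_matrix: np.ndarray, blocks: Optional[np.ndarray] = None
) -> float:
    """Pearson r between centered fitted and centered true coefficients.

    Computed over all defined (block, dinucleotide) cells of the fitted
    blocks; the truth matrix is centered per block the same way.
    """
    blocks = fit.blocks if blocks is None else blocks
    fitted = fit.centered()[blocks]
    true_c = truth_matrix - truth_matrix.mean(axis=1, keepdims=True)
    true_c = true_c[blocks]
    ok = ~np.isnan(fitted)
    return float(np.corrcoef(fitted[ok], true_c[ok])[0, 1])
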