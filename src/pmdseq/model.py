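"""Position-specific dinucleotide regression for single-CpG methylation.

The sequence environment of every CpG (+-78 bp, excluding the CpG itself)
is tiled into 78 non-overlapping dinucleotide blocks.  Each block is a
categorical predictor with 16 states; dropping one reference state per
block gives 78 x 15 = 1170 dummy variables.  Methylation level is fit by
ordinary least squares on these dummies plus an intercept, trained and
evaluated on disjoint random subsets.  For display, the dropped state is
reinserted as zero and each block's 16 coefficients are centered to mean
zero; the centered matrix is invariant to the choice of reference state
whenever the design has full rank.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .sequence import (
    BLOCK_LEFT_OFFSETS,
    DINUCS,
    FLANK,
    Genome,
    N_BLOCKS,
    block_codes,
    window_codes,
)

log = logging.getLogger(__name__)

N_STATES = 16
N_DUMMIES = N_BLOCKS * (N_STATES - 1)  # 1170

#: relative singular-value cutoff of the least-squares solver
SOLVER_RCOND = 1e-10


@dataclass
class ContextDesign:
    """Compact design-matrix description: one dinucleotide code per block."""

    codes: np.ndarray  # (n_sites, 78) int8, values 0..15
    cpgs: pd.DataFrame  # retained CpG rows, aligned with ``codes``

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        """Number of dummy predictor columns after dropping references."""
        return self.codes.shape[1] * (N_STATES - 1)

    def subset(self, idx: np.ndarray) -> "ContextDesign":
        return ContextDesign(self.codes[idx], self.cpgs.iloc[idx].reset_index(drop=True))


@dataclass
class DinucCoefficients:
    """Per-block dinucleotide coefficients plus intercept.

    ``matrix[b, d]`` is the contribution of dinucleotide ``d`` in block
    ``b``; for a fitted model the reference state of each block is exactly
    zero.  ``reference`` records the dropped state per block (None for a
    ground-truth matrix that was never fit).
    """

    matrix: np.ndarray  # (78, 16)
    intercept: float
    reference: Optional[np.ndarray] = None  # (78,) dinucleotide codes
    zero_count: List[Tuple[int, int]] = field(default_factory=list)

    def centered(self) -> np.ndarray:
        """Per-block mean-zero coefficient matrix, shape (78, 16)."""
        return self.matrix - self.matrix.mean(axis=1, keepdims=True)

    def linear_predictor(self, codes: np.ndarray) -> np.ndarray:
        """intercept + sum of block coefficients for observed dinucleotides."""
        codes = np.atleast_2d(codes).astype(np.int64)
        contrib = self.matrix[np.arange(codes.shape[1])[None, :], codes]
        return self.intercept + contrib.sum(axis=1)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# intercept\t{self.intercept!r}\n")
            if self.reference is not None:
                refs = "\t".join(DINUCS[c] for c in self.reference)
                fh.write(f"# reference\t{refs}\n")
            df = pd.DataFrame(
                self.matrix.T, index=DINUCS, columns=BLOCK_LEFT_OFFSETS
            )
            df.to_csv(fh, sep="\t", index_label="dinucleotide")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "DinucCoefficients":
        intercept = 0.0
        reference = None
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("# intercept"):
                intercept = float(line.split("\t")[1])
            elif line.startswith("# reference"):
                refs = line.rstrip("\n").split("\t")[1:]
                reference = np.array([DINUCS.index(r) for r in refs])
            else:
                body_start = i
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
        matrix = df.loc[DINUCS].to_numpy().T
        return cls(matrix=matrix, intercept=intercept, reference=reference)


@dataclass
class ModelEvaluation:
    """Held-out performance of a fitted model."""

    r: float
    r2: float  # 1 - SSE/SST on the test set
    n_train: int
    n_test: int


def encode_contexts(cpgs: pd.DataFrame, genome: Genome) -> ContextDesign:
    """Build the block-code design for every CpG with full non-N flanks.

    CpGs whose +-78 bp window runs off the chromosome or contains an N are
    skipped with a log entry.
    """
    all_codes = []
    all_rows = []
    n_skipped = 0
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        codes = genome[chrom]
        win, valid = window_codes(codes, sub["pos"].to_numpy(), flank=FLANK)
        n_skipped += int((~valid).sum())
        if valid.any():
            all_codes.append(block_codes(win[valid]))
            all_rows.append(sub[valid])
    if n_skipped:
        log.info("skipped %d CpGs without a full non-N +-%d bp flank", n_skipped, FLANK)
    if not all_codes:
        return ContextDesign(np.empty((0, N_BLOCKS), dtype=np.int8), cpgs.iloc[:0])
    return ContextDesign(
        np.concatenate(all_codes, axis=0),
        pd.concat(all_rows, axis=0).reset_index(drop=True),
    )


def _choose_references(counts: np.ndarray, how: str) -> np.ndarray:
    """Dropped dinucleotide per block: first/last observed in code order."""
    refs = np.empty(N_BLOCKS, dtype=np.int64)
    for b in range(N_BLOCKS):
        observed = np.flatnonzero(counts[b] > 0)
        if len(observed) == 0:
            refs[b] = 0
            continue
        refs[b] = observed[0] if how == "first_observed" else observed[-1]
    return refs


def _column_map(references: np.ndarray) -> np.ndarray:
    """(78, 16) map from (block, dinucleotide) to dummy column, -1 = reference."""
    col_of = np.full((N_BLOCKS, N_STATES), -1, dtype=np.int64)
    for b in range(N_BLOCKS):
        states = [d for d in range(N_STATES) if d != references[b]]
        for rank, d in enumerate(states):
            col_of[b, d] = b * (N_STATES - 1) + rank
    return col_of


def dummy_matrix(codes: np.ndarray, references: np.ndarray) -> sp.csr_matrix:
    """Expand block codes to the sparse 1170-column dummy matrix (+intercept).

    The last column is the constant-one intercept column.
    """
    n = codes.shape[0]
    col_of = _column_map(references)
    cols = col_of[np.arange(codes.shape[1])[None, :], codes.astype(np.int64)]
    mask = cols >= 0
    row_idx = np.repeat(np.arange(n), codes.shape[1])[mask.ravel()]
    col_idx = cols.ravel()[mask.ravel()]
    row_idx = np.concatenate([row_idx, np.arange(n)])
    col_idx = np.concatenate([col_idx, np.full(n, N_DUMMIES)])
    data = np.ones(len(row_idx))
    return sp.csr_matrix((data, (row_idx, col_idx)), shape=(n, N_DUMMIES + 1))


def fit_dinuc_model(
    design: ContextDesign,
    levels: Optional[np.ndarray] = None,
    n_train: int = 100_000,
    n_test: int = 100_000,
    seed: int = 0,
    reference: str = "first_observed",
) -> Tuple[DinucCoefficients, ModelEvaluation]:
    """Fit the positional dinucleotide model by ordinary least squares.

    Training and test rows are disjoint random subsets of the design.  The
    normal equations are solved by SVD with a relative singular-value
    cutoff of ``SOLVER_RCOND``; dinucleotides absent from the training set
    keep a coefficient of exactly zero and are flagged in ``zero_count``.
    """
    if levels is None:
        levels = design.cpgs["level"].to_numpy()
    levels = np.asarray(levels, dtype=np.float64)
    n = design.n_sites
    if n_train + n_test > n:
        raise ValueError(f"n_train + n_test = {n_train + n_test} exceeds {n} sites")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train : n_train + n_test])

    codes_train = design.codes[train_idx].astype(np.int64)
    counts = np.zeros((N_BLOCKS, N_STATES), dtype=np.int64)
    for b in range(N_BLOCKS):
        counts[b] = np.bincount(codes_train[:, b], minlength=N_STATES)
    refs = _choose_references(counts, reference)

    X = dummy_matrix(codes_train, refs)
    y = levels[train_idx]
    A = (X.T @ X).toarray()
    b_vec = X.T @ y
    sol, _, rank, _ = scipy.linalg.lstsq(A, b_vec, cond=SOLVER_RCOND)

    col_of = _column_map(refs)
    matrix = np.zeros((N_BLOCKS, N_STATES))
    has_col = col_of >= 0
    matrix[has_col] = sol[col_of[has_col]]
    zero_count = [
        (b, d)
        for b in range(N_BLOCKS)
        for d in range(N_STATES)
        if counts[b, d] == 0 and d != refs[b]
    ]
    for b, d in zero_count:
        matrix[b, d] = 0.0
    if zero_count:
        log.warning(
            "%d (block, dinucleotide) states absent from training; "
            "coefficients reported as 0",
            len(zero_count),
        )
    coeffs = DinucCoefficients(
        matrix=matrix, intercept=float(sol[N_DUMMIES]), reference=refs,
        zero_count=zero_count,
    )

    pred = coeffs.linear_predictor(design.codes[test_idx].astype(np.int64))
    obs = levels[test_idx]
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    r = (
        float(np.corrcoef(pred, obs)[0, 1])
        if np.std(pred) > 0 and np.std(obs) > 0
        else float("nan")
    )
    return coeffs, ModelEvaluation(r=r, r2=r2, n_train=len(train_idx), n_test=len(test_idx))


def predict(
    coeffs: DinucCoefficients, design: ContextDesign, clip: bool = False
) -> np.ndarray:
    """Linear prediction for every site of a design."""
    if design.codes.shape[1] != coeffs.matrix.shape[0]:
        raise ValueError(
            f"design has {design.codes.shape[1]} blocks, "
            f"model expects {coeffs.matrix.shape[0]}"
        )
    pred = coeffs.linear_predictor(design.codes.astype(np.int64))
    if clip:
        pred = np.clip(pred, 0.0, 1.0)
    return pred


def normalize_heatmap(coeffs: DinucCoefficients) -> np.ndarray:
    """Mean-zero coefficient matrix for display, shape (16, 78).

    The dropped reference state re-enters as zero (it is stored as zero)
    and each block's 16 values are centered to mean zero.
    """
    return coeffs.centered().T
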