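"""Synthetic methylome generator with known ground truth.

Generates a genome with CpGs at realistic density, PMD / non-PMD domains,
CpG islands (CpG-enriched and unmethylated), DNase hypersensitive sites,
classed repeat intervals and optional duplicated segments; assigns every
CpG a true methylation probability p; and samples per-strand bisulfite
counts, allele-resolved diploid counts around heterozygous SNPs, and
MNase read starts with ~180 bp nucleosome spacing.

Inside PMDs, p is a deterministic linear function of the +-78 bp sequence
environment through a positional dinucleotide coefficient matrix with
(a) positive CpG-state weights in a +-20 bp band, strongest at the two
innermost blocks, (b) flanking-dinucleotide effects at the innermost
blocks, and (c) a weak 10 bp periodic component; the linear predictor is
clamped to [0, 1], with magnitudes chosen so clamping stays rare.  Outside
PMDs p is near 1; in islands near 0 — independent of sequence, so the
sequence signal is PMD-specific.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .model import DinucCoefficients
from .regions import RegionSet
from .sequence import (
    BLOCK_CENTERS,
    DINUCS,
    FLANK,
    Genome,
    N_BLOCKS,
    block_codes,
    block_of_offset,
    dinuc_code,
    find_cpgs,
    window_codes,
    CG_CODE,
)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named generation stage."""
    key = zlib.crc32(stage.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson(mean) conditioned on being >= 1."""
    out = rng.poisson(mean, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(mean, size=int(zero.sum()))
        zero = out == 0
    return out


@dataclass
class SimConfig:
    """Study conditions of the synthetic methylome."""

    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 9_000_000, "chr2": 7_000_000}
    )
    base_probs: Tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    cpg_density: float = 0.01  # CpG starts per bp outside islands
    pmd_length_range: Tuple[int, int] = (150_000, 750_000)
    gap_length_range: Tuple[int, int] = (300_000, 1_050_000)
    island_spacing_mean: int = 150_000
    island_length_range: Tuple[int, int] = (600, 2000)
    island_cpg_density: float = 0.08
    dhs_spacing_mean: int = 120_000
    dhs_length_range: Tuple[int, int] = (150, 400)
    repeat_coverage: float = 0.40
    repeat_length_range: Tuple[int, int] = (300, 6000)
    repeat_classes: Tuple[str, ...] = ("LINE", "SINE", "LTR", "DNA", "SVA")
    repeat_class_probs: Tuple[float, ...] = (0.35, 0.35, 0.15, 0.10, 0.05)
    duplication_lengths: Tuple[int, ...] = (25_000, 25_000)
    coverage_mean: float = 30.0
    # ground-truth coefficient structure
    intercept: float = 0.45
    cg_inner: float = 0.26
    cg_band: float = 0.13
    cg_outer: float = 0.025
    band_halfwidth: int = 20
    flank_left: Dict[str, float] = field(
        default_factory=lambda: {
            "TT": -0.10, "AA": -0.08, "TG": 0.07, "CA": 0.05, "CT": -0.06, "AG": -0.04,
        }
    )
    flank_right: Dict[str, float] = field(
        default_factory=lambda: {
            "TT": -0.10, "AA": -0.08, "TG": -0.07, "CA": -0.05, "CT": 0.06, "AG": 0.04,
        }
    )
    periodic_amplitude: float = 0.012
    periodic_period: float = 10.3
    periodic_dinucs: Tuple[str, ...] = ("AA", "TT", "AT", "TA")
    # non-PMD level laws
    outside_scale: float = 0.08  # p = 1 - scale * Beta(1, 4)
    island_scale: float = 0.1  # p = scale * Beta(1, 4)
    dhs_scale: float = 0.6  # p = scale * Beta(2, 6)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


@dataclass
class GroundTruth:
    """Fully specified synthetic dataset: genome, regions, coefficients, p."""

    config: SimConfig
    seed: int
    genome: Genome
    regions: Dict[str, RegionSet]
    coeffs: DinucCoefficients
    cpgs: pd.DataFrame  # chrom, pos, p, region, pmd
    duplications: List[Tuple[str, int, str, int, int]]  # src chrom/start, tgt chrom/start, length
    clamp_fraction: float

    @property
    def pmd_cpgs(self) -> pd.DataFrame:
        return self.cpgs[self.cpgs["region"] == "PMD"].reset_index(drop=True)


def build_coefficients(config: SimConfig) -> DinucCoefficients:
    """Deterministic ground-truth coefficient matrix from the config."""
    matrix = np.zeros((N_BLOCKS, 16))
    centers = BLOCK_CENTERS
    in_band = np.abs(centers) <= config.band_halfwidth
    matrix[:, CG_CODE] = np.where(in_band, config.cg_band, config.cg_outer)
    inner_left, inner_right = N_BLOCKS // 2 - 1, N_BLOCKS // 2
    matrix[inner_left, CG_CODE] = config.cg_inner
    matrix[inner_right, CG_CODE] = config.cg_inner
    for d, s in config.flank_left.items():
        matrix[inner_left, dinuc_code(d)] += s
    for d, s in config.flank_right.items():
        matrix[inner_right, dinuc_code(d)] += s
    phases = {"AA": 0.0, "TT": 0.0, "AT": np.pi, "TA": np.pi}
    for d in config.periodic_dinucs:
        phase = phases.get(d, 0.0)
        matrix[:, dinuc_code(d)] += config.periodic_amplitude * np.cos(
            2 * np.pi * centers / config.periodic_period + phase
        )
    return DinucCoefficients(matrix=matrix, intercept=config.intercept)


def _segment_chromosome(rng, length, pmd_range, gap_range):
    pmds = []
    cursor = int(rng.uniform(*gap_range) * 0.5)
    while cursor < length:
        pmd_len = int(rng.uniform(*pmd_range))
        start, end = cursor, min(cursor + pmd_len, length)
        if end - start >= 50_000:
            pmds.append((start, end))
        cursor = end + int(rng.uniform(*gap_range))
    return pmds


def _poisson_intervals(rng, length, spacing_mean, len_range):
    out = []
    cursor = int(rng.exponential(spacing_mean))
    while cursor < length:
        ln = int(rng.uniform(*len_range))
        out.append((cursor, min(cursor + ln, length)))
        cursor += ln + int(rng.exponential(spacing_mean))
    return out


def make_ground_truth(config: Optional[SimConfig] = None, seed: int = 0) -> GroundTruth:
    """Generate the synthetic dataset; bit-identical for fixed (config, seed)."""
    config = config or SimConfig()
    if not config.chrom_lengths:
        raise ValueError("no chromosomes configured")
    if config.cpg_density <= 0:
        raise ValueError("cpg_density must be positive")
    raw_cg = config.base_probs[1] * config.base_probs[2]
    if config.cpg_density > raw_cg:
        raise ValueError(
            f"cpg_density {config.cpg_density} exceeds the raw CG rate {raw_cg:.4f}"
        )

    rng_regions = stage_rng(seed, "regions")
    rng_seq = stage_rng(seed, "sequence")
    rng_thin = stage_rng(seed, "thinning")
    rng_dup = stage_rng(seed, "duplications")
    rng_levels = stage_rng(seed, "levels")

    pmd_rows, island_rows, dhs_rows, rep_rows, rep_tags = [], [], [], [], []
    for chrom, length in config.chrom_lengths.items():
        for s, e in _segment_chromosome(
            rng_regions, length, config.pmd_length_range, config.gap_length_range
        ):
            pmd_rows.append((chrom, s, e))
        for s, e in _poisson_intervals(
            rng_regions, length, config.island_spacing_mean, config.island_length_range
        ):
            island_rows.append((chrom, s, e))
        for s, e in _poisson_intervals(
            rng_regions, length, config.dhs_spacing_mean, config.dhs_length_range
        ):
            dhs_rows.append((chrom, s, e))
        covered = 0
        target = config.repeat_coverage * length
        lo, hi = config.repeat_length_range
        while covered < target:
            ln = int(np.exp(rng_regions.uniform(np.log(lo), np.log(hi))))
            start = int(rng_regions.uniform(0, max(1, length - ln)))
            rep_rows.append((chrom, start, start + ln))
            rep_tags.append(
                str(rng_regions.choice(config.repeat_classes, p=config.repeat_class_probs))
            )
            covered += ln

    pmds = RegionSet("PMD", pmd_rows)
    islands = RegionSet("CpG_island", island_rows)
    dhs = RegionSet("DHS", dhs_rows)
    repeats = RegionSet("repeat", rep_rows, rep_tags)

    # sequence: iid bases, CpG-enriched islands, CpG thinning outside islands
    chroms: Dict[str, np.ndarray] = {}
    base_cdf = np.cumsum(config.base_probs)
    for chrom, length in config.chrom_lengths.items():
        u = rng_seq.random(length)
        codes = (
            (u > base_cdf[0]).astype(np.uint8)
            + (u > base_cdf[1])
            + (u > base_cdf[2])
        )
        del u
        for c, s, e in islands:
            if c != chrom:
                continue
            cand = np.arange(s, min(e, length) - 1, 2)
            plant = cand[rng_seq.random(len(cand)) < config.island_cpg_density * 2]
            codes[plant] = 1
            codes[plant + 1] = 2
        cg = find_cpgs(codes)
        in_island = islands.overlaps(chrom, cg)
        outside = cg[~in_island]
        density = len(outside) / length
        keep_p = min(1.0, config.cpg_density / max(density, 1e-12))
        drop = outside[rng_thin.random(len(outside)) >= keep_p]
        codes[drop + 1] = rng_thin.choice([0, 3], size=len(drop)).astype(np.uint8)
        chroms[chrom] = codes

    # duplicated segments inside PMDs (identical-context pairs)
    duplications: List[Tuple[str, int, str, int, int]] = []
    avoid = RegionSet(
        "avoid", island_rows + dhs_rows
    ) if island_rows or dhs_rows else None
    big_pmds = [
        (c, s, e) for c, s, e in pmds if e - s >= max(config.duplication_lengths or (0,)) + 20_000
    ]
    for dup_len in config.duplication_lengths:
        for _ in range(200):
            if not big_pmds:
                break
            cs, ss, se = big_pmds[rng_dup.integers(len(big_pmds))]
            ct, ts, te = big_pmds[rng_dup.integers(len(big_pmds))]
            src = int(rng_dup.uniform(ss + FLANK, se - dup_len - FLANK))
            tgt = int(rng_dup.uniform(ts + FLANK, te - dup_len - FLANK))
            if cs == ct and abs(src - tgt) < dup_len + 2 * FLANK:
                continue
            clean = True
            if avoid is not None:
                for c, lo in ((cs, src), (ct, tgt)):
                    pts = np.arange(lo, lo + dup_len, 200)
                    if avoid.overlaps(c, pts).any():
                        clean = False
                        break
            if not clean:
                continue
            chroms[ct][tgt : tgt + dup_len] = chroms[cs][src : src + dup_len]
            duplications.append((cs, src, ct, tgt, dup_len))
            break

    genome = Genome(chroms)
    coeffs = build_coefficients(config)

    # per-CpG true probabilities
    frames = []
    n_clamped = 0
    n_pmd_sites = 0
    for chrom in config.chrom_lengths:
        codes = genome[chrom]
        pos = find_cpgs(codes)
        in_island = islands.overlaps(chrom, pos)
        in_dhs = dhs.overlaps(chrom, pos)
        in_pmd = pmds.overlaps(chrom, pos)
        region = np.full(len(pos), "background", dtype=object)
        region[in_pmd] = "PMD"
        region[in_dhs] = "DHS"
        region[in_island] = "island"
        p = np.empty(len(pos))
        bg = region == "background"
        p[bg] = 1.0 - config.outside_scale * rng_levels.beta(1, 4, size=int(bg.sum()))
        isl = region == "island"
        p[isl] = config.island_scale * rng_levels.beta(1, 4, size=int(isl.sum()))
        dh = region == "DHS"
        p[dh] = config.dhs_scale * rng_levels.beta(2, 6, size=int(dh.sum()))
        pm = region == "PMD"
        if pm.any():
            win, valid = window_codes(codes, pos[pm])
            raw = np.full(int(pm.sum()), config.intercept)
            if valid.any():
                raw[valid] = coeffs.linear_predictor(block_codes(win[valid]))
            clipped = np.clip(raw, 0.0, 1.0)
            n_clamped += int((clipped != raw).sum())
            n_pmd_sites += int(pm.sum())
            p[pm] = clipped
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "p": p, "region": region, "pmd": in_pmd}
            )
        )
    cpg_table = pd.concat(frames, ignore_index=True)
    clamp_fraction = n_clamped / max(n_pmd_sites, 1)

    return GroundTruth(
        config=config,
        seed=seed,
        genome=genome,
        regions={"PMD": pmds, "CpG_island": islands, "DHS": dhs, "repeat": repeats},
        coeffs=coeffs,
        cpgs=cpg_table,
        duplications=duplications,
        clamp_fraction=clamp_fraction,
    )


def simulate_methylome(
    gt: GroundTruth, coverage_mean: Optional[float] = None, seed: int = 0
) -> pd.DataFrame:
    """Sample a per-strand bisulfite call table from the ground truth.

    Per CpG, total coverage follows a Poisson law truncated at >= 1 and is
    split binomially between strands; methylated counts are Binomial(n, p)
    per strand.  The output is valid input to ``combine_strands``.
    """
    coverage_mean = coverage_mean if coverage_mean is not None else gt.config.coverage_mean
    if coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    rng = stage_rng(seed, "methylome")
    n = len(gt.cpgs)
    p = gt.cpgs["p"].to_numpy()
    totals = truncated_poisson(rng, coverage_mean, n)
    n_plus = rng.binomial(totals, 0.5)
    n_minus = totals - n_plus
    meth_plus = rng.binomial(n_plus, p)
    meth_minus = rng.binomial(n_minus, p)
    plus = pd.DataFrame(
        {
            "chrom": gt.cpgs["chrom"],
            "pos": gt.cpgs["pos"],
            "strand": "+",
            "meth": meth_plus,
            "total": n_plus,
        }
    )
    minus = pd.DataFrame(
        {
            "chrom": gt.cpgs["chrom"],
            "pos": gt.cpgs["pos"] + 1,
            "strand": "-",
            "meth": meth_minus,
            "total": n_minus,
        }
    )
    calls = pd.concat([plus, minus], ignore_index=True)
    calls = calls[calls["total"] > 0]
    return calls.sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass
class DiploidSim:
    """Allele-resolved methylation tables with ground-truth allelic effects."""

    ref_table: pd.DataFrame  # chrom, pos, meth, total
    alt_table: pd.DataFrame
    snps: pd.DataFrame  # chrom, pos, ref_base, alt_base, heterozygous
    truth: pd.DataFrame  # per site: snp offset, block, d_R, d_A, p_ref, p_alt, true_dm


def simulate_diploid(
    gt: GroundTruth,
    snp_count: int = 5000,
    window: int = 40,
    coverage_mean: float = 30.0,
    seed: int = 0,
) -> DiploidSim:
    """Place heterozygous SNPs near PMD CpGs and sample allele-resolved counts.

    Each selected CpG receives exactly one SNP within +-``window`` bp (in
    whole blocks, never inside the CpG itself); selected CpGs are spaced so
    windows never contain a second SNP.  The alternative allele's p is the
    reference p shifted by the coefficient difference of the affected
    block, so the true allelic difference dm equals s_d(alt) - s_d(ref)
    exactly; sites whose shifted p would leave the linear range are skipped.
    """
    rng = stage_rng(seed, "diploid")
    bases = "ACGT"
    offsets = np.array(
        [o for o in range(-window, 0)] + [o for o in range(2, window + 2)]
    )
    pmd = gt.pmd_cpgs
    rows = []
    for chrom, sub in pmd.groupby("chrom", sort=True):
        codes = gt.genome[chrom]
        pos = sub["pos"].to_numpy()
        ok = (pos >= FLANK + window) & (pos < len(codes) - FLANK - window - 2)
        pos = pos[ok]
        last = -10**9
        for x in pos:
            if x - last > 2 * window + 4:
                rows.append((chrom, int(x)))
                last = x
    if len(rows) < snp_count:
        raise ValueError(
            f"only {len(rows)} PMD CpGs satisfy the spacing constraint; "
            f"{snp_count} requested"
        )
    pick = rng.choice(len(rows), size=snp_count, replace=False)
    chosen = [rows[i] for i in np.sort(pick)]

    matrix = gt.coeffs.matrix
    records = []
    for chrom, cpos in chosen:
        codes = gt.genome[chrom]
        win, valid = window_codes(codes, np.array([cpos]))
        if not valid[0]:
            continue
        bcodes = block_codes(win)[0]
        p_ref = float(gt.coeffs.linear_predictor(bcodes[None, :])[0])
        if not (0.02 <= p_ref <= 0.98):
            continue
        for _ in range(25):
            off = int(offsets[rng.integers(len(offsets))])
            spos = cpos + off
            ref_code = int(codes[spos])
            if ref_code > 3:
                continue
            alt_code = int(rng.choice([c for c in range(4) if c != ref_code]))
            block = block_of_offset(off)
            d_ref = int(bcodes[block])
            # substitute the SNP base inside its block (left base at b_left)
            b_left = -FLANK + 2 * block if block < N_BLOCKS // 2 else 2 + 2 * (block - N_BLOCKS // 2)
            first = alt_code if off == b_left else int(codes[cpos + b_left])
            second = alt_code if off == b_left + 1 else int(codes[cpos + b_left + 1])
            d_alt = 4 * first + second
            if d_alt == d_ref:
                continue
            dm = float(matrix[block, d_alt] - matrix[block, d_ref])
            p_alt = p_ref + dm
            if not (0.02 <= p_alt <= 0.98):
                continue
            records.append(
                (chrom, cpos, spos, off, block, d_ref, d_alt,
                 bases[ref_code], bases[alt_code], p_ref, p_alt, dm)
            )
            break
    truth = pd.DataFrame(
        records,
        columns=[
            "chrom", "pos", "snp_pos", "offset", "block", "d_R", "d_A",
            "ref_base", "alt_base", "p_ref", "p_alt", "true_dm",
        ],
    )
    n = len(truth)
    cov_r = truncated_poisson(rng, coverage_mean, n)
    cov_a = truncated_poisson(rng, coverage_mean, n)
    meth_r = rng.binomial(cov_r, truth["p_ref"].to_numpy())
    meth_a = rng.binomial(cov_a, truth["p_alt"].to_numpy())
    ref_table = pd.DataFrame(
        {"chrom": truth["chrom"], "pos": truth["pos"], "meth": meth_r, "total": cov_r}
    )
    alt_table = pd.DataFrame(
        {"chrom": truth["chrom"], "pos": truth["pos"], "meth": meth_a, "total": cov_a}
    )
    snps = pd.DataFrame(
        {
            "chrom": truth["chrom"],
            "pos": truth["snp_pos"],
            "ref_base": truth["ref_base"],
            "alt_base": truth["alt_base"],
            "heterozygous": True,
        }
    )
    return DiploidSim(ref_table=ref_table, alt_table=alt_table, snps=snps, truth=truth)


def simulate_mnase_reads(
    gt: GroundTruth,
    reads_per_kb: float = 100.0,
    spacing: float = 180.0,
    spacing_jitter: float = 8.0,
    center_jitter: float = 2.0,
    coupling: float = 0.4,
    footprint: int = 147,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample stranded MNase read 5' ends around regularly spaced dyads.

    Nucleosome dyads are laid down with the configured spacing; each dyad's
    sampling weight decreases with the mean true methylation of CpGs within
    half a footprint (``coupling`` > 0 reproduces the depletion of
    positioned nucleosomes at methylated CpGs; 0 decouples them).  A read's
    recorded coordinate is its 5' end: dyad - 74 on plus, dyad + 74 on
    minus (the largest coordinate of a minus-strand read).
    """
    rng = stage_rng(seed, "mnase")
    half = footprint // 2
    shift = 74
    frames = []
    for chrom, length in gt.config.chrom_lengths.items():
        sub = gt.cpgs[gt.cpgs["chrom"] == chrom]
        cpg_pos = sub["pos"].to_numpy()
        cpg_p = sub["p"].to_numpy()
        p_global = float(cpg_p.mean()) if len(cpg_p) else 0.5
        csum = np.concatenate([[0.0], np.cumsum(cpg_p)])

        dyads = []
        cur = rng.uniform(0, spacing)
        while cur < length:
            dyads.append(int(cur))
            step = spacing + rng.normal(0, spacing_jitter)
            cur += max(step, 20.0)
        dyads = np.asarray(dyads)
        lo = np.searchsorted(cpg_pos, dyads - half)
        hi = np.searchsorted(cpg_pos, dyads + half + 1)
        n_local = hi - lo
        mean_local = np.where(
            n_local > 0, (csum[hi] - csum[lo]) / np.maximum(n_local, 1), p_global
        )
        weights = np.clip(1.0 - coupling * (mean_local - p_global), 0.05, None)
        prob = weights / weights.sum()

        n_reads = int(round(reads_per_kb * length / 1000.0))
        idx = rng.choice(len(dyads), size=n_reads, p=prob)
        centers = dyads[idx]
        if center_jitter > 0:
            centers = centers + np.rint(rng.normal(0, center_jitter, n_reads)).astype(int)
        plus = rng.random(n_reads) < 0.5
        starts = np.where(plus, centers - shift, centers + shift)
        keep = (starts >= 0) & (starts < length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep],
                    "strand": np.where(plus[keep], "+", "-"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
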