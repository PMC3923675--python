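# pmdseq

Sequence determinants of single-CpG methylation in partially methylated
domains (PMDs).

## The problem

PMDs are large genomic domains (hundreds of kilobases) found in
fibroblast, cancer and placental methylomes, covering 20–40% of the
genome. Inside them, single-CpG methylation levels are not uniformly
reduced: they span 0–100% in a seemingly disordered pattern along the
genome, yet that pattern is strongly conserved across cell types. `pmdseq`
implements the analyses that trace this variability back to the local DNA
sequence, for anyone working with whole-genome bisulfite data that
contains PMDs:

- standard single-CpG preprocessing (strand combining; removal of CpGs in
  CpG islands ±100 bp, DNase I hypersensitive sites, SNPs, and low
  coverage; PMD/repeat annotation);
- **identical-context correlation** — the Pearson correlation of
  methylation between pairs of CpGs whose flanking sequence is exactly
  identical, as a function of context length;
- the **positional dinucleotide model** — the core method (below);
- **allele-specific validation** — re-estimating the same dinucleotide
  effects from heterozygous SNPs flanking homozygous CpGs;
- **spatial correlation** — distance-dependent correlation of consecutive
  CpGs and per-PMD cross-sample concordance;
- **MNase profiling** — methylation-stratified composite nucleosome
  profiles and a positional-count regression bounding how much of the
  methylation signal nucleosome positioning could explain.

Because the real datasets are multi-gigabyte public methylomes, the
package ships a first-class synthetic methylome generator
(`pmdseq.simulate`) that produces a genome, region annotations,
ground-truth methylation probabilities, bisulfite counts, allele-resolved
diploid counts and MNase reads with the statistical structure these
analyses assume — so the entire pipeline is testable end-to-end against
known truth.

## The model

For a CpG with cytosine at position 0, the sequence environment ±78 bp
(excluding the CpG itself) is tiled into 78 non-overlapping dinucleotide
blocks: offsets (−78,−77)…(−2,−1) and (+2,+3)…(+78,+79). Each block is a
categorical predictor with 16 states; with one reference state dropped per
block the design has 78 × 15 = 1170 dummy variables. The methylation
level m of a CpG is modeled linearly,

    m = β₀ + Σ_b s_b(d_b) + ε,

where d_b is the dinucleotide observed in block b and s_b(·) its
coefficient vector. The model is fit by ordinary least squares on a
random training subset and evaluated on a disjoint held-out subset
(Pearson r, and R² = 1 − SSE/SST). For display, each block's 16
coefficients (with the dropped state reinserted as 0) are centered to
mean zero; this normalized heatmap is invariant to the choice of dropped
state.

The allelic variant of the model uses CpGs intact on both alleles with
exactly one heterozygous SNP within ±40 bp and ≥10 reads per allele. The
between-allele difference dm = m_alt − m_ref obeys
dm = s_d(alt) − s_d(ref); per block, a singular 16-state regression with
TT fixed to zero (15 free variables, no intercept) recovers the same
coefficients from genetic variation alone.

## Worked example

```python
import pmdseq as pq
from pmdseq import core

gt = pq.make_ground_truth(pq.SimConfig(), seed=1)       # 16 Mb synthetic genome
calls = pq.simulate_methylome(gt, seed=2)               # 30x bisulfite counts
cpgs = core.combine_strands(calls)
cpgs = core.apply_filters(cpgs, gt.regions["CpG_island"],
                          dhs=gt.regions["DHS"], min_cov=10)
cpgs = core.annotate_intervals(cpgs, gt.regions["PMD"], gt.regions["repeat"])
pmd = cpgs[cpgs["pmd"]].reset_index(drop=True)
print(f"{len(pmd)} PMD CpGs after filtering")

design = pq.encode_contexts(pmd, gt.genome)
coeffs, ev = pq.fit_dinuc_model(design, n_train=38_000, n_test=10_000, seed=3)
print(f"held-out r = {ev.r:.2f}, R2 = {ev.r2:.2f} "
      f"({design.n_columns} sequence predictors)")

curve = pq.correlation_curve(pmd, gt.genome, [10, 40, 80], seed=4)
print(curve.to_string(index=False))
```

prints

```
48407 PMD CpGs after filtering
held-out r = 0.73, R2 = 0.54 (1170 sequence predictors)
 length        r  n_pairs
     10 0.280941    12260
     40 0.617851      244
     80 0.618396      244
```

Reading the output: sequence alone predicts about half of the held-out
level variance inside PMDs — close to the attenuation ceiling set by
binomial counting noise at 30x coverage, i.e. essentially all of the
predictable signal, since in this simulation the true methylation
probability is a pure function of sequence. The identical-context curve
rises with context length and then saturates at the same noise ceiling:
short contexts (10 bp) capture only part of the determining sequence,
while 40+ bp contexts (here, pairs from duplicated segments) share their
entire modeled environment. The same experiment on the CpGs *outside*
PMDs yields r ≈ 0: the sequence signal is PMD-specific.

The same steps are available from the shell via the `pmdseq` console
script (`pmdseq simulate`, `pmdseq preprocess`, `pmdseq fit`,
`pmdseq context-corr`, `pmdseq allelic`, `pmdseq spatial`,
`pmdseq concord`, `pmdseq mnase`); each subcommand documents its options
with `--help`.

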