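# Methods

This note documents the models and procedures implemented in `pmdseq`,
the synthetic data they are validated on, the numerical choices, and the
limits of what the passing test suite demonstrates.

## Preprocessing

Per-strand cytosine calls are combined per CpG (plus-strand call at the C,
minus-strand call at the G one base to the right); counts are summed and
the level recomputed from the sums, so a CpG covered on one strand keeps
that strand's counts and the coverage filter applies to the combined
total. Calls whose reference dinucleotide is not CG are rejected with a
warning; negative counts are a hard error. The standard filter set
retains CpGs that lie on configured autosomes, reach coverage ≥ 10, fall
outside CpG islands extended by 100 bp on each side, fall outside DNase I
hypersensitive sites when such an annotation is available, and overlap no
SNP with either base of the dinucleotide (a SNP "overlaps" a CpG when its
position equals either base — the natural reading, fixed here as the
definition). PMDs enter downstream analyses only when ≥ 200 kb long
(configurable); a CpG is "outside PMDs" when it overlaps no retained PMD.
Repeat-class ties from nested annotations resolve to the first
overlapping interval in sorted order. All coordinates are 0-based
half-open internally; VCF positions are converted on read.

## Positional dinucleotide model

The ±78 bp environment of each CpG is tiled into 78 non-overlapping
dinucleotide blocks; blocks tile outward starting adjacent to the CpG
(left blocks at offsets (−78,−77)…(−2,−1); right blocks at
(+2,+3)…(+78,+79), i.e. measured after the G). The tiling phase and
right-flank origin are package constants so the convention is auditable.
Each block is one-hot encoded over its 16 states with one reference state
dropped — by default the lexicographically first dinucleotide observed in
training — giving 1170 predictors plus an intercept. Sites lacking a full
non-N window are skipped with a log entry.

Fitting is ordinary least squares on seeded disjoint random train/test
subsets. The normal equations are solved by SVD with singular values
below 1e−10 of the maximum treated as zero; a dinucleotide state absent
from training therefore yields a coefficient of exactly 0, which is
flagged rather than silently reported. Evaluation is on the held-out set
only: Pearson r between predicted and observed levels, and R² = 1 −
SSE/SST. Both are reported because "accuracy" of such a model can mean
either; R² is the headline number. Predictions are unclipped by default
with an optional clip to [0,1].

For the coefficient heatmap the dropped state re-enters as zero and each
block's 16 values are centered to mean zero. For a full-rank design the
centered matrix is invariant to which state was dropped (verified to
< 1e−8 max difference when refitting with a different reference), so the
reference choice is immaterial.

## Allele-specific validation

Selection keeps CpGs present on both alleles with ≥ 10 reads each and
exactly one heterozygous SNP within the ±40 bp window, where the window
is defined in whole blocks (offsets −40…−1 and +2…+41) so a SNP's block
never straddles the window edge; SNPs hitting the CpG dinucleotide
exclude the site. Each site contributes one equation
dm = s(d_alt) − s(d_ref) for its block. Because adding a constant to all
16 coefficients of a block changes no dm, the system is singular; TT is
fixed to zero as the reference, leaving 15 free variables per block,
solved independently per block with no intercept. States appearing in no
equation are reported missing (NaN), never zero; blocks with fewer than
50 equations (configurable; scaled down from the thousands available in
full methylomes) are skipped. Displayed coefficients are mean-centered
per block exactly as in the sequence model, which removes the gauge
entirely — so consistently relabeling Reference↔Alternative (swapping
dinucleotides and negating dm) leaves the inference invariant, while
negating the responses alone negates every coefficient.

## Context similarity, spatial correlation, MNase

**Identical-context pairs.** The L-bp window centered on a CpG is
L/2 − 1 bases, the CG, then L/2 − 1 bases (the off-by-one is fixed by
this convention; the CpG itself is included but is identical by
construction). CpGs are grouped by exact window identity; windows with N
or truncated at a chromosome edge are dropped; groups of two yield their
pair and larger groups exactly one seeded uniformly random pair, so each
CpG enters at most one pair per length. Reverse-complement contexts are
not merged. Pair order is randomized (seeded) before computing Pearson r
so the estimate is symmetric in expectation. Repeat stratification
assigns a pair to a class only when both CpGs share it (else "mixed";
CpGs outside repeats are "non-repeat") and suppresses classes with fewer
than 100 pairs. With 87 bp reads, a 140 bp centered context leaves
read_len − 1 − (L−2)/2 = 17 bp outside the window for unique mapping —
the practical ceiling on usable context length in real data.

**Spatial correlation.** Distance-dependent correlation uses consecutive
CpGs only, at exact base-pair distances (no pooling) up to 300 bp, with a
minimum pair count per distance; a descriptive detrended periodogram is
available for periodicity inspection, with no significance machinery
attached. Cross-sample concordance restricts both samples to identically
filtered shared CpGs, intersects the two PMD annotations (each connected
component of the intersection is one common domain), and reports one
Pearson r per domain with ≥ 10 shared CpGs.

**MNase.** Read 5′ ends (a minus-strand read's 5′ end is its largest
coordinate) are shifted 74 bp toward the fragment midpoint — half the
147 bp nucleosome footprint — so shifted centers mark dyads. Reads whose
unshifted 5′ end coincides with either base of an interrogated CpG are
excluded before shifting, since MNase cutting preferences at CpGs produce
sharp artifacts in CpG-anchored averages; the accounting (retained =
input − excluded − off-chromosome) is exact. Composite profiles stratify
CpGs into 5 equally spaced level bins (half-open, top bin closed) and
express each bin's mean center count per offset as enrichment over the
grand mean across all CpGs and offsets, which therefore averages to 1.
The positional-count regression uses the raw counts at every offset
within ±200 bp (one nucleosome repeat per side; the window is exposed in
the API) as 401 predictors in an OLS with held-out evaluation, giving an
upper bound on how much methylation the nucleosome signal can explain.

## The synthetic methylome

The generator defines the study conditions under which everything above
is validated. Defaults: a 16 Mb two-chromosome genome with i.i.d. bases
(A/T 0.3, C/G 0.2) thinned to 1 CpG per 100 bp outside islands; PMDs of
150–750 kb alternating with 300 kb–1.05 Mb gaps (≈ 40% PMD fraction,
with occasional sub-200 kb domains to exercise the length filter);
CpG-enriched islands every ~150 kb; DHS every ~120 kb; classed repeat
intervals (LINE/SINE/LTR/DNA/SVA) covering ~40%; and two 25 kb segments
duplicated between PMDs to create identical-context pairs at long L, the
synthetic analogue of the repeat-driven duplications that dominate such
pairs in real genomes.

Inside PMDs the true methylation probability is
p = clamp(β₀ + Σ_b s_b(d_b), 0, 1) with a deterministic coefficient
matrix: CG-state weights of +0.13 in the ±20 bp band (+0.26 at the two
innermost blocks, +0.025 beyond the band), flanking-dinucleotide effects
at the innermost blocks (TT/AA negative on both sides; TG/CA/CT/AG with
opposite signs on the two sides), and a 0.012-amplitude, 10.3 bp-period
cosine on the A/T dinucleotides across all blocks; β₀ = 0.45. These
magnitudes were chosen once to reproduce the qualitative coefficient
architecture (CpG density dominant and methylation-promoting, strongest
immediately at the CpG; antisymmetric flanking effects; weak helical
periodicity) subject to the design rule that clamping stay rare (< 0.1%
observed), which keeps the generator linear and recovery tests exact. A
consequence is Var(p) ≈ 0.015 — the sequence-determined component of
variation — rather than the full 0–100% spread of real PMDs, where
non-sequence variation adds the rest; pushing the linear model to a
uniform p distribution would require routine clamping and was rejected.
Outside PMDs p is drawn i.i.d. in [0.92, 1] (independent of sequence, so
the sequence signal is PMD-specific by construction); island CpGs are
≤ 0.1, DHS CpGs low. Counts are Binomial(n, p) per strand with total
coverage following a Poisson law truncated at ≥ 1 (mean 30), split
binomially between strands. One global seed feeds per-stage substreams
(regions, sequence, thinning, duplications, levels, counts), so any stage
regenerates independently and outputs are bit-identical per
(config, seed).

The diploid simulator places exactly one heterozygous SNP in the ±40 bp
window of selected PMD CpGs, spaced so windows never contain a second
SNP, and recomputes p on each allele's sequence; since a SNP changes
exactly one block, the true dm equals the coefficient difference of that
block exactly. Sites whose shifted p would leave [0.02, 0.98] are skipped
to stay in the linear regime. The MNase simulator lays dyads at ~180 bp
spacing (jittered), weights each dyad by 1 − κ·(local mean p − global
mean p) with κ = 0.4 — so nucleosomes avoid methylated neighborhoods —
and emits stranded 5′ ends at dyad ∓ 74.

### Validation experiments and their sizes

- **Coefficient recovery**: 50k filtered PMD CpGs at 30x, fit on 40k,
  evaluated on 10k. Expected per-coefficient standard error ≈ 0.002–0.005
  (rarest state: CG at ~1% frequency), so the maximum centered error over
  all 1248 cells sits near 0.013, and held-out r lands within a few
  thousandths of the analytic attenuation ceiling
  √(Var(p)/(Var(p)+E[p(1−p)/c])) ≈ 0.75.
- **Allelic concordance**: 5k qualifying sites with per-allele coverage
  400. The coverage was set by a power calculation made before running
  the experiment: per-block estimator variance is roughly
  2·E[p(1−p)]/c per equation spread over ~125 equations/block, and at
  realistic coverage (10–30x) that noise, summed over 640 heatmap cells,
  exceeds the total squared coefficient signal (≈ 0.5), capping the
  expected concordance near 0.6–0.85 regardless of implementation
  correctness. At c = 400 the noise term drops to ≈ 0.05 and the
  concordance between the allelic heatmap and the generator's centered
  matrix is ≈ 0.95. This trades the paper-scale site count (tens of
  thousands) for depth at equal total information, which is the right
  currency for an estimator-consistency check.
- **Attenuation oracles**: identical-context pairs (~300 at L = 80, from
  the duplicated segments) are checked against
  v/(v+E[p(1−p)/c]) within the Fisher 95% CI of the observed r; per-PMD
  cross-replicate correlations are checked as a 95% CI of the mean
  observed-minus-predicted difference across domains (a per-domain
  all-inside-CI test would be incoherent: with thousands of CpGs per
  domain, ~5% of domains must fall outside their own CI by construction).
- **Null contrast**: the model fit on the near-fully-methylated CpGs
  outside PMDs yields a heatmap with max |value| < 0.01 and held-out
  r ≈ 0.
- **MNase ordering**: with the default weak coupling, the positional-count
  regression reaches only r ≈ 0.02–0.03, far below the sequence model's
  ≈ 0.74 on the same CpGs, and the least methylated level bin shows the
  highest near-CpG enrichment.

## What passing tests do and do not show

The generator makes p a *pure* function of the ±78 bp window. Passing
tests therefore demonstrate correct implementation and calibration of the
estimators, not that real methylomes are fully sequence-determined — in
real data the identical-context correlation and the model's R² are
bounded by biology, not only by counting noise. Features deliberately not
emulated: bisulfite conversion errors, mapping bias and mappability,
repeat-sequence composition (repeat intervals are annotation only, so the
SVA hypermethylation seen in real PMDs is absent), MNase sequence bias,
and any non-sequence epigenetic contribution to p. One structural
artifact is worth knowing: because the generator reads sequence in fixed
dinucleotide frames, the short-range correlation of consecutive CpGs is
parity-dependent (a neighboring CpG at odd spacing straddles two blocks
and contributes nothing), so the smooth high correlation of adjacent
CpGs in real data is only partially reproduced; no test relies on it.

## Numerical choices and degenerate inputs

OLS solves use SVD with relative cutoff 1e−10 (exact zeros for absent
states); correlations are undefined (NaN) below 3 pairs or at zero
variance rather than raising; empty filter output is allowed and logged;
intervals are merged per label, with touching intervals considered one
domain; truncated-Poisson sampling resamples zeros exactly rather than
shifting the law. Test and acceptance problem sizes (16 Mb genome, 50k
model sites, 5k allelic sites, 100 MNase reads/kb) were chosen as the
smallest at which the statistical checks above have comfortable power.
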