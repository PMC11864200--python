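# Methods

This note documents the models behind `chromtrace`: what each statistic
assumes, the defaults and why, what the synthetic generator does and does not
emulate, and the numerical choices that were genuinely open.

## Input model and conventions

The central input is a long-format chromatin trace table: one row per decoded
(cell, locus, homolog) with 3D coordinates in µm. Genomic coordinates are
0-based half-open (BED); loci are unstranded fixed-width 20-kb segments and
genomic distance between loci is the absolute midpoint difference. Missing
observations are absent rows, never sentinel values; matrix-level missingness
is NaN. All readers validate invariants (key uniqueness, finite coordinates,
panel membership) and reject rather than coerce.

Defaults shared across the pipeline (in `RunConfig`): 0.75 µm proximity
cutoff, 10-Mb scaling boundary, 1250 decoded loci minimum for nuclear-volume
estimation (600 as the lenient alternative for sparser perturbation data),
1 µm local-density kernel, 10 equal-count radial bins, 20 observations
minimum per pairwise statistic.

## Barcode codebooks

MERFISH barcodes are constant-weight binary codes: n bits, exactly w on-bits
per word, pairwise Hamming distance ≥ 4. Because all words share weight w,
HD(u,v) = 2(w − o) for on-bit overlap o, so HD ≥ 4 is exactly "no two words
share w−1 on-bits", and in general HD ≥ 2d forbids any shared on-bit subset
of size w − d + 1. The builder exploits this: it enumerates all C(n, w)
words, shuffles them, and greedily accepts a word iff none of its forbidden
subsets has been consumed — an O(1) test per candidate — keeping the largest
code over 20 restarts and verifying the pairwise minimum exhaustively before
returning. This construction needs no external covering-design tables and
comfortably exceeds the panel sizes used in practice (typically ~295 words at
22/HW4, ~1,520 at 99/HW3, ~1,390 at 95/HW3, against requirements of 242, 988
and 965).

Assignment to loci optimizes two stated objectives in order: (1) per-bit
load balance, by always assigning the codeword that minimizes the maximum
per-bit usage (ties by total on-bit load, then lexicographically); (2)
within-chromosome spreading, by swap-based local search that lexicographically
improves (minimum same-bit genomic gap, −CV of same-bit gaps) to a fixed
point, multi-started to avoid local optima. Same-bit gaps are measured
between genomically consecutive loci sharing a bit. Decoding maps exact
matches, then unique distance-1 neighbours (valid single-error correction at
HD 4), else fails to null.

## Panel design

Genome-wide loci are 20-kb segments centred on a spacing grid (default
2.5 Mb), clipped to chromosome bounds; chrY is excluded. Probe target
windows are 42-nt; windows containing N are dropped, then filtered to GC
40–60% and nearest-neighbor Tm 57–67 °C, and tiled greedily left-to-right
without overlap; a locus must support 50 windows to be retained. The Tm
reference conditions are 50 mM Na+ and 250 nM oligo (Bio.SeqUtils defaults):
at molar salt every GC-passing 42-mer melts above the band, so the low-salt
reference is the only self-consistent choice for these filter constants.

Super-enhancer calling per cell type: drop peaks with any point within
2.5 kb of a TSS, stitch peaks whose edges are within 12.5 kb, rank stitched
regions by summed signal and apply the ROSE cutoff — on the min-max-scaled
rank/signal curve, the threshold is the signal at the first point whose
forward slope exceeds 1; regions strictly above it are super-enhancers.
Across cell types, super-enhancers within 100 kb (edge distance) are merged
iteratively to a fixed point; merged regions are kept when the mean
member-length/merged-length ratio is ≥ 0.8 and the merged length exceeds
15 kb. Members entering the ratio are the per-cell-type (post-cutoff)
super-enhancer regions.

## Geometry

The nucleus is proxied by the convex hull of all decoded loci (no membrane
stain is assumed), so the volume is only meaningful for well-sampled cells —
hence the 1250-locus filter. A practical caveat quantified in the tests: the
hull of n points sampled uniformly in a ball underestimates the ball volume
by a sampling deficit (~6% at n = 5,000, ~3% at n = 20,000); this is a
property of finite sampling, not of the volume computation, which is exact
for the given points.

Radial positions are normalized directionally: r = |p − c| / |q − c| with c
the hull's *volume* centroid (robust to locus-density asymmetry, unlike the
vertex mean) and q the exit of the ray c→p through the hull, found by a
facet-by-facet parametric test with nearest-intersection tie-breaking.
Values marginally above 1 (localization noise) are clipped and counted; more
than 1% clipped raises a warning. Territory size is the radius of gyration
of a homolog's loci; territory intermixing is the mean fraction of a locus's
k = 10 nearest neighbours (within the cell) on a different chromosome — a
stand-in definition, as no canonical metric exists for imaged territories.

## Distance scaling

Median spatial distance per cis locus pair (same homolog, never mixed) is
fitted as log d vs log g by least squares, separately below and above the
10-Mb boundary (boundary pairs go long; each pair weighted equally, matching
scatterplot-level fitting). A regime needs ≥ 3 distinct genomic distances.
An order-2 log-log polynomial over the full range is stored for plotting.
Exponents are invariant to global spatial rescaling and genomic unit changes.
Activity-binned variants split pairs into equal-count bins of mean locus
activity; one bin reproduces the pooled fit exactly.

## Compartments and megadomains

Per chromosome and cell type: observed proximity = fraction of homolog
copies with both loci decoded and closer than 0.75 µm; expected = mean
observed over pairs in the same log-spaced genomic-distance bin (20 bins per
decade; the qualitative results are insensitive to bin count); O/E = ratio.
NaNs (up to 20% off-diagonal) are imputed by the mean of their diagonal
offset stratum. The cross-correlation matrix is the Pearson correlation
between O/E rows, excluding the diagonal ± 1 entries of both rows to avoid
self-correlation inflation. PCA runs on the column-centred correlation
matrix; among the first three PCs the compartment axis is the one with the
highest |correlation| to CpG density, sign-oriented so the correlation is
positive; label A means positive oriented value. The first PC is *not*
assumed: with a strong planted megadomain the first PC tracks the bipartite
split and the compartment axis is a later PC, exactly as in low-activity
glial cell types. Correlations use raw O/E values; a log transform was
evaluated and recovered planted labels slightly worse.

Segregation score: median distances are first divided by the median of their
genomic-distance bin; the score is median(normalized A–B) over
median(normalized pooled A–A and B–B). Permuted labels give 1.00 ± 0.02;
values above 1 mean segregation. Insulation: IS(i) is the mean O/E over the
w×w square upstream×downstream of position i (w = 5 loci ≈ 12.5 Mb),
normalized as log2(IS / chromosome mean); the IQR over positions summarizes
domain prominence and local minima are boundary candidates. Megadomain
strength is the median inter-boundary distance over the median
intra-boundary distance on *raw* distances (a genomic-distance-normalized
variant exists but is not the default); the boundary is either fixed
externally or taken as the argmin of the normalized insulation profile.

## Local chromatin environment and perturbation analysis

The local A/B density ratio of locus p in one cell is
(Σ_A exp(−d²/2σ²) + ε) / (Σ_B exp(−d²/2σ²) + ε) over *trans-chromosomal*
loci only (cis neighbours would leak the polymer backbone into the
environment measure), with σ = 1 µm and ε = 10⁻³; both homologs are scored
independently, and cells with fewer than 10 decoded trans loci yield NaN.
Per-locus summaries are medians over cells of per-cell ratios. Comparisons
across groups (cell types, genotypes) first divide each group's per-locus
medians by the group's grand mean, so only relative, per-locus differences
survive — mirroring the total-count normalization conventional in
differential expression.

Genes map to the nearest locus whose interval lies within 100 kb of the TSS
(midpoint distance, ties to the lower coordinate); locus activity is the sum
of mapped gene counts, with top/bottom quartiles as high/low classes. DE
scores are Welch t statistics (KO − WT) after scaling every cell to the
median total count; ≥ 2 cells per group are required. Radial-bin analyses
use equal-count bins (counts differ by ≤ 1) with normal-approximation 95%
CIs. The WT-vs-KO comparison reports per-locus deltas of group-normalized
median ratios, per-compartment one-sample t tests against 0 with Bonferroni
correction over the tests performed, per-WT-radial-decile delta profiles,
and the Spearman correlation between delta-ratio deciles and DE scores.

## The synthetic generator

The generator's role is to plant known structure at realistic scales, not to
simulate polymer physics. Per cell and homolog, a chromosome backbone is the
sum of two fractional-Brownian chains: fine chains with exponent `h_short`,
drawn independently per crossover block (loci spanning `g_c` = 10 Mb of
sequence) and centred within the block so their contribution saturates
beyond `g_c`; and a coarse block-level chain with exponent `h_long` carrying
the long-range behaviour. Amplitudes are matched at `g_c` (RMS 3D distance
`contact_distance_um` = 2 µm), which places the scaling crossover there. A
literal superposition of two full-length fBm chains cannot produce the
neuron-like downward bend — the larger exponent would dominate at long range
— which is why the fine component saturates by construction. When
`h_short == h_long` a single full-chromosome fBm is used, making the planted
exponent exact at every scale.

Each chain is rescaled by a *deterministic* factor, computed from the
analytic chain covariance, so its expected radius of gyration equals
`territory_frac` (0.5) times the nucleus radius; territories are then placed
with random rotation and a uniform-in-ball centroid offset (0.6 R), with a
rare uniform safety clamp at 0.95 R. Determinism of the scale factor
matters: a per-realization rescale would couple the factor to the chain's
long-range excursions and bias fitted exponents (and an early per-cell
max-radius rescale also piled all territories at the nucleus centre,
systematically weakening the planted radial signal for mid-chromosome loci).

Radial segregation is planted by warping normalized radius r → r^(1+γ) for
compartment-A loci (inward) and r → r^(1−γ) for B loci (outward); γ ∈ [0, 1).
The warp displacement field (not the chain itself) is smoothed with a
window-3 moving average along the chain, preserving continuity across label
flips without low-pass filtering the backbone's distance statistics.
Megadomains add a ± amp/2 rigid offset along a random direction per homolog
to the two sides of the boundary. The KO genotype mixes each warped
configuration toward its unwarped, label-blind counterpart with weight
`ko_mixing` (0.5 by default) — de-segregation without changing labels.
Detection dropout (p_det = 0.75, a free choice; per-locus efficiencies are
not published) and isotropic 50-nm localization noise are applied last.
Every cell draws from a counter-based stream keyed on (seed, cell index), so
populations are reproducible and order-independent.

CpG density is built with *exact* sample correlation ρ (default 0.8) to the
A indicator by orthogonalizing the noise component first. Expression is
negative binomial (dispersion 2; Poisson in the infinite-dispersion limit)
with log-mean `log(activity) + α·A + ε_gene`; nucleus radius grows as the
cube root of activity so volume tracks total transcription across cell
types. The KO adds a per-gene log shift proportional to the locus's planted
radial position minus the median — interior down, peripheral up — scaled by
a per-cell-type response factor (neuron-like 1, glia-like ~0).

What the generator does **not** emulate: loop extrusion, TADs and loops;
B-B co-clustering at the lamina or nucleoli (the radial warp yields
layering, so B–B pairs on the peripheral shell are laterally distant — real
B compartments also self-associate; planted-label recovery and segregation
scores are therefore conservative); chromatin-state-dependent detection
bias; chromosome-scale confinement effects on scaling beyond the territory
rescaling; sex chromosomes (homolog count is fixed at 2). Passing tests
demonstrate estimator correctness under these planted conditions, not
biological discovery on real data.

## Problem sizes used in the tests

The suite runs at desk scale: populations of 80–500 cells, one or two
chromosomes of 40–100 loci at 2.5-Mb spacing, 5-seed averages for
exponent-recovery checks, and 100-permutation nulls. These sizes were chosen
so that every statistical contract (±0.05 exponent error, ≥ 95% label
recovery, Bonferroni calibration) is comfortably resolved by the planted
effect sizes.

## Known limitations

- The intermixing metric and the O/E binning are stand-in conventions where
  no published definition exists; both are parameterized.
- The insulation normalization (log2 against the chromosome mean) is one of
  several reasonable choices; the IQR contrast is robust to it, absolute
  values are not.
- The ROSE tangent rule is applied to the discrete scaled curve; for tiny
  region counts (< 3) the cutoff degenerates to "keep everything".
- Convex-hull volumes carry the finite-sampling deficit described above;
  comparisons across cell types with similar locus counts are unaffected.
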