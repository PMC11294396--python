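# Methods

This note documents the models and procedures implemented in `srslnc`,
the defaults that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Coordinate conventions

All intervals are 0-based half-open internally. GTF input (1-based
inclusive) is converted at the parse boundary and converted back on
write; BED-style inputs pass through unchanged. Transcript ("spliced")
coordinates run 5′→3′: a genomic segment inside an exon maps through
cumulative exon offsets, and on the minus strand a plus-orientation
segment [a, b) becomes [L−b, L−a) for spliced length L. The projection
is exactly invertible, and the round trip is covered by property tests.

## Repeat qualification and transcript classification

A tandem-repeat record qualifies when its genomic span strictly exceeds
`min_len` (default 200 bp) **and** its (fractional) copy number is at
least `min_copies` (default 3.0). A transcript is SRS-containing when a
*single* qualifying record contributes more than `min_len` bp of exonic
overlap — overlaps are never summed across records, the strictest
defensible reading of "contains a >200-nt simple repeat". Intersection
is with exons by default; a whole-span mode is available because either
reading is plausible for assembled transcript models.

Transcripts whose exonic bases are covered by qualifying repeats at a
fraction ≥ `full_repeat_frac` (default 0.95) are excluded as
repeat-only. The threshold operationalizes "consisting entirely of
repetitious sequences" while tolerating a few non-repeat edge bases from
assembly imprecision; a re-admission flag restores these transcripts to
the SRS-lncRNA set for sensitivity analyses. Biotype is binary: a
transcript is protein-coding iff its annotation says so, everything else
is non-coding; a gene is protein-coding if any of its transcripts is,
SRS-containing if any non-excluded transcript is, and excluded only if
all of its transcripts are.

Repeat strand is ignored throughout (repeat tracks are unstranded).

## Differential expression

Counts are gene-level. Samples are normalized with median-of-ratios size
factors (reference = genes positive in all samples), rescaled to
geometric mean 1. For a contrast B vs A with n_a, n_b replicates:

- group means μ̂_A, μ̂_B of normalized counts, pseudo-count ε = 0.5;
- lfc = log₂((μ̂_B+ε)/(μ̂_A+ε));
- per-gene dispersion by method of moments from the pooled within-group
  variance s² (df = n_a+n_b−2): α̂_g = (s²−m)/m² at grand mean m,
  **shrunk** toward a cross-gene trend with weight df/(df + prior_df),
  prior_df = 20, and floored at the Poisson limit. The trend is the
  ratio estimator Σ(s²_g−m_g)/Σ(m_g²) over expressed genes (m > 5),
  which is nearly unbiased where the per-gene estimate is not;
- delta-method standard error
  se² = [(μ_A+α μ_A²)/(n_A μ_A²) + (μ_B+α μ_B²)/(n_B μ_B²)] / ln²2,
  evaluated at the pseudo-counted means;
- two-sided normal p-value on z = lfc/se, BH-adjusted per contrast.

With three replicates per group the raw per-gene moment estimate has
four degrees of freedom and is far too noisy to plug into a normal-
reference Wald test: in null simulations (NB, dispersion 0.1, mean 100,
3 vs 3) the unshrunk test rejects at ~12% for nominal 5%. Replacing the
normal reference with a Student-t (df 4) calibrates the null but caps
how small p-values can get, collapsing BH-adjusted power. Dispersion
moderation — the same idea DESeq2 uses — solves both at once: measured
type-I error is 4.8–6% and recovery of planted 4-fold changes at base
mean ≥ 50 is 97–99% after BH. The cost is that genuinely outlying
dispersions are pulled toward the trend; with heavy-tailed dispersion
heterogeneity the test will be mildly anti-conservative for the noisiest
genes. An import path for externally computed lfc/q tables (e.g. from
DESeq2 itself) is the long DE-table format consumed by
`shortlist_regulated`.

Shortlisting: genes below 0.1 TPM in the nuclear fraction in **all**
samples are removed first. *Up* requires lfc > 1 and q < 0.05 in at
least one neural (stage × fraction) contrast — "at least one neural
sample" is read as stage × fraction, consistent with per-compartment
candidate counts being reported separately. *Down* requires lfc < −1 and
q < 0.05 at all three neural stages within one fraction and no
significant up-call at any stage in the other fraction.

## Localization ratios

Per stage, raw ratio = mean cytoplasmic TPM / mean nuclear TPM over
replicates, restricted to genes above 0.1 TPM nuclear at that stage
(genes failing the floor are dropped from that stage only, with a
warning). Normalized ratio divides by the stage-specific median raw
ratio of the non-SRS protein-coding group, which makes that group's
median exactly 1 by construction and cancels any global
fraction-specific scaling. Classes are compared per stage with
Kruskal–Wallis, then Dunn's pairwise z-tests on pooled ranks with tie
correction and BH adjustment across the pairs.

## Genome position

Arm coordinate t: 0 at the centromere-interval midpoint, 1 at the
telomere end of the arm containing the anchor; anchor is the locus
midpoint by default (configurable to TSS — the choice is not dictated by
the analysis definition). Features inside the centromere interval get
small t rather than being discarded. p-arms of acrocentric chromosomes
(human 13, 14, 15, 21, 22) are flagged and excluded from pooled
statistics. Distributions use 10 equal t-bins, last bin closed at 1.
Two-sample comparisons use the two-sided Kolmogorov–Smirnov test
(exact p for small samples, asymptotic otherwise), runnable pooled or
per chromosome. Window densities tile fixed windows (default 5 Mb) from
position 0, keeping the last partial window. Divergent pairs are
(−, +) locus pairs whose TSSs face away with gap ≤ 5 kb (this package's
detection rule; the biology fixes the orientation, not the gap), matched
greedily by smallest gap, one pair per locus.

## Motif scanning and multivalency

PWMs are scored as log₂ odds against a 0-order background (uniform by
default; configurable) after adding a pseudocount of 0.1 × background
and renormalizing — FIMO's construction. Scores are scaled by 1000 and
floored to integers; the exact null distribution of the integer window
score under the background is computed by convolution across positions,
and the threshold is the smallest score whose tail probability does not
exceed the requested p-value (default 1e-4). Flooring makes collisions
conservative, so the attained p never exceeds the requested p; the DP
distribution matches full 4^w enumeration exactly (tested to w = 8).

Spliced transcript sequences are scanned on the sense strand only — RBP
motifs bind RNA, so the antisense genomic strand is not a binding
substrate. T and U are equivalent. Overlapping hits are all kept (FIMO
behaviour); a greedy non-overlapping mode exists for sensitivity
analysis. Hits are labelled SRS/non-SRS by their midpoint against the
transcript's SRS intervals (half-open membership). Densities are
hits/kb per region; transcripts lacking either region are excluded from
the paired Wilcoxon signed-rank test (exact for small samples without
ties, normal approximation with Pratt zero-handling otherwise).
Multivalency: an RBP is multivalent on a transcript when it has ≥ 10
hits inside the SRS regions, counted per RBP (aggregating that RBP's
motifs), and the cohort summary is the median number of multivalent
RBPs over transcripts with at least one.

## CLIP-peak overlap null

A motif site counts as peak-overlapped when any of its genomic segments
shares ≥ 1 bp with any peak. The null re-allocates each peak-sized
window to a transcript drawn with probability proportional to spliced
length (uniform-per-transcript mode available) and a uniform start
within it, projecting the window back through the exons (windows may
split across introns). The re-allocation runs `n_iter` = 100 times; the
summary reports the null mean ± SD, z = (observed − mean)/SD, and an
empirical p with the +1 correction, (1 + #{null ≥ obs})/(n_iter + 1),
which can never be 0. Length-proportional allocation keeps expected
per-transcript coverage comparable to real peak placement; the overlap
unit is the site, not basepairs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
scaled to desk size: 3 chromosomes × 2 Mb with centromeres at
0.9–1.1 Mb, ~300 genes (100 non-SRS coding, 50 SRS coding, 80 non-SRS
lnc, 50 SRS-lnc including 6 divergent pairs near the centromere of the
designated chromosome, 20 repeat-only decoys), 180 qualifying repeats
(300–5000 bp, ≥ 3 units, unit lengths 5–171 bp, 1% per-base mutation)
plus 40 non-qualifying decoy repeats, NB counts (dispersion 0.1,
3 replicates, baseline ~200 log-normal) with planted log₂FC ±2 on
subsets of SRS-lncRNAs, class-wise localization medians
(coding 1.0 / 0.6, lnc 0.25 / 0.45 for non-SRS/SRS), motif planting at
12 sites/kb/RBP inside SRS vs 2 outside, and CLIP peaks (20–60 bp) over
60% of the ELAVL-like RBP's planted sites plus 200 background windows.
Six lnc genes are additionally silenced below the nuclear TPM floor to
exercise the abundance filter.

Placements are laid out on a grid of non-overlapping 10-kb cells per
chromosome arm, so planted features never collide and every truth table
is exact by construction. All randomness flows from one master seed
through named substreams (genome / transcriptome / expression / motifs /
peaks), making regeneration byte-identical and stages independently
reproducible. TPM matrices are computed from expected (not sampled)
counts, length-normalized and rescaled to 1e6 per column: localization
structure is then exact while counts carry full sampling noise.

What the benchmark does **not** emulate: genome-scale repeat landscapes
(interspersed repeats, nested or overlapping tandem arrays), isoform
diversity (one transcript per gene; multi-isoform gene aggregation is
unit-tested directly), read-level noise and mapping ambiguity upstream
of the count matrices, dispersion heterogeneity across genes, and
sequence-composition confounders between SRS and non-SRS regions.
Passing tests demonstrate correctness of the implemented rules and
statistics under the stated generative model, not robustness to those
real-data complications.

## Problem sizes and determinism

Default problem sizes (300 genes, 6 Mb genome, 2000-gene calibration
simulations, 100-iteration permutation nulls, 20-seed detection sweeps)
keep the full test suite and the acceptance script in the low minutes on
one CPU while leaving every statistic estimable. End-to-end reruns under
a fixed seed are byte-identical; integer RNG paths are used for all
placements.
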