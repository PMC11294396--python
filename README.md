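# srslnc

Discovery and characterization of **simple-repeated-sequence-containing
long noncoding RNAs (SRS-lncRNAs)** regulated during neuronal
differentiation.

Many lncRNAs harbour head-to-tail tandem repeats — micro-, mini- or
satellite-sized units repeated in tandem. Such simple repeated sequences
(SRSs) can turn a transcript into a multivalent scaffold that recruits
many copies of an RNA-binding protein (RBP), and they shape where the
transcript accumulates in the cell. `srslnc` implements, as a tested and
reusable pipeline, the computational analysis needed to find and
characterize these transcripts in a nuclear/cytoplasmic-fractionated
RNA-seq time course over neuronal differentiation (ESC → NPC → early →
mature neurons):

1. **Catalog** — qualify tandem-repeat records (span > 200 bp, ≥ 3 repeat
   units), intersect them with transcript exons, and classify every
   transcript/gene as SRS-lncRNA, non-SRS lncRNA, SRS-coding, non-SRS
   coding, or excluded (consisting entirely of repeats).
2. **Differential expression** — median-of-ratios normalization, a
   negative-binomial Wald test per gene (log₂FC, moderated dispersion,
   Benjamini–Hochberg FDR), low-abundance filtering (< 0.1 TPM nuclear in
   all samples), and the shortlist rules: *up* = log₂FC > 1 and FDR < 0.05
   in at least one neural stage × fraction; *down* = log₂FC < −1 and
   FDR < 0.05 at **all** neural stages in one compartment, with no
   significant up-regulation in the other.
3. **Genome position** — normalized centromere-to-telomere arm coordinate
   t ∈ [0, 1], 10-bin distributions, Kolmogorov–Smirnov comparisons,
   5-Mb window densities, and detection of divergent (bidirectional)
   SRS-lncRNA pairs sharing a promoter region.
4. **Motifs & multivalency** — FIMO-style PWM scanning of spliced
   transcript sequences with *exact* p-value-calibrated score thresholds
   (dynamic-programming null distribution), SRS vs non-SRS motif density
   with a paired Wilcoxon signed-rank test, and multivalency calls (≥ 10
   sites for one RBP inside the SRS regions).
5. **CLIP overlap** — fraction of predicted motif sites touched by
   HITS-CLIP peaks, against a scrambled-peak permutation null
   (peak-sized windows re-allocated to transcripts, 100 iterations,
   mean ± SD and z-score).
6. **Localization** — cytoplasmic/nuclear TPM ratio per gene and stage,
   normalized by the stage-specific median of the non-SRS protein-coding
   group, compared across classes with Kruskal–Wallis + Dunn post hoc.

Because the original deposited datasets are genome-scale, the package
ships a first-class **synthetic-data generator**: a miniature
multi-chromosome genome with centromeres, implanted qualifying and decoy
repeats, five transcript classes (including fully-repetitive decoys and
divergent SRS-lncRNA pairs), negative-binomial counts with planted fold
changes over 4 stages × 2 fractions, motif-enriched repeat regions, and
CLIP peaks planted over motif sites — all with exact truth tables, so
every stage of the analysis is testable against known ground truth.

## Worked example

```bash
srslnc simulate --out demo --seed 17
srslnc run-all --data demo --out demo_results
```

prints

```
catalog: n_transcripts=300, n_repeats=220, n_qualifying_repeats=180, n_coding_nonsrs=100, n_coding_srs=50, n_lnc_nonsrs=80, n_lnc_srs=50, n_excluded_repeat_only=20
filter: n_genes=300, n_kept=294, n_removed=6
shortlist_up: n_genes=16, n_srs_lnc=15
shortlist_down: n_genes=10, n_srs_lnc=10
position: n_all_srs=180, n_expressed=50, n_neural=15, n_divergent_pairs=6
motifs: n_hits=1678, wilcoxon_p=1.78e-15, n_transcripts_multivalent=33, median_multivalent_rbps=2.0
clip: n_sites=566, observed_fraction=0.678, null_mean=0.130, null_sd=0.0166, z=33.1, empirical_p=0.0099
ratios: n_records=1176, n_tests=24
```

Reading this: all 300 synthetic transcripts are classified into their
planted classes (including the 20 repeat-only exclusions); 6 silent genes
fall below the nuclear 0.1-TPM floor; the up-shortlist recovers the 15
planted up-regulated SRS-lncRNAs (plus one borderline null gene) and the
down-shortlist all 10 planted ones; all 6 planted divergent pairs are
found; motif density in SRS regions is significantly higher than in
non-SRS parts of the same transcripts (paired Wilcoxon p ≈ 2e-15); and
the observed motif/CLIP-peak overlap (68%) sits 33 SD above the
scrambled-peak null (13%). Per-stage ratio tables and Kruskal–Wallis/Dunn
summaries land in `demo_results/ratios.tsv` and `ratio_tests.tsv`.

Every stage is also callable as a library function; see
`srslnc.srs_catalog`, `srslnc.expression_analysis`,
`srslnc.genome_position`, `srslnc.motif_multivalency`,
`srslnc.clip_overlap` and `srslnc.pipeline`.

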