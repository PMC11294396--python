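"""End-to-end orchestration: catalog → filter → DE → shortlists → position →
motifs → CLIP → ratios, with a run report and resolved-config provenance.

Each stage reads and writes plain files (TSV/BED/GTF/FASTA) so stages are
independently runnable and testable; the report is a view re-derivable from
the stage outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import clip_overlap as co
from . import expression_analysis as ea
from . import genome_position as gp
from . import motif_multivalency as mm
from . import srs_catalog as sc
from .io_formats import (
    read_bed_peaks,
    read_chrom_info,
    read_expression_table,
    read_fasta,
    read_gtf,
    read_meme,
    read_repeat_track,
    spliced_sequence,
)


@dataclass
class PipelineConfig:
    """All input paths and thresholds of one reproducible run."""

    gtf: str = "transcripts.gtf"
    repeats: str = "simple_repeats.tsv"
    chrom_info: str = "chrom_info.tsv"
    genome: str = "genome.fa"
    counts: str = "counts.tsv"
    tpm: str = "tpm.tsv"
    motifs: str = "motifs.meme"
    peaks: str = "clip_peaks.bed"
    outdir: str = "results"

    min_len: int = 200
    min_copies: float = 3.0
    full_repeat_frac: float = 0.95
    tpm_threshold: float = 0.1
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    min_sites: int = 10
    motif_pvalue: float = 1e-4
    n_iter: int = 100
    window: int = 5_000_000
    n_bins: int = 10
    max_tss_gap: int = 5000
    clip_rbp: str = "ELAVL3"
    seed: int = 17

    def validate(self) -> None:
        checks = [
            (0 < self.fdr_threshold <= 1, "fdr_threshold must lie in (0, 1]"),
            (0 < self.motif_pvalue < 1, "motif_pvalue must lie in (0, 1)"),
            (0 < self.full_repeat_frac <= 1, "full_repeat_frac must lie in (0, 1]"),
            (self.min_len >= 0, "min_len must be >= 0"),
            (self.min_copies > 0, "min_copies must be positive"),
            (self.tpm_threshold >= 0, "tpm_threshold must be >= 0"),
            (self.lfc_threshold >= 0, "lfc_threshold must be >= 0"),
            (self.min_sites >= 1, "min_sites must be >= 1"),
            (self.n_iter >= 1, "n_iter must be >= 1"),
            (self.n_bins >= 1, "n_bins must be >= 1"),
            (self.window >= 1, "window must be >= 1"),
            (self.max_tss_gap >= 0, "max_tss_gap must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)


@dataclass
class RunReport:
    seed: int
    version: str = ""
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **counts) -> None:
        self.stages[stage] = counts

    def to_dict(self) -> dict:
        return {"seed": self.seed, "version": self.version, "stages": self.stages}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order; outputs land in ``config.outdir``."""
    from . import __version__

    config.validate()
    for name in ("gtf", "repeats", "chrom_info", "genome", "counts", "tpm",
                 "motifs", "peaks"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"input {name!r} missing: {p}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)

    # --- catalog
    transcripts = read_gtf(config.gtf)
    repeats = read_repeat_track(config.repeats)
    chrom_info = read_chrom_info(config.chrom_info)
    qualified = sc.qualify_repeats(repeats, config.min_len, config.min_copies)
    annotations = sc.annotate_srs(transcripts, qualified, min_overlap=config.min_len)
    classification = sc.classify_transcripts(
        transcripts, annotations, config.full_repeat_frac
    )
    classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    by_tid = {t.transcript_id: t for t in transcripts}
    srs_rows = []
    for tid, ann in annotations.items():
        for s, e in ann.srs_tx_intervals:
            for seg in sc.transcript_to_genomic(by_tid[tid], s, e):
                srs_rows.append(
                    {"transcript_id": tid, "tx_start": s, "tx_end": e,
                     "chrom": seg.chrom, "g_start": seg.start, "g_end": seg.end}
                )
    pd.DataFrame(
        srs_rows, columns=["transcript_id", "tx_start", "tx_end", "chrom",
                           "g_start", "g_end"],
    ).to_csv(out / "srs_intervals.tsv", sep="\t", index=False)
    summary = sc.catalog_summary(classification)
    summary.rename("n_transcripts").to_csv(out / "catalog_summary.tsv", sep="\t")
    report.record(
        "catalog",
        n_transcripts=len(transcripts),
        n_repeats=len(repeats),
        n_qualifying_repeats=sum(q.qualifies for q in qualified),
        **{f"n_{k}": int(v) for k, v in summary.items()},
    )
    gene_classes = classification.drop_duplicates("gene_id").set_index("gene_id")["gene_class"]

    # --- abundance filter
    counts_tbl = read_expression_table(config.counts, kind="counts")
    tpm_tbl = read_expression_table(config.tpm, kind="TPM")
    kept = ea.filter_low_abundance(tpm_tbl, config.tpm_threshold)
    report.record(
        "filter",
        n_genes=len(tpm_tbl.genes),
        n_kept=len(kept),
        n_removed=len(tpm_tbl.genes) - len(kept),
    )

    # --- differential expression
    de = ea.de_all_contrasts(counts_tbl, genes=kept)
    de.to_csv(out / "de.tsv", sep="\t", index=False)

    # --- shortlists
    shortlists = {}
    for direction in ("up", "down"):
        short = ea.shortlist_regulated(
            de, direction, config.lfc_threshold, config.fdr_threshold
        )
        rows = [
            {"gene_id": g,
             "gene_class": gene_classes.get(g, "NA"),
             "contrasts": ";".join(f"{s}.{f}" for s, f in prov)}
            for g, prov in sorted(short.provenance.items())
        ]
        df = pd.DataFrame(rows, columns=["gene_id", "gene_class", "contrasts"])
        df.to_csv(out / f"shortlist_{direction}.tsv", sep="\t", index=False)
        shortlists[direction] = df
        report.record(
            f"shortlist_{direction}",
            n_genes=len(df),
            n_srs_lnc=int((df["gene_class"] == "lnc_srs").sum()) if len(df) else 0,
        )

    # --- positional statistics
    qual_records = [q.record for q in qualified if q.qualifies]
    srs_pos = [gp.arm_coordinate(r.interval, chrom_info) for r in qual_records]
    lnc_ids = set(classification.loc[
        classification["transcript_class"] == "lnc_srs", "transcript_id"
    ])
    lnc_srs_loci = [t for t in transcripts if t.transcript_id in lnc_ids]
    expressed = {g for g in kept}
    expressed_loci = [t for t in lnc_srs_loci if t.gene_id in expressed]
    up_genes = set(shortlists["up"]["gene_id"]) if len(shortlists["up"]) else set()
    neural_loci = [t for t in lnc_srs_loci if t.gene_id in up_genes]
    pos_sets = {
        "all_srs": srs_pos,
        "expressed_srs_lnc": [gp.arm_coordinate(t, chrom_info) for t in expressed_loci],
        "neural_srs_lnc": [gp.arm_coordinate(t, chrom_info) for t in neural_loci],
    }
    bin_rows = []
    for name, positions in pos_sets.items():
        counts_b = gp.bin_distribution(positions, config.n_bins)
        for i, c in enumerate(counts_b):
            bin_rows.append({"set": name, "bin": i, "count": int(c)})
    pd.DataFrame(bin_rows).to_csv(out / "position_bins.tsv", sep="\t", index=False)
    ks_rows = []
    for a, b in (("all_srs", "expressed_srs_lnc"), ("expressed_srs_lnc", "neural_srs_lnc")):
        if pos_sets[a] and pos_sets[b]:
            try:
                ks = gp.ks_compare_positions(pos_sets[a], pos_sets[b])
            except ValueError:
                continue
            ks_rows.append({"set_a": a, "set_b": b, "d": ks.d, "p": ks.p,
                            "n_a": ks.n_a, "n_b": ks.n_b})
    pd.DataFrame(
        ks_rows, columns=["set_a", "set_b", "d", "p", "n_a", "n_b"]
    ).to_csv(out / "position_ks.tsv", sep="\t", index=False)
    anchors = [(t.chrom, gp.locus_anchor(t)) for t in lnc_srs_loci]
    gp.window_density(anchors, chrom_info, config.window).to_csv(
        out / "window_density.tsv", sep="\t", index=False
    )
    pairs = gp.find_divergent_pairs(lnc_srs_loci, config.max_tss_gap)
    pd.DataFrame(
        [{"minus_id": p.minus_id, "plus_id": p.plus_id, "tss_gap": p.tss_gap}
         for p in pairs],
        columns=["minus_id", "plus_id", "tss_gap"],
    ).to_csv(out / "divergent_pairs.tsv", sep="\t", index=False)
    report.record(
        "position",
        n_all_srs=len(pos_sets["all_srs"]),
        n_expressed=len(pos_sets["expressed_srs_lnc"]),
        n_neural=len(pos_sets["neural_srs_lnc"]),
        n_divergent_pairs=len(pairs),
    )

    # --- motif scanning on SRS-lncRNA transcripts
    genome = read_fasta(config.genome)
    pwms = read_meme(config.motifs)
    sequences = {t.transcript_id: spliced_sequence(t, genome) for t in lnc_srs_loci}
    hits = mm.scan_transcripts(sequences, pwms, annotations, pvalue=config.motif_pvalue)
    hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    lengths = {t.transcript_id: t.spliced_length for t in lnc_srs_loci}
    density = mm.region_density(hits, annotations, lengths)
    density.to_csv(out / "motif_density.tsv", sep="\t", index=False)
    try:
        w_stat, w_p = mm.paired_density_test(density)
    except ValueError:
        w_stat, w_p = float("nan"), float("nan")
    multival = mm.multivalency_summary(hits, config.min_sites)
    multival.per_transcript.to_csv(out / "multivalency.tsv", sep="\t", index=False)
    n_multi = len(multival.multivalent_sets)
    report.record(
        "motifs",
        n_hits=len(hits),
        wilcoxon_p=float(w_p),
        n_transcripts_multivalent=n_multi,
        median_multivalent_rbps=multival.cohort_median,
    )

    # --- CLIP overlap with scrambled null
    peaks = read_bed_peaks(config.peaks)
    clip_hits = hits[hits["rbp_name"] == config.clip_rbp]
    sites = [
        sc.transcript_to_genomic(by_tid[row.transcript_id], row.start, row.end)
        for row in clip_hits.itertuples()
    ]
    if sites and len(peaks):
        null = co.overlap_null(
            sites, peaks, transcripts, n_iter=config.n_iter, seed=config.seed
        )
        pd.DataFrame({"iteration": np.arange(config.n_iter),
                      "null_fraction": null.null_fractions}).to_csv(
            out / "clip_null.tsv", sep="\t", index=False
        )
        report.record(
            "clip",
            n_sites=null.observed.n_motifs,
            observed_fraction=null.observed.fraction,
            null_mean=null.mean,
            null_sd=null.sd,
            z=null.z,
            empirical_p=null.empirical_p,
        )
    else:
        report.record("clip", n_sites=0)

    # --- localization ratios
    ratios, tests = ea.cyto_nuclear_ratios(
        tpm_tbl, gene_classes, tpm_threshold=config.tpm_threshold, genes=kept
    )
    ratios.to_csv(out / "ratios.tsv", sep="\t", index=False)
    tests.to_csv(out / "ratio_tests.tsv", sep="\t", index=False)
    report.record("ratios", n_records=len(ratios), n_tests=len(tests))

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return report


def compare_shortlists(
    list_a: set[str], list_b: set[str], universe: set[str]
) -> dict:
    """Overlap counts of two gene shortlists plus a two-sided Fisher exact
    test of association within a declared gene universe."""
    outside = (set(list_a) | set(list_b)) - set(universe)
    if outside:
        raise ValueError(f"genes outside universe: {sorted(outside)[:5]}")
    a, b = set(list_a), set(list_b)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(universe) - both - only_a - only_b
    _, p = stats.fisher_exact([[both, only_a], [only_b, neither]], alternative="two-sided")
    return {
        "n_a": len(a), "n_b": len(b), "n_intersection": both,
        "n_a_only": only_a, "n_b_only": only_b, "n_universe": len(universe),
        "fisher_p": float(p),
    }
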