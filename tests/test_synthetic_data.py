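"""Generator guarantees: determinism, construction invariants, planted
truth consistent with the emitted files."""

import numpy as np
import pandas as pd
import pytest

from srslnc.io_formats import spliced_sequence
from srslnc.srs_catalog import annotate_srs, classify_transcripts, qualify_repeats
from srslnc.synthetic_data import (
    SyntheticConfig,
    generate_dataset,
    generate_genome,
    substream,
    transcript_sequences,
)


class TestDeterminism:
    def test_regeneration_is_byte_identical(self, dataset):
        ds2 = generate_dataset(SyntheticConfig())
        assert ds2.genome == dataset.genome
        pd.testing.assert_frame_equal(ds2.counts.values, dataset.counts.values)
        pd.testing.assert_frame_equal(ds2.truth.genes, dataset.truth.genes)
        assert [(p.chrom, p.start, p.end) for p in ds2.peaks.peaks] == \
               [(p.chrom, p.start, p.end) for p in dataset.peaks.peaks]

    def test_different_seed_changes_output(self):
        small = SyntheticConfig(seed=99, n_coding_nonsrs=5, n_coding_srs=3,
                                n_lnc_nonsrs=4, n_lnc_srs=8, n_repeat_only=2,
                                n_divergent_pairs=2, n_up=2, n_down=2, n_silent=1,
                                n_extra_qualifying=4, n_decoy_repeats=4)
        a = generate_dataset(small)
        small2 = SyntheticConfig(**{**small.__dict__, "seed": 100})
        b = generate_dataset(small2)
        assert a.genome != b.genome


class TestGenome:
    def test_repeat_records_match_construction(self, dataset):
        for r in dataset.repeats:
            assert r.span_bp == len(r.interval)
            assert r.copy_number == pytest.approx(r.span_bp / r.period, abs=0.06)

    def test_implanted_locus_recovers_unit_concatenation(self):
        """At 1% per-base mutation the emitted sequence at a repeat locus is
        >=97% identical to unit^k; in clean mode identity is exact."""
        for rate, floor in ((0.0, 1.0), (0.01, 0.97)):
            cfg = SyntheticConfig(mutation_rate=rate)
            plan = generate_genome(cfg)
            for r in plan.repeats[:40]:
                emitted = plan.genome[r.interval.chrom][r.interval.start:r.interval.end]
                reps = -(-r.span_bp // len(r.unit_seq))
                expected = (r.unit_seq * reps)[: r.span_bp]
                ident = np.mean([a == b for a, b in zip(emitted, expected)])
                assert ident >= floor

    def test_qualifying_and_decoy_repeats_both_present(self, dataset):
        q = qualify_repeats(dataset.repeats)
        flags = {x.qualifies for x in q}
        assert flags == {True, False}


class TestTranscriptome:
    def test_srs_transcripts_exceed_overlap_rule_by_construction(self, dataset):
        q = qualify_repeats(dataset.repeats)
        ann = annotate_srs(dataset.transcripts, q)
        truth = dataset.truth.genes
        for tid in truth.loc[truth["true_class"].isin(["lnc_srs", "coding_srs"]),
                             "transcript_id"]:
            assert max(ann[tid].exonic_overlap_bp.values()) > 200

    def test_repeat_only_decoys_are_fully_repetitive(self, dataset):
        q = qualify_repeats(dataset.repeats)
        ann = annotate_srs(dataset.transcripts, q)
        truth = dataset.truth.genes
        for tid in truth.loc[truth["true_class"] == "excluded_repeat_only",
                             "transcript_id"]:
            assert ann[tid].repeat_fraction >= 0.95

    def test_divergent_pairs_convention(self, dataset):
        by_tid = {t.transcript_id: t for t in dataset.transcripts}
        for row in dataset.truth.pairs.itertuples():
            minus, plus = by_tid[row.minus_id], by_tid[row.plus_id]
            assert minus.strand == "-" and plus.strand == "+"
            assert minus.tss < plus.tss
            assert 0 <= row.tss_gap <= dataset.config.promoter_gap
            assert minus.chrom == dataset.config.designated_chrom

    def test_clean_mode_classification_equals_truth(self, dataset):
        q = qualify_repeats(dataset.repeats)
        ann = annotate_srs(dataset.transcripts, q)
        cls = classify_transcripts(dataset.transcripts, ann)
        merged = cls.merge(dataset.truth.genes[["transcript_id", "true_class"]],
                          on="transcript_id")
        assert (merged["transcript_class"] == merged["true_class"]).all()


class TestExpression:
    def test_tpm_columns_sum_to_a_million(self, dataset):
        sums = dataset.tpm.values.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-3)

    def test_planted_fold_change_visible_in_count_means(self, dataset):
        """Group-mean ratio for broadly planted up genes is ~4 at lfc=2."""
        counts = dataset.counts.values
        genes = dataset.truth.genes.set_index("gene_id")
        de = dataset.truth.de
        broad_up = de[(de["true_lfc"] > 0) & (de["stage"] == "NPC")
                      & (de["fraction"] == "nuclear")]["gene_id"].unique()
        broad_up = [g for g in broad_up
                    if (de[(de["gene_id"] == g) & (de["true_lfc"] > 0)].shape[0] == 6)]
        esc = counts.loc[broad_up, ("ESC", "nuclear")].mean(axis=1)
        npc = counts.loc[broad_up, ("NPC", "nuclear")].mean(axis=1)
        ratio = (npc / esc).mean()
        assert 2.5 < ratio < 6.0

    def test_null_genes_have_no_systematic_shift(self, dataset):
        counts = dataset.counts.values
        genes = dataset.truth.genes
        null = genes.loc[genes["de_status"] == "null", "gene_id"]
        esc = counts.loc[null, ("ESC", "nuclear")].mean(axis=1)
        npc = counts.loc[null, ("NPC", "nuclear")].mean(axis=1)
        lfc = np.log2((npc + 0.5) / (esc + 0.5))
        assert abs(lfc.mean()) < 0.15

    def test_silent_genes_below_tpm_floor(self, dataset):
        genes = dataset.truth.genes
        silent = genes.loc[genes["de_status"] == "silent", "gene_id"]
        nuc_cols = [c for c in dataset.tpm.values.columns if c[1] == "nuclear"]
        assert (dataset.tpm.values.loc[silent, nuc_cols] < 0.1).all().all()


class TestMotifPlanting:
    def test_planted_sites_spell_consensus_in_transcript_sequence(self, dataset):
        seqs = transcript_sequences(dataset)
        cons = {p.rbp_name: p.consensus for p in dataset.pwms}
        truth = dataset.truth.motif_sites
        sample = truth.sample(n=200, random_state=0)
        for row in sample.itertuples():
            seq = seqs[row.transcript_id]
            assert seq[row.tx_start:row.tx_end] == cons[row.rbp_name]

    def test_srs_planting_density_ratio(self, dataset):
        truth = dataset.truth.motif_sites
        cfg = dataset.config
        counts = truth.groupby("region").size()
        # SRS regions are much shorter than non-SRS, yet carry comparable
        # site numbers; check the per-kb ratio is near the configured 6x
        genes = dataset.truth.genes.set_index("transcript_id")
        srs_len = dataset.truth.srs.assign(
            ln=lambda d: d["tx_end"] - d["tx_start"]
        ).groupby("transcript_id")["ln"].sum()
        total_len = genes["spliced_length"].sum()
        d_srs = counts["SRS"] / (srs_len.sum() / 1000)
        d_non = counts["nonSRS"] / ((total_len - srs_len.sum()) / 1000)
        assert d_srs / d_non == pytest.approx(
            cfg.srs_motif_density / cfg.nonsrs_motif_density, rel=0.25
        )

    def test_planted_peaks_cover_configured_site_fraction(self, dataset):
        truth_peaks = dataset.truth.peaks
        n_planted = int(truth_peaks["planted"].sum())
        clip_sites = dataset.truth.motif_sites[
            dataset.truth.motif_sites["rbp_name"] == dataset.config.clip_rbp
        ]
        frac = n_planted / len(clip_sites)
        # binomial fluctuation around the configured coverage
        assert frac == pytest.approx(dataset.config.clip_coverage, abs=0.08)

    def test_no_background_peaks_when_disabled(self):
        cfg = SyntheticConfig(n_background_peaks=0, n_coding_nonsrs=5,
                              n_coding_srs=3, n_lnc_nonsrs=4, n_lnc_srs=8,
                              n_repeat_only=2, n_divergent_pairs=2, n_up=2,
                              n_down=2, n_silent=1, n_extra_qualifying=4,
                              n_decoy_repeats=4)
        ds = generate_dataset(cfg)
        assert not (~ds.truth.peaks["planted"]).any()


def test_substreams_are_independent():
    a = substream(17, "genome").integers(0, 1_000_000, 5)
    b = substream(17, "expression").integers(0, 1_000_000, 5)
    assert list(a) != list(b)
    a2 = substream(17, "genome").integers(0, 1_000_000, 5)
    assert list(a) == list(a2)
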