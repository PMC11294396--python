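"""Normalization, NB Wald test, BH, shortlist rules, localization ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from srslnc import expression_analysis as ea
from srslnc.io_formats import ExpressionTable, FRACTIONS, NEURAL_STAGES


class TestSizeFactors:
    def test_median_of_ratios_hand_example(self):
        counts = pd.DataFrame({"s1": [2, 8], "s2": [4, 16]}, index=["g1", "g2"])
        sf = ea.size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), [0.70710678, 1.41421356], rtol=1e-6)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [3, 7, 11], "b": [3, 7, 11]})
        np.testing.assert_allclose(ea.size_factors(counts).to_numpy(), [1, 1])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 3)), columns=list("abc"))
        sf1 = ea.size_factors(counts)
        doubled = counts.copy()
        doubled["c"] = doubled["c"] * 2
        sf2 = ea.size_factors(doubled)
        np.testing.assert_allclose((sf2 / sf1)["c"] / (sf2 / sf1)["a"], 2.0, rtol=1e-9)

    def test_no_always_positive_gene_is_error(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            ea.size_factors(counts)


class TestNbWald:
    def test_identical_groups_are_null(self):
        counts = pd.DataFrame(
            np.tile([[10], [100], [1000]], (1, 6)), columns=list("abcdef")
        )
        res = ea.nb_wald_de(counts, ["a", "b", "c"], ["d", "e", "f"])
        np.testing.assert_allclose(res["lfc"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_zero_dispersion_reduces_to_poisson_se(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(500, (50, 6)), columns=list("abcdef"))
        sf = pd.Series(1.0, index=counts.columns)
        res = ea.nb_wald_de(counts, ["a", "b", "c"], ["d", "e", "f"],
                            sf=sf, dispersion=0.0)
        a = counts[["a", "b", "c"]].mean(axis=1) + 0.5
        b = counts[["d", "e", "f"]].mean(axis=1) + 0.5
        expected = np.sqrt(1 / (3 * a) + 1 / (3 * b)) / np.log(2)
        np.testing.assert_allclose(res["se"], expected, rtol=1e-9)

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], columns=list("abc"))
        with pytest.raises(ValueError, match="replicates"):
            ea.nb_wald_de(counts, ["a"], ["b", "c"])


class TestBh:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            ea.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_degenerate_inputs(self):
        assert ea.bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(ea.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ea.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariance(self, pvals, rnd):
        """BH q-values travel with their p-values under any input order."""
        p = np.array(pvals)
        order = list(range(len(p)))
        rnd.shuffle(order)
        q1 = ea.bh_adjust(p)
        q2 = ea.bh_adjust(p[order])
        np.testing.assert_allclose(q2, q1[order], rtol=1e-12)


def make_tpm(nuclear_rows, cyt_value=5.0):
    """Tiny TPM-like table; one stage isn't needed for the filter test."""
    cols = pd.MultiIndex.from_tuples(
        [("ESC", "nuclear", 1), ("NPC", "nuclear", 1),
         ("N14", "nuclear", 1), ("N50", "nuclear", 1),
         ("ESC", "cytoplasmic", 1)],
        names=["stage", "fraction", "replicate"],
    )
    data = [list(r) + [cyt_value] for r in nuclear_rows]
    df = pd.DataFrame(data, index=[f"g{i}" for i in range(len(nuclear_rows))],
                      columns=cols)
    return ExpressionTable(values=df, kind="counts")


class TestLowAbundanceFilter:
    def test_all_below_threshold_excluded(self):
        tbl = make_tpm([[0.05, 0.08, 0.09, 0.02]])
        assert len(ea.filter_low_abundance(tbl)) == 0

    def test_single_sample_rescues_gene(self):
        tbl = make_tpm([[0.05, 0.2, 0.09, 0.02]])
        assert list(ea.filter_low_abundance(tbl)) == ["g0"]

    def test_exact_threshold_kept(self):
        tbl = make_tpm([[0.1, 0.0, 0.0, 0.0]])
        assert list(ea.filter_low_abundance(tbl)) == ["g0"]

    def test_cytoplasmic_abundance_is_ignored(self):
        tbl = make_tpm([[0.0, 0.0, 0.0, 0.0]], cyt_value=100.0)
        assert len(ea.filter_low_abundance(tbl)) == 0


def de_table(entries):
    """Long DE frame covering all neural contrasts; entries override
    (gene, stage, fraction) -> (lfc, q)."""
    rows = []
    genes = sorted({g for g, _, _ in entries})
    for g in genes:
        for s in NEURAL_STAGES:
            for f in FRACTIONS:
                lfc, q = entries.get((g, s, f), (0.0, 1.0))
                rows.append({"gene_id": g, "stage": s, "fraction": f,
                             "lfc": lfc, "q": q})
    return pd.DataFrame(rows)


class TestShortlist:
    def test_up_single_contrast_with_provenance(self):
        de = de_table({("gA", "NPC", "nuclear"): (1.2, 0.01)})
        short = ea.shortlist_regulated(de, "up")
        assert short.genes == {"gA"}
        assert short.provenance["gA"] == [("NPC", "nuclear")]

    def test_down_requires_all_stages_one_compartment(self):
        entries = {("gB", s, "nuclear"): (-1.5, 0.01) for s in NEURAL_STAGES}
        short = ea.shortlist_regulated(de_table(entries), "down")
        assert short.genes == {"gB"}
        # drop one stage: no longer down
        partial = {k: v for k, v in entries.items() if k[1] != "N50"}
        assert ea.shortlist_regulated(de_table(partial), "down").genes == set()

    def test_down_vetoed_by_up_in_other_compartment(self):
        entries = {("gC", s, "nuclear"): (-1.5, 0.01) for s in NEURAL_STAGES}
        entries[("gC", "N14", "cytoplasmic")] = (1.4, 0.02)
        assert ea.shortlist_regulated(de_table(entries), "down").genes == set()

    def test_missing_contrast_is_error(self):
        de = de_table({("gA", "NPC", "nuclear"): (1.2, 0.01)})
        de = de[~((de["stage"] == "N50") & (de["fraction"] == "cytoplasmic"))]
        with pytest.raises(ValueError, match="missing contrasts"):
            ea.shortlist_regulated(de, "up")

    def test_truth_tables_reproduce_planted_sets(self, dataset):
        """Applying the rules to the generator's true lfc values (oracle q)
        recovers exactly the planted up/down gene sets."""
        truth = dataset.truth.de.copy()
        truth["lfc"] = truth["true_lfc"]
        truth["q"] = np.where(truth["true_lfc"] != 0.0, 0.0, 1.0)
        up = ea.shortlist_regulated(truth, "up").genes
        down = ea.shortlist_regulated(truth, "down").genes
        genes = dataset.truth.genes
        assert up == set(genes.loc[genes["de_status"] == "up", "gene_id"])
        assert down == set(genes.loc[genes["de_status"] == "down", "gene_id"])


class TestRatios:
    def test_kruskal_matches_brute_force_ranks(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=n) for n in (5, 7, 6)]
        h, _ = ea.kruskal_wallis(groups)
        # brute force: H = (12/(N(N+1))) * sum n_i (Rbar_i - (N+1)/2)^2
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n_tot = pooled.size
        pos, hh = 0, 0.0
        for g in groups:
            r = ranks[pos:pos + g.size].mean()
            hh += g.size * (r - (n_tot + 1) / 2) ** 2
            pos += g.size
        hh *= 12 / (n_tot * (n_tot + 1))
        assert h == pytest.approx(hh, rel=1e-9)

    def test_normalizer_median_is_exactly_one(self, dataset, pipeline_run):
        _, _, out = pipeline_run
        ratios = pd.read_csv(out / "ratios.tsv", sep="\t")
        for stage, sub in ratios.groupby("stage"):
            med = sub.loc[sub["gene_class"] == "coding_nonsrs", "norm_ratio"].median()
            assert med == pytest.approx(1.0, abs=1e-12)

    def test_missing_normalizer_class_is_error(self, dataset):
        classes = pd.Series("lnc_srs", index=dataset.tpm.genes)
        with pytest.raises(ValueError, match="normalizer"):
            ea.cyto_nuclear_ratios(dataset.tpm, classes)

    def test_dunn_detects_planted_localization_shift(self, dataset):
        classes = dataset.truth.genes.set_index("gene_id")["true_class"]
        ratios, tests = ea.cyto_nuclear_ratios(dataset.tpm, classes)
        pair = tests[
            (tests["stage"] == "ESC")
            & (tests["group_a"].isin(["lnc_nonsrs", "lnc_srs"]))
            & (tests["group_b"].isin(["lnc_nonsrs", "lnc_srs"]))
        ]
        assert (pair["q"] < 0.05).all()
        med = ratios[ratios["stage"] == "ESC"].groupby("gene_class")["norm_ratio"].median()
        assert med["lnc_nonsrs"] < med["lnc_srs"] < med["coding_srs"] < med["coding_nonsrs"]
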