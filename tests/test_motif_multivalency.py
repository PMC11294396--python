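"""PWM threshold exactness, scanning behaviour, densities, multivalency,
paired testing."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srslnc import motif_multivalency as mm
from srslnc.io_formats import ALPHABET, Pwm
from srslnc.srs_catalog import SrsAnnotation


def random_pwm(rng, width, motif_id="M", rbp="R"):
    mat = rng.dirichlet(np.ones(4), size=width)
    return Pwm(motif_id, rbp, mat)


def enumerate_tail(pwm, cutoff, scale=1000):
    """Independent oracle: exact tail probability over all 4^w sequences."""
    imat = np.floor(mm.log_odds_matrix(pwm) * scale).astype(int)
    total = 0.0
    w = pwm.width
    for letters in product(range(4), repeat=w):
        score = sum(imat[i, l] for i, l in enumerate(letters))
        if score >= cutoff:
            total += 0.25 ** w
    return total


class TestPwmThreshold:
    @pytest.mark.parametrize("width", [2, 3, 5, 8])
    def test_dp_distribution_matches_full_enumeration(self, width):
        rng = np.random.default_rng(width)
        pwm = random_pwm(rng, width)
        imat = np.floor(mm.log_odds_matrix(pwm) * 1000).astype(np.int64)
        dist, offset = mm.exact_score_distribution(imat)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        # compare every attainable score's probability with enumeration
        from collections import defaultdict
        enum = defaultdict(float)
        for letters in product(range(4), repeat=width):
            enum[sum(int(imat[i, l]) for i, l in enumerate(letters))] += 0.25 ** width
        for score, prob in enum.items():
            assert dist[score - offset] == pytest.approx(prob, abs=1e-12)

    def test_attained_p_never_exceeds_requested(self):
        rng = np.random.default_rng(9)
        for width in (3, 6):
            pwm = random_pwm(rng, width)
            for pval in (1e-2, 1e-3, 1e-4):
                th = mm.pwm_threshold(pwm, pvalue=pval)
                assert th.attained_p <= pval
                assert enumerate_tail(pwm, th.cutoff) == pytest.approx(
                    th.attained_p, abs=1e-12
                )

    def test_single_position_certain_letter(self):
        pwm = Pwm("M", "R", np.array([[1.0, 0.0, 0.0, 0.0]]))
        th = mm.pwm_threshold(pwm, pvalue=0.25)
        assert th.attained_p == pytest.approx(0.25)
        hits = mm.scan_sequence("ACGT", pwm, th)
        assert [h[0] for h in hits] == [0]

    def test_log_odds_one_bit_without_pseudocount(self):
        pwm = Pwm("M", "R", np.array([[0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3]]))
        lo = mm.log_odds_matrix(pwm, pseudocount=0.0)
        assert lo[0, 0] == pytest.approx(1.0)

    def test_invalid_pvalue_rejected(self):
        pwm = Pwm("M", "R", np.full((2, 4), 0.25))
        with pytest.raises(ValueError):
            mm.pwm_threshold(pwm, pvalue=0.0)


class TestScanning:
    def test_planted_consensus_found_exactly_once(self):
        rng = np.random.default_rng(4)
        pwm = Pwm("M", "R", np.where(
            np.eye(4)[[3, 2, 3, 3, 3, 2, 3, 3]], 0.85, 0.05
        ))  # consensus TGTTTGTT
        th = mm.pwm_threshold(pwm, pvalue=1e-4)
        flank = "".join(ALPHABET[i] for i in rng.integers(0, 4, 200))
        seq = flank[:100] + "TGTTTGTT" + flank[100:]
        hits = mm.scan_sequence(seq, pwm, th)
        assert (100, ) in {(h[0],) for h in hits}

    def test_shift_equivariance(self):
        """Prepending k background bases shifts every hit start by k."""
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, 5)
        th = mm.pwm_threshold(pwm, pvalue=1e-2)
        seq = "".join(ALPHABET[i] for i in rng.integers(0, 4, 300))
        base = mm.scan_sequence(seq, pwm, th)
        shifted = mm.scan_sequence("ACGTACG" + seq, pwm, th)
        tail = [(s - 7, sc) for s, sc in shifted if s >= 7]
        assert tail == base

    def test_u_and_t_sequences_equivalent(self):
        pwm = Pwm("M", "R", np.where(np.eye(4)[[3, 2]], 0.85, 0.05))
        th = mm.pwm_threshold(pwm, pvalue=0.1)
        assert mm.scan_sequence("ATGA", pwm, th) == mm.scan_sequence("AUGA", pwm, th)

    def test_short_and_empty_sequences(self):
        pwm = Pwm("M", "R", np.full((4, 4), 0.25))
        th = mm.pwm_threshold(pwm, pvalue=0.5)
        assert mm.scan_sequence("", pwm, th) == []
        assert mm.scan_sequence("AC", pwm, th) == []


class TestRegionDensity:
    def annotation(self):
        ann = SrsAnnotation("t", srs_tx_intervals=[(0, 300)])
        return {"t": ann}

    def hits(self, srs_n, non_n, w=7):
        rows = [{"transcript_id": "t", "rbp_name": "R", "start": 10 * i,
                 "end": 10 * i + w, "region": "SRS"} for i in range(srs_n)]
        rows += [{"transcript_id": "t", "rbp_name": "R", "start": 400 + 10 * i,
                  "end": 400 + 10 * i + w, "region": "nonSRS"} for i in range(non_n)]
        return pd.DataFrame(rows)

    def test_density_arithmetic(self):
        df = mm.region_density(self.hits(12, 7), self.annotation(), {"t": 1000})
        row = df.iloc[0]
        assert row["srs_density"] == pytest.approx(40.0)
        assert row["nonsrs_density"] == pytest.approx(10.0)

    def test_boundary_midpoint_is_half_open(self):
        ann = {"t": SrsAnnotation("t", srs_tx_intervals=[(100, 200)])}
        # hit [97,104) has midpoint 100 -> inside SRS (closed start)
        hits = pd.DataFrame([{"transcript_id": "t", "rbp_name": "R",
                              "start": 97, "end": 104, "region": "SRS"}])
        df = mm.region_density(hits, ann, {"t": 1000})
        assert df.iloc[0]["srs_hits"] == 1


class TestMultivalency:
    def test_min_sites_boundary(self):
        counts = pd.DataFrame(
            [{"transcript_id": "t1", "rbp_name": "X", "srs_hits": 12},
             {"transcript_id": "t1", "rbp_name": "Y", "srs_hits": 9}]
        )
        summ = mm.multivalency_from_counts(counts)
        assert summ.multivalent_sets == {"t1": {"X"}}

    def test_planted_sets_recovered_from_truth_counts(self, dataset):
        truth = dataset.truth.motif_sites
        counts = (
            truth[truth["region"] == "SRS"]
            .groupby(["transcript_id", "rbp_name"]).size().rename("srs_hits")
            .reset_index()
        )
        summ = mm.multivalency_from_counts(counts, min_sites=10)
        expected = {
            tid: set(sub.loc[sub["srs_hits"] >= 10, "rbp_name"])
            for tid, sub in counts.groupby("transcript_id")
        }
        expected = {t: s for t, s in expected.items() if s}
        assert summ.multivalent_sets == expected

    def test_cohort_median(self):
        counts = pd.DataFrame(
            [{"transcript_id": f"t{i}", "rbp_name": r, "srs_hits": 11}
             for i, rbps in enumerate([["A"], ["A", "B"], ["A", "B", "C"]])
             for r in rbps]
        )
        assert mm.multivalency_from_counts(counts).cohort_median == 2.0


class TestPairedTest:
    def make_density(self, diffs):
        return pd.DataFrame(
            [{"transcript_id": f"t{i}", "srs_density": 10.0 + d,
              "nonsrs_density": 10.0, "paired_ok": True}
             for i, d in enumerate(diffs)]
        )

    def test_all_positive_six_pairs_exact_p(self):
        _, p = mm.paired_density_test(self.make_density([1, 2, 3, 4, 5, 6]))
        assert p == pytest.approx(1 / 32)

    def test_antisymmetric_pairs_are_null(self):
        _, p = mm.paired_density_test(self.make_density([3, -3, 5, -5, 7, -7]))
        assert p > 0.9

    def test_statistic_matches_brute_force_signed_ranks(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=8)
        stat, _ = mm.paired_density_test(self.make_density(d))
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        w_minus = ranks[d < 0].sum()
        assert stat == pytest.approx(min(w_plus, w_minus))

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mm.paired_density_test(self.make_density([0.0] * 6))
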