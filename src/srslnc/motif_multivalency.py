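"""PWM scanning with exact p-value calibration, and multivalency analysis.

Scanning mirrors FIMO's construction: a log-odds matrix against a 0-order
background with a pseudocount of 0.1 x background, integer-scaled scores,
and a score threshold chosen from the *exact* null score distribution
(computed by dynamic programming over positions) so that the attained tail
probability never exceeds the requested p-value.  Spliced transcript
sequences are scanned on the sense strand only, since RBP motifs bind RNA.

Multivalency — the capacity of a transcript to recruit many copies of one
RBP — is operationalized as >= ``min_sites`` (default 10) predicted sites
for that RBP inside the transcript's SRS regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ALPHABET, Pwm
from .srs_catalog import SrsAnnotation

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T(=U) to 0..3; anything else to -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoreThreshold:
    motif_id: str
    cutoff: int  # integer-scaled log-odds
    attained_p: float
    requested_p: float
    scale: int

    def __post_init__(self):
        if self.attained_p > self.requested_p:
            raise ValueError("attained p exceeds requested p")


def log_odds_matrix(
    pwm: Pwm, background: np.ndarray | None = None, pseudocount: float = 0.1
) -> np.ndarray:
    """log2((p + pc*bg)/(1 + pc) / bg) per position and letter."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    p = (pwm.matrix + pseudocount * bg[None, :]) / (1.0 + pseudocount)
    return np.log2(p / bg[None, :])


def _integer_matrix(lo_matrix: np.ndarray, scale: int) -> np.ndarray:
    # floor keeps integer scores <= true scaled scores, so the integer-score
    # tail is conservative: attained p <= requested p
    return np.floor(lo_matrix * scale).astype(np.int64)


def exact_score_distribution(
    int_matrix: np.ndarray, background: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Exact null distribution of the integer window score under the
    background, by position-wise convolution.

    Returns (probabilities, offset): ``probabilities[s - offset]`` is the
    null probability of integer score ``s``.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    dist = np.array([1.0])
    offset = 0
    for row in int_matrix:
        r_lo, r_hi = int(row.min()), int(row.max())
        new = np.zeros(dist.size + (r_hi - r_lo))
        for letter in range(4):
            shift = int(row[letter]) - r_lo
            new[shift:shift + dist.size] += bg[letter] * dist
        dist = new
        offset += r_lo
    return dist, offset


def pwm_threshold(
    pwm: Pwm,
    background: np.ndarray | None = None,
    pvalue: float = 1e-4,
    scale: int = 1000,
    pseudocount: float = 0.1,
) -> ScoreThreshold:
    """Smallest integer score whose exact null tail probability is <= the
    requested p-value."""
    if not (0.0 < pvalue < 1.0):
        raise ValueError("pvalue must lie in (0, 1)")
    imat = _integer_matrix(log_odds_matrix(pwm, background, pseudocount), scale)
    dist, offset = exact_score_distribution(imat, background)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[i] = P(score >= i + offset)
    ok = np.nonzero(tail <= pvalue)[0]
    if ok.size == 0:
        # even the maximal score is too probable; threshold above the max
        cutoff = offset + dist.size
        attained = 0.0
    else:
        cutoff = int(ok[0]) + offset
        attained = float(tail[ok[0]])
    return ScoreThreshold(
        motif_id=pwm.motif_id, cutoff=cutoff, attained_p=attained,
        requested_p=pvalue, scale=scale,
    )


def scan_sequence(
    seq: str,
    pwm: Pwm,
    threshold: ScoreThreshold,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> list[tuple[int, float]]:
    """All windows scoring at or above the threshold.

    Returns (start, score_bits) tuples; overlapping hits are all kept.
    Windows containing non-ACGT(U) characters never match.
    """
    w = pwm.width
    codes = encode_sequence(seq)
    if codes.size < w:
        return []
    imat = _integer_matrix(log_odds_matrix(pwm, background, pseudocount), threshold.scale)
    n_win = codes.size - w + 1
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(w):
        cj = codes[j:j + n_win]
        valid &= cj >= 0
        scores += imat[j, np.clip(cj, 0, 3)]
    hits = np.nonzero(valid & (scores >= threshold.cutoff))[0]
    return [(int(i), scores[i] / threshold.scale) for i in hits]


def scan_transcripts(
    sequences: dict[str, str],
    pwms: list[Pwm],
    annotations: dict[str, SrsAnnotation] | None = None,
    pvalue: float = 1e-4,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Scan every transcript with every motif; label hits SRS/nonSRS by hit
    midpoint when annotations are given."""
    thresholds = {p.motif_id: pwm_threshold(p, background, pvalue) for p in pwms}
    rows = []
    for tid, seq in sequences.items():
        ann = annotations.get(tid) if annotations else None
        for pwm in pwms:
            for start, score in scan_sequence(seq, pwm, thresholds[pwm.motif_id], background):
                end = start + pwm.width
                region = "nonSRS"
                if ann is not None:
                    mid = (start + end) // 2
                    if any(s <= mid < e for s, e in ann.srs_tx_intervals):
                        region = "SRS"
                rows.append(
                    {"transcript_id": tid, "motif_id": pwm.motif_id,
                     "rbp_name": pwm.rbp_name, "start": start, "end": end,
                     "score": score, "region": region}
                )
    return pd.DataFrame(
        rows, columns=["transcript_id", "motif_id", "rbp_name", "start", "end",
                       "score", "region"],
    )


# ---------------------------------------------------------------------------
# densities and multivalency

def region_density(
    hits: pd.DataFrame,
    annotations: dict[str, SrsAnnotation],
    spliced_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-transcript motif density (hits/kb) in SRS vs non-SRS regions.

    Transcripts without both a positive SRS and non-SRS length are flagged
    ``paired_ok=False`` and left out of paired testing.
    """
    counts = hits.groupby(["transcript_id", "region"]).size() if len(hits) else pd.Series(dtype=int)
    rows = []
    for tid, L in spliced_lengths.items():
        srs_len = annotations[tid].srs_length
        non_len = L - srs_len
        n_srs = int(counts.get((tid, "SRS"), 0))
        n_non = int(counts.get((tid, "nonSRS"), 0))
        rows.append(
            {
                "transcript_id": tid,
                "srs_len": srs_len,
                "nonsrs_len": non_len,
                "srs_hits": n_srs,
                "nonsrs_hits": n_non,
                "srs_density": n_srs / (srs_len / 1000.0) if srs_len else np.nan,
                "nonsrs_density": n_non / (non_len / 1000.0) if non_len else np.nan,
                "paired_ok": srs_len > 0 and non_len > 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MultivalencySummary:
    per_transcript: pd.DataFrame  # transcript_id, rbp_name, srs_hits, multivalent
    min_sites: int

    @property
    def multivalent_sets(self) -> dict[str, set[str]]:
        df = self.per_transcript[self.per_transcript["multivalent"]]
        out: dict[str, set[str]] = {}
        for tid, sub in df.groupby("transcript_id"):
            out[tid] = set(sub["rbp_name"])
        return out

    @property
    def cohort_median(self) -> float:
        """Median number of multivalent RBPs over transcripts having >=1."""
        sizes = [len(s) for s in self.multivalent_sets.values()]
        return float(np.median(sizes)) if sizes else float("nan")


def multivalency_summary(hits: pd.DataFrame, min_sites: int = 10) -> MultivalencySummary:
    """Call RBPs with >= ``min_sites`` SRS-region hits per transcript."""
    if len(hits):
        srs_hits = hits[hits["region"] == "SRS"]
        counts = (
            srs_hits.groupby(["transcript_id", "rbp_name"]).size().rename("srs_hits")
        )
        df = counts.reset_index()
    else:
        df = pd.DataFrame(columns=["transcript_id", "rbp_name", "srs_hits"])
    df["multivalent"] = df["srs_hits"] >= min_sites
    return MultivalencySummary(per_transcript=df, min_sites=min_sites)


def multivalency_from_counts(
    counts: pd.DataFrame, min_sites: int = 10
) -> MultivalencySummary:
    """Multivalency calls from a precomputed (transcript, RBP, srs_hits)
    count table — used to evaluate calling against known site counts."""
    df = counts[["transcript_id", "rbp_name", "srs_hits"]].copy()
    df["multivalent"] = df["srs_hits"] >= min_sites
    return MultivalencySummary(per_transcript=df, min_sites=min_sites)


def paired_density_test(density: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of SRS vs non-SRS density over
    transcripts with both regions present.

    Exact null distribution for small samples without ties; normal
    approximation with Pratt zero handling otherwise.
    """
    sub = density[density["paired_ok"]]
    x = sub["srs_density"].to_numpy(float)
    y = sub["nonsrs_density"].to_numpy(float)
    d = x - y
    if d.size == 0 or np.all(d == 0):
        raise ValueError("degenerate pairing: all density differences are zero")
    res = stats.wilcoxon(x, y, zero_method="pratt", alternative="two-sided",
                         method="auto")
    return float(res.statistic), float(res.pvalue)
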