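"""Chromosome-arm positional statistics.

Positions are expressed on the normalized centromere-to-telomere axis
t ∈ [0, 1]: 0 at the centromere midpoint, 1 at the arm's telomere end.
p-arms of acrocentric chromosomes (human 13, 14, 15, 21, 22, carrying the
rDNA arrays) are flagged and excluded from pooled statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ChromInfo, GenomicInterval, TranscriptModel


@dataclass(frozen=True)
class ArmPosition:
    chrom: str
    arm: str  # "p" | "q"
    t: float
    excluded: bool = False

    def __post_init__(self):
        if not (0.0 <= self.t <= 1.0):
            raise ValueError(f"t={self.t} outside [0, 1]")
        if self.arm not in ("p", "q"):
            raise ValueError(f"invalid arm {self.arm!r}")


@dataclass(frozen=True)
class KsResult:
    d: float
    p: float
    n_a: int
    n_b: int


def locus_anchor(locus, anchor: str = "midpoint") -> float:
    """Anchor coordinate of a locus: interval midpoint (default) or TSS."""
    if isinstance(locus, TranscriptModel):
        if anchor == "tss":
            return float(locus.tss)
        iv = locus.span
    else:
        iv = locus
        if anchor == "tss":
            if iv.strand == "-":
                return float(iv.end - 1)
            return float(iv.start)
    return (iv.start + iv.end) / 2.0


def arm_coordinate(
    locus, chrom_info: ChromInfo, anchor: str = "midpoint"
) -> ArmPosition:
    """Normalized arm position of a locus.

    For anchor position a and centromere midpoint c: p-arm t = (c - a)/c
    when a < c, q-arm t = (a - c)/(length - c) otherwise.  Anchors inside
    the centromere interval get small t on the corresponding arm rather than
    being discarded.
    """
    chrom_name = locus.chrom if not isinstance(locus, GenomicInterval) else locus.chrom
    chrom = chrom_info[chrom_name]
    a = locus_anchor(locus, anchor)
    if not (0 <= a < chrom.length):
        raise ValueError(f"anchor {a} outside [0, {chrom.length}) on {chrom.name}")
    c = chrom.centromere_mid
    if a < c:
        arm, t = "p", (c - a) / c
    else:
        arm, t = "q", (a - c) / (chrom.length - c)
    t = min(max(t, 0.0), 1.0)
    excluded = arm == "p" and chrom.acrocentric_p
    return ArmPosition(chrom=chrom.name, arm=arm, t=t, excluded=excluded)


def bin_distribution(positions: Iterable[ArmPosition], n_bins: int = 10) -> np.ndarray:
    """Counts of non-excluded positions in ``n_bins`` equal t-bins.

    Bin i covers [i/n, (i+1)/n); the last bin is closed at t = 1.
    """
    counts = np.zeros(n_bins, dtype=int)
    for pos in positions:
        if pos.excluded:
            continue
        i = min(int(pos.t * n_bins), n_bins - 1)
        counts[i] += 1
    return counts


def ks_compare(values_a: Sequence[float], values_b: Sequence[float]) -> KsResult:
    """Two-sample two-sided Kolmogorov–Smirnov comparison."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison needs two non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return KsResult(d=float(res.statistic), p=float(res.pvalue), n_a=a.size, n_b=b.size)


def ks_compare_positions(
    positions_a: Iterable[ArmPosition],
    positions_b: Iterable[ArmPosition],
    chrom: str | None = None,
) -> KsResult:
    """KS on arm coordinates, dropping excluded arms; optionally restricted
    to one chromosome (both arms pooled)."""

    def take(ps):
        return [
            p.t for p in ps
            if not p.excluded and (chrom is None or p.chrom == chrom)
        ]

    return ks_compare(take(positions_a), take(positions_b))


def window_density(
    anchors: Iterable[tuple[str, float]],
    chrom_info: ChromInfo,
    window: int = 5_000_000,
) -> pd.DataFrame:
    """Locus counts per fixed-width window tiled from position 0 of every
    chromosome; the last partial window is kept."""
    rows = []
    counts: dict[tuple[str, int], int] = {}
    for chrom, a in anchors:
        counts[(chrom, int(a // window))] = counts.get((chrom, int(a // window)), 0) + 1
    for chrom in chrom_info:
        n_windows = max(1, -(-chrom_info[chrom].length // window))
        for i in range(n_windows):
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": i * window,
                    "window_end": min((i + 1) * window, chrom_info[chrom].length),
                    "count": counts.get((chrom, i), 0),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DivergentPair:
    minus_id: str
    plus_id: str
    tss_gap: int

    def __post_init__(self):
        if self.tss_gap < 0:
            raise ValueError("negative TSS gap")


def find_divergent_pairs(
    loci: Sequence[TranscriptModel], max_tss_gap: int = 5000
) -> list[DivergentPair]:
    """Divergent (bidirectional) locus pairs sharing a promoter region.

    Reports (minus, plus) pairs where the minus-strand TSS lies left of the
    plus-strand TSS with gap <= ``max_tss_gap``; greedy nearest-gap matching
    with each locus in at most one pair.
    """
    candidates = []
    by_chrom: dict[str, tuple[list, list]] = {}
    for t in loci:
        slot = by_chrom.setdefault(t.chrom, ([], []))
        (slot[0] if t.strand == "-" else slot[1]).append(t)
    for minus, plus in by_chrom.values():
        for m in minus:
            for p in plus:
                gap = p.tss - m.tss
                if 0 <= gap <= max_tss_gap:
                    candidates.append((gap, m.transcript_id, p.transcript_id))
    candidates.sort()
    used: set[str] = set()
    pairs = []
    for gap, mid, pid in candidates:
        if mid in used or pid in used:
            continue
        used.update((mid, pid))
        pairs.append(DivergentPair(minus_id=mid, plus_id=pid, tss_gap=gap))
    return pairs
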