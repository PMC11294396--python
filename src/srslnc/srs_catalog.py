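"""Repeat qualification, SRS annotation of transcripts, and class calls.

A simple repeated sequence (SRS) qualifies when its genomic span exceeds
``min_len`` (strictly, default 200 bp) and it comprises at least
``min_copies`` repeat units (default 3, fractional copy numbers allowed).
A transcript is SRS-containing when a single qualifying repeat contributes
more than ``min_len`` bp of exonic overlap; transcripts whose exons are
almost entirely repeat-covered (fraction >= ``full_repeat_frac``) are
excluded as repeat-only.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import GenomicInterval, RepeatRecord, TranscriptModel

CLASSES = ("coding_nonsrs", "coding_srs", "lnc_nonsrs", "lnc_srs", "excluded_repeat_only")


@dataclass(frozen=True)
class QualifiedRepeat:
    record: RepeatRecord
    qualifies: bool


def qualify_repeats(
    repeats: Iterable[RepeatRecord], min_len: int = 200, min_copies: float = 3.0
) -> list[QualifiedRepeat]:
    """Apply the span > ``min_len`` (strict) and copies >= ``min_copies``
    (inclusive) rule to every repeat record."""
    return [
        QualifiedRepeat(
            record=r,
            qualifies=(r.span_bp > min_len) and (r.copy_number >= min_copies),
        )
        for r in repeats
    ]


# ---------------------------------------------------------------------------
# transcript <-> genome coordinate projection

def _plus_tx_segments(
    transcript: TranscriptModel, g_start: int, g_end: int
) -> list[tuple[int, int]]:
    """Project a genomic interval onto plus-orientation transcript coordinates
    (cumulative exon offsets in genome order), clipped to the exons."""
    segs = []
    offset = 0
    for e in transcript.exons:
        lo = max(e.start, g_start)
        hi = min(e.end, g_end)
        if lo < hi:
            segs.append((offset + lo - e.start, offset + hi - e.start))
        offset += len(e)
    return segs


def genomic_to_transcript(
    transcript: TranscriptModel, g_start: int, g_end: int
) -> list[tuple[int, int]]:
    """Map a genomic interval into 5'→3' spliced-transcript coordinates.

    Returns the (possibly empty) sorted list of half-open transcript
    segments covered by the interval's exonic part.  On the minus strand a
    plus-orientation segment [a, b) becomes [L-b, L-a).
    """
    segs = _plus_tx_segments(transcript, g_start, g_end)
    if transcript.strand == "-":
        L = transcript.spliced_length
        segs = [(L - b, L - a) for a, b in segs]
    return sorted(segs)


def transcript_to_genomic(
    transcript: TranscriptModel, t_start: int, t_end: int
) -> list[GenomicInterval]:
    """Inverse projection: a spliced-transcript interval back to genomic
    intervals (split across introns when needed)."""
    L = transcript.spliced_length
    if not (0 <= t_start < t_end <= L):
        raise ValueError(f"transcript interval [{t_start},{t_end}) outside [0,{L})")
    if transcript.strand == "-":
        t_start, t_end = L - t_end, L - t_start
    out = []
    offset = 0
    for e in transcript.exons:
        lo = max(offset, t_start)
        hi = min(offset + len(e), t_end)
        if lo < hi:
            out.append(
                GenomicInterval(
                    transcript.chrom, e.start + lo - offset, e.start + hi - offset,
                    transcript.strand,
                )
            )
        offset += len(e)
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _total_len(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# SRS annotation

@dataclass
class SrsAnnotation:
    """Per-transcript SRS content in spliced-transcript coordinates."""

    transcript_id: str
    srs_tx_intervals: list[tuple[int, int]] = field(default_factory=list)
    source_repeat_ids: list[str] = field(default_factory=list)
    exonic_overlap_bp: dict[str, int] = field(default_factory=dict)
    repeat_fraction: float = 0.0

    @property
    def has_srs(self) -> bool:
        return bool(self.srs_tx_intervals)

    @property
    def srs_length(self) -> int:
        return _total_len(self.srs_tx_intervals)


class _ChromRepeatIndex:
    """Sorted-start index over repeat records of one chromosome."""

    def __init__(self, repeats: Sequence[RepeatRecord]):
        self.repeats = sorted(repeats, key=lambda r: r.interval.start)
        self.starts = [r.interval.start for r in self.repeats]
        self.max_len = max((r.span_bp for r in self.repeats), default=0)

    def overlapping(self, start: int, end: int) -> list[RepeatRecord]:
        lo = bisect_left(self.starts, start - self.max_len)
        out = []
        for r in self.repeats[lo:]:
            if r.interval.start >= end:
                break
            if r.interval.end > start:
                out.append(r)
        return out


def annotate_srs(
    transcripts: Sequence[TranscriptModel],
    qualified: Sequence[QualifiedRepeat],
    min_overlap: int = 200,
    use_exons: bool = True,
) -> dict[str, SrsAnnotation]:
    """Compute exonic repeat overlap and SRS transcript intervals.

    A repeat qualifies the transcript when its exonic overlap exceeds
    ``min_overlap`` bp on its own (overlaps are never summed across repeat
    records).  ``repeat_fraction`` is the fraction of the spliced length
    covered by the union of *all* track-qualified repeats.  With
    ``use_exons=False`` qualification uses overlap with the whole genomic
    span instead (the projection into transcript coordinates stays exonic).
    """
    by_chrom: dict[str, list[RepeatRecord]] = {}
    for q in qualified:
        if q.qualifies:
            by_chrom.setdefault(q.record.interval.chrom, []).append(q.record)
    index = {c: _ChromRepeatIndex(rs) for c, rs in by_chrom.items()}

    out: dict[str, SrsAnnotation] = {}
    for t in transcripts:
        ann = SrsAnnotation(transcript_id=t.transcript_id)
        idx = index.get(t.chrom)
        if idx is not None:
            span = t.span
            cover_segs: list[tuple[int, int]] = []
            tx_segs: list[tuple[int, int]] = []
            for r in idx.overlapping(span.start, span.end):
                plus_segs = _plus_tx_segments(t, r.interval.start, r.interval.end)
                exonic_bp = _total_len(plus_segs)
                if exonic_bp == 0 and use_exons:
                    continue
                rid = r.repeat_id or f"{r.interval.chrom}:{r.interval.start}"
                ann.exonic_overlap_bp[rid] = exonic_bp
                cover_segs.extend(plus_segs)
                qual_bp = exonic_bp if use_exons else span.overlap_bp(r.interval)
                if qual_bp > min_overlap:
                    ann.source_repeat_ids.append(rid)
                    tx_segs.extend(
                        genomic_to_transcript(t, r.interval.start, r.interval.end)
                    )
            L = t.spliced_length
            ann.repeat_fraction = _total_len(merge_intervals(cover_segs)) / L
            ann.srs_tx_intervals = merge_intervals(tx_segs)
        out[t.transcript_id] = ann
    return out


# ---------------------------------------------------------------------------
# classification

def classify_transcripts(
    transcripts: Sequence[TranscriptModel],
    annotations: dict[str, SrsAnnotation],
    full_repeat_frac: float = 0.95,
) -> pd.DataFrame:
    """Assign each transcript and gene to one of the five classes.

    Transcript: ``excluded_repeat_only`` when the exonic repeat fraction
    reaches ``full_repeat_frac``; otherwise {coding|lnc} × {srs|nonsrs}.
    Gene: excluded only if every transcript is excluded; coding if any
    transcript is coding; srs if any non-excluded transcript carries SRS.
    """
    rows = []
    for t in transcripts:
        ann = annotations[t.transcript_id]
        if ann.repeat_fraction >= full_repeat_frac:
            cls = "excluded_repeat_only"
        else:
            kind = "coding" if t.biotype == "protein_coding" else "lnc"
            srs = "srs" if ann.has_srs else "nonsrs"
            cls = f"{kind}_{srs}"
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "biotype": t.biotype,
                "repeat_fraction": ann.repeat_fraction,
                "srs_length": ann.srs_length,
                "transcript_class": cls,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["transcript_id", "gene_id", "biotype", "repeat_fraction",
                     "srs_length", "transcript_class", "gene_class"]
        )
        return df

    def gene_call(sub: pd.DataFrame) -> str:
        kept = sub[sub["transcript_class"] != "excluded_repeat_only"]
        if kept.empty:
            return "excluded_repeat_only"
        coding = (sub["biotype"] == "protein_coding").any()
        srs = kept["transcript_class"].isin(["coding_srs", "lnc_srs"]).any()
        return f"{'coding' if coding else 'lnc'}_{'srs' if srs else 'nonsrs'}"

    gene_classes = df.groupby("gene_id", sort=False).apply(gene_call, include_groups=False)
    df["gene_class"] = df["gene_id"].map(gene_classes)
    return df


def catalog_summary(
    classification: pd.DataFrame, readmit_repeat_only: bool = False
) -> pd.Series:
    """Per-class transcript counts.

    With ``readmit_repeat_only=True`` non-coding repeat-only transcripts are
    counted into the SRS-lncRNA class instead of the excluded set (the
    sensitivity variant that keeps fully repetitive transcripts).
    """
    cls = classification["transcript_class"].copy()
    if readmit_repeat_only and len(classification):
        mask = (cls == "excluded_repeat_only") & (
            classification["biotype"] != "protein_coding"
        )
        cls[mask] = "lnc_srs"
    counts = cls.value_counts()
    return counts.reindex(CLASSES, fill_value=0)
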