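"""Readers, writers and domain types for the formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals.
GTF (1-based inclusive) is converted at the parse/write boundary; BED-style
inputs (repeat track, peaks) are already 0-based half-open and pass through
unchanged.  A single convention everywhere removes off-by-one drift between
annotation and interval tracks.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STAGES = ("ESC", "NPC", "N14", "N50")
NEURAL_STAGES = ("NPC", "N14", "N50")
FRACTIONS = ("nuclear", "cytoplasmic")

#: human acrocentric chromosomes whose p-arms carry the rDNA arrays
ACROCENTRIC_DEFAULT = frozenset({"chr13", "chr14", "chr15", "chr21", "chr22"})

ALPHABET = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Basepairs shared with ``other`` (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """Exon-structured transcript with a binary coding/non-coding biotype."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str  # "protein_coding" | "non_coding"

    def __post_init__(self):
        if self.biotype not in ("protein_coding", "non_coding"):
            raise ValueError(f"invalid biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for e in self.exons:
            if e.chrom != self.chrom:
                raise FormatError(
                    f"{self.transcript_id}: exon on {e.chrom}, transcript on {self.chrom}"
                )
            if e.strand != self.strand:
                raise FormatError(f"{self.transcript_id}: exons on mixed strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base for '+', rightmost-1 for '-'."""
        if self.strand == "-":
            return self.exons[-1].end - 1
        return self.exons[0].start


@dataclass(frozen=True)
class RepeatRecord:
    """Tandem-repeat interval with unit period and fractional copy number."""

    interval: GenomicInterval
    period: float
    copy_number: float
    unit_seq: str | None = None
    repeat_id: str | None = None

    def __post_init__(self):
        if self.period < 1:
            raise ValueError("period < 1")
        if self.copy_number <= 0:
            raise ValueError("copy_number <= 0")

    @property
    def span_bp(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: GenomicInterval
    acrocentric_p: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.centromere.chrom != self.name:
            raise ValueError("centromere on wrong chromosome")
        if self.centromere.end > self.length:
            raise ValueError(f"{self.name}: centromere beyond chromosome end")

    @property
    def centromere_mid(self) -> float:
        return (self.centromere.start + self.centromere.end) / 2.0


class ChromInfo(Mapping):
    """Per-chromosome length + centromere interval + acrocentric flag."""

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self._chroms = {c.name: c for c in chromosomes}

    def __getitem__(self, name: str) -> Chromosome:
        return self._chroms[name]

    def __iter__(self):
        return iter(self._chroms)

    def __len__(self):
        return len(self._chroms)


@dataclass
class ExpressionTable:
    """Genes × samples matrix of counts or TPM.

    Columns are a MultiIndex (stage, fraction, replicate).  For TPM input
    every column must sum to 1e6 within 0.1%.
    """

    values: pd.DataFrame
    kind: str  # "counts" | "TPM"

    def __post_init__(self):
        if self.kind not in ("counts", "TPM"):
            raise ValueError(f"invalid kind {self.kind!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dups[:5]))}")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("negative expression value")
        if self.kind == "TPM":
            sums = self.values.sum(axis=0)
            off = sums[(sums - 1e6).abs() > 1e3]
            if len(off):
                warnings.warn(
                    f"{len(off)} TPM column(s) deviate from 1e6 by >0.1%",
                    stacklevel=2,
                )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset(self, stage=None, fraction=None) -> pd.DataFrame:
        df = self.values
        idx = [slice(None)] * 3
        if stage is not None:
            idx[0] = stage
        if fraction is not None:
            idx[1] = fraction
        return df.loc[:, tuple(idx)]


@dataclass
class Pwm:
    """Position probability matrix over ACGT (U folded into T)."""

    motif_id: str
    rbp_name: str
    matrix: np.ndarray  # shape (w, 4), rows sum to 1

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must have shape (w, 4)")
        if (self.matrix < 0).any():
            raise ValueError("negative PWM entry")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-3:
            raise FormatError(f"{self.motif_id}: PWM rows do not sum to 1")
        self.matrix = self.matrix / sums[:, None]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class PeakSet:
    """CLIP peak intervals with optional height scores."""

    peaks: list[GenomicInterval]
    heights: list[float] | None = None

    def __post_init__(self):
        if self.heights is not None:
            if len(self.heights) != len(self.peaks):
                raise ValueError("heights length mismatch")
            if any(h < 0 for h in self.heights):
                raise ValueError("negative peak height")

    def __len__(self):
        return len(self.peaks)


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(s: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(s))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into :class:`TranscriptModel` s.

    Coordinates are converted from GTF 1-based inclusive to internal 0-based
    half-open.  A transcript is ``protein_coding`` iff a
    ``transcript_type``/``transcript_biotype`` attribute equals
    "protein_coding"; every other value collapses to ``non_coding``.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"{path}:{lineno}: invalid GTF coordinates")
            attr = _parse_gtf_attributes(attrs)
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise FormatError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id attribute"
                )
            tid = attr["transcript_id"]
            biotype_raw = attr.get("transcript_type", attr.get("transcript_biotype", ""))
            biotype = "protein_coding" if biotype_raw == "protein_coding" else "non_coding"
            rec = meta.setdefault(
                tid,
                {"gene_id": attr["gene_id"], "chrom": chrom, "strand": strand,
                 "biotype": biotype},
            )
            if rec["strand"] != strand:
                raise FormatError(
                    f"{path}:{lineno}: transcript {tid} has exons on mixed strands"
                )
            if biotype == "protein_coding":
                rec["biotype"] = "protein_coding"
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start_i - 1, end_i, strand)
            )
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=meta[tid]["gene_id"],
            chrom=meta[tid]["chrom"],
            strand=meta[tid]["strand"],
            exons=exs,
            biotype=meta[tid]["biotype"],
        )
        for tid, exs in exons.items()
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write exon features; internal 0-based half-open back to 1-based GTF."""
    with open(path, "w") as fh:
        for t in transcripts:
            btype = t.biotype if t.biotype == "protein_coding" else "lncRNA"
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_type "{btype}";'
                )
                fh.write(
                    f"{t.chrom}\tsrslnc\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# UCSC simpleRepeat track

def read_repeat_track(path: str | Path) -> list[RepeatRecord]:
    """Read a UCSC simpleRepeat-style tab dump (or the minimal 5-column
    dialect chrom/start/end/period/copyNum).

    Coordinates are BED-convention 0-based half-open and pass through
    unchanged.  Rows with empty intervals or non-positive copy numbers are
    rejected with a warning; no length/copy filtering happens here.
    """
    records: list[RepeatRecord] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            # full UCSC dump has a leading bin column and 17 fields total
            if len(f) >= 17:
                chrom, start, end = f[1], f[2], f[3]
                period, copy_num = f[5], f[6]
                unit = f[16] if len(f) > 16 else None
            elif len(f) >= 5:
                chrom, start, end, period, copy_num = f[:5]
                unit = f[5] if len(f) > 5 else None
            else:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns")
            start_i, end_i = int(start), int(end)
            period_f, copy_f = float(period), float(copy_num)
            if end_i <= start_i or copy_f <= 0 or period_f < 1:
                n_rejected += 1
                continue
            records.append(
                RepeatRecord(
                    interval=GenomicInterval(chrom, start_i, end_i),
                    period=period_f,
                    copy_number=copy_f,
                    unit_seq=unit,
                    repeat_id=f"rep{len(records)}",
                )
            )
    if n_rejected:
        warnings.warn(f"{n_rejected} malformed repeat row(s) rejected", stacklevel=2)
    return records


def write_repeat_track(repeats: Sequence[RepeatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            unit = r.unit_seq or ""
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.period:g}\t{r.copy_number:g}\t{unit}\n"
            )


# ---------------------------------------------------------------------------
# Chromosome info

def read_chrom_info(
    path: str | Path, acrocentric: frozenset[str] | set[str] = ACROCENTRIC_DEFAULT
) -> ChromInfo:
    """Read chromosome lengths and centromeres.

    Accepts either a 4-column TSV (chrom, length, cen_start, cen_end) or a
    cytoband-style file whose centromere is the union of "acen" bands (with a
    companion length implied by the maximal band end).
    """
    with open(path) as fh:
        lines = [l.rstrip("\n").split("\t") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty chromosome info")
    is_cytoband = len(lines[0]) >= 5 and lines[0][4] in (
        "acen", "gneg", "gpos25", "gpos50", "gpos75", "gpos100", "gvar", "stalk"
    )
    chroms: list[Chromosome] = []
    if is_cytoband:
        by_chrom: dict[str, list[list[str]]] = {}
        for f in lines:
            by_chrom.setdefault(f[0], []).append(f)
        for name, rows in by_chrom.items():
            length = max(int(r[2]) for r in rows)
            acen = [r for r in rows if r[4] == "acen"]
            if not acen:
                raise FormatError(f"{name}: no acen (centromere) bands")
            cen_start = min(int(r[1]) for r in acen)
            cen_end = max(int(r[2]) for r in acen)
            chroms.append(
                Chromosome(name, length, GenomicInterval(name, cen_start, cen_end),
                           acrocentric_p=name in acrocentric)
            )
    else:
        for f in lines:
            if len(f) < 4:
                raise FormatError(f"{path}: expected 4-column chrom info TSV")
            name, length, cs, ce = f[0], int(f[1]), int(f[2]), int(f[3])
            chroms.append(
                Chromosome(name, length, GenomicInterval(name, cs, ce),
                           acrocentric_p=name in acrocentric)
            )
    return ChromInfo(chroms)


def write_chrom_info(info: ChromInfo, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in info.values():
            fh.write(f"{c.name}\t{c.length}\t{c.centromere.start}\t{c.centromere.end}\n")


# ---------------------------------------------------------------------------
# Expression matrices

_SAMPLE_RE = re.compile(r"^([A-Za-z0-9]+)\.(nuclear|cytoplasmic)\.r(\d+)$")


def parse_sample_name(name: str) -> tuple[str, str, int]:
    m = _SAMPLE_RE.match(name)
    if not m:
        raise FormatError(
            f"sample name {name!r} does not match STAGE.FRACTION.rN"
        )
    stage, fraction, rep = m.group(1), m.group(2), int(m.group(3))
    if stage not in STAGES:
        raise FormatError(f"unknown stage {stage!r} in sample {name!r}")
    return stage, fraction, rep


def read_expression_table(path: str | Path, kind: str) -> ExpressionTable:
    """Read a TSV matrix whose header encodes stage/fraction/replicate
    (e.g. ``NPC.nuclear.r1``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [parse_sample_name(c) for c in df.columns]
    df.columns = pd.MultiIndex.from_tuples(cols, names=["stage", "fraction", "replicate"])
    return ExpressionTable(values=df, kind=kind)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    df = table.values.copy()
    df.columns = [f"{s}.{f}.r{r}" for s, f, r in df.columns]
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# MEME minimal motif format

def read_meme(path: str | Path) -> list[Pwm]:
    """Read MEME minimal-format motifs.  ``U`` and ``T`` alphabets are
    treated identically; probability rows off 1 by more than 1e-3 are an
    error, smaller drift is renormalized."""
    pwms: list[Pwm] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            rbp = parts[2] if len(parts) > 2 else motif_id
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability"):
                if lines[j].strip().startswith("MOTIF"):
                    raise FormatError(f"{motif_id}: missing letter-probability matrix")
                j += 1
            if j == len(lines):
                raise FormatError(f"{motif_id}: missing letter-probability matrix")
            header = lines[j].strip()
            m = re.search(r"w\s*=\s*(\d+)", header)
            declared_w = int(m.group(1)) if m else None
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in s.split()])
                j += 1
            mat = np.array(rows, dtype=float)
            if declared_w is not None and mat.shape[0] != declared_w:
                raise FormatError(
                    f"{motif_id}: declared w={declared_w} but {mat.shape[0]} matrix rows"
                )
            pwms.append(Pwm(motif_id=motif_id, rbp_name=rbp, matrix=mat))
            i = j
        else:
            i += 1
    return pwms


def write_meme(pwms: Sequence[Pwm], path: str | Path, alphabet: str = "ACGU") -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + alphabet + "\n\n")
        fh.write("Background letter frequencies\n")
        letters = " ".join(f"{c} 0.25000" for c in alphabet)
        fh.write(letters + "\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id} {p.rbp_name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in p.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED peaks

def read_bed_peaks(path: str | Path) -> PeakSet:
    """Read a BED3+ peak file; optional 5th column is a height score."""
    peaks: list[GenomicInterval] = []
    heights: list[float] = []
    have_heights = False
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                n_rejected += 1
                continue
            peaks.append(GenomicInterval(chrom, start, end))
            if len(f) >= 5:
                have_heights = True
                heights.append(float(f[4]))
            else:
                heights.append(0.0)
    if n_rejected:
        warnings.warn(f"{n_rejected} empty peak interval(s) rejected", stacklevel=2)
    return PeakSet(peaks=peaks, heights=heights if have_heights else None)


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                cols.append(names[i] if names is not None else ".")
            if scores is not None or iv.strand != ".":
                cols.append(f"{scores[i]:g}" if scores is not None else "0")
            if iv.strand != ".":
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def spliced_sequence(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """5'→3' spliced transcript sequence from a genome dict."""
    chrom_seq = genome[transcript.chrom]
    s = "".join(chrom_seq[e.start:e.end] for e in transcript.exons)
    return revcomp(s) if transcript.strand == "-" else s
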