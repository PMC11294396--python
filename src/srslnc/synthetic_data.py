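"""Synthetic miniature genome with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a few megabase-scale chromosomes with centromere intervals;
* implanted tandem repeats (unit^k concatenations with a per-base mutation
  rate), both qualifying (>200 bp span, >=3 units) and non-qualifying
  decoys, recorded in a simpleRepeat-style track;
* multi-exon coding and noncoding transcripts in five classes — with and
  without exonic SRS content, plus fully-repetitive decoy transcripts — and
  divergent (bidirectional) SRS-lncRNA pairs near the centromere of one
  designated chromosome;
* negative-binomial gene-level counts over 4 differentiation stages × 2
  cellular fractions with planted up/down fold changes and class-specific
  cytoplasmic/nuclear localization ratios, plus matched TPM matrices;
* RBP motifs (one U/G-rich ELAVL-like) planted densely inside SRS regions
  and sparsely outside, with CLIP peaks centered on a configured fraction
  of the planted sites.

Every placement decision is laid out on a grid of non-overlapping "cells"
per chromosome arm, so regeneration under a fixed seed is byte-identical
and planted features never collide.  All randomness flows from the master
seed through named substreams, one per generation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    ALPHABET,
    Chromosome,
    ChromInfo,
    ExpressionTable,
    FRACTIONS,
    GenomicInterval,
    PeakSet,
    Pwm,
    RepeatRecord,
    STAGES,
    TranscriptModel,
    revcomp,
    spliced_sequence,
    write_bed,
    write_chrom_info,
    write_expression_table,
    write_fasta,
    write_gtf,
    write_meme,
    write_repeat_track,
)
from .srs_catalog import genomic_to_transcript, transcript_to_genomic

_SUBSTREAMS = {"genome": 0, "transcriptome": 1, "expression": 2, "motifs": 3, "peaks": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],)))


@dataclass
class SyntheticConfig:
    seed: int = 17
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    centromere: tuple[int, int] = (900_000, 1_100_000)
    cell_size: int = 10_000

    # class counts (genes; one transcript per gene)
    n_coding_nonsrs: int = 100
    n_coding_srs: int = 50
    n_lnc_nonsrs: int = 80
    n_lnc_srs: int = 50
    n_repeat_only: int = 20
    n_divergent_pairs: int = 6  # pairs; members are lnc_srs genes
    promoter_gap: int = 1000

    # repeats
    qualifying_span: tuple[int, int] = (300, 1200)
    n_extra_qualifying: int = 60  # gene-free qualifying repeats
    n_decoy_repeats: int = 40    # non-qualifying (short or <3 units)
    mutation_rate: float = 0.01
    telomere_skew: float = 0.0   # >0 biases gene-free repeat cells to telomeres

    # expression
    replicates: int = 3
    dispersion: float = 0.1
    n_up: int = 15
    n_down: int = 10
    up_lfc: float = 2.0
    down_lfc: float = -2.0
    n_silent: int = 6  # lnc_nonsrs genes below the nuclear TPM floor
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 0.6
    localization_medians: dict = field(
        default_factory=lambda: {
            "coding_nonsrs": 1.0, "coding_srs": 0.6,
            "lnc_nonsrs": 0.25, "lnc_srs": 0.45,
        }
    )
    localization_log_sd: float = 0.5

    # motifs and CLIP
    srs_motif_density: float = 12.0   # planted sites per kb per RBP
    nonsrs_motif_density: float = 2.0
    clip_rbp: str = "ELAVL3"
    clip_coverage: float = 0.6
    n_background_peaks: int = 200
    peak_width: tuple[int, int] = (20, 60)

    def validate(self) -> None:
        if self.n_divergent_pairs * 2 > self.n_lnc_srs:
            raise ValueError("divergent pair members exceed lnc_srs count")
        if self.n_up + self.n_down > self.n_lnc_srs:
            raise ValueError("planted DE subsets exceed lnc_srs count")
        if self.n_silent > self.n_lnc_nonsrs:
            raise ValueError("silent genes exceed lnc_nonsrs count")
        if not (0 <= self.clip_coverage <= 1):
            raise ValueError("clip_coverage outside [0, 1]")
        for k in ("n_coding_nonsrs", "n_coding_srs", "n_lnc_nonsrs", "n_lnc_srs",
                  "n_repeat_only", "n_extra_qualifying", "n_decoy_repeats"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chrS{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def designated_chrom(self) -> str:
        """Chromosome hosting the divergent pairs near its centromere."""
        return self.chrom_names[-1]


@dataclass
class TruthTables:
    """Planted ground truth, re-derivable from the emitted files."""

    genes: pd.DataFrame            # gene_id, transcript_id, class, position, DE, ratio
    de: pd.DataFrame               # gene_id × stage × fraction true lfc
    srs: pd.DataFrame              # transcript_id, repeat_id, tx/genomic intervals
    motif_sites: pd.DataFrame      # transcript_id, rbp, tx_start, region
    peaks: pd.DataFrame            # peak index, planted flag
    pairs: pd.DataFrame            # pair_id, minus_id, plus_id, tss_gap


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    chrom_info: ChromInfo
    repeats: list[RepeatRecord]
    transcripts: list[TranscriptModel]
    counts: ExpressionTable
    tpm: ExpressionTable
    pwms: list[Pwm]
    peaks: PeakSet
    truth: TruthTables


# ---------------------------------------------------------------------------
# cell layout

@dataclass
class _Cell:
    chrom: str
    start: int
    arm: str
    t: float  # arm coordinate of the cell midpoint (0 centromere, 1 telomere)
    role: str = "free"


def _build_cells(cfg: SyntheticConfig) -> list[_Cell]:
    cells = []
    cen_s, cen_e = cfg.centromere
    cen_mid = (cen_s + cen_e) / 2
    for chrom in cfg.chrom_names:
        for arm, lo, hi in (("p", 0, cen_s), ("q", cen_e, cfg.chrom_length)):
            n = (hi - lo) // cfg.cell_size
            for i in range(n):
                start = lo + i * cfg.cell_size
                mid = start + cfg.cell_size / 2
                if arm == "p":
                    t = (cen_mid - mid) / cen_mid
                else:
                    t = (mid - cen_mid) / (cfg.chrom_length - cen_mid)
                cells.append(_Cell(chrom=chrom, start=start, arm=arm, t=min(max(t, 0.0), 1.0)))
    return cells


def sample_arm_positions(
    n: int, rng: np.random.Generator, skew: float = 0.0
) -> np.ndarray:
    """Draw arm coordinates t in [0, 1] with density proportional to
    (t)^skew — skew 0 is uniform, larger values push placements toward the
    telomere end (t = 1).  Used for positional-skew planting."""
    u = rng.random(n)
    return u ** (1.0 / (1.0 + skew))


# ---------------------------------------------------------------------------
# genome + repeats

@dataclass
class _PlannedRepeat:
    cell_index: int
    offset: int          # repeat start within the cell
    unit: str
    span: int
    role: str            # gene-linked role or "extra"/"decoy"

    @property
    def copy_number(self) -> float:
        return round(self.span / len(self.unit), 1)


@dataclass
class GenomePlan:
    """Genome sequences plus the cell/repeat layout consumed downstream."""

    config: SyntheticConfig
    genome: dict[str, str]
    chrom_info: ChromInfo
    cells: list[_Cell]
    repeats: list[RepeatRecord]
    cell_repeats: dict[int, list[int]]  # cell index -> repeat indices
    cell_assignment: dict[str, list[int]]  # role -> cell indices


_REPEAT_UNIT_LENGTHS = (5, 12, 25, 60, 171)


def _random_unit(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def _repeat_sequence(rng: np.random.Generator, unit: str, span: int, mutation_rate: float) -> str:
    reps = -(-span // len(unit))
    seq = list((unit * reps)[:span])
    if mutation_rate > 0:
        n_mut = rng.binomial(span, mutation_rate)
        for pos in rng.integers(0, span, size=n_mut):
            seq[pos] = ALPHABET[rng.integers(0, 4)]
    return "".join(seq)


def generate_genome(config: SyntheticConfig, seed: int | None = None) -> GenomePlan:
    """Random background sequence with implanted tandem repeats, and the
    cell layout that later stages build genes on."""
    config.validate()
    rng = substream(seed if seed is not None else config.seed, "genome")
    cells = _build_cells(config)

    # --- assign cells to roles
    pair_cells = [
        i for i, c in enumerate(cells)
        if c.chrom == config.designated_chrom and c.arm == "q"
    ]
    pair_cells = sorted(pair_cells, key=lambda i: cells[i].start)[: config.n_divergent_pairs]
    for i in pair_cells:
        cells[i].role = "pair"
    free = [i for i, c in enumerate(cells) if c.role == "free"]
    perm = rng.permutation(len(free))
    free = [free[i] for i in perm]

    def take(role: str, n: int, telomere_weighted: bool = False) -> list[int]:
        nonlocal free
        if n > len(free):
            raise ValueError(f"cannot place {n} {role} cells; only {len(free)} free")
        if telomere_weighted and config.telomere_skew > 0:
            w = np.array([(cells[i].t + 0.05) ** config.telomere_skew for i in free])
            idx = rng.choice(len(free), size=n, replace=False, p=w / w.sum())
            chosen = [free[int(j)] for j in idx]
            free = [f for f in free if f not in set(chosen)]
        else:
            chosen, free = free[:n], free[n:]
        for i in chosen:
            cells[i].role = role
        return chosen

    assignment = {
        "pair": pair_cells,
        "coding_srs": take("coding_srs", config.n_coding_srs),
        "lnc_srs": take("lnc_srs", config.n_lnc_srs - 2 * config.n_divergent_pairs),
        "repeat_only": take("repeat_only", config.n_repeat_only),
        "extra": take("extra", config.n_extra_qualifying, telomere_weighted=True),
        "decoy": take("decoy", config.n_decoy_repeats),
        "coding_nonsrs": take("coding_nonsrs", config.n_coding_nonsrs),
        "lnc_nonsrs": take("lnc_nonsrs", config.n_lnc_nonsrs),
    }

    # --- plan repeats per cell
    planned: list[_PlannedRepeat] = []
    lo_span, hi_span = config.qualifying_span

    def plan_qualifying(cell_index: int, offset: int, role: str, max_span: int | None = None):
        unit_len = int(rng.choice(_REPEAT_UNIT_LENGTHS))
        hi = min(hi_span, max_span) if max_span else hi_span
        span = int(rng.integers(max(lo_span, 3 * unit_len), hi + 1))
        planned.append(_PlannedRepeat(cell_index, offset, _random_unit(rng, unit_len), span, role))

    for role in ("coding_srs", "lnc_srs", "repeat_only"):
        for ci in assignment[role]:
            plan_qualifying(ci, 2000, role)
    for ci in assignment["pair"]:
        plan_qualifying(ci, 1200, "pair_minus", max_span=800)
        plan_qualifying(ci, 5800, "pair_plus", max_span=800)
    for ci in assignment["extra"]:
        unit_len = int(rng.choice(_REPEAT_UNIT_LENGTHS))
        span = int(rng.integers(max(lo_span, 3 * unit_len), 5001))
        planned.append(_PlannedRepeat(ci, 2000, _random_unit(rng, unit_len), span, "extra"))
    for ci in assignment["decoy"]:
        if rng.random() < 0.5:
            # short: span <= 200 bp, >= 3 units
            unit_len = int(rng.choice((5, 12, 25)))
            span = int(rng.integers(3 * unit_len, 201))
        else:
            # long enough but < 3 units
            unit_len = int(rng.integers(150, 300))
            span = int(rng.integers(unit_len * 2, int(unit_len * 2.9)))
        planned.append(_PlannedRepeat(ci, 2000, _random_unit(rng, unit_len), span, "decoy"))

    # --- emit sequences
    genome = {}
    for chrom in config.chrom_names:
        genome[chrom] = rng.integers(0, 4, size=config.chrom_length)
    repeats: list[RepeatRecord] = []
    cell_repeats: dict[int, list[int]] = {}
    for pr in sorted(planned, key=lambda p: (p.cell_index, p.offset)):
        cell = cells[pr.cell_index]
        start = cell.start + pr.offset
        seq = _repeat_sequence(rng, pr.unit, pr.span, config.mutation_rate)
        arr = genome[cell.chrom]
        arr[start:start + pr.span] = [ALPHABET.index(b) for b in seq]
        repeats.append(
            RepeatRecord(
                interval=GenomicInterval(cell.chrom, start, start + pr.span),
                period=float(len(pr.unit)),
                copy_number=pr.copy_number,
                unit_seq=pr.unit,
                repeat_id=f"rep{len(repeats):04d}",
            )
        )
        cell_repeats.setdefault(pr.cell_index, []).append(len(repeats) - 1)

    byte_map = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    genome_str = {c: byte_map[v].tobytes().decode() for c, v in genome.items()}
    cen = config.centromere
    chrom_info = ChromInfo(
        Chromosome(c, config.chrom_length, GenomicInterval(c, cen[0], cen[1]))
        for c in config.chrom_names
    )
    return GenomePlan(
        config=config, genome=genome_str, chrom_info=chrom_info, cells=cells,
        repeats=repeats, cell_repeats=cell_repeats, cell_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# transcriptome

def _rand_strand(rng) -> str:
    return "+" if rng.random() < 0.5 else "-"


def generate_transcriptome(
    plan: GenomePlan, seed: int | None = None
) -> tuple[list[TranscriptModel], pd.DataFrame, pd.DataFrame]:
    """Multi-exon transcripts per class over the planned cells.

    Returns (transcripts, gene truth frame, divergent-pair truth frame).
    SRS-class transcripts get an exon fully containing their qualifying
    repeat (plus flanks), guaranteeing >200 bp exonic overlap; repeat-only
    decoys are single exons inside their repeat (exonic repeat fraction 1).
    """
    cfg = plan.config
    rng = substream(seed if seed is not None else cfg.seed, "transcriptome")
    transcripts: list[TranscriptModel] = []
    rows = []
    pair_rows = []
    counter = 0

    def next_ids():
        nonlocal counter
        counter += 1
        return f"G{counter:04d}", f"T{counter:04d}"

    def add(gene_id, tid, chrom, strand, exons, biotype, cls, repeat_id=None, pair_id=None):
        t = TranscriptModel(tid, gene_id, chrom, strand,
                            [GenomicInterval(chrom, s, e, strand) for s, e in exons],
                            biotype)
        transcripts.append(t)
        rows.append(
            {"gene_id": gene_id, "transcript_id": tid, "true_class": cls,
             "chrom": chrom, "strand": strand, "span_start": exons[0][0],
             "span_end": exons[-1][1], "spliced_length": t.spliced_length,
             "repeat_id": repeat_id, "pair_id": pair_id}
        )
        return t

    def srs_exons(repeat: RepeatRecord):
        pad_l = int(rng.integers(100, 301))
        pad_r = int(rng.integers(100, 301))
        ex2 = (repeat.interval.start - pad_l, repeat.interval.end + pad_r)
        e1 = int(rng.integers(200, 501))
        g1 = int(rng.integers(200, 601))
        ex1 = (ex2[0] - g1 - e1, ex2[0] - g1)
        exons = [ex1, ex2]
        if rng.random() < 0.5:
            e3 = int(rng.integers(200, 501))
            g2 = int(rng.integers(200, 601))
            exons.append((ex2[1] + g2, ex2[1] + g2 + e3))
        return exons

    def plain_exons(cell_start: int):
        n_ex = int(rng.integers(2, 4))
        pos = cell_start + 1000
        exons = []
        for _ in range(n_ex):
            e = int(rng.integers(300, 801))
            exons.append((pos, pos + e))
            pos += e + int(rng.integers(200, 601))
        return exons

    for role, biotype, cls in (
        ("coding_srs", "protein_coding", "coding_srs"),
        ("lnc_srs", "non_coding", "lnc_srs"),
    ):
        for ci in plan.cell_assignment[role]:
            rep = plan.repeats[plan.cell_repeats[ci][0]]
            gid, tid = next_ids()
            add(gid, tid, plan.cells[ci].chrom, _rand_strand(rng),
                srs_exons(rep), biotype, cls, repeat_id=rep.repeat_id)

    for pi, ci in enumerate(plan.cell_assignment["pair"]):
        cell = plan.cells[ci]
        rep_m = plan.repeats[plan.cell_repeats[ci][0]]
        rep_p = plan.repeats[plan.cell_repeats[ci][1]]
        pair_id = f"pair{pi}"
        # minus-strand member: leftmost, TSS at its right end
        pad = int(rng.integers(100, 201))
        ex_m1 = (rep_m.interval.start - pad, rep_m.interval.end + pad)
        e2 = int(rng.integers(200, 401))
        g = int(rng.integers(200, 501))
        ex_m2 = (ex_m1[1] + g, ex_m1[1] + g + e2)
        gid_m, tid_m = next_ids()
        t_m = add(gid_m, tid_m, cell.chrom, "-", [ex_m1, ex_m2], "non_coding",
                  "lnc_srs", repeat_id=rep_m.repeat_id, pair_id=pair_id)
        # plus-strand member: TSS right of the minus TSS by <= promoter_gap
        gap = int(rng.integers(200, cfg.promoter_gap + 1))
        p_start = t_m.tss + gap
        e1 = int(rng.integers(200, 401))
        pad2 = int(rng.integers(100, 201))
        ex_p1 = (p_start, p_start + e1)
        ex_p2 = (rep_p.interval.start - pad2, rep_p.interval.end + pad2)
        gid_p, tid_p = next_ids()
        t_p = add(gid_p, tid_p, cell.chrom, "+", [ex_p1, ex_p2], "non_coding",
                  "lnc_srs", repeat_id=rep_p.repeat_id, pair_id=pair_id)
        pair_rows.append(
            {"pair_id": pair_id, "minus_id": tid_m, "plus_id": tid_p,
             "tss_gap": t_p.tss - t_m.tss}
        )

    for ci in plan.cell_assignment["repeat_only"]:
        rep = plan.repeats[plan.cell_repeats[ci][0]]
        gid, tid = next_ids()
        add(gid, tid, plan.cells[ci].chrom, _rand_strand(rng),
            [(rep.interval.start, rep.interval.end)], "non_coding",
            "excluded_repeat_only", repeat_id=rep.repeat_id)

    for role, biotype, cls in (
        ("coding_nonsrs", "protein_coding", "coding_nonsrs"),
        ("lnc_nonsrs", "non_coding", "lnc_nonsrs"),
    ):
        for ci in plan.cell_assignment[role]:
            gid, tid = next_ids()
            add(gid, tid, plan.cells[ci].chrom, _rand_strand(rng),
                plain_exons(plan.cells[ci].start), biotype, cls)

    genes = pd.DataFrame(rows)
    pairs = pd.DataFrame(pair_rows, columns=["pair_id", "minus_id", "plus_id", "tss_gap"])
    return transcripts, genes, pairs


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    genes: pd.DataFrame, config: SyntheticConfig, seed: int | None = None
) -> tuple[ExpressionTable, ExpressionTable, pd.DataFrame, pd.DataFrame]:
    """NB counts and matched TPM over 4 stages × 2 fractions × replicates.

    Counts ~ NB(mean = baseline × 2^planted_lfc × fraction ratio × size
    factor, dispersion α).  TPM is computed from the expected counts
    normalized by spliced length and rescaled to 1e6 per column, so the
    localization structure is exact while counts carry sampling noise.
    Returns (counts, tpm, DE truth long table, augmented gene table).
    """
    rng = substream(seed if seed is not None else config.seed, "expression")
    genes = genes.reset_index(drop=True)
    n = len(genes)
    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))

    # planted localization ratio per gene around its class median
    med = genes["true_class"].map(
        lambda c: config.localization_medians.get(c, 1.0)
    ).to_numpy(dtype=float)
    ratio = med * np.exp(rng.normal(0.0, config.localization_log_sd, size=n))

    # planted DE subsets inside lnc_srs; silent genes inside lnc_nonsrs
    lnc_srs_idx = genes.index[genes["true_class"] == "lnc_srs"].to_numpy()
    picked = rng.permutation(lnc_srs_idx)
    up_idx = picked[: config.n_up]
    down_idx = picked[config.n_up: config.n_up + config.n_down]
    # half the up genes regulated everywhere, half only in one late contrast
    up_broad = up_idx[: len(up_idx) // 2 + len(up_idx) % 2]
    up_narrow = up_idx[len(up_broad):]
    lnc_non_idx = genes.index[genes["true_class"] == "lnc_nonsrs"].to_numpy()
    silent_idx = rng.permutation(lnc_non_idx)[: config.n_silent]
    baseline[silent_idx] = 1e-4

    true_lfc = np.zeros((n, len(STAGES), len(FRACTIONS)))
    for s_i, stage in enumerate(STAGES):
        if stage == "ESC":
            continue
        for f_i in range(len(FRACTIONS)):
            true_lfc[up_broad, s_i, f_i] = config.up_lfc
            true_lfc[down_idx, s_i, f_i] = config.down_lfc
    # narrow up genes: N50 nuclear only
    true_lfc[up_narrow, STAGES.index("N50"), FRACTIONS.index("nuclear")] = config.up_lfc

    n1 = 1.0 / config.dispersion if config.dispersion > 0 else None
    cols, count_cols, tpm_cols = [], [], []
    lengths = genes["spliced_length"].to_numpy(dtype=float)
    for s_i, stage in enumerate(STAGES):
        for f_i, fraction in enumerate(FRACTIONS):
            mu = baseline * 2.0 ** true_lfc[:, s_i, f_i]
            if fraction == "cytoplasmic":
                mu = mu * ratio
            tpm_vec = mu / lengths
            tpm_vec = tpm_vec / tpm_vec.sum() * 1e6
            for r in range(1, config.replicates + 1):
                sf = float(np.exp(rng.normal(0.0, 0.15)))
                mean = mu * sf
                if n1 is None:
                    counts = rng.poisson(mean)
                else:
                    counts = rng.negative_binomial(n1, n1 / (n1 + mean))
                cols.append((stage, fraction, r))
                count_cols.append(counts)
                tpm_cols.append(tpm_vec)

    index = pd.Index(genes["gene_id"], name="gene_id")
    mi = pd.MultiIndex.from_tuples(cols, names=["stage", "fraction", "replicate"])
    counts_df = pd.DataFrame(np.column_stack(count_cols), index=index, columns=mi)
    tpm_df = pd.DataFrame(np.column_stack(tpm_cols), index=index, columns=mi)

    de_rows = []
    status = np.full(n, "null", dtype=object)
    status[up_idx] = "up"
    status[down_idx] = "down"
    status[silent_idx] = "silent"
    for g_i in range(n):
        for s_i, stage in enumerate(STAGES):
            if stage == "ESC":
                continue
            for f_i, fraction in enumerate(FRACTIONS):
                de_rows.append(
                    {"gene_id": genes.loc[g_i, "gene_id"], "stage": stage,
                     "fraction": fraction, "true_lfc": true_lfc[g_i, s_i, f_i],
                     "de_status": status[g_i]}
                )
    de_truth = pd.DataFrame(de_rows)
    genes = genes.copy()
    genes["de_status"] = status
    genes["true_ratio"] = ratio
    genes["baseline_mean"] = baseline
    return (
        ExpressionTable(values=counts_df, kind="counts"),
        ExpressionTable(values=tpm_df, kind="TPM"),
        de_truth,
        genes,
    )


# ---------------------------------------------------------------------------
# motifs and peaks

_DEFAULT_MOTIFS = (
    ("M_ELAVL3", "ELAVL3", "TGTTTGTT"),  # U/G-rich ELAVL-like
    ("M_RBPA", "RBPA", "GACGCAG"),
    ("M_RBPB", "RBPB", "CCATCCA"),
)


def _consensus_pwm(motif_id: str, rbp: str, consensus: str, p_major: float = 0.85) -> Pwm:
    w = len(consensus)
    mat = np.full((w, 4), (1.0 - p_major) / 3.0)
    for i, c in enumerate(consensus):
        mat[i, ALPHABET.index(c)] = p_major
    return Pwm(motif_id=motif_id, rbp_name=rbp, matrix=mat)


def _place_nonoverlapping(rng, region_len: int, k: int, w: int) -> np.ndarray:
    """k non-overlapping width-w starts, uniform over feasible placements."""
    slack = region_len - k * w
    if slack < 0:
        k = region_len // w
        slack = region_len - k * w
        if k == 0:
            return np.array([], dtype=int)
    gaps = np.sort(rng.choice(slack + 1, size=k, replace=True)) if k else np.array([], dtype=int)
    return gaps + np.arange(k) * w


def generate_motifs_and_peaks(
    plan: GenomePlan,
    transcripts: list[TranscriptModel],
    srs_truth: pd.DataFrame,
    seed: int | None = None,
) -> tuple[list[Pwm], PeakSet, pd.DataFrame, pd.DataFrame]:
    """Plant exact-consensus motif sites and CLIP peaks over them.

    Sites are placed without overlap inside each transcript's SRS regions at
    ``srs_motif_density`` per kb per RBP and outside at
    ``nonsrs_motif_density``, by rewriting the genome sequence through the
    exon projection (reverse-complemented on the minus strand).  CLIP peaks
    (width 20-60 bp in transcript space) are centered on a
    ``clip_coverage`` fraction of the CLIP'd RBP's planted sites; background
    peaks are length-proportional random windows.  Mutates ``plan.genome``.
    Returns (pwms, peaks, motif-site truth, peak truth).
    """
    cfg = plan.config
    rng = substream(seed if seed is not None else cfg.seed, "motifs")
    peak_rng = substream(seed if seed is not None else cfg.seed, "peaks")
    pwms = [_consensus_pwm(m, r, c) for m, r, c in _DEFAULT_MOTIFS]
    by_tid = {t.transcript_id: t for t in transcripts}

    genome_arr = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
                  for c, s in plan.genome.items()}

    def write_site(t: TranscriptModel, tx_start: int, consensus: str) -> None:
        segs = transcript_to_genomic(t, tx_start, tx_start + len(consensus))
        seq = consensus if t.strand == "+" else revcomp(consensus)
        # genome-order bases of the site
        pos = 0
        for seg in segs:
            sub = seq[pos:pos + len(seg)]
            genome_arr[t.chrom][seg.start:seg.end] = np.frombuffer(sub.encode(), dtype=np.uint8)
            pos += len(seg)

    srs_by_tid: dict[str, list[tuple[int, int]]] = {}
    for _, row in srs_truth.iterrows():
        srs_by_tid.setdefault(row["transcript_id"], []).append(
            (int(row["tx_start"]), int(row["tx_end"]))
        )

    site_rows = []
    for t in transcripts:
        L = t.spliced_length
        srs_ivs = sorted(srs_by_tid.get(t.transcript_id, []))
        regions = []
        cursor = 0
        for s, e in srs_ivs:
            if cursor < s:
                regions.append(("nonSRS", cursor, s))
            regions.append(("SRS", s, e))
            cursor = e
        if cursor < L:
            regions.append(("nonSRS", cursor, L))
        for label, r_s, r_e in regions:
            r_len = r_e - r_s
            density = cfg.srs_motif_density if label == "SRS" else cfg.nonsrs_motif_density
            # draw per-RBP counts, then one joint non-overlapping placement
            counts = {p.rbp_name: int(rng.poisson(density * r_len / 1000.0)) for p in pwms}
            total = sum(counts.values())
            if total == 0:
                continue
            w_max = max(p.width for p in pwms)
            starts = _place_nonoverlapping(rng, r_len, total, w_max)
            labels = sum(([p.rbp_name] * counts[p.rbp_name] for p in pwms), [])
            order = rng.permutation(len(labels))
            cons = {p.rbp_name: p.consensus for p in pwms}
            for start, l_i in zip(starts, order):
                rbp = labels[int(l_i)]
                tx_start = r_s + int(start)
                write_site(t, tx_start, cons[rbp])
                site_rows.append(
                    {"transcript_id": t.transcript_id, "rbp_name": rbp,
                     "tx_start": tx_start, "tx_end": tx_start + len(cons[rbp]),
                     "region": label}
                )
    motif_truth = pd.DataFrame(
        site_rows, columns=["transcript_id", "rbp_name", "tx_start", "tx_end", "region"]
    )

    # --- CLIP peaks over the CLIP'd RBP's sites
    peak_ivs: list[GenomicInterval] = []
    peak_rows = []
    lo_w, hi_w = cfg.peak_width
    clip_sites = motif_truth[motif_truth["rbp_name"] == cfg.clip_rbp]
    for _, row in clip_sites.iterrows():
        if peak_rng.random() >= cfg.clip_coverage:
            continue
        t = by_tid[row["transcript_id"]]
        width = int(peak_rng.integers(lo_w, hi_w + 1))
        center = (int(row["tx_start"]) + int(row["tx_end"])) // 2
        p_s = max(0, min(center - width // 2, t.spliced_length - width))
        for seg in transcript_to_genomic(t, p_s, p_s + width):
            peak_ivs.append(GenomicInterval(seg.chrom, seg.start, seg.end))
            peak_rows.append({"planted": True, "transcript_id": t.transcript_id})
    eligible = [t for t in transcripts if t.spliced_length >= hi_w]
    lengths = np.array([t.spliced_length for t in eligible], dtype=float)
    for _ in range(cfg.n_background_peaks):
        width = int(peak_rng.integers(lo_w, hi_w + 1))
        t = eligible[int(peak_rng.choice(lengths.size, p=lengths / lengths.sum()))]
        p_s = int(peak_rng.integers(0, t.spliced_length - width + 1))
        for seg in transcript_to_genomic(t, p_s, p_s + width):
            peak_ivs.append(GenomicInterval(seg.chrom, seg.start, seg.end))
            peak_rows.append({"planted": False, "transcript_id": t.transcript_id})

    plan.genome = {c: arr.tobytes().decode() for c, arr in genome_arr.items()}
    peak_truth = pd.DataFrame(peak_rows, columns=["planted", "transcript_id"])
    return pwms, PeakSet(peaks=peak_ivs), motif_truth, peak_truth


# ---------------------------------------------------------------------------
# orchestration

def _srs_truth(plan: GenomePlan, transcripts, genes: pd.DataFrame) -> pd.DataFrame:
    """Planted SRS intervals in transcript coordinates, from the layout."""
    rep_by_id = {r.repeat_id: r for r in plan.repeats}
    rows = []
    by_tid = {t.transcript_id: t for t in transcripts}
    for _, g in genes.iterrows():
        rid = g["repeat_id"]
        if rid is None or (isinstance(rid, float) and np.isnan(rid)):
            continue
        rep = rep_by_id[rid]
        t = by_tid[g["transcript_id"]]
        for s, e in genomic_to_transcript(t, rep.interval.start, rep.interval.end):
            rows.append(
                {"transcript_id": t.transcript_id, "repeat_id": rid,
                 "tx_start": s, "tx_end": e,
                 "g_start": rep.interval.start, "g_end": rep.interval.end}
            )
    return pd.DataFrame(
        rows, columns=["transcript_id", "repeat_id", "tx_start", "tx_end",
                       "g_start", "g_end"]
    )


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Run every generation stage under the config's master seed."""
    cfg = config or SyntheticConfig()
    plan = generate_genome(cfg)
    transcripts, genes, pairs = generate_transcriptome(plan)
    counts, tpm, de_truth, genes = simulate_expression(genes, cfg)
    srs_truth = _srs_truth(plan, transcripts, genes)
    pwms, peaks, motif_truth, peak_truth = generate_motifs_and_peaks(
        plan, transcripts, srs_truth
    )
    truth = TruthTables(
        genes=genes, de=de_truth, srs=srs_truth, motif_sites=motif_truth,
        peaks=peak_truth, pairs=pairs,
    )
    return SyntheticDataset(
        config=cfg, genome=plan.genome, chrom_info=plan.chrom_info,
        repeats=plan.repeats, transcripts=transcripts, counts=counts, tpm=tpm,
        pwms=pwms, peaks=peaks, truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every emitted file (FASTA, GTF, repeat track, matrices, MEME,
    peaks BED, chrom info, truth tables, config YAML); returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "gtf": out / "transcripts.gtf",
        "repeats": out / "simple_repeats.tsv",
        "chrom_info": out / "chrom_info.tsv",
        "counts": out / "counts.tsv",
        "tpm": out / "tpm.tsv",
        "motifs": out / "motifs.meme",
        "peaks": out / "clip_peaks.bed",
        "config": out / "config.yaml",
    }
    write_fasta(ds.genome, paths["genome"])
    write_gtf(ds.transcripts, paths["gtf"])
    write_repeat_track(ds.repeats, paths["repeats"])
    write_chrom_info(ds.chrom_info, paths["chrom_info"])
    write_expression_table(ds.counts, paths["counts"])
    write_expression_table(ds.tpm, paths["tpm"])
    write_meme(ds.pwms, paths["motifs"])
    write_bed(ds.peaks.peaks, paths["peaks"])
    cfg = asdict(ds.config)
    cfg["centromere"] = list(cfg["centromere"])
    cfg["qualifying_span"] = list(cfg["qualifying_span"])
    cfg["peak_width"] = list(cfg["peak_width"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for name in ("genes", "de", "srs", "motif_sites", "peaks", "pairs"):
        p = truth_dir / f"{name}.tsv"
        getattr(ds.truth, name).to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    return paths


def transcript_sequences(ds: SyntheticDataset) -> dict[str, str]:
    """Spliced 5'→3' sequences for every transcript in the dataset."""
    return {t.transcript_id: spliced_sequence(t, ds.genome) for t in ds.transcripts}
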