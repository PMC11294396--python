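"""Differential expression and nuclear/cytoplasmic localization analysis.

Counts are normalized with median-of-ratios size factors and tested per gene
with a negative-binomial Wald test: per-gene dispersion by method of moments
on pooled within-group residuals (floored at the Poisson limit), delta-method
standard error on the log2 fold change, and a two-sided normal p-value,
Benjamini–Hochberg adjusted per contrast.  Shortlisting follows the study
design: three neural stages (NPC, N14, N50) each contrasted against ESC,
separately in the nuclear and cytoplasmic fractions.

Localization is summarized as the cytoplasmic/nuclear TPM ratio per gene and
stage, normalized by the stage-specific median ratio of non-SRS
protein-coding genes, and compared across transcript classes with
Kruskal–Wallis plus Dunn's post hoc test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionTable, FRACTIONS, NEURAL_STAGES, STAGES

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# normalization

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors, rescaled to geometric
    mean 1.

    Uses genes with strictly positive counts in every sample as the
    reference set.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; cannot form the "
            "median-of-ratios reference — consider a pseudo-reference "
            "(e.g. add a pseudocount before normalization)"
        )
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1)
    log_sf = np.median(logx - log_geomean[:, None], axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns)


# ---------------------------------------------------------------------------
# NB Wald test

def nb_wald_de(
    counts: pd.DataFrame,
    samples_a: list,
    samples_b: list,
    sf: pd.Series | None = None,
    pseudocount: float = 0.5,
    dispersion: float | np.ndarray | None = None,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-gene NB Wald test of group B vs group A (lfc = log2 B/A).

    Size factors default to median-of-ratios over the union of the two
    groups.  Dispersion is a per-gene method-of-moments estimate from the
    pooled within-group variance of normalized counts, shrunk toward a
    cross-gene trend (the ratio estimator Σ(s²-m)/Σ(m²) over expressed
    genes) with weight df/(df + ``prior_df``), then floored at the Poisson
    limit.  With only a handful of residual degrees of freedom the
    gene-wise estimate carries little information, so shrinkage both
    stabilizes the standard error and keeps the Wald z approximately
    standard normal under the null.  Pass ``dispersion`` to override the
    estimate with a known value.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >=2 replicates per group")
    sub = counts[list(samples_a) + list(samples_b)]
    if sf is None:
        sf = size_factors(sub)
    norm = sub.div(sf[sub.columns], axis=1)
    a = norm[list(samples_a)].to_numpy(dtype=float)
    b = norm[list(samples_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]

    mu_a = a.mean(axis=1)
    mu_b = b.mean(axis=1)
    # pooled within-group variance, df = n_a + n_b - 2
    df = n_a + n_b - 2
    ss = ((a - mu_a[:, None]) ** 2).sum(axis=1) + ((b - mu_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    grand = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
    if dispersion is not None:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), grand.shape).copy()
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_g = np.where(grand > 0, (s2 - grand) / np.maximum(grand, 1e-300) ** 2, 0.0)
        expressed = grand > 5
        if expressed.any():
            trend = max(0.0, float(
                np.sum(s2[expressed] - grand[expressed])
                / np.sum(grand[expressed] ** 2)
            ))
        else:
            trend = 0.0
        w = df / (df + prior_df)
        alpha = np.clip(w * alpha_g + (1.0 - w) * trend, 0.0, None)

    eps = pseudocount
    lfc = np.log2((mu_b + eps) / (mu_a + eps))
    va = (mu_a + eps + alpha * (mu_a + eps) ** 2) / (n_a * (mu_a + eps) ** 2)
    vb = (mu_b + eps + alpha * (mu_b + eps) ** 2) / (n_b * (mu_b + eps) ** 2)
    se = np.sqrt(va + vb) / LN2
    z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {"base_mean": grand, "lfc": lfc, "se": se, "p": p,
         "dispersion": alpha},
        index=counts.index,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_all_contrasts(
    counts_table: ExpressionTable,
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Run every neural-stage-vs-ESC contrast within each fraction.

    Returns a long table (gene_id, stage, fraction, base_mean, lfc, se, p, q)
    with BH adjustment applied per contrast.  Size factors are computed once
    over all samples.
    """
    df = counts_table.values
    if genes is not None:
        df = df.loc[genes]
    flat = df.copy()
    flat.columns = list(df.columns)
    sf = size_factors(flat)
    out = []
    for fraction in FRACTIONS:
        esc_cols = [c for c in df.columns if c[0] == "ESC" and c[1] == fraction]
        for stage in NEURAL_STAGES:
            stage_cols = [c for c in df.columns if c[0] == stage and c[1] == fraction]
            if not esc_cols or not stage_cols:
                raise ValueError(f"missing samples for contrast {stage} vs ESC ({fraction})")
            res = nb_wald_de(flat, esc_cols, stage_cols, sf=sf)
            res["q"] = bh_adjust(res["p"].to_numpy())
            res.insert(0, "fraction", fraction)
            res.insert(0, "stage", stage)
            res.insert(0, "gene_id", res.index)
            out.append(res.reset_index(drop=True))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# filtering and shortlisting

def filter_low_abundance(tpm_table: ExpressionTable, threshold: float = 0.1) -> pd.Index:
    """Keep genes whose nuclear TPM reaches ``threshold`` in at least one
    sample (any stage, any replicate); genes below in all nuclear samples
    are excluded."""
    nuclear_cols = [c for c in tpm_table.values.columns if c[1] == "nuclear"]
    if not nuclear_cols:
        raise ValueError("no nuclear samples in TPM table")
    nuc = tpm_table.values[nuclear_cols]
    keep = (nuc >= threshold).any(axis=1)
    return tpm_table.values.index[keep]


@dataclass
class Shortlist:
    """Regulated gene set with per-gene provenance of qualifying contrasts."""

    direction: str
    provenance: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.provenance)

    def __len__(self):
        return len(self.provenance)


def shortlist_regulated(
    de: pd.DataFrame,
    direction: str,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> Shortlist:
    """Apply the regulation shortlist rules to a long DE table.

    UP: the gene clears lfc > ``lfc_threshold`` and q < ``fdr_threshold`` in
    at least one neural (stage, fraction) contrast.

    DOWN: in at least one fraction the gene clears lfc < -``lfc_threshold``
    and q < ``fdr_threshold`` at *all* neural stages, and is not
    significantly upregulated (lfc > threshold, q < threshold) at any stage
    in the other fraction.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    required = {(s, f) for s in NEURAL_STAGES for f in FRACTIONS}
    have = set(map(tuple, de[["stage", "fraction"]].drop_duplicates().to_numpy()))
    missing = required - have
    if missing:
        raise ValueError(f"missing contrasts: {sorted(missing)}")

    sig_up = (de["lfc"] > lfc_threshold) & (de["q"] < fdr_threshold)
    sig_dn = (de["lfc"] < -lfc_threshold) & (de["q"] < fdr_threshold)
    short = Shortlist(direction=direction)
    if direction == "up":
        hits = de[sig_up]
        for gene, sub in hits.groupby("gene_id", sort=False):
            short.provenance[gene] = list(map(tuple, sub[["stage", "fraction"]].to_numpy()))
        return short

    de_idx = de.set_index(["gene_id", "stage", "fraction"])
    dn_tbl = sig_dn.groupby(
        [de["gene_id"], de["fraction"]]
    ).sum().unstack(fill_value=0)
    up_tbl = sig_up.groupby(
        [de["gene_id"], de["fraction"]]
    ).any().unstack(fill_value=False)
    n_stages = len(NEURAL_STAGES)
    for gene in dn_tbl.index:
        prov = []
        for frac in FRACTIONS:
            other = FRACTIONS[1] if frac == FRACTIONS[0] else FRACTIONS[0]
            if dn_tbl.loc[gene, frac] == n_stages and not up_tbl.loc[gene, other]:
                prov.extend((s, frac) for s in NEURAL_STAGES)
        if prov:
            short.provenance[gene] = prov
    return short


# ---------------------------------------------------------------------------
# localization ratios

def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and p (chi-square approximation)."""
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction and BH
    adjustment across pairs."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    pos = 0
    for g in names:
        n = groups[g].size
        mean_rank[g] = ranks[pos:pos + n].mean()
        pos += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(names, 2):
        n1, n2 = groups[g1].size, groups[g2].size
        se = np.sqrt(var_unit * (1.0 / n1 + 1.0 / n2))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": g1, "group_b": g2, "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def cyto_nuclear_ratios(
    tpm_table: ExpressionTable,
    gene_classes: pd.Series,
    tpm_threshold: float = 0.1,
    normalizer_class: str = "coding_nonsrs",
    genes: pd.Index | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage normalized cytoplasmic/nuclear ratios and class tests.

    For each stage, raw_ratio = mean cytoplasmic TPM / mean nuclear TPM over
    replicates, restricted to genes whose stage-specific mean nuclear TPM
    exceeds ``tpm_threshold``; norm_ratio divides by that stage's median
    raw_ratio of the ``normalizer_class`` group.  Returns the ratio table
    and a per-stage test summary (Kruskal–Wallis + Dunn pairs).
    """
    gene_index = tpm_table.genes if genes is None else pd.Index(genes)
    classes = gene_classes.reindex(gene_index)
    ratio_rows = []
    test_rows = []
    for stage in STAGES:
        nuc = tpm_table.subset(stage=stage, fraction="nuclear").loc[gene_index].mean(axis=1)
        cyt = tpm_table.subset(stage=stage, fraction="cytoplasmic").loc[gene_index].mean(axis=1)
        ok = nuc > tpm_threshold
        n_dropped = int((~ok).sum())
        if n_dropped:
            warnings.warn(
                f"{stage}: {n_dropped} gene(s) below nuclear TPM threshold "
                "dropped from ratio analysis", stacklevel=2,
            )
        raw = (cyt[ok] / nuc[ok]).rename("raw_ratio")
        cls = classes[ok]
        norm_group = raw[cls == normalizer_class]
        if norm_group.empty:
            raise ValueError(
                f"{stage}: no {normalizer_class} genes pass the filter; "
                "normalizer undefined"
            )
        med = float(np.median(norm_group))
        df = pd.DataFrame(
            {"gene_id": raw.index, "stage": stage, "raw_ratio": raw.to_numpy(),
             "norm_ratio": raw.to_numpy() / med, "gene_class": cls.to_numpy()}
        )
        ratio_rows.append(df)

        groups = {
            c: df.loc[df["gene_class"] == c, "norm_ratio"].to_numpy()
            for c in ("coding_nonsrs", "coding_srs", "lnc_nonsrs", "lnc_srs")
            if (df["gene_class"] == c).sum() >= 2
        }
        if len(groups) >= 2:
            h, p = kruskal_wallis(list(groups.values()))
            dunn = dunn_posthoc(groups)
            dunn.insert(0, "stage", stage)
            dunn.insert(1, "kw_h", h)
            dunn.insert(2, "kw_p", p)
            test_rows.append(dunn)
    ratios = pd.concat(ratio_rows, ignore_index=True)
    tests = pd.concat(test_rows, ignore_index=True) if test_rows else pd.DataFrame()
    return ratios, tests
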