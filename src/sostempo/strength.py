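"""Intrinsic promoter-strength proxies and gene-context covariates.

The maximal expression rate of a repressed promoter (beta_max) is proxied by
the log2 fold change of the repressor-deletion strain over wild type in the
absence of damage; this module carries that proxy, basal RPKM, TU length and
replication-origin distance per promoter, and the Pearson correlation
between derepression strength and damage induction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation
from .diffexpr import CountMatrix


def beta_proxy(de_dlexa_vs_wt: pd.DataFrame, genes=None) -> pd.Series:
    """beta_max proxy: the derepression contrast's log2FC, passed through.

    ``genes`` restricts (and orders) the output; missing genes are an error.
    """
    s = de_dlexa_vs_wt["log2fc"]
    if genes is not None:
        missing = [g for g in genes if g not in s.index]
        if missing:
            raise KeyError(f"genes missing from derepression contrast: {missing}")
        s = s.loc[list(genes)]
    return s.rename("beta_proxy")


def basal_rpkm(
    cm: CountMatrix,
    gene_lengths: pd.Series,
    genotype: str = "WT",
    treatment: str = "none",
    timepoint: int = 0,
) -> pd.Series:
    """Reads per kb per million in the untreated reference, replicate-averaged.

    RPKM_gs = count / ((CDS length / 1e3) * (library size / 1e6)).
    """
    samples = cm.select(genotype, treatment, timepoint)
    if not samples:
        raise ValueError("no untreated reference samples found")
    lengths = gene_lengths.reindex(cm.gene_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all genes need positive lengths")
    sub = cm.counts[samples].to_numpy(dtype=float)
    libsize = sub.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("zero library size")
    rpkm = sub / (lengths.to_numpy()[:, None] / 1e3) / (libsize[None, :] / 1e6)
    return pd.Series(rpkm.mean(axis=1), index=cm.gene_ids, name="basal_rpkm")


def ori_distance(position: int, ori: int, genome_length: int) -> int:
    """Shortest arc between a CDS start and the replication origin."""
    d = abs(position - ori) % genome_length
    return min(d, genome_length - d)


def tu_length(tu_id: str, annotation: Annotation) -> int:
    """Span from the first CDS start to the last CDS end of the TU.

    Genes must be contiguous on one strand; a TU laid across the coordinate
    origin of the circular genome still yields a positive span < genome
    length.
    """
    members = annotation.tus()[tu_id]  # raises on mixed strands
    gl = annotation.genome_length
    first = members[0]
    last = members[-1]
    if first.strand == "+":
        span = (last.end - first.start) % gl
    else:
        span = (first.end - last.start) % gl
    if span == 0:
        span = gl
    return span


def pearson_r2(x, y) -> dict:
    """Pearson r with r^2, 95% CI on r (Fisher z) and a two-sided t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    n = x.size
    if n > 3 and abs(r) < 1:
        z = np.arctanh(r)
        hw = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    else:
        ci = (float("nan"), float("nan"))
    return {"r": float(r), "r2": float(r**2), "ci_low": ci[0], "ci_high": ci[1],
            "p": float(p)}


def strength_table(
    promoter_genes: pd.DataFrame,
    de_dlexa: pd.DataFrame,
    de_wt40: pd.DataFrame,
    cm: CountMatrix,
    annotation: Annotation,
) -> pd.DataFrame:
    """Per-promoter strength record for TU promoter genes.

    ``promoter_genes`` needs columns tu_id, gene_id (the TU's first gene in
    transcription direction) and temporal_class.
    """
    lengths = pd.Series(
        {g.gene_id: g.length for g in annotation}, name="cds_length"
    )
    rpkm = basal_rpkm(cm, lengths)
    rows = []
    for _, rec in promoter_genes.iterrows():
        gid, tu = rec["gene_id"], rec["tu_id"]
        g = annotation.get(gid)
        rows.append(
            {
                "tu_id": tu,
                "gene_id": gid,
                "temporal_class": rec["temporal_class"],
                "beta_proxy": float(de_dlexa.loc[gid, "log2fc"]),
                "damage_lfc": float(de_wt40.loc[gid, "log2fc"]),
                "basal_rpkm": float(rpkm[gid]),
                "tu_length": tu_length(tu, annotation),
                "ori_distance": ori_distance(
                    g.five_prime, annotation.ori, annotation.genome_length
                ),
            }
        )
    return pd.DataFrame(rows).set_index("tu_id")
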