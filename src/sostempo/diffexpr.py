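"""Differential expression for bacterial RNA-seq count matrices.

Normalisation is median-of-ratios against a geometric-mean pseudo-reference,
per-dataset dispersion is a common (shared) negative-binomial dispersion with
Var = mu + phi * mu^2, and two-group comparisons use a conditional NB exact
test on group sums (minimum-likelihood two-sided convention).  Genes are
called induced at log2FC > 1, p < 0.01 and BH-FDR < 0.1, all strict — the
thresholds used throughout the temporal-hierarchy analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

#: induction thresholds (strict inequalities)
LOG2FC_MIN = 1.0
P_MAX = 0.01
FDR_MAX = 0.1

GROUP_COLS = ["genotype", "treatment", "timepoint_min"]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample metadata.

    ``samples`` is indexed by sample id with columns genotype, treatment,
    timepoint_min and replicate; its index must match the count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample metadata index must match count columns")
        if self.counts.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in GROUP_COLS + ["replicate"] if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if self.samples[GROUP_COLS].isna().any().any():
            raise ValueError("incomplete sample metadata")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def select(self, genotype: str, treatment: str, timepoint: int) -> list[str]:
        m = self.samples
        mask = (
            (m["genotype"] == genotype)
            & (m["treatment"] == treatment)
            & (m["timepoint_min"] == timepoint)
        )
        return list(m.index[mask])

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample_id").to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta)


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with non-zero counts in every sample enter the per-gene
    geometric-mean reference.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has non-zero counts in all samples; cannot form a reference"
        )
    logx = np.log(x[allpos])
    logref = logx.mean(axis=1)
    logfac = np.median(logx - logref[:, None], axis=0)
    logfac -= logfac.mean()  # geometric mean 1
    return pd.Series(np.exp(logfac), index=counts.columns, name="size_factor")


def estimate_dispersion(cm: CountMatrix, group_cols: list[str] = GROUP_COLS) -> float:
    """Common NB dispersion phi from within-group method-of-moments.

    Per gene, on size-factor-normalised counts, within-group variances are
    pooled; phi_g = (s^2 - mu) / mu^2, and the returned phi is the median
    over informative genes, clipped below at 0.
    """
    sf = size_factors(cm)
    norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    groups = cm.samples.groupby(group_cols, observed=True).groups
    if not any(len(ix) >= 2 for ix in groups.values()):
        raise ValueError("need at least 2 replicates in at least one group")
    col_pos = {s: i for i, s in enumerate(cm.counts.columns)}
    ss = np.zeros(norm.shape[0])
    df = 0
    mu_acc = np.zeros(norm.shape[0])
    n_acc = 0
    for ix in groups.values():
        cols = [col_pos[s] for s in ix]
        sub = norm[:, cols]
        mu_acc += sub.sum(axis=1)
        n_acc += len(cols)
        if len(cols) >= 2:
            ss += sub.var(axis=1, ddof=1) * (len(cols) - 1)
            df += len(cols) - 1
    mu = mu_acc / n_acc
    s2 = ss / df
    ok = mu > 0
    if not ok.any():
        raise ValueError("all genes have zero mean; cannot estimate dispersion")
    phi_g = (s2[ok] - mu[ok]) / mu[ok] ** 2
    return float(max(0.0, np.median(phi_g)))


def nb_exact_test(
    counts_a,
    counts_b,
    phi: float,
    sf_a=None,
    sf_b=None,
) -> float:
    """Conditional NB exact test on the two group sums.

    Counts are scaled to a common effective library size with the supplied
    size factors and rounded to integer pseudo-counts.  With group sums
    S_a + S_b = N fixed, each sum is NB with mean proportional to its
    replicate number and dispersion phi divided by that number; the
    two-sided p-value sums the probabilities of all splits (a, b = N - a)
    no more likely than the observed one (minimum-likelihood convention).
    At phi = 0 this reduces to the binomial exact test.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if sf_a is not None or sf_b is not None:
        fa = np.ones(a.size) if sf_a is None else np.asarray(sf_a, dtype=float)
        fb = np.ones(b.size) if sf_b is None else np.asarray(sf_b, dtype=float)
        # common effective library = the median sample's library, so the
        # typical sample is left (nearly) unrounded and a rescaled outlier
        # sample does not inflate everyone's pseudo-counts
        scale = np.median(np.concatenate([fa, fb]))
        a = a / (fa / scale)
        b = b / (fb / scale)
    s_a = int(np.rint(a).sum())
    s_b = int(np.rint(b).sum())
    n = s_a + s_b
    if n == 0:
        return 1.0
    n_a, n_b = a.size, b.size
    mu = n / (n_a + n_b)
    k = np.arange(n + 1)
    if phi == 0:
        la = stats.poisson.logpmf(k, n_a * mu)
        lb = stats.poisson.logpmf(k, n_b * mu)
    else:
        r_a, r_b = n_a / phi, n_b / phi
        la = stats.nbinom.logpmf(k, r_a, r_a / (r_a + n_a * mu))
        lb = stats.nbinom.logpmf(k, r_b, r_b / (r_b + n_b * mu))
    joint = la + lb[::-1]
    obs = joint[s_a]
    keep = joint <= obs + 1e-12
    p = float(np.exp(logsumexp(joint[keep]) - logsumexp(joint)))
    return min(1.0, max(0.0, p))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample groups named by (genotype, treatment, timepoint)."""

    label: str
    treated: tuple[str, str, int]
    reference: tuple[str, str, int]

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse e.g. ``"WT:MMC:40 vs WT:none:0"``."""
        try:
            left, right = text.split(" vs ")
            gt, tr, tp = left.split(":")
            gr, rr, rp = right.split(":")
        except ValueError:
            raise ValueError(f"cannot parse contrast {text!r}") from None
        return cls(text, (gt, tr, int(tp)), (gr, rr, int(rp)))


def run_contrast(
    cm: CountMatrix,
    contrast: Contrast | str,
    phi: float | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene DE table (log2fc, p, q, induced) for one two-group contrast.

    log2FC compares mean normalised counts with a pseudo-count offset; the
    p-value comes from the NB exact test; q is BH-adjusted over all genes in
    the contrast.
    """
    if isinstance(contrast, str):
        contrast = Contrast.parse(contrast)
    treated = cm.select(*contrast.treated)
    reference = cm.select(*contrast.reference)
    if not treated or not reference:
        raise ValueError(
            f"contrast {contrast.label!r}: empty group "
            f"(treated n={len(treated)}, reference n={len(reference)})"
        )
    if set(treated) & set(reference):
        raise ValueError("contrast groups must be disjoint")
    sf = size_factors(cm)
    if phi is None:
        phi = estimate_dispersion(cm)
    ct = cm.counts[treated].to_numpy(dtype=float)
    cr = cm.counts[reference].to_numpy(dtype=float)
    sft = sf[treated].to_numpy()
    sfr = sf[reference].to_numpy()
    mean_t = (ct / sft).mean(axis=1)
    mean_r = (cr / sfr).mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_r + pseudocount))
    pvals = np.array(
        [
            nb_exact_test(ct[i], cr[i], phi, sft, sfr)
            for i in range(ct.shape[0])
        ]
    )
    q = bh_fdr(pvals)
    induced = (log2fc > LOG2FC_MIN) & (pvals < P_MAX) & (q < FDR_MAX)
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "contrast": contrast.label,
            "log2fc": log2fc,
            "p": pvals,
            "q": q,
            "induced": induced,
        }
    ).set_index("gene_id")


def write_de(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t")


def read_de(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
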