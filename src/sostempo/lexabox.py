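"""LexA operator (SOS box) analysis.

The *Caulobacter* LexA operator is a dyad of two GTTC half-sites separated by
a short spacer (consensus GTTC-N7-GTTC).  This module extracts promoter
windows, discovers the dyad motif with a seeded one-occurrence-per-sequence
(OOPS) expectation-maximisation, scores sites against the learned position
weight matrix, derives per-box features (distance to the CDS, spacer length
and GC), runs a one-hot PCA of box sequences, and compares feature
distributions between gene groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation, Gene, circular_slice, revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: promoter window relative to the CDS start: (bp upstream, bp downstream)
PROMOTER_WINDOW = (200, 75)

HALF_SITE = "GTTC"


def encode(seq: str) -> np.ndarray:
    """DNA string -> int array (A=0, C=1, G=2, T=3); rejects non-ACGT."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from None


@dataclass
class Pwm:
    """Position weight matrix over ACGT with log2-odds scoring.

    ``probs`` is a 4 x L column-stochastic matrix (rows in ACGT order);
    ``background`` the 0-order base frequencies the odds are taken against.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.background.shape != (4,):
            raise ValueError("PWM must be 4 x L with a length-4 background")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            raise ValueError("PWM probability columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs) - np.log2(self.background)[:, None]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def score(self, sequence: str, start: int) -> float:
        """Log2-odds score of the window ``sequence[start:start+L]``."""
        if start < 0 or start + self.length > len(sequence):
            raise ValueError("window does not fit in sequence")
        idx = encode(sequence[start : start + self.length])
        return float(self.log_odds[idx, np.arange(self.length)].sum())

    def scan(self, sequence: str) -> np.ndarray:
        """Log2-odds score at every start offset of ``sequence``."""
        idx = encode(sequence)
        return _scan_encoded(idx, self.log_odds)

    def reverse_complement(self) -> "Pwm":
        return replace(self, probs=self.probs[::-1, ::-1], background=self.background[::-1])

    @classmethod
    def from_sites(
        cls,
        sites: list[str],
        background: np.ndarray | None = None,
        pseudocount: float = 0.25,
    ) -> "Pwm":
        if not sites:
            raise ValueError("no sites to build a PWM from")
        L = len(sites[0])
        if any(len(s) != L for s in sites):
            raise ValueError("sites must all have the same length")
        counts = np.full((4, L), pseudocount)
        for s in sites:
            counts[encode(s), np.arange(L)] += 1
        if background is None:
            background = np.full(4, 0.25)
        return cls(counts / counts.sum(axis=0), background, pseudocount)

    def to_files(self, prefix: str | Path) -> None:
        """Write the position-probability matrix (TSV) and metadata (JSON)."""
        prefix = Path(prefix)
        df = pd.DataFrame(self.probs.T, columns=list(BASES))
        df.index.name = "position"
        df.to_csv(prefix.with_suffix(".tsv"), sep="\t")
        meta = {
            "consensus": self.consensus,
            "length": self.length,
            "pseudocount": self.pseudocount,
            "background": dict(zip(BASES, self.background.tolist())),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _scan_encoded(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    L = log_odds.shape[1]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    return log_odds[windows, np.arange(L)].sum(axis=1)


@dataclass
class LexABox:
    """A located LexA operator with score and derived features."""

    gene_id: str
    seq: str
    strand: str  # '+' = coding strand of the promoter's gene
    offset: int  # box start relative to CDS start (negative = upstream)
    score: float
    spacer_len: int | None = None
    spacer_gc: float | None = None
    distance_to_cds: int | None = None


def extract_promoters(
    annotation: Annotation,
    genome: str,
    window: tuple[int, int] = PROMOTER_WINDOW,
    genes: list[str] | None = None,
) -> dict[str, str]:
    """Promoter sequence per gene, 5'->3' on the coding strand.

    The window spans ``window[0]`` bp upstream and ``window[1]`` bp downstream
    of the CDS start, wrapping across the origin of the circular genome.
    """
    up, down = window
    if up + down > len(genome):
        raise ValueError("promoter window longer than genome")
    gene_ids = genes if genes is not None else [g.gene_id for g in annotation]
    out: dict[str, str] = {}
    for gid in gene_ids:
        g = annotation.get(gid)
        if g.strand == "+":
            seq = circular_slice(genome, g.start - up, g.start + down)
        else:
            seq = revcomp(circular_slice(genome, g.end - down, g.end + up))
        out[gid] = seq.upper()
    return out


def _dyad_seed_sites(
    seqs: dict[str, str],
    spacer_range: tuple[int, int],
    max_mismatch: int,
) -> list[tuple[int, str]]:
    """All windows matching HALF-N_k-HALF with <= max_mismatch per half-site.

    Returns (spacer length, window string) pairs over both strands.
    """
    half = np.frombuffer(HALF_SITE.encode(), dtype=np.uint8)
    hits: list[tuple[int, str]] = []
    for seq in seqs.values():
        for oriented in (seq, revcomp(seq)):
            arr = np.frombuffer(oriented.upper().encode(), dtype=np.uint8)
            mm = np.array(
                [
                    (np.lib.stride_tricks.sliding_window_view(arr, 4) != half).sum(axis=1)
                    if arr.size >= 4
                    else np.empty(0, int)
                ]
            )[0]
            ok = np.flatnonzero(mm <= max_mismatch)
            okset = set(ok.tolist())
            for k in range(spacer_range[0], spacer_range[1] + 1):
                L = 8 + k
                for i in ok:
                    j = i + 4 + k
                    if j in okset and i + L <= len(oriented):
                        hits.append((k, oriented[i : i + L]))
    return hits


@dataclass
class DiscoveryResult:
    pwm: Pwm
    boxes: dict[str, LexABox | None]
    n_iterations: int
    log_likelihood: float
    loglik_series: list[float] = None


def discover_boxes(
    promoters: dict[str, str],
    spacer_range: tuple[int, int] = (5, 9),
    max_mismatch: int = 1,
    pseudocount: float = 0.25,
    score_floor: float = 6.0,
    max_iter: int = 50,
    tol: float = 1e-4,
    upstream: int = PROMOTER_WINDOW[0],
) -> DiscoveryResult:
    """Discover the dyad operator in a promoter set.

    Procedure: (1) enumerate GTTC-N_k-GTTC windows (k in ``spacer_range``,
    <= ``max_mismatch`` mismatches per half-site, both strands); (2) seed a
    PWM of the modal dyad length from those windows (background = promoter
    base composition); (3) refine with one-occurrence-per-sequence EM until
    the relative log-likelihood gain drops below ``tol``; (4) report the best
    site per promoter, or ``None`` where the best site scores below
    ``score_floor`` (log2-odds).
    """
    if len(promoters) < 5:
        raise ValueError("need at least 5 promoter sequences for discovery")
    comp = np.zeros(4)
    for seq in promoters.values():
        idx = encode(seq)
        comp += np.bincount(idx, minlength=4)
    comp = (comp + comp[::-1]) / 2  # strand-symmetric background (dsDNA)
    background = comp / comp.sum()

    hits = _dyad_seed_sites(promoters, spacer_range, max_mismatch)
    if not hits:
        raise ValueError(
            "no dyad seed matches found; consider relaxing max_mismatch or the spacer range"
        )
    ks = np.array([k for k, _ in hits])
    k_mode = int(np.bincount(ks).argmax())
    sites = [w for k, w in hits if k == k_mode]
    pwm = Pwm.from_sites(sites, background=background, pseudocount=pseudocount)
    L = pwm.length

    # Pre-encode all windows of every promoter on both strands.
    per_seq: list[tuple[str, np.ndarray, np.ndarray]] = []  # (gene, windows, strands)
    for gid, seq in promoters.items():
        fwd = encode(seq)
        rev = encode(revcomp(seq))
        if fwd.size < L:
            raise ValueError(f"promoter of {gid} shorter than motif length {L}")
        wf = np.lib.stride_tricks.sliding_window_view(fwd, L)
        wr = np.lib.stride_tricks.sliding_window_view(rev, L)
        windows = np.vstack([wf, wr])
        strands = np.array([1] * len(wf) + [-1] * len(wr))
        per_seq.append((gid, windows, strands))

    log_bg = np.log(background)
    loglik = -np.inf
    lls: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_motif = np.log(pwm.probs)
        new_counts = np.full((4, L), pseudocount)
        ll = 0.0
        pos = np.arange(L)
        for _, windows, _ in per_seq:
            llr = (log_motif[windows, pos] - log_bg[windows]).sum(axis=1)
            m = llr.max()
            w = np.exp(llr - m)
            z = w / w.sum()
            ll += m + np.log(w.mean())
            for b in range(4):
                new_counts[b] += (z[:, None] * (windows == b)).sum(axis=0)
        pwm = Pwm(new_counts / new_counts.sum(axis=0), background, pseudocount)
        lls.append(ll)
        if ll - loglik < tol * abs(ll) + tol:
            loglik = ll
            break
        loglik = ll

    # Best site per promoter under the final PWM (log2-odds).
    boxes: dict[str, LexABox | None] = {}
    lo = pwm.log_odds
    pos = np.arange(L)
    for (gid, windows, strands), seq in zip(per_seq, promoters.values()):
        scores = lo[windows, pos].sum(axis=1)
        best = int(scores.argmax())
        if scores[best] < score_floor:
            boxes[gid] = None
            continue
        n_fwd = len(seq) - L + 1
        if strands[best] == 1:
            start_fwd = best
            site = seq[start_fwd : start_fwd + L]
            strand = "+"
        else:
            j = best - n_fwd
            start_fwd = len(seq) - j - L
            site = revcomp(seq[start_fwd : start_fwd + L])
            strand = "-"
        offset = start_fwd - upstream
        boxes[gid] = LexABox(gid, site, strand, offset, float(scores[best]))
    return DiscoveryResult(pwm, boxes, n_iter, float(loglik), lls)


def score_box(pwm: Pwm, sequence: str, start: int) -> float:
    """Log2-odds PWM score of the window starting at ``start``."""
    return pwm.score(sequence, start)


def box_features(box: LexABox, spacer_len: int | None = None) -> LexABox:
    """Fill distance-to-CDS, spacer length and spacer GC on a located box.

    Offsets are in coding-strand coordinates with the CDS start at 0, so the
    gap between the box 3' end and the CDS start is ``-offset - L``; a box
    ending immediately before the CDS start has distance 0, and boxes
    overlapping the CDS have negative distance.
    """
    L = len(box.seq)
    k = spacer_len if spacer_len is not None else L - 8
    if k < 0:
        raise ValueError("box shorter than two half-sites")
    spacer = box.seq[4 : 4 + k]
    gc = sum(1 for b in spacer.upper() if b in "GC") / k if k else 0.0
    return replace(
        box,
        spacer_len=k,
        spacer_gc=gc,
        distance_to_cds=-box.offset - L,
    )


@dataclass
class PcaResult:
    scores: np.ndarray  # n_boxes x n_components
    variance_explained: np.ndarray
    degenerate: bool


def onehot_pca(boxes: list[str]) -> PcaResult:
    """PCA of one-hot-encoded, equal-length box sequences.

    Sequences are one-hot encoded (4L columns), column-centred, and
    decomposed by SVD; scores are U*S and variance fractions the normalised
    squared singular values.  A set of identical sequences has zero total
    variance and is reported as degenerate.
    """
    if len(boxes) < 3:
        raise ValueError("need at least 3 boxes for PCA")
    L = len(boxes[0])
    if any(len(b) != L for b in boxes):
        raise ValueError("boxes must all have the same length")
    X = np.zeros((len(boxes), 4 * L))
    for i, b in enumerate(boxes):
        idx = encode(b)
        X[i, np.arange(L) * 4 + idx] = 1.0
    X -= X.mean(axis=0)
    if np.allclose(X, 0):
        k = min(X.shape)
        return PcaResult(np.zeros((len(boxes), k)), np.zeros(k), True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return PcaResult(U * S, S**2 / (S**2).sum(), False)


def compare_groups(
    values_a, values_b, method: str = "mann_whitney"
) -> tuple[float, float]:
    """Two-sample comparison: unpaired t or Mann-Whitney U.

    Mann-Whitney uses the exact permutation null (midranks, two-sided) when
    the smaller group has <= 8 observations and full enumeration is cheap,
    and the normal approximation with continuity correction otherwise.
    Returns ``(statistic, p)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method == "t_unpaired":
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("zero variance in both groups")
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return float(t), float(p)
    if method != "mann_whitney":
        raise ValueError(f"unknown method {method!r}")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    if min(na, nb) <= 8 and comb(na + nb, na) <= 50_000:
        centre = na * nb / 2
        d_obs = abs(u_obs - centre) - 1e-9
        hits = 0
        total = 0
        for pick in combinations(range(na + nb), na):
            u = ranks[list(pick)].sum() - na * (na + 1) / 2
            if abs(u - centre) >= d_obs:
                hits += 1
            total += 1
        return float(u_obs), hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def boxes_to_frame(boxes: dict[str, LexABox | None]) -> pd.DataFrame:
    rows = []
    for gid, box in boxes.items():
        if box is None:
            rows.append({"gene_id": gid, "has_box": False})
        else:
            rows.append(
                {
                    "gene_id": gid,
                    "has_box": True,
                    "seq": box.seq,
                    "strand": box.strand,
                    "offset": box.offset,
                    "score": box.score,
                    "spacer_len": box.spacer_len,
                    "spacer_gc": box.spacer_gc,
                    "distance_to_cds": box.distance_to_cds,
                }
            )
    return pd.DataFrame(rows)
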