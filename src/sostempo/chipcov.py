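"""ChIP coverage analysis on a circular genome.

Per-bp coverage tracks are scaled to reads-per-million, smoothed with a
circular Gaussian kernel, and reduced to promoter peak heights, summit
calls (local maxima with greedy separation), summit-to-gene assignments
within +/-100 bp of the CDS start, bound-promoter fractions, and
CDS-anchored meta-profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .annotation import Annotation, Gene, circular_distance
from .lexabox import PROMOTER_WINDOW


@dataclass
class CoverageTrack:
    """Per-bp values over the circular genome."""

    values: np.ndarray
    total_reads: float | None = None
    rpm: bool = False
    sigma: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    def __len__(self):
        return self.values.size


@dataclass
class PeakAssignment:
    summit: int
    height: float
    gene_id: str | None


def normalize_rpm(track: CoverageTrack | np.ndarray, total_reads: float) -> CoverageTrack:
    """Scale values by 1e6 / total mapped reads."""
    if total_reads <= 0:
        raise ValueError("total reads must be positive")
    values = track.values if isinstance(track, CoverageTrack) else np.asarray(track, float)
    sigma = track.sigma if isinstance(track, CoverageTrack) else 0.0
    return CoverageTrack(values * 1e6 / total_reads, total_reads, rpm=True, sigma=sigma)


def smooth_gaussian(track: CoverageTrack | np.ndarray, sigma: float) -> CoverageTrack:
    """Circular convolution with a unit-mass Gaussian truncated at 4 sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if isinstance(track, CoverageTrack):
        values, total, rpm = track.values, track.total_reads, track.rpm
    else:
        values, total, rpm = np.asarray(track, float), None, False
    if sigma == 0:
        return CoverageTrack(values.copy(), total, rpm, 0.0)
    sm = gaussian_filter1d(values, sigma, mode="wrap", truncate=4.0)
    return CoverageTrack(sm, total, rpm, sigma)


def promoter_peak_height(
    track: CoverageTrack,
    gene: Gene,
    genome_length: int | None = None,
    window: tuple[int, int] = PROMOTER_WINDOW,
) -> float:
    """Maximum track value within the gene's promoter window."""
    gl = genome_length or len(track)
    up, down = window
    p5 = gene.five_prime
    if gene.strand == "+":
        idx = (np.arange(p5 - up, p5 + down)) % gl
    else:
        idx = (np.arange(p5 - down + 1, p5 + up + 1)) % gl
    return float(track.values[idx].max())


def call_summits(
    track: CoverageTrack | np.ndarray,
    min_height: float,
    min_separation: int = 200,
) -> list[tuple[int, float]]:
    """Circular local maxima above ``min_height``, greedily thinned.

    Candidates are sorted by descending height and accepted only when at
    least ``min_separation`` bp (shortest arc) from every already-accepted
    summit.  Returns (position, height) pairs in descending height order.
    """
    v = track.values if isinstance(track, CoverageTrack) else np.asarray(track, float)
    n = v.size
    left = np.roll(v, 1)
    right = np.roll(v, -1)
    cand = np.flatnonzero((v >= left) & (v >= right) & (v >= min_height))
    order = cand[np.argsort(v[cand])[::-1]]
    accepted: list[tuple[int, float]] = []
    for i in order:
        if all(circular_distance(int(i), p, n) >= min_separation for p, _ in accepted):
            accepted.append((int(i), float(v[i])))
    return accepted


def assign_summits(
    summits: list[tuple[int, float]],
    annotation: Annotation,
    margin: int = 100,
    anchor: str = "start",
) -> list[PeakAssignment]:
    """Assign each summit to the gene whose CDS (start by default) it flanks.

    With ``anchor='start'`` a summit qualifies when within ``margin`` bp of
    the CDS start (5' end, strand-aware); ``anchor='span'`` accepts summits
    anywhere within the CDS extended by ``margin`` on both sides.  Ties go
    to the nearest CDS start.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if anchor not in ("start", "span"):
        raise ValueError("anchor must be 'start' or 'span'")
    gl = annotation.genome_length
    out = []
    for pos, height in summits:
        best: tuple[int, str] | None = None
        for g in annotation:
            d_start = circular_distance(pos, g.five_prime, gl)
            if anchor == "start":
                ok = d_start <= margin
            else:
                span_start = (g.start - margin) % gl
                rel = (pos - span_start) % gl
                ok = rel < g.length + 2 * margin
            if ok and (best is None or d_start < best[0]):
                best = (d_start, g.gene_id)
        out.append(PeakAssignment(pos, height, best[1] if best else None))
    return out


def fraction_bound(gene_set, assignments: list[PeakAssignment]) -> float:
    """Percentage of genes in ``gene_set`` with at least one assigned summit."""
    genes = set(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    bound = {a.gene_id for a in assignments if a.gene_id is not None}
    return 100.0 * len(genes & bound) / len(genes)


def meta_profile(
    track: CoverageTrack,
    annotation: Annotation,
    gene_set,
    flank: int = 500,
) -> dict[str, pd.DataFrame]:
    """Coding-strand-oriented coverage around CDS boundaries.

    Because CDS lengths vary, two anchored blocks are reported: positions
    -flank..+flank around the CDS start and around the CDS end, rows per
    gene, minus-strand genes flipped so positive positions always point
    into/downstream of the feature.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    gl = len(track)
    offsets = np.arange(-flank, flank + 1)
    blocks = {"start": [], "end": []}
    gene_ids = list(gene_set)
    for gid in gene_ids:
        g = annotation.get(gid)
        if g.strand == "+":
            anchors = {"start": g.start, "end": g.end - 1}
            for name, a in anchors.items():
                blocks[name].append(track.values[(a + offsets) % gl])
        else:
            anchors = {"start": g.end - 1, "end": g.start}
            for name, a in anchors.items():
                blocks[name].append(track.values[(a - offsets) % gl])
    return {
        name: pd.DataFrame(np.stack(rows), index=gene_ids, columns=offsets)
        for name, rows in blocks.items()
    }


def write_bedgraph(
    track: CoverageTrack | np.ndarray, path: str | Path, seqid: str = "chromosome"
) -> None:
    """4-column bedGraph (0-based half-open), equal-value runs merged."""
    v = track.values if isinstance(track, CoverageTrack) else np.asarray(track, float)
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [v.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{seqid}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(path: str | Path, genome_length: int | None = None) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["seqid", "start", "end", "value"])
    n = genome_length or int(df["end"].max())
    v = np.zeros(n)
    for s, e, val in zip(df["start"], df["end"], df["value"]):
        v[s:e] = val
    return CoverageTrack(v)
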