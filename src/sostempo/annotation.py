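"""Circular bacterial genome annotation: genes, transcription units, coordinates, I/O.

Coordinate contract used throughout the package: 0-based, half-open intervals
on the forward strand of a single circular replicon; all positional arithmetic
is modulo the genome length.  For a minus-strand gene the transcription start
(5' base of the CDS) is the base at index ``end - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGT, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def circular_slice(genome: str, start: int, end: int) -> str:
    """Extract ``genome[start:end)`` with wrap-around on a circular sequence.

    ``start`` may be negative or exceed the length; the extracted span must
    not be longer than the genome itself.
    """
    n = len(genome)
    span = end - start
    if span < 0 or span > n:
        raise ValueError(f"requested span {span} invalid for genome length {n}")
    start %= n
    end = start + span
    if end <= n:
        return genome[start:end]
    return genome[start:] + genome[: end - n]


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest arc distance between two positions on a circular genome."""
    d = abs(a - b) % length
    return min(d, length - d)


@dataclass(frozen=True)
class Gene:
    """A CDS on the circular genome (0-based, half-open, no wrap)."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    tu_id: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty/negative CDS for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genome coordinate of the first transcribed base of the CDS."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Annotation:
    """Gene set on one circular replicon plus the replication origin."""

    genes: list[Gene]
    genome_length: int
    ori: int = 0
    seqid: str = "chromosome"
    _by_id: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def get(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def tus(self) -> dict[str, list[Gene]]:
        """Genes grouped by TU, ordered in the direction of transcription."""
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.tu_id, []).append(g)
        for tu_id, members in out.items():
            strands = {g.strand for g in members}
            if len(strands) > 1:
                raise ValueError(f"TU {tu_id} has genes on both strands")
            members.sort(key=lambda g: g.start, reverse=(members[0].strand == "-"))
        return out

    def tu_promoter_gene(self, tu_id: str) -> Gene:
        """First gene of the TU in transcription direction (promoter-proximal)."""
        return self.tus()[tu_id][0]


def write_fasta(genome: str, path: str | Path, seqid: str = "chromosome") -> None:
    rec = SeqRecord(Seq(genome), id=seqid, description="circular")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> str:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"expected a single-replicon FASTA, got {len(recs)} records")
    return str(recs[0].seq).upper()


def write_gff3(annotation: Annotation, path: str | Path) -> None:
    """Write CDS features with locus_tag and tu_id attributes, plus the ori."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.seqid} 1 {annotation.genome_length}\n")
        fh.write(
            "\t".join(
                [
                    annotation.seqid,
                    "sostempo",
                    "rep_origin",
                    str(annotation.ori + 1),
                    str(annotation.ori + 1),
                    ".",
                    "+",
                    ".",
                    "ID=oriC",
                ]
            )
            + "\n"
        )
        for g in sorted(annotation.genes, key=lambda g: g.start):
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id};tu_id={g.tu_id}"
            fh.write(
                "\t".join(
                    [
                        annotation.seqid,
                        "sostempo",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path, genome_length: int | None = None) -> Annotation:
    """Read an annotation written by :func:`write_gff3` (GFF3, 1-based closed)."""
    genes: list[Gene] = []
    ori = 0
    seqid = "chromosome"
    seqlen = genome_length
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                seqid, seqlen = parts[1], int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            ftype, start, end, strand, attrs = cols[2], int(cols[3]), int(cols[4]), cols[6], cols[8]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "rep_origin":
                ori = start - 1
                continue
            if ftype != "CDS":
                continue
            gid = attr.get("locus_tag") or attr.get("ID")
            genes.append(Gene(gid, start - 1, end, strand, attr.get("tu_id", gid)))
    if seqlen is None:
        raise ValueError("genome length not found in GFF3 and not provided")
    return Annotation(genes, seqlen, ori=ori, seqid=seqid)
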