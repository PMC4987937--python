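"""Sequence and gene-model I/O.

Genomes are held in memory as plain uppercase DNA strings over {A,C,G,T,N};
coordinates are 0-based half-open throughout the library, and strand-aware
extraction returns the sequence 5'->3' on the requested strand. Gene models
come in as BED12 records (blocks become exons, the thick interval becomes the
CDS). Human-readable reports print 1-based inclusive coordinates; everything
internal stays BED-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

# IUPAC complement table; used for both concrete DNA and degenerate patterns.
_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVN",
    "TGCAAYRSWMKVHDBN",
)


class SequenceError(ValueError):
    """Malformed sequence input (bad FASTA/BED, bad alphabet, bad coordinates)."""


@dataclass(frozen=True)
class Region:
    """Half-open genomic interval [start, end) on one strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise SequenceError(
                f"invalid region {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise SequenceError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """In-memory genome: contig name -> uppercase DNA string over A,C,G,T,N."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise SequenceError(f"contig {name!r} is empty")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise SequenceError(
                    f"contig {name!r} contains characters outside A/C/G/T/N: "
                    f"{sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences


@dataclass
class GeneModel:
    """One transcript: span, ordered exons, optional CDS interval.

    Exons are stored 5'->3' on the transcript strand (so genomic-descending for
    minus-strand models). ``tss`` is the reference coordinate of the first
    transcribed base: ``start`` on plus-strand models, ``end - 1`` on minus.
    """

    name: str
    region: Region
    exons: list[Region]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    @property
    def strand(self) -> str:
        return self.region.strand

    @property
    def tss(self) -> int:
        return self.region.start if self.strand == "+" else self.region.end - 1

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA or IUPAC-degenerate string."""
    seq = seq.upper().replace("U", "T")
    unknown = set(seq) - set("ACGTRYSWKMBDHVN")
    if unknown:
        raise SequenceError(f"cannot complement unknown characters {sorted(unknown)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Sequences are uppercased; any character outside A/C/G/T/N (including IUPAC
    ambiguity codes and soft-mask lowercase after folding) is replaced by N and
    a single warning with the substitution count is logged. Duplicate headers
    and empty files are fatal.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    n_subst = 0
    for rec in records:
        name = rec.id
        if name in sequences:
            raise SequenceError(f"{path}: duplicate FASTA header {name!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise SequenceError(f"{path}: contig {name!r} is empty")
        cleaned = []
        for ch in seq:
            if ch in DNA_ALPHABET:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_subst += 1
        sequences[name] = "".join(cleaned)
    if n_subst:
        log.warning(
            "%s: replaced %d non-ACGTN character(s) with N", path.name, n_subst
        )
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    """Write a genome back to FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract(genome: Genome, region: Region) -> str:
    """Strand-aware subsequence: minus-strand regions come back reverse-complemented."""
    if region.contig not in genome:
        raise SequenceError(f"unknown contig {region.contig!r}")
    contig_len = len(genome.sequences[region.contig])
    if region.end > contig_len:
        raise SequenceError(
            f"region {region.contig}:{region.start}-{region.end} exceeds contig "
            f"length {contig_len}"
        )
    sub = genome.sequences[region.contig][region.start : region.end]
    return revcomp(sub) if region.strand == "-" else sub


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Parse BED12 gene models (blocks -> exons, thick interval -> CDS).

    Block arithmetic is validated: the first block must start at chromStart and
    the last must end at chromEnd, else the offending line number is reported.
    """
    path = Path(path)
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise SequenceError(
                    f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            contig = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise SequenceError(
                    f"{path}:{lineno}: blockCount={block_count} does not match "
                    f"blockSizes/blockStarts lengths"
                )
            exons = []
            for bs, sz in zip(starts, sizes):
                exons.append(Region(contig, start + bs, start + bs + sz, strand))
            if exons[0].start != start or exons[-1].end != end:
                raise SequenceError(
                    f"{path}:{lineno}: block arithmetic inconsistent with "
                    f"chromStart/chromEnd for record {name!r}"
                )
            for a, b in zip(exons, exons[1:]):
                if b.start < a.end:
                    raise SequenceError(
                        f"{path}:{lineno}: overlapping or unsorted blocks in {name!r}"
                    )
            if strand == "-":
                exons = exons[::-1]  # transcript 5'->3'
            cds_start = cds_end = None
            if thick_end > thick_start:
                if not (start <= thick_start < thick_end <= end):
                    raise SequenceError(
                        f"{path}:{lineno}: thick interval outside transcript span"
                    )
                cds_start, cds_end = thick_start, thick_end
            models.append(
                GeneModel(
                    name=name,
                    region=Region(contig, start, end, strand),
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return models


def write_bed6(rows: Iterable[tuple[str, int, int, str, int | float, str]], path: str | Path) -> None:
    """Write BED6 rows (contig, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
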