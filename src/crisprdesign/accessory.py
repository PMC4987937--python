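"""Validation accessories: restriction-site annotation and flanking primers.

Restriction sites are found by scanning IUPAC recognition motifs over both
strands of an amplicon; palindromic motifs are reported once per position. A
site is flagged unique when its enzyme cuts the amplicon exactly once —
unique sites overlapping the cut position are the useful ones for RFLP
validation, so that overlap is reported too.

Primer design is a self-contained exhaustive scan: all left/right primers in
the requested length and Tm bands whose product brackets the cut site with a
safety margin, ranked by Tm balance and then closeness of the product size to
the middle of the requested range. Melting temperatures come from
nearest-neighbor thermodynamics (SantaLucia 2004 unified parameters with salt
correction, via Biopython's MeltingTemp). The designer deliberately skips
secondary-structure screening; an external Primer3-compatible engine can be
plugged in through the same function signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from Bio.SeqUtils import MeltingTemp

from .effectors import PamError, iupac_match
from .seqio import Genome, Region, SequenceError, revcomp

log = logging.getLogger(__name__)

DEFAULT_PRIMER_LEN = (18, 25)
DEFAULT_PRIMER_TM = (57.0, 63.0)
DEFAULT_PRODUCT_SIZE = (200, 600)
DEFAULT_MIN_MARGIN = 50

MIN_PRIMER_LEN, MAX_PRIMER_LEN = 10, 40


@dataclass(frozen=True)
class RestrictionSite:
    enzyme: str
    motif: str
    pos: int  # amplicon coordinate of the motif's leftmost base
    strand: str
    unique_in_amplicon: bool
    overlaps_cut: bool = False


@dataclass(frozen=True)
class PrimerPair:
    left_seq: str
    right_seq: str
    left_tm: float
    right_tm: float
    product_size: int
    product_region: Region


def load_enzymes(path: str | Path | None = None) -> dict[str, str]:
    """Enzyme name -> IUPAC motif table (bundled ~20-enzyme resource by default)."""
    if path is not None:
        text = Path(path).read_text()
    else:
        text = resources.files("crisprdesign.resources").joinpath("enzymes.tsv").read_text()
    enzymes: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, _, motif = line.partition("\t")
        enzymes[name.strip()] = motif.strip().upper()
    return enzymes


def find_restriction_sites(
    amplicon: str,
    enzymes: dict[str, str],
    cut_pos: Optional[int] = None,
) -> list[RestrictionSite]:
    """All IUPAC motif matches on both strands of an amplicon.

    Palindromic motifs (motif == its reverse complement as a pattern) are
    reported once per position on the '+' strand. Malformed motifs skip the
    enzyme with a warning rather than aborting the scan. ``cut_pos`` (amplicon
    coordinate) flags sites overlapping the modeled cut for RFLP use.
    """
    amplicon = amplicon.upper()
    sites: list[RestrictionSite] = []
    for name, motif in sorted(enzymes.items()):
        try:
            rc = revcomp(motif)
        except SequenceError:
            log.warning("skipping enzyme %s: malformed motif %r", name, motif)
            continue
        m = len(motif)
        if m > len(amplicon):
            continue
        matches: list[tuple[int, str]] = []
        try:
            for i in range(len(amplicon) - m + 1):
                window = amplicon[i : i + m]
                if iupac_match(motif, window):
                    matches.append((i, "+"))
                elif rc != motif and iupac_match(rc, window):
                    matches.append((i, "-"))
        except PamError:
            log.warning("skipping enzyme %s: malformed motif %r", name, motif)
            continue
        unique = len(matches) == 1
        for pos, strand in matches:
            overlaps = cut_pos is not None and pos <= cut_pos < pos + m
            sites.append(RestrictionSite(name, motif, pos, strand, unique, overlaps))
    sites.sort(key=lambda s: (s.pos, s.enzyme, s.strand))
    return sites


def melting_temp(primer: str) -> float:
    """Nearest-neighbor duplex melting temperature in degrees C.

    SantaLucia (2004) unified NN parameters with the SantaLucia (1998)
    entropy salt correction at 50 mM Na+ and 25 nM strand concentrations
    (Biopython Tm_NN defaults). Monotone-increasing in GC content at fixed
    length; identical for a primer and its reverse complement.
    """
    primer = primer.upper()
    if not MIN_PRIMER_LEN <= len(primer) <= MAX_PRIMER_LEN:
        raise ValueError(
            f"primer length {len(primer)} outside [{MIN_PRIMER_LEN}, {MAX_PRIMER_LEN}]"
        )
    if set(primer) - set("ACGT"):
        raise ValueError("primer must be concrete ACGT")
    return float(MeltingTemp.Tm_NN(primer))


def design_primers(
    genome: Genome,
    contig: str,
    cut_pos: int,
    primer_len: tuple[int, int] = DEFAULT_PRIMER_LEN,
    tm_range: tuple[float, float] = DEFAULT_PRIMER_TM,
    product_size: tuple[int, int] = DEFAULT_PRODUCT_SIZE,
    min_margin: int = DEFAULT_MIN_MARGIN,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Exhaustively scan flanking primers bracketing the cut site.

    The left primer's 3' end must sit at least ``min_margin`` bp left of the
    cut, the right primer's 3' end at least ``min_margin`` bp right of it
    (right primer reported 5'->3' on the '-' strand). Pairs are ranked by
    |Tm_left - Tm_right|, then |product - midpoint of requested range|, then
    genomic position; at most ``max_pairs`` are returned. An empty list means
    the constraints are unsatisfiable on this locus.
    """
    if contig not in genome:
        raise SequenceError(f"unknown contig {contig!r}")
    seq = genome.sequences[contig]
    n = len(seq)
    if not 0 <= cut_pos < n:
        raise SequenceError(f"cut position {cut_pos} outside contig {contig!r}")
    pmin, pmax = product_size
    if pmax < 2 * min_margin + 2 * primer_len[0]:
        return []
    if cut_pos < min_margin or n - cut_pos < min_margin:
        raise SequenceError(
            f"cut site {contig}:{cut_pos} is within {min_margin} bp of a contig end"
        )
    lo = max(0, cut_pos - pmax)
    hi = min(n, cut_pos + pmax)

    def admissible(start: int, length: int, strand: str):
        sub = seq[start : start + length]
        if set(sub) - set("ACGT"):
            return None
        s = sub if strand == "+" else revcomp(sub)
        tm = melting_temp(s)
        if not tm_range[0] <= tm <= tm_range[1]:
            return None
        return s, tm

    lefts = []  # (start, length, seq, tm); 3' end = start+length
    for length in range(primer_len[0], primer_len[1] + 1):
        for start in range(lo, cut_pos - min_margin - length + 1):
            got = admissible(start, length, "+")
            if got:
                lefts.append((start, length, *got))
    rights = []  # 3' end on '-' strand = start (leftmost base)
    for length in range(primer_len[0], primer_len[1] + 1):
        for start in range(cut_pos + min_margin, hi - length + 1):
            got = admissible(start, length, "-")
            if got:
                rights.append((start, length, *got))
    mid = (pmin + pmax) / 2
    band_mid = (tm_range[0] + tm_range[1]) / 2
    # cap each side before pairing so the cross product stays tractable;
    # keep the primers closest to the Tm band centre (deterministic ties)
    cap = 250
    if len(lefts) > cap:
        lefts = sorted(lefts, key=lambda t: (abs(t[3] - band_mid), t[0], t[1]))[:cap]
    if len(rights) > cap:
        rights = sorted(rights, key=lambda t: (abs(t[3] - band_mid), t[0], t[1]))[:cap]
    pairs = []
    for ls, ll, lseq, ltm in lefts:
        for rs, rl, rseq, rtm in rights:
            size = rs + rl - ls
            if not pmin <= size <= pmax:
                continue
            pairs.append(
                PrimerPair(
                    left_seq=lseq,
                    right_seq=rseq,
                    left_tm=round(ltm, 2),
                    right_tm=round(rtm, 2),
                    product_size=size,
                    product_region=Region(contig, ls, rs + rl),
                )
            )
    pairs.sort(
        key=lambda p: (
            abs(p.left_tm - p.right_tm),
            abs(p.product_size - mid),
            p.product_region.start,
            p.product_size,
        )
    )
    return pairs[:max_pairs]
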