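"""Guide enumeration: scan regions on both strands for PAM-adjacent targets.

A candidate is emitted at every position where the PAM pattern matches next to
a full-length protospacer, with both the protospacer and the PAM lying fully
inside the selected region. The protospacer is always reported 5'->3' as the
sgRNA spacer would read; for 3'-anchored PAMs the PAM follows it, for
5'-anchored PAMs it precedes it. The scoring context window may extend past
the contig and is then N-padded with ``partial_context`` set — edge targets
are marked, never silently dropped.

Region modes resolve a gene model to sub-regions: whole transcript, CDS, 5'/3'
UTR, splice-junction flanks, a single exon, or a promoter window around the
TSS. Mode windows (splice flank 20 bp; promoter 2000 bp up / 500 bp down) are
documented defaults, overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .effectors import FIVE_PRIME, THREE_PRIME, PamSpec, iupac_match
from .seqio import GeneModel, Genome, Region, SequenceError, revcomp

DEFAULT_SPLICE_FLANK = 20
DEFAULT_PROMOTER_UP = 2000
DEFAULT_PROMOTER_DOWN = 500
DEFAULT_CONTEXT = (4, 3)  # bp beyond the protospacer+PAM unit: (5' side, 3' side)


@dataclass(frozen=True)
class GuideCandidate:
    """One enumerated target site.

    ``proto_start``/``proto_end`` bound the protospacer in reference
    coordinates regardless of strand; ``protospacer`` and ``pam_seq`` read
    5'->3' in guide orientation. ``context`` is the physical sequence window
    around the protospacer+PAM unit in guide orientation; ``pad_left`` /
    ``pad_right`` count N bases appended where the window ran off the contig.
    ``cut_pos`` is the reference coordinate immediately 3' (reference sense)
    of the modeled cut.
    """

    id: str
    contig: str
    strand: str
    proto_start: int
    proto_end: int
    protospacer: str
    pam_seq: str
    cut_pos: int
    context: str
    pad_left: int = 0
    pad_right: int = 0

    @property
    def partial_context(self) -> bool:
        return self.pad_left > 0 or self.pad_right > 0

    @property
    def location_1based(self) -> str:
        return f"{self.contig}:{self.proto_start + 1}-{self.proto_end}"


@dataclass(frozen=True)
class RegionMode:
    """Sub-region selection for a gene model."""

    mode: str = "whole"  # whole|cds|utr5|utr3|splice|exon|promoter
    exon_index: int = 1  # 1-based, transcript orientation
    splice_flank: int = DEFAULT_SPLICE_FLANK
    promoter_up: int = DEFAULT_PROMOTER_UP
    promoter_down: int = DEFAULT_PROMOTER_DOWN

    def __post_init__(self) -> None:
        if self.mode not in ("whole", "cds", "utr5", "utr3", "splice", "exon", "promoter"):
            raise ValueError(f"unknown region mode {self.mode!r}")
        if min(self.splice_flank, self.promoter_up, self.promoter_down) <= 0:
            raise ValueError("mode windows must be positive")
        if self.exon_index < 1:
            raise ValueError("exon index is 1-based")


def _merge(regions: list[Region]) -> list[Region]:
    """Sort and merge overlapping/adjacent same-strand regions."""
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.contig, r.start, r.end))
    merged = [regions[0]]
    for r in regions[1:]:
        last = merged[-1]
        if r.contig == last.contig and r.start <= last.end:
            if r.end > last.end:
                merged[-1] = replace(last, end=r.end)
        else:
            merged.append(r)
    return merged


def _clip(contig: str, start: int, end: int, strand: str, contig_len: Optional[int]) -> Optional[Region]:
    start = max(0, start)
    if contig_len is not None:
        end = min(end, contig_len)
    if start >= end:
        return None
    return Region(contig, start, end, strand)


def resolve_region(
    model: GeneModel, mode: RegionMode, contig_length: Optional[int] = None
) -> list[Region]:
    """Resolve a region mode against a gene model into disjoint genomic regions.

    Returned regions carry the model's strand; coordinates ascend genomically.
    Windows are clipped at the contig boundaries (position 0, and
    ``contig_length`` when given).
    """
    contig = model.region.contig
    strand = model.strand
    exons_asc = sorted(model.exons, key=lambda e: e.start)

    if mode.mode == "whole":
        return [model.region]

    if mode.mode in ("cds", "utr5", "utr3") and not model.has_cds:
        raise SequenceError(
            f"mode {mode.mode!r} needs a CDS interval but model {model.name!r} has none"
        )

    out: list[Region] = []
    if mode.mode == "cds":
        for e in exons_asc:
            s, t = max(e.start, model.cds_start), min(e.end, model.cds_end)
            if s < t:
                out.append(Region(contig, s, t, strand))
    elif mode.mode in ("utr5", "utr3"):
        # genomic-left exon parts before cds_start, genomic-right after cds_end
        left_is_5p = strand == "+"
        want_left = (mode.mode == "utr5") == left_is_5p
        for e in exons_asc:
            if want_left:
                s, t = e.start, min(e.end, model.cds_start)
            else:
                s, t = max(e.start, model.cds_end), e.end
            if s < t:
                out.append(Region(contig, s, t, strand))
    elif mode.mode == "splice":
        # internal boundaries: every exon edge except the transcript's two ends
        boundaries: list[int] = []
        for i, e in enumerate(exons_asc):
            if i > 0:
                boundaries.append(e.start)
            if i < len(exons_asc) - 1:
                boundaries.append(e.end)
        for b in boundaries:
            r = _clip(contig, b - mode.splice_flank, b + mode.splice_flank, strand, contig_length)
            if r is not None:
                out.append(r)
    elif mode.mode == "exon":
        if mode.exon_index > len(model.exons):
            raise SequenceError(
                f"model {model.name!r} has {len(model.exons)} exon(s); "
                f"exon {mode.exon_index} requested"
            )
        out.append(model.exons[mode.exon_index - 1])
    elif mode.mode == "promoter":
        tss = model.tss
        if strand == "+":
            r = _clip(contig, tss - mode.promoter_up, tss + mode.promoter_down, strand, contig_length)
        else:
            r = _clip(contig, tss - mode.promoter_down + 1, tss + mode.promoter_up + 1, strand, contig_length)
        if r is None:
            raise SequenceError(f"promoter window for {model.name!r} is empty after clipping")
        out.append(r)
    return _merge(out)


def _window(contig_seq: str, start: int, end: int) -> tuple[str, int, int]:
    """Contig substring with N-padding outside [0, len); returns (seq, pad_lo, pad_hi)."""
    n = len(contig_seq)
    pad_lo = max(0, -start)
    pad_hi = max(0, end - n)
    core = contig_seq[max(0, start) : min(end, n)]
    return "N" * pad_lo + core + "N" * pad_hi, pad_lo, pad_hi


def _site_at(
    contig: str,
    contig_seq: str,
    pam: PamSpec,
    guide_len: int,
    strand: str,
    proto_start: int,
    context: tuple[int, int],
    cut_offset: int,
) -> Optional[GuideCandidate]:
    """Build a candidate with protospacer at [proto_start, proto_start+guide_len), or None."""
    p = len(pam)
    proto_end = proto_start + guide_len
    n = len(contig_seq)
    # genomic span of the PAM
    pam_left = (pam.anchor == THREE_PRIME) == (strand == "+")
    if pam_left:
        pam_s, pam_e = proto_end, proto_end + p
    else:
        pam_s, pam_e = proto_start - p, proto_start
    unit_s, unit_e = min(proto_start, pam_s), max(proto_end, pam_e)
    if unit_s < 0 or unit_e > n:
        return None
    proto_ref = contig_seq[proto_start:proto_end]
    pam_ref = contig_seq[pam_s:pam_e]
    if "N" in proto_ref or "N" in pam_ref:
        return None
    protospacer = proto_ref if strand == "+" else revcomp(proto_ref)
    pam_seq = pam_ref if strand == "+" else revcomp(pam_ref)
    if not iupac_match(pam.pattern, pam_seq):
        return None
    # modeled cut position (reference coordinate)
    if pam.anchor == THREE_PRIME:
        cut_pos = proto_end - cut_offset if strand == "+" else proto_start + cut_offset
    else:
        cut_pos = proto_start + cut_offset if strand == "+" else proto_end - cut_offset
    up, down = context
    if strand == "+":
        ctx, pad_lo, pad_hi = _window(contig_seq, unit_s - up, unit_e + down)
        pad_left, pad_right = pad_lo, pad_hi
    else:
        ctx, pad_lo, pad_hi = _window(contig_seq, unit_s - down, unit_e + up)
        ctx = revcomp(ctx)
        pad_left, pad_right = pad_hi, pad_lo
    return GuideCandidate(
        id=f"{contig}_{proto_start}_{strand}",
        contig=contig,
        strand=strand,
        proto_start=proto_start,
        proto_end=proto_end,
        protospacer=protospacer,
        pam_seq=pam_seq,
        cut_pos=cut_pos,
        context=ctx,
        pad_left=pad_left,
        pad_right=pad_right,
    )


def enumerate_guides(
    genome: Genome,
    regions: list[Region],
    pam: PamSpec,
    guide_len: int,
    context: tuple[int, int] = DEFAULT_CONTEXT,
    cut_offset: int = 3,
) -> list[GuideCandidate]:
    """Emit every guide candidate in the given regions, both strands.

    Both the protospacer and the PAM must lie fully inside a region.
    Overlapping candidates are all kept; duplicates arising from overlapping
    regions are collapsed by (contig, proto_start, strand). Order is
    deterministic: (contig, proto_start, strand) with '+' before '-'.
    """
    if guide_len < 10:
        raise ValueError(f"guide length must be >= 10, got {guide_len}")
    p = len(pam)
    seen: set[tuple[str, int, str]] = set()
    out: list[GuideCandidate] = []
    for region in regions:
        if region.contig not in genome:
            raise SequenceError(f"unknown contig {region.contig!r}")
        contig_seq = genome.sequences[region.contig]
        if region.end > len(contig_seq):
            raise SequenceError(
                f"region {region.contig}:{region.start}-{region.end} exceeds contig"
            )
        for strand in ("+", "-"):
            pam_left = (pam.anchor == THREE_PRIME) == (strand == "+")
            # protospacer starts such that protospacer+PAM fit inside the region
            lo = region.start + (0 if pam_left else p)
            hi = region.end - guide_len - (p if pam_left else 0)
            for proto_start in range(lo, hi + 1):
                key = (region.contig, proto_start, strand)
                if key in seen:
                    continue
                cand = _site_at(
                    region.contig, contig_seq, pam, guide_len, strand,
                    proto_start, context, cut_offset,
                )
                if cand is not None:
                    seen.add(key)
                    out.append(cand)
    out.sort(key=lambda c: (c.contig, c.proto_start, c.strand))
    return out
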