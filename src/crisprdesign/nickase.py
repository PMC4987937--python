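"""Paired Cas9-nickase design.

A double-strand break from two nickases requires opposite-strand guides in
PAM-out orientation (PAMs on the outer ends of the paired site) binding
within a bounded distance of each other; the accepted window defaults to
10-31 bp, bounds inclusive. The pair offset is defined as the gap between the
two PAM-distal protospacer edges: with the minus-strand guide at genomic left
and the plus-strand guide at genomic right,

    offset = right.proto_start - left.proto_end

and the reported break region is exactly that inter-protospacer gap. This
measuring convention is stated here once and used everywhere, including
output headers.

Paired off-targets are genomic locations where off-target hits of the two
guides (either guide on either side) again sit opposite-strand, PAM-out and
within a configurable offset window, so that two nicks could join into an
unintended DSB.
"""

from __future__ import annotations

from dataclasses import dataclass

from .effectors import THREE_PRIME
from .offtarget import OffTargetHit, SiteIndex, find_offtargets
from .scan import GuideCandidate
from .seqio import Region

DEFAULT_MIN_OFFSET = 10
DEFAULT_MAX_OFFSET = 31


class NickaseError(ValueError):
    """Nickase mode misuse (e.g. 5'-anchored effector)."""


@dataclass(frozen=True)
class NickasePair:
    """PAM-out opposite-strand guide pair with its inter-nick gap."""

    guide_left: GuideCandidate  # '-' strand, PAM at genomic left
    guide_right: GuideCandidate  # '+' strand, PAM at genomic right
    offset: int

    @property
    def break_region(self) -> Region:
        return Region(
            self.guide_left.contig,
            self.guide_left.proto_end,
            self.guide_right.proto_start,
        )


@dataclass(frozen=True)
class PairedOffTarget:
    """Opposite-strand, PAM-out pairing of two single-guide off-target hits."""

    hit_left: OffTargetHit  # '-' strand, genomic left
    hit_right: OffTargetHit  # '+' strand, genomic right
    offset: int

    @property
    def total_mismatches(self) -> int:
        return self.hit_left.mismatches + self.hit_right.mismatches


def pair_nicks(
    candidates: list[GuideCandidate],
    min_offset: int = DEFAULT_MIN_OFFSET,
    max_offset: int = DEFAULT_MAX_OFFSET,
    anchor: str = THREE_PRIME,
) -> list[NickasePair]:
    """All PAM-out opposite-strand pairs with offset in [min, max], inclusive.

    Requires a 3'-anchored (Cas9-type) effector: with the PAM 3' of the
    spacer, a minus-strand guide carries its PAM at genomic left and a
    plus-strand guide at genomic right, so left='-' + right='+' is PAM-out.
    Each candidate may appear in multiple pairs. Order is deterministic by
    (left start, right start).
    """
    if anchor != THREE_PRIME:
        raise NickaseError(
            "nickase pairing requires a 3'-anchored (Cas9-type) effector; "
            "5'-anchored effectors are not supported in this mode"
        )
    minus = sorted(
        (c for c in candidates if c.strand == "-"), key=lambda c: c.proto_start
    )
    plus = sorted(
        (c for c in candidates if c.strand == "+"), key=lambda c: c.proto_start
    )
    pairs = []
    for left in minus:
        for right in plus:
            if right.contig != left.contig:
                continue
            offset = right.proto_start - left.proto_end
            if min_offset <= offset <= max_offset:
                pairs.append(NickasePair(left, right, offset))
    pairs.sort(key=lambda p: (p.guide_left.contig, p.guide_left.proto_start, p.guide_right.proto_start))
    return pairs


def paired_offtargets(
    pair: NickasePair,
    index: SiteIndex,
    per_nick_max_mm: int = 3,
    ot_min_offset: int = DEFAULT_MIN_OFFSET,
    ot_max_offset: int = DEFAULT_MAX_OFFSET,
) -> list[PairedOffTarget]:
    """Off-target half-site pairings that could produce an unintended DSB.

    Both guides' single-guide off-target hit lists are paired exhaustively
    (either guide may take either side); a pairing is kept when the two hits
    are on the same contig, opposite strands, PAM-out, and the offset lies in
    the configured window. The on-target pair itself never appears because
    each guide's own locus is already excluded from its hit list.
    """
    hits_a = find_offtargets(pair.guide_left, index, per_nick_max_mm)
    hits_b = find_offtargets(pair.guide_right, index, per_nick_max_mm)
    guide_len = index.guide_len
    on_target = (
        (pair.guide_left.contig, pair.guide_left.proto_start, "-"),
        (pair.guide_right.contig, pair.guide_right.proto_start, "+"),
    )
    out = []
    seen: set[tuple] = set()
    for ha, hb in ((x, y) for x in hits_a for y in hits_b):
        if ha.contig != hb.contig or ha.strand == hb.strand:
            continue
        left, right = (ha, hb) if ha.strand == "-" else (hb, ha)
        offset = right.proto_start - (left.proto_start + guide_len)
        if not ot_min_offset <= offset <= ot_max_offset:
            continue
        key = (left.locus, right.locus)
        if key in seen or key == on_target:
            continue
        seen.add(key)
        out.append(PairedOffTarget(left, right, offset))
    out.sort(key=lambda p: (p.hit_left.contig, p.hit_left.proto_start, p.hit_right.proto_start))
    return out
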