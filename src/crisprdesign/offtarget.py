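"""Bounded-Hamming-distance off-target search.

Every PAM-adjacent window on both strands of the genome is a potential
off-target site; a guide hits a site when the PAM pattern validates and the
protospacer differs by at most ``max_mm`` mismatches (plain Hamming distance
over the spacer — the PAM itself must match the degenerate pattern exactly,
at any mismatch level). Sites containing N never match, and a guide's own
locus is excluded by coordinate identity, so a second exact genomic copy is a
genuine mm0 off-target.

The search is exact: sites are indexed by ``max_mm + 1`` non-overlapping seed
fragments of the spacer, so by pigeonhole any site within ``max_mm``
mismatches matches at least one seed exactly; seed candidates are then
verified by full Hamming comparison. A naive linear scan over all indexed
sites serves as fallback for very short guides and as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .effectors import PamSpec, iupac_match
from .scan import GuideCandidate, enumerate_guides
from .seqio import Genome, Region, revcomp

DEFAULT_MAX_MM = 3


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic site matched by a guide within the mismatch bound."""

    contig: str
    strand: str
    proto_start: int
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 1-based guide positions, 5'->3'
    pam_seq: str

    @property
    def locus(self) -> tuple[str, int, str]:
        return (self.contig, self.proto_start, self.strand)


@dataclass(frozen=True)
class OffTargetSummary:
    """Counts per mismatch level; mm0 counts additional exact copies only."""

    mm0: int = 0
    mm1: int = 0
    mm2: int = 0
    mm3: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.mm0, self.mm1, self.mm2, self.mm3)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass
class _Site:
    contig: str
    strand: str
    proto_start: int
    protospacer: str  # guide orientation
    pam_seq: str


@dataclass
class SiteIndex:
    """Seed-fragment index over all PAM-adjacent windows of a genome."""

    guide_len: int
    pam: PamSpec
    max_mm: int
    sites: list[_Site]
    naive: bool
    seed_bounds: list[tuple[int, int]] = field(default_factory=list)
    seed_maps: list[dict[str, list[int]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)


def _seed_bounds(guide_len: int, n_seeds: int) -> list[tuple[int, int]]:
    base = guide_len // n_seeds
    bounds = []
    pos = 0
    for i in range(n_seeds):
        size = base + (1 if i < guide_len % n_seeds else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


def build_index(
    genome: Genome, pam: PamSpec, guide_len: int, max_mm: int = DEFAULT_MAX_MM
) -> SiteIndex:
    """Index every PAM-valid window on both strands for <= ``max_mm`` lookup.

    Falls back to a plain linear scan (still exact) when the guide is too
    short to carry ``max_mm + 1`` seeds of at least 2 bp each.
    """
    regions = [
        Region(name, 0, length) for name, length in genome.lengths.items()
    ]
    sites = [
        _Site(c.contig, c.strand, c.proto_start, c.protospacer, c.pam_seq)
        for c in enumerate_guides(genome, regions, pam, guide_len, context=(0, 0))
    ]
    n_seeds = max_mm + 1
    naive = guide_len < 2 * n_seeds
    index = SiteIndex(
        guide_len=guide_len, pam=pam, max_mm=max_mm, sites=sites, naive=naive
    )
    if not naive:
        index.seed_bounds = _seed_bounds(guide_len, n_seeds)
        index.seed_maps = [dict() for _ in range(n_seeds)]
        for sid, site in enumerate(sites):
            for slot, (a, b) in enumerate(index.seed_bounds):
                index.seed_maps[slot].setdefault(site.protospacer[a:b], []).append(sid)
    return index


def _hamming_hit(
    guide_seq: str, site: _Site, max_mm: int
) -> Optional[OffTargetHit]:
    mm_pos = []
    for i, (a, b) in enumerate(zip(guide_seq, site.protospacer)):
        if a != b:
            mm_pos.append(i + 1)
            if len(mm_pos) > max_mm:
                return None
    return OffTargetHit(
        contig=site.contig,
        strand=site.strand,
        proto_start=site.proto_start,
        mismatches=len(mm_pos),
        mismatch_positions=tuple(mm_pos),
        pam_seq=site.pam_seq,
    )


def find_offtargets(
    guide: GuideCandidate, index: SiteIndex, max_mm: int = DEFAULT_MAX_MM
) -> list[OffTargetHit]:
    """All genomic sites hit by the guide within ``max_mm``, own locus excluded."""
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    if len(guide.protospacer) != index.guide_len:
        raise ValueError(
            f"guide length {len(guide.protospacer)} != index guide length {index.guide_len}"
        )
    seq = guide.protospacer
    own = (guide.contig, guide.proto_start, guide.strand)
    if index.naive or max_mm > index.max_mm:
        candidate_ids: set[int] = set(range(len(index.sites)))
    else:
        candidate_ids = set()
        for slot, (a, b) in enumerate(index.seed_bounds):
            candidate_ids.update(index.seed_maps[slot].get(seq[a:b], ()))
    hits = []
    for sid in candidate_ids:
        site = index.sites[sid]
        if (site.contig, site.proto_start, site.strand) == own:
            continue
        hit = _hamming_hit(seq, site, max_mm)
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (h.contig, h.proto_start, h.strand, h.mismatches))
    return hits


def naive_offtargets(
    genome: Genome,
    guide: GuideCandidate,
    pam: PamSpec,
    max_mm: int = DEFAULT_MAX_MM,
) -> list[OffTargetHit]:
    """Independent O(n*L) scan used as oracle and cross-check.

    Slides the guide over every position of both strands, validates the PAM
    directly against the reference, and counts mismatches position by
    position. Shares no code with the indexed search path.
    """
    g = guide.protospacer
    L = len(g)
    p = len(pam.pattern)
    hits = []
    for contig, seq in genome.sequences.items():
        n = len(seq)
        for start in range(0, n - L + 1):
            window = seq[start : start + L]
            # forward strand: guide orientation == reference orientation
            if pam.anchor == "3":
                pam_s, pam_e = start + L, start + L + p
            else:
                pam_s, pam_e = start - p, start
            if 0 <= pam_s and pam_e <= n:
                pam_fwd = seq[pam_s:pam_e]
                if (
                    "N" not in window
                    and "N" not in pam_fwd
                    and iupac_match(pam.pattern, pam_fwd)
                    and (contig, start, "+") != (guide.contig, guide.proto_start, guide.strand)
                ):
                    mm = [i + 1 for i in range(L) if g[i] != window[i]]
                    if len(mm) <= max_mm:
                        hits.append(
                            OffTargetHit(contig, "+", start, len(mm), tuple(mm), pam_fwd)
                        )
            # reverse strand: protospacer occupies [start, start+L) on reference
            if pam.anchor == "3":
                pam_s, pam_e = start - p, start
            else:
                pam_s, pam_e = start + L, start + L + p
            if 0 <= pam_s and pam_e <= n:
                pam_rev = revcomp(seq[pam_s:pam_e])
                if (
                    "N" not in window
                    and "N" not in seq[pam_s:pam_e]
                    and iupac_match(pam.pattern, pam_rev)
                    and (contig, start, "-") != (guide.contig, guide.proto_start, guide.strand)
                ):
                    # compare in guide orientation: reference window reversed-complemented
                    site_seq = revcomp(window)
                    mm = [i + 1 for i in range(L) if g[i] != site_seq[i]]
                    if len(mm) <= max_mm:
                        hits.append(
                            OffTargetHit(contig, "-", start, len(mm), tuple(mm), pam_rev)
                        )
    hits.sort(key=lambda h: (h.contig, h.proto_start, h.strand, h.mismatches))
    return hits


def summarize(hits: list[OffTargetHit]) -> OffTargetSummary:
    """Bucket one guide's hits by mismatch count (0-3)."""
    counts = [0, 0, 0, 0]
    for h in hits:
        if 0 <= h.mismatches <= 3:
            counts[h.mismatches] += 1
    return OffTargetSummary(*counts)
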