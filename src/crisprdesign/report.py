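"""Ranking, colors, tabular outputs, and the whole-pipeline driver.

Guides are ordered by specificity first and efficiency second: ascending
off-target counts (mm0, mm1, mm2, mm3), then descending efficiency score,
then ascending self-complementarity, with genomic position as the final
tiebreak. Colors summarise quality at a glance — green for guides with no
0-1-mismatch off-targets, ideal GC and no stems; red for guides with an
additional exact genomic match; amber otherwise. The policy constants live in
:class:`RankPolicy` and are configurable; the ordering itself is an explicit
artifact of this tool, stated here and in the output header.

Outputs are flat files: a TSV with a fixed documented column order, BED6 of
target spans (score = rank), and FASTA of protospacers. Identical inputs
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .accessory import PrimerPair, RestrictionSite
from .effectors import PamSpec, THREE_PRIME
from .offtarget import OffTargetSummary
from .scan import GuideCandidate
from .scoring import ScoreSet
from .seqio import Genome, extract, Region, write_bed6

TSV_COLUMNS = [
    "rank",
    "id",
    "location",
    "strand",
    "protospacer",
    "pam",
    "gc_pct",
    "selfcomp",
    "efficiency",
    "mm0",
    "mm1",
    "mm2",
    "mm3",
    "color",
    "restriction_count",
    "left_primer",
    "right_primer",
    "left_tm",
    "right_tm",
    "product_size",
]


@dataclass(frozen=True)
class RankPolicy:
    """Color thresholds; green requires clean near-off-targets, ideal GC, no stems."""

    green_max_mm0: int = 0
    green_max_mm1: int = 0
    green_max_selfcomp: int = 0
    red_min_mm0: int = 1


@dataclass
class RankedGuide:
    candidate: GuideCandidate
    scores: ScoreSet
    offtargets: OffTargetSummary
    rank: int = 0
    color: str = "amber"
    restriction_sites: list[RestrictionSite] = field(default_factory=list)
    primers: list[PrimerPair] = field(default_factory=list)


def _color(scores: ScoreSet, ot: OffTargetSummary, policy: RankPolicy) -> str:
    if ot.mm0 >= policy.red_min_mm0:
        return "red"
    if (
        ot.mm0 <= policy.green_max_mm0
        and ot.mm1 <= policy.green_max_mm1
        and scores.gc_ideal
        and scores.selfcomp <= policy.green_max_selfcomp
    ):
        return "green"
    return "amber"


def rank_guides(
    scored: list[tuple[GuideCandidate, ScoreSet, OffTargetSummary]],
    policy: RankPolicy = RankPolicy(),
) -> list[RankedGuide]:
    """Assign ranks 1..N and colors by the documented ordering policy."""

    def key(item: tuple[GuideCandidate, ScoreSet, OffTargetSummary]):
        cand, sc, ot = item
        eff = sc.efficiency if sc.efficiency is not None else float("-inf")
        return (
            ot.mm0,
            ot.mm1,
            ot.mm2,
            ot.mm3,
            -eff,
            sc.selfcomp,
            cand.contig,
            cand.proto_start,
            cand.strand,
        )

    ordered = sorted(scored, key=key)
    out = []
    for i, (cand, sc, ot) in enumerate(ordered, start=1):
        out.append(
            RankedGuide(
                candidate=cand,
                scores=sc,
                offtargets=ot,
                rank=i,
                color=_color(sc, ot, policy),
            )
        )
    return out


def _fmt_eff(eff: Optional[float]) -> str:
    return "NA" if eff is None else f"{eff:.4f}"


def write_outputs(
    ranked: list[RankedGuide],
    out_dir: str | Path,
    genome: Optional[Genome] = None,
) -> dict[str, Path]:
    """Write results.tsv, targets.bed and guides.fasta into ``out_dir``.

    Column order is exactly :data:`TSV_COLUMNS`; floats use fixed formats so
    repeat runs on identical input are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "results.tsv"
    bed = out_dir / "targets.bed"
    fasta = out_dir / "guides.fasta"
    with open(tsv, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rg in ranked:
            c = rg.candidate
            best = rg.primers[0] if rg.primers else None
            row = [
                str(rg.rank),
                c.id,
                c.location_1based,
                c.strand,
                c.protospacer,
                c.pam_seq,
                f"{100 * rg.scores.gc_fraction:.1f}",
                str(rg.scores.selfcomp),
                _fmt_eff(rg.scores.efficiency),
                *(str(x) for x in rg.offtargets.as_tuple()),
                rg.color,
                str(len(rg.restriction_sites)),
                best.left_seq if best else "NA",
                best.right_seq if best else "NA",
                f"{best.left_tm:.2f}" if best else "NA",
                f"{best.right_tm:.2f}" if best else "NA",
                str(best.product_size) if best else "NA",
            ]
            fh.write("\t".join(row) + "\n")
    write_bed6(
        (
            (rg.candidate.contig, rg.candidate.proto_start, rg.candidate.proto_end,
             rg.candidate.id, rg.rank, rg.candidate.strand)
            for rg in ranked
        ),
        bed,
    )
    with open(fasta, "w") as fh:
        for rg in ranked:
            fh.write(f">{rg.candidate.id}\n{rg.candidate.protospacer}\n")
    return {"tsv": tsv, "bed": bed, "fasta": fasta}


def write_offtarget_bed(
    ranked: list[RankedGuide],
    hits_by_guide: dict[str, list],
    index_guide_len: int,
    path: str | Path,
) -> None:
    """BED6 of off-target loci; the score column is the mismatch count."""
    rows = []
    for rg in ranked:
        for h in hits_by_guide.get(rg.candidate.id, []):
            rows.append(
                (h.contig, h.proto_start, h.proto_start + index_guide_len,
                 rg.candidate.id, h.mismatches, h.strand)
            )
    write_bed6(rows, path)


def design_pipeline(
    genome: Genome,
    regions: list[Region],
    pam: PamSpec,
    guide_len: int,
    model=None,
    backbone: str = "",
    max_mm: int = 3,
    cut_offset: int = 3,
    policy: RankPolicy = RankPolicy(),
    wobble: bool = False,
    index=None,
) -> tuple[list[RankedGuide], dict[str, list], "object"]:
    """Run enumerate -> score -> off-target -> rank end to end.

    Returns (ranked guides, off-target hits keyed by guide id, site index).
    The index is built genome-wide once and may be passed back in for reuse.
    """
    from .offtarget import build_index, find_offtargets, summarize
    from .scan import enumerate_guides
    from .scoring import score_candidate

    context = (4, 3)
    if model is not None:
        up, g, p, down = model.window
        context = (up, down)
    candidates = enumerate_guides(
        genome, regions, pam, guide_len, context=context, cut_offset=cut_offset
    )
    if index is None:
        index = build_index(genome, pam, guide_len, max_mm)
    scored = []
    hits_by_guide: dict[str, list] = {}
    for cand in candidates:
        hits = find_offtargets(cand, index, max_mm)
        hits_by_guide[cand.id] = hits
        sc = score_candidate(
            cand, model=model, backbone=backbone, anchor=pam.anchor, wobble=wobble
        )
        scored.append((cand, sc, summarize(hits)))
    return rank_guides(scored, policy), hits_by_guide, index
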