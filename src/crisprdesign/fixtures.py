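"""Seeded synthetic genomes with planted ground truth.

The generator emulates the situations the designer must handle: a background
of random sequence at a chosen GC content, with planted on-target sites
(protospacer + PAM), planted off-target copies of a chosen guide at exact
Hamming distances, and planted PAM-out nickase half-site pairs at chosen
offsets. Every planted feature is recorded in a truth table so tests can
check recovery bucket by bucket. The same seed always yields byte-identical
FASTA output.

Features are planted at fixed, well-separated slots; planted spacer sequences
are drawn from the seeded RNG. Random background can in principle contain
spurious near-matches to a planted guide, but for 20-nt guides at the default
genome sizes the expected count is far below one, which the recovery tests
rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import Genome, revcomp, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass
class Fixture:
    """A synthetic genome plus the truth table of everything planted in it."""

    genome: Genome
    truth: pd.DataFrame  # columns: kind, contig, start, end, strand, seq, pam, mm, offset, guide
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "fixture.fasta"
        truth = out_dir / "truth.tsv"
        write_fasta(self.genome, fasta)
        self.truth.to_csv(truth, sep="\t", index=False)
        return {"fasta": fasta, "truth": truth}


class PlantingError(ValueError):
    """Planted features do not fit in the requested genome."""


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Exactly k substitutions at distinct positions."""
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_fixture(
    seed: int,
    length: int = 20_000,
    gc: float = 0.5,
    guide_len: int = 20,
    n_on_targets: int = 1,
    offtarget_mms: Sequence[int] = (1, 2, 3),
    nickase_offsets: Sequence[int] = (),
    contig: str = "chrS",
    slot_spacing: int = 400,
    slot_start: int = 300,
) -> Fixture:
    """Build a planted synthetic genome for an NGG/20-nt style run.

    ``n_on_targets`` plus-strand on-target sites are planted, each a random
    spacer followed by AGG. ``offtarget_mms`` plants, for the FIRST planted
    guide, one plus-strand copy per entry at exactly that Hamming distance
    (0 allowed: an exact duplicate locus), each followed by TGG.
    ``nickase_offsets`` plants, per entry, a fresh PAM-out pair — a
    minus-strand half-site (CCT + revcomp(spacer) on the reference) and a
    plus-strand half-site (spacer + AGG) — separated by exactly that gap.
    """
    rng = np.random.default_rng(seed)
    pam_len = 3
    site_len = guide_len + pam_len
    n_pair_slots = len(nickase_offsets)
    pair_span = 2 * site_len + (max(nickase_offsets) if n_pair_slots else 0)
    n_slots = n_on_targets + len(offtarget_mms) + n_pair_slots
    needed = slot_start + n_slots * slot_spacing + pair_span + 100
    if needed > length:
        raise PlantingError(
            f"genome of {length} bp cannot hold {n_slots} planted slots "
            f"(needs >= {needed} bp)"
        )
    seq = list(_random_seq(rng, length, gc))
    rows: list[dict] = []
    slots = iter(range(slot_start, length, slot_spacing))

    def plant(pos: int, s: str) -> None:
        if pos + len(s) > length:
            raise PlantingError("planted feature runs past the genome end")
        seq[pos : pos + len(s)] = list(s)

    guides = []
    for i in range(n_on_targets):
        spacer = _random_seq(rng, guide_len, 0.5)
        pos = next(slots)
        plant(pos, spacer + "AGG")
        guides.append((spacer, pos))
        rows.append(
            dict(kind="on_target", contig=contig, start=pos, end=pos + guide_len,
                 strand="+", seq=spacer, pam="AGG", mm=0, offset=pd.NA, guide=f"g{i}")
        )
    if offtarget_mms and not guides:
        raise PlantingError("off-target copies need at least one on-target guide")
    for mm in offtarget_mms:
        spacer0 = guides[0][0]
        copy = _mutate(rng, spacer0, mm) if mm else spacer0
        pos = next(slots)
        plant(pos, copy + "TGG")
        rows.append(
            dict(kind="offtarget_copy", contig=contig, start=pos, end=pos + guide_len,
                 strand="+", seq=copy, pam="TGG", mm=mm, offset=pd.NA, guide="g0")
        )
    for offset in nickase_offsets:
        spacer_l = _random_seq(rng, guide_len, 0.5)
        spacer_r = _random_seq(rng, guide_len, 0.5)
        pos = next(slots)
        # minus-strand half-site: reference reads revcomp(PAM) + revcomp(spacer)
        left_block = revcomp("AGG") + revcomp(spacer_l)
        left_proto_start = pos + pam_len
        left_proto_end = left_proto_start + guide_len
        right_proto_start = left_proto_end + offset
        plant(pos, left_block)
        plant(right_proto_start, spacer_r + "AGG")
        rows.append(
            dict(kind="nick_left", contig=contig, start=left_proto_start,
                 end=left_proto_end, strand="-", seq=spacer_l, pam="AGG",
                 mm=0, offset=offset, guide=f"nickL_{offset}")
        )
        rows.append(
            dict(kind="nick_right", contig=contig, start=right_proto_start,
                 end=right_proto_start + guide_len, strand="+", seq=spacer_r,
                 pam="AGG", mm=0, offset=offset, guide=f"nickR_{offset}")
        )
    genome = Genome({contig: "".join(seq)})
    truth = pd.DataFrame(
        rows,
        columns=["kind", "contig", "start", "end", "strand", "seq", "pam", "mm",
                 "offset", "guide"],
    )
    return Fixture(genome=genome, truth=truth, seed=seed)
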