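"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results along different code paths
from the implementation: vectorized window scans for off-target search,
run-walking over explicit pair matrices for stem counting, and literal
feature matching for the efficiency model.
"""

from __future__ import annotations

import numpy as np
import pytest

from crisprdesign import Genome, Region, expand_iupac, parse_pam, revcomp

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = WC | {("G", "T"), ("T", "G")}


@pytest.fixture
def spcas9():
    return parse_pam("NGG", "3", name="spCas9")


@pytest.fixture
def small_genome():
    return Genome({"c1": "ACGTACGTACGTACGTACGTACGTACGTACGT", "c2": "GGGGGGGGGGGGGGGG"})


def random_genome(rng: np.random.Generator, length: int, name: str = "chrR") -> Genome:
    return Genome({name: "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])})


# ---------------------------------------------------------------- oracles


def oracle_selfcomp(guide: str, backbone: str = "", min_stem: int = 4,
                    min_loop: int = 3, wobble: bool = False) -> int:
    """Stem count by explicit pair-matrix run walking (independent path)."""
    pairs = WOBBLE if wobble else WC
    g = guide.upper()
    n = len(g)
    count = 0
    # intramolecular: cell (x, y), x < y, base-pairing AND loop constraint
    def ok(x, y):
        return 0 <= x < y < n and (g[x], g[y]) in pairs and y - x - 1 >= min_loop
    for x in range(n):
        for y in range(x + 1, n):
            if ok(x, y) and not ok(x - 1, y + 1):  # start of a maximal run
                L = 0
                while ok(x + L, y - L):
                    L += 1
                if L >= min_stem:
                    count += 1
    b = backbone.upper().replace("U", "T")
    m = len(b)
    def okx(x, y):
        return 0 <= x < n and 0 <= y < m and (g[x], b[y]) in pairs
    for x in range(n):
        for y in range(m):
            if okx(x, y) and not okx(x - 1, y + 1):
                L = 0
                while okx(x + L, y - L):
                    L += 1
                if L >= min_stem:
                    count += 1
    return count


def oracle_efficiency(context: str, model) -> float:
    """Literal feature matching, no padding logic."""
    import math
    s = model.intercept
    for offset, kmer, weight in model.features:
        if context[offset : offset + len(kmer)] == kmer:
            s += weight
    if model.link == "logistic":
        return 1.0 / (1.0 + math.exp(-s))
    return s


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def oracle_offtargets(genome: Genome, guide_seq: str, pam_pattern: str,
                      anchor: str, max_mm: int,
                      exclude: tuple[str, int, str] | None = None):
    """Vectorized full scan: every window on both strands, PAM set-expanded.

    Returns a set of (contig, proto_start, strand, mismatches).
    """
    L = len(guide_seq)
    p = len(pam_pattern)
    pam_fwd = expand_iupac(pam_pattern)
    hits = set()
    for contig, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(arr)
        if n < L + p:
            continue
        for strand in ("+", "-"):
            if strand == "+":
                gvec = np.frombuffer(guide_seq.encode(), dtype=np.uint8)
            else:
                gvec = np.frombuffer(revcomp(guide_seq).encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mism = (windows != gvec[None, :]).sum(axis=1) if strand == "+" else (
                windows != gvec[None, :]
            ).sum(axis=1)
            has_n = (windows == ord("N")).any(axis=1)
            for start in np.nonzero((mism <= max_mm) & ~has_n)[0]:
                start = int(start)
                # PAM genomic span for this strand/anchor
                pam_is_right = (anchor == "3") == (strand == "+")
                ps, pe = (start + L, start + L + p) if pam_is_right else (start - p, start)
                if ps < 0 or pe > n:
                    continue
                pam_ref = seq[ps:pe]
                pam_guide = pam_ref if strand == "+" else revcomp(pam_ref)
                if "N" in pam_ref or pam_guide not in pam_fwd:
                    continue
                if exclude is not None and (contig, start, strand) == exclude:
                    continue
                hits.add((contig, start, strand, int(mism[start])))
    return hits
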