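"""Restriction-site scan, melting temperature, primer design."""

import math

import pytest

from crisprdesign.accessory import (
    design_primers,
    find_restriction_sites,
    load_enzymes,
    melting_temp,
)
from crisprdesign.effectors import expand_iupac
from crisprdesign.seqio import Genome, SequenceError, revcomp


class TestRestrictionSites:
    def test_palindrome_reported_once_and_unique(self):
        sites = find_restriction_sites("TTGGATCCTT", {"BamHI": "GGATCC"})
        assert len(sites) == 1
        assert sites[0].pos == 2 and sites[0].strand == "+" and sites[0].unique_in_amplicon

    def test_two_occurrences_not_unique(self):
        sites = find_restriction_sites("GAATTCTTTTGAATTC", {"EcoRI": "GAATTC"})
        assert len(sites) == 2
        assert not any(s.unique_in_amplicon for s in sites)

    def test_degenerate_motif(self):
        sites = find_restriction_sites("TTGACGTCTT", {"Hin1I": "GRCGYC"})
        assert len(sites) == 1 and sites[0].pos == 2

    def test_non_palindromic_motif_found_on_minus_strand(self):
        # GGTCTC (BsaI-like) present only as its reverse complement GAGACC
        sites = find_restriction_sites("TTGAGACCTT", {"BsaI": "GGTCTC"})
        assert len(sites) == 1 and sites[0].strand == "-"

    def test_malformed_motif_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            sites = find_restriction_sites("GAATTC", {"bad": "GAXTTC", "EcoRI": "GAATTC"})
        assert [s.enzyme for s in sites] == ["EcoRI"]
        assert "bad" in caplog.text

    def test_overlap_with_cut_flag(self):
        sites = find_restriction_sites("TTGGATCCTT", {"BamHI": "GGATCC"}, cut_pos=4)
        assert sites[0].overlaps_cut
        sites = find_restriction_sites("TTGGATCCTT", {"BamHI": "GGATCC"}, cut_pos=9)
        assert not sites[0].overlaps_cut

    def test_matches_expand_and_search_oracle(self):
        amplicon = ("ACGTGAATTCGGATCCTTGACGTCAAGCTTCYCGRG".replace("Y", "C")
                    .replace("R", "A") * 3)
        enzymes = load_enzymes()
        sites = find_restriction_sites(amplicon, enzymes)
        expected = set()
        for name, motif in enzymes.items():
            fwd = expand_iupac(motif)
            rc = expand_iupac(revcomp(motif))
            for i in range(len(amplicon) - len(motif) + 1):
                w = amplicon[i : i + len(motif)]
                if w in fwd:
                    expected.add((name, i, "+"))
                elif motif != revcomp(motif) and w in rc:
                    expected.add((name, i, "-"))
        assert {(s.enzyme, s.pos, s.strand) for s in sites} == expected

    def test_bundled_enzyme_table(self):
        enzymes = load_enzymes()
        assert enzymes["EcoRI"] == "GAATTC" and len(enzymes) >= 15


# SantaLucia unified NN parameters (kcal/mol, cal/mol/K) for the hand oracle
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)


def _oracle_tm(seq: str) -> float:
    """Hand-summed nearest-neighbor Tm at 50 mM Na+, 25 nM strands."""
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        h, s = _INIT_AT if end in "AT" else _INIT_GC
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(0.05)  # SantaLucia 1998 salt entropy
    k = (25 - 25 / 2.0) * 1e-9
    return dh * 1000.0 / (ds + 1.987 * math.log(k)) - 273.15


class TestMeltingTemp:
    def test_gc_raises_tm_at_fixed_length(self):
        assert melting_temp("A" * 20) < melting_temp("ACGTACGTACGTACGTACGT")

    def test_monotone_in_gc_content(self):
        seqs = ["AT" * 10, "ATATACGCGCATATATATAT", "ACGCGCGCATACGTATGCGC", "GC" * 10]
        tms = [melting_temp(s) for s in seqs]
        assert tms == sorted(tms)

    def test_revcomp_has_identical_tm(self):
        s = "ACCGTTGAGCTTACGGATCA"
        assert melting_temp(s) == pytest.approx(melting_temp(revcomp(s)), abs=1e-9)

    @pytest.mark.parametrize("seq", ["ACCGTTGAGCTTACGGATCA", "TTGCAATCTGATCGGACTTG", "GATTACAGATTACAGATTAC"])
    def test_matches_hand_summed_nn_oracle(self, seq):
        assert melting_temp(seq) == pytest.approx(_oracle_tm(seq), abs=0.1)

    def test_out_of_range_length_refused(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACGT")  # 8 < 10
        with pytest.raises(ValueError):
            melting_temp("ACGT" * 11)


class TestDesignPrimers:
    @pytest.fixture
    def locus(self):
        # deterministic pseudo-random 1.6 kb locus around a cut at 800
        import numpy as np
        rng = np.random.default_rng(77)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1600))
        return Genome({"L": seq})

    def test_pairs_satisfy_their_constraints(self, locus):
        pairs = design_primers(locus, "L", 800)
        assert pairs
        for p in pairs:
            assert 18 <= len(p.left_seq) <= 25 and 18 <= len(p.right_seq) <= 25
            assert 57 <= p.left_tm <= 63 and 57 <= p.right_tm <= 63
            assert 200 <= p.product_size <= 600
            assert p.product_region.start <= 800 - 50
            assert p.product_region.end >= 800 + 50
            # re-derive the primer sequences from the locus
            seq = locus.sequences["L"]
            assert seq.startswith(p.left_seq, p.product_region.start)
            assert revcomp(seq[p.product_region.end - len(p.right_seq) : p.product_region.end]) == p.right_seq

    def test_ranked_by_tm_balance(self, locus):
        pairs = design_primers(locus, "L", 800)
        diffs = [abs(p.left_tm - p.right_tm) for p in pairs]
        assert diffs == sorted(diffs)

    def test_infeasible_product_geometry_returns_empty(self, locus):
        assert design_primers(locus, "L", 800, product_size=(60, 80)) == []

    def test_widening_tm_band_never_loses_pairs(self, locus):
        narrow = design_primers(locus, "L", 800, tm_range=(59.0, 61.0), max_pairs=10**6)
        wide = design_primers(locus, "L", 800, tm_range=(57.0, 63.0), max_pairs=10**6)
        key = lambda p: (p.left_seq, p.right_seq)
        assert {key(p) for p in narrow} <= {key(p) for p in wide}

    def test_cut_too_close_to_contig_end_is_error(self, locus):
        with pytest.raises(SequenceError, match="contig end"):
            design_primers(locus, "L", 10)

    def test_single_admissible_pair_by_construction(self):
        # N-filler makes every window except the two planted 20-mers inadmissible
        left = "ACGGCTAGCTAGGCTAGCTA"
        right_site = revcomp("TGCCGATCGATCCGATCGAT")
        seq = "N" * 100 + left + "N" * 250 + right_site + "N" * 100
        g = Genome({"L": seq})
        cut = 100 + 20 + 125
        pairs = design_primers(
            g, "L", cut, primer_len=(20, 20), tm_range=(53.0, 56.0),
            product_size=(200, 320), min_margin=50,
        )
        assert len(pairs) == 1
        assert pairs[0].left_seq == left
        assert pairs[0].right_seq == "TGCCGATCGATCCGATCGAT"
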