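"""GC window, PAM-proximal G, self-complementarity, efficiency models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import oracle_efficiency, oracle_selfcomp
from crisprdesign.scan import GuideCandidate
from crisprdesign.scoring import (
    EfficiencyModel,
    ModelError,
    builtin_model,
    efficiency_score,
    gc_fraction,
    load_backbone,
    load_model,
    pam_proximal_g,
    selfcomp,
    write_model,
)


def _candidate(context, protospacer="A" * 20, pam="AGG", pad_left=0, pad_right=0):
    return GuideCandidate(
        id="t", contig="c1", strand="+", proto_start=100, proto_end=100 + len(protospacer),
        protospacer=protospacer, pam_seq=pam, cut_pos=117, context=context,
        pad_left=pad_left, pad_right=pad_right,
    )


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq,frac,ideal",
        [
            ("GCGCGCGCGCGCGCGCGCGC", 1.0, False),
            ("ATATATATATATATATATAT", 0.0, False),
            ("GCGCGCGCATATATATATAT", 0.40, True),   # exactly 40%: inclusive bound
            ("GCGCGCGCGCGCGCGCATAT", 0.80, True),   # exactly 80%: inclusive bound
            ("GCGCGCGCGCGCGCGCGCAT", 0.90, False),
        ],
    )
    def test_boundaries(self, seq, frac, ideal):
        got_frac, got_ideal = gc_fraction(seq)
        assert got_frac == pytest.approx(frac)
        assert got_ideal is ideal

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_range_and_reversal_invariance(self, s):
        f, _ = gc_fraction(s)
        assert 0.0 <= f <= 1.0
        assert gc_fraction(s[::-1]) == gc_fraction(s)


class TestPamProximalG:
    def test_depends_only_on_final_base(self):
        base = list("ACGTACGTACGTACGTACGT")
        for i in range(20):
            flipped = base.copy()
            flipped[i] = "G" if flipped[i] != "G" else "A"
            expected = flipped[19] == "G"
            assert pam_proximal_g("".join(flipped)) is expected

    def test_truncated_guide_uses_its_own_final_base(self):
        assert pam_proximal_g("A" * 17 + "G") is True
        assert pam_proximal_g("G" * 17 + "A") is False

    def test_not_applicable_for_five_prime_anchor(self):
        assert pam_proximal_g("A" * 19 + "G", anchor="5") is None


class TestSelfcomp:
    def test_no_stem_by_construction(self):
        assert selfcomp("ACGACGACGACGACGACGAC", "") == 0

    def test_single_hairpin_stem(self):
        assert selfcomp("GGGG" + "A" * 12 + "CCCC", "") == 1

    def test_three_bp_stem_not_counted(self):
        assert selfcomp("GGG" + "A" * 14 + "CCC", "") == 0

    def test_five_bp_stem_counts_once(self):
        # non-repetitive 5 bp stem: a single maximal duplex, not two 4 bp windows
        assert selfcomp("GCATG" + "A" * 10 + "CATGC", "") == 1

    def test_homopolymer_stem_counts_per_register(self):
        # G5:C5 can anneal in three shifted registers of >= 4 bp; each maximal
        # duplex counts once
        assert selfcomp("GGGGG" + "A" * 10 + "CCCCC", "") == 3

    def test_short_loop_suppresses_stem(self):
        # only 2 unpaired bases between the halves: below the loop minimum
        assert selfcomp("GGGG" + "AA" + "CCCC", "") == 0

    def test_cross_stem_with_backbone(self):
        guide = "TAGC" + "A" * 16
        backbone = "TTTTGCTATTTT"
        assert selfcomp(guide, backbone) >= 1

    def test_short_guide_with_empty_backbone_is_zero(self):
        # too short to host stem + loop + stem
        for s in ("ACGTACGTAC", "GGGGGCCCCC"):
            assert len(s) < 2 * 4 + 3
            assert selfcomp(s, "") == 0

    def test_min_stem_below_two_refused(self):
        with pytest.raises(ValueError):
            selfcomp("ACGT" * 5, "", min_stem=1)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=24))
    @settings(max_examples=150, derandomize=True)
    def test_matches_pair_matrix_oracle(self, guide):
        backbone = "GTTTTAGAGCTAGAAATAGCAAG"
        for wobble in (False, True):
            assert selfcomp(guide, backbone, wobble=wobble) == oracle_selfcomp(
                guide, backbone, wobble=wobble
            )

    @given(st.text(alphabet="ACGT", min_size=10, max_size=24))
    @settings(max_examples=150, derandomize=True)
    def test_wobble_never_loses_stems_on_typical_guides(self, guide):
        # wobble widens the pairing alphabet; on guide-scale inputs this only
        # adds stems (see the methods note for the contrived merge caveat)
        assert selfcomp(guide, "", wobble=True) >= selfcomp(guide, "", wobble=False)

    def test_backbone_resource_loads(self):
        bb = load_backbone()
        assert set(bb) <= set("ACGT") and len(bb) > 50


class TestEfficiencyModel:
    def test_load_fixture_model(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "# name=fix\n# window=4,20,3,3\n# link=identity\n# intercept=0.5\n"
            "0\tA\t1.0\n22\tGG\t-0.5\n"
        )
        m = load_model(p)
        assert m.name == "fix" and len(m.features) == 2 and m.window == (4, 20, 3, 3)

    def test_out_of_window_offset_names_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("# name=x\n# window=0,10,3,0\n# intercept=0\n13\tA\t1.0\n")
        with pytest.raises(ModelError, match="offset 13"):
            load_model(p)

    def test_non_numeric_weight_names_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("# name=x\n# window=0,10,3,0\n# intercept=0\n0\tA\tbad\n")
        with pytest.raises(ModelError, match=":4"):
            load_model(p)

    def test_roundtrip_exact(self, tmp_path):
        m = builtin_model()
        p = tmp_path / "m.tsv"
        write_model(m, p)
        again = load_model(p)
        assert again == m

    def test_single_feature_identity_and_logistic(self):
        ctx = "A" + "C" * 29
        ident = EfficiencyModel("m", (4, 20, 3, 3), 0.0, ((0, "A", 1.0),), "identity")
        logi = EfficiencyModel("m", (4, 20, 3, 3), 0.0, ((0, "A", 1.0),), "logistic")
        c = _candidate(ctx)
        assert efficiency_score(c, ident) == pytest.approx(1.0)
        assert efficiency_score(c, logi) == pytest.approx(0.7311, abs=1e-4)

    def test_hand_summed_fixture(self):
        m = EfficiencyModel(
            "hand", (4, 20, 3, 3), 0.25,
            ((0, "G", 0.5), (4, "AC", -0.3), (10, "T", 0.2), (24, "G", 0.1), (29, "A", -0.9)),
            "identity",
        )
        ctx = "GATCACGTACTGCATGCATGCATAGGCTGA"
        # matches: offset0 G, offset4 AC, offset10 T, offset24 G, offset29 A
        assert efficiency_score(_candidate(ctx), m) == pytest.approx(
            0.25 + 0.5 - 0.3 + 0.2 + 0.1 - 0.9
        )

    def test_window_mismatch_fatal(self):
        m = EfficiencyModel("m", (4, 18, 3, 3), 0.0, (), "identity")
        with pytest.raises(ModelError):
            efficiency_score(_candidate("A" * 30), m)

    def test_padding_makes_score_unavailable(self):
        m = EfficiencyModel("m", (4, 20, 3, 3), 0.0, ((1, "N", 1.0),), "identity")
        c = _candidate("NNNN" + "A" * 26, pad_left=4)
        assert efficiency_score(c, m) is None

    def test_padded_but_untouched_features_still_score(self):
        m = EfficiencyModel("m", (4, 20, 3, 3), 0.0, ((10, "A", 2.0),), "identity")
        c = _candidate("NNNN" + "A" * 26, pad_left=4)
        assert efficiency_score(c, m) == pytest.approx(2.0)

    def test_brute_force_matcher_on_random_contexts(self):
        m = builtin_model()
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(1000):
            ctx = "".join(bases[rng.integers(0, 4, size=30)])
            got = efficiency_score(_candidate(ctx), m)
            assert got == pytest.approx(oracle_efficiency(ctx, m))
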