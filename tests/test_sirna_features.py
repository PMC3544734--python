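"""The eight siRNA feature groups and their pinned dimensions."""

import math

import numpy as np
import pytest

from csrnai import (
    COMBINED_DIM,
    GROUP_DIMS,
    NNTable,
    apply_psf,
    combine_features,
    extract_psf_rules,
    image_features,
    ngram_features,
    ngsk_features,
    pc_features,
    speech_features,
    thermo_features,
)
from csrnai.sirna_features import PSFRule, _haralick_13, _levinson, _lpc

SEQ = "ACGTACGTACGTACGTACG"


class TestPsfRules:
    def test_fully_separated_classes(self):
        pos = ["CC" + "A" + "C" * 16] * 20
        neg = ["CC" + "C" + "C" * 16] * 20
        rules = extract_psf_rules(pos, neg, "single", k=20)
        top = rules[0]
        assert (top.position, top.pattern, top.direction) == (3, "A", "desired")
        assert top.p_value == pytest.approx(2.0 / math.comb(40, 20), rel=1e-9)

    def test_returns_exactly_k_rules(self):
        pos = ["A" * 19, "C" * 19, "G" * 19] * 5
        neg = ["T" * 19, "G" * 19, "A" * 19] * 5
        assert len(extract_psf_rules(pos, neg, "single", k=20)) == 20
        assert len(extract_psf_rules(pos, neg, "dinucleotide", k=16)) == 16

    def test_identical_classes_carry_no_signal(self):
        seqs = ["ACGTACGTACGTACGTACG", "GGGTACGTACGTACGTACC"] * 10
        rules = extract_psf_rules(seqs, list(seqs), "single", k=10)
        assert all(r.p_value == pytest.approx(1.0) for r in rules)
        # ordering falls back to the deterministic (p, position, pattern) tie-break
        keys = [(r.p_value, r.position, r.pattern) for r in rules]
        assert keys == sorted(keys)

    def test_empty_class_and_oversized_k_rejected(self):
        with pytest.raises(ValueError):
            extract_psf_rules([], ["A" * 19], "single", k=5)
        with pytest.raises(ValueError, match="exceeds"):
            extract_psf_rules(["A" * 19] * 3, ["C" * 19] * 3, "single", k=1000)


class TestApplyPsf:
    def test_signed_match_convention(self):
        seq = "CCACC" + "C" * 14
        desired = PSFRule(3, "A", "desired", 0.01)
        undesired = PSFRule(3, "A", "undesired", 0.01)
        miss = PSFRule(5, "G", "desired", 0.02)
        fv = apply_psf(seq, [desired, undesired, miss])
        assert fv.values.tolist() == [1.0, -1.0, 0.0]

    def test_no_matches_all_zero(self):
        rules = [PSFRule(i + 1, "G", "desired", 0.1) for i in range(19)]
        assert not apply_psf("A" * 19, rules).values.any()

    def test_rule_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            apply_psf("ACG", [PSFRule(3, "GT", "desired", 0.1)])


class TestNGram:
    def test_dimension_and_homopolymer_counts(self):
        fv = ngram_features("A" * 19)
        assert len(fv) == 336
        vals = dict(zip(fv.names, fv.values))
        assert vals["n2_AA"] == 18 and vals["n3_AAA"] == 17 and vals["n4_AAAA"] == 16
        assert fv.values.sum() == 18 + 17 + 16

    def test_order2_counts_sum_to_18(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=19))
            fv = ngram_features(seq, orders=(2,))
            assert fv.values.sum() == 18


class TestNgsk:
    def test_decay_zero_equals_ngram(self):
        g0 = ngsk_features(SEQ, decay=0.0)
        ng = ngram_features(SEQ)
        assert np.array_equal(g0.values, ng.values)

    def test_single_gap_contribution(self):
        fv = ngsk_features("ACA", orders=(2,), decay=0.5)
        assert dict(zip(fv.names, fv.values))["g2_AA"] == pytest.approx(0.5)

    def test_monotone_in_decay(self):
        lo = ngsk_features(SEQ, decay=0.3).values
        hi = ngsk_features(SEQ, decay=0.7).values
        assert (hi >= lo - 1e-12).all()

    def test_decay_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ngsk_features(SEQ, decay=1.5)


class TestThermo:
    def test_homopolymer_hand_sum(self):
        stacks = {a + b: 0.0 for a in "ACGT" for b in "ACGT"}
        stacks["AA"] = -0.9
        nn = NNTable(stack_dG=stacks, initiation_dG=4.0)
        fv = thermo_features("A" * 19, nn)
        assert len(fv) == 21
        assert np.allclose(fv.values[:18], -0.9)
        vals = dict(zip(fv.names, fv.values))
        assert vals["duplex_dG"] == pytest.approx(18 * -0.9 + 4.0)
        assert vals["end5_dG"] == pytest.approx(-0.9)

    def test_zero_table_gives_zero_vector(self):
        nn = NNTable({a + b: 0.0 for a in "ACGT" for b in "ACGT"}, 0.0)
        assert not thermo_features(SEQ, nn).values.any()

    def test_missing_stack_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            NNTable({"AA": -1.0}, 4.0)


class TestPositionComposition:
    def test_one_hot_structure(self):
        fv = pc_features("AG" + "C" * 17)
        assert len(fv) == 364
        assert fv.values[:76].sum() == 19 and fv.values[76:].sum() == 18
        vals = dict(zip(fv.names, fv.values))
        assert vals["pos1_A"] == 1 and vals["pair1_AG"] == 1


class TestImageFeatures:
    def test_dimension_and_determinism(self):
        a, b = image_features(SEQ), image_features(SEQ)
        assert len(a) == 132
        assert np.array_equal(a.values, b.values)
        assert np.isfinite(a.values).all()

    def test_constant_image_contrast_is_zero(self):
        # a one-level co-occurrence distribution has no gray transitions
        glcm = np.zeros((2, 2))
        glcm[1, 1] = 10.0
        stats = _haralick_13(glcm)
        assert stats[1] == 0.0  # contrast
        assert np.isfinite(stats).all()


class TestSpeechFeatures:
    def test_dimension_and_determinism(self):
        a, b = speech_features(SEQ), speech_features(SEQ)
        assert len(a) == 199
        assert np.array_equal(a.values, b.values)
        assert np.isfinite(a.values).all()

    def test_lpc_recovers_ar1_coefficient(self):
        # Yule-Walker closed form: AR(1) with a=0.8 has r(k) ~ 0.8^k
        rng = np.random.default_rng(42)
        x = np.zeros(4000)
        for t in range(1, len(x)):
            x[t] = 0.8 * x[t - 1] + rng.normal()
        a = _lpc(x, 12)
        assert a[0] == pytest.approx(0.8, abs=0.05)
        assert np.abs(a[1:]).max() < 0.12

    def test_all_zero_frame_falls_back_to_zeros(self):
        assert not _lpc(np.zeros(16), 12).any()
        assert not _levinson(np.zeros(13), 12).any()


class TestCombined:
    def test_total_dimension_and_group_layout(self, psf_rules, spsf_rules, nn_table):
        fv = combine_features(SEQ, psf_rules, spsf_rules, nn=nn_table)
        assert len(fv) == COMBINED_DIM == 1424
        for group, dim in GROUP_DIMS.items():
            assert sum(n.startswith(group + "_") for n in fv.names) == dim

    def test_wrong_rule_count_rejected(self, psf_rules, spsf_rules):
        with pytest.raises(ValueError, match="PSF rules"):
            combine_features(SEQ, psf_rules[:5], spsf_rules)
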