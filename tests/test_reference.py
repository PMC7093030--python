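import math

import numpy as np
import pytest

from tcrpair import synthetic
from tcrpair.reference import (GAP, ClonotypeExcluded, GeneRecord,
                               GeneReference, ReferenceError, build_profiles,
                               index_clonotype_residues, information_content,
                               load_gene_reference)
from tests.conftest import make_clonotype


def test_load_tsv_reference_roundtrip(small_ref, tmp_path):
    path = tmp_path / "ref.tsv"
    synthetic.write_reference_tsv(small_ref, path)
    loaded = load_gene_reference(path)
    assert len(loaded) == 10
    assert {r.gapped_seq for r in loaded.records} == \
        {r.gapped_seq for r in small_ref.records}


def test_load_fasta_reference(tmp_path, small_ref):
    path = tmp_path / "ref.fasta"
    with open(path, "w") as fh:
        for rec in small_ref.records:
            fh.write(f">{rec.name}*{rec.allele}|{rec.chain}|{rec.seg_class}\n"
                     f"{rec.gapped_seq}\n")
    loaded = load_gene_reference(path)
    assert len(loaded) == len(small_ref)
    assert loaded.get("alpha", "V", "TRAV1")[0].gapped_seq == \
        small_ref.get("alpha", "V", "TRAV1")[0].gapped_seq


def test_missing_cys104_flagged_but_retained():
    seq = "A" * 107
    ref = GeneReference([GeneRecord("alpha", "V", "TRAV-X", "01", seq)])
    assert "missing-Cys104" in ref.records[0].flags


def test_duplicate_name_rejected(tmp_path, small_ref):
    path = tmp_path / "dup.tsv"
    with open(path, "w") as fh:
        fh.write("chain\tclass\tname\tallele\tgapped_seq\n")
        rec = small_ref.records[0]
        for _ in range(2):
            fh.write(f"{rec.chain}\t{rec.seg_class}\tTRBV-X\t01\t{rec.gapped_seq}\n")
    with pytest.raises(ReferenceError, match="duplicate"):
        load_gene_reference(path)


def test_j_gene_without_anchor_rejected():
    with pytest.raises(ReferenceError, match="FW"):
        GeneReference([GeneRecord("alpha", "J", "TRAJ-X", "01", "AAAAAAAAA")])


class TestIndexing:
    def test_cdr3_flanks_follow_4_plus_4_rule(self, small_ref, clonotype_factory):
        c = clonotype_factory()
        c.cdr3_beta = "CASSLGQAYEQYF"
        m = index_clonotype_residues(c, small_ref, "beta")
        assert [m.symbol(p) for p in range(104, 108)] == list("CASS")
        assert [m.symbol(p) for p in range(108, 112)] == list("EQYF")

    def test_gap_propagates_to_map(self, clonotype_factory):
        ref = synthetic.make_reference(n_gap_genes=1, seed=3)
        c = make_clonotype(ref)
        m = index_clonotype_residues(c, ref, "alpha")
        assert ref.get("alpha", "V", "TRAV1")[0].gapped_seq[9] == GAP
        assert m.symbol(10) == GAP

    def test_short_cdr3_excluded(self, small_ref, clonotype_factory):
        c = clonotype_factory()
        c.cdr3_alpha = "CASSF"
        with pytest.raises(ClonotypeExcluded):
            index_clonotype_residues(c, small_ref, "alpha")

    def test_germline_determinism_outside_flanks(self, small_ref,
                                                 clonotype_factory):
        a = clonotype_factory(middle_a="GGS")
        b = clonotype_factory(middle_a="WWWWW")
        ma = index_clonotype_residues(a, small_ref, "alpha")
        mb = index_clonotype_residues(b, small_ref, "alpha")
        for pos in range(1, 104):
            assert ma.symbol(pos) == mb.symbol(pos)
        assert ma.positions == index_clonotype_residues(
            a, small_ref, "alpha").positions  # deterministic re-run


class TestInformationContent:
    def test_point_mass_is_one(self):
        p = np.zeros(21)
        p[0] = 1.0
        assert information_content(p) == pytest.approx(1.0)

    def test_uniform20_is_zero(self):
        assert information_content(np.full(20, 0.05)) == pytest.approx(0.0, abs=1e-12)

    def test_two_equiprobable_residues(self):
        # 1 - log 2 / log 20, evaluated directly
        expected = 1.0 - math.log(2) / math.log(20)
        assert information_content([0.5, 0.5]) == pytest.approx(expected)
        assert expected == pytest.approx(0.7686, abs=1e-4)

    def test_uniform21_goes_negative_unclamped(self):
        val = information_content(np.full(21, 1 / 21))
        assert val == pytest.approx(1.0 - math.log(21) / math.log(20))
        assert val < 0

    def test_invalid_vectors_rejected(self):
        with pytest.raises(ValueError):
            information_content([0.5, -0.5, 1.0])
        with pytest.raises(ValueError):
            information_content([0.3, 0.3])


class TestProfiles:
    def test_conserved_position_has_info_one(self):
        ref = synthetic.make_reference(variability=0.0, seed=5)
        profiles = build_profiles(ref, "alpha")
        v_profiles = [p for p in profiles if p.position <= 103]
        assert all(p.info == pytest.approx(1.0) for p in v_profiles)

    def test_uniform_weights_equal_unweighted(self, small_ref):
        genes = {r.name for r in small_ref.records if r.chain == "alpha"}
        weighted = build_profiles(small_ref, "alpha", {g: 1.0 for g in genes})
        unweighted = build_profiles(small_ref, "alpha")
        for w, u in zip(weighted, unweighted):
            assert w.position == u.position
            np.testing.assert_allclose(w.probs, u.probs)

    def test_profiles_are_distributions(self, variable_ref):
        for prof in build_profiles(variable_ref, "beta"):
            assert prof.probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert prof.info <= 1.0 + 1e-12

    def test_skewed_weights_shift_probabilities(self, variable_ref):
        genes = variable_ref.genes("alpha", "V")
        weights = {g: (1.0 if g == genes[0] else 1e-6) for g in genes}
        weights.update({g: 1.0 for g in variable_ref.genes("alpha", "J")})
        profs = build_profiles(variable_ref, "alpha", weights)
        top = variable_ref.get("alpha", "V", genes[0])[0]
        prof_50 = next(p for p in profs if p.position == 50)
        assert prof_50.prob(top.gapped_seq[49]) > 0.99

    def test_all_zero_weights_rejected(self, small_ref):
        with pytest.raises(ValueError):
            build_profiles(small_ref, "alpha", {"TRAV1": 0.0})
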