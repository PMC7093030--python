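import filecmp
import json
import re

import numpy as np
import pytest

from tcrpair import synthetic
from tcrpair.bayesnet import dataset_from_combos
from tcrpair.pairing import PairCountMatrix, dependence_stats
from tcrpair.reference import GAP, J_ANCHOR_MOTIF
from tcrpair.repertoire import resolve_gene_calls


class TestReferenceGenerator:
    def test_anchors_enforced(self):
        ref = synthetic.make_reference(seed=3)
        for rec in ref.records:
            if rec.seg_class == "V":
                assert rec.gapped_seq[103] == "C"
            else:
                m = J_ANCHOR_MOTIF.search(rec.ungapped)
                assert m is not None
                # motif start maps to IMGT 111
                assert rec.positions()[111] == rec.ungapped[m.start()]

    def test_zero_variability_makes_identical_genes(self):
        ref = synthetic.make_reference(variability=0.0, seed=4)
        v_alpha = {r.gapped_seq for r in ref.records
                   if r.chain == "alpha" and r.seg_class == "V"}
        assert len(v_alpha) == 1

    def test_same_seed_byte_identical(self, tmp_path):
        for i in (1, 2):
            synthetic.write_reference_tsv(synthetic.make_reference(seed=11),
                                          tmp_path / f"r{i}.tsv")
        assert filecmp.cmp(tmp_path / "r1.tsv", tmp_path / "r2.tsv",
                           shallow=False)

    def test_gap_genes_carry_gap_at_position_10(self):
        ref = synthetic.make_reference(n_gap_genes=1, seed=5)
        assert ref.get("alpha", "V", "TRAV1")[0].gapped_seq[9] == GAP
        assert ref.get("alpha", "V", "TRAV2")[0].gapped_seq[9] != GAP


class TestRepertoireGenerator:
    def test_null_mi_vanishes_at_scale(self, variable_ref):
        clns, truth = synthetic.sample_repertoire(variable_ref, 50_000, seed=6)
        assert truth["gene_mi_nats"] == pytest.approx(0.0, abs=1e-12)
        data = dataset_from_combos(resolve_gene_calls(clns), variable_ref,
                                   [("alpha", 45), ("beta", 45)])
        counts = np.zeros((data.card("a45"), data.card("b45")))
        ia = {s: i for i, s in enumerate(data.alphabets["a45"])}
        ib = {s: i for i, s in enumerate(data.alphabets["b45"])}
        for (sa, sb), w in zip(data.configs.itertuples(index=False),
                               data.weights):
            counts[ia[sa], ib[sb]] += w
        st = dependence_stats(PairCountMatrix(45, 45, counts))
        # empirical MI bias for a r x c table is ~ (r-1)(c-1)/2n
        r, c = counts.shape
        assert st.mi_nats < (r - 1) * (c - 1) / (2 * 50_000) * 5

    def test_coupling_scaled_to_target_and_recovered(self, variable_ref):
        sym_a = sorted({r.gapped_seq[44] for r in variable_ref.records
                        if r.chain == "alpha" and r.seg_class == "V"})
        sym_b = sorted({r.gapped_seq[44] for r in variable_ref.records
                        if r.chain == "beta" and r.seg_class == "V"})
        spec = synthetic.scale_coupling({(sym_a[0], sym_b[0]): 4.0}, variable_ref,
                                        45, 45, 0.03)
        _, _, truth = synthetic.repertoire_joint(variable_ref, couplings=[spec])
        assert truth["couplings"][0]["mi_nats"] == pytest.approx(0.03, abs=1e-8)
        # empirical recovery within 3 sigma
        clns, _ = synthetic.sample_repertoire(variable_ref, 50_000,
                                              couplings=[spec], seed=7)
        data = dataset_from_combos(resolve_gene_calls(clns), variable_ref,
                                   [("alpha", 45), ("beta", 45)])
        counts = np.zeros((data.card("a45"), data.card("b45")))
        ia = {s: i for i, s in enumerate(data.alphabets["a45"])}
        ib = {s: i for i, s in enumerate(data.alphabets["b45"])}
        for (sa, sb), w in zip(data.configs.itertuples(index=False),
                               data.weights):
            counts[ia[sa], ib[sb]] += w
        from tcrpair.pairing import mi_standard_error

        m = PairCountMatrix(45, 45, counts)
        st = dependence_stats(m)
        assert abs(st.mi_nats - 0.03) < 3 * mi_standard_error(m) + 1e-3

    def test_subset_count_within_binomial_range(self, small_ref):
        subset = synthetic.PlantedSubset(("TRAV3", "TRAJ2", "TRBV3", "TRBJ2"),
                                         frequency=0.01)
        n = 50_000
        _, truth = synthetic.sample_repertoire(small_ref, n, subsets=[subset],
                                               seed=8)
        observed = truth["subsets"][0]["observed"]
        sd = (n * 0.01 * 0.99) ** 0.5
        assert abs(observed - n * 0.01) < 3 * sd

    def test_cdr3_flanks_are_germline(self, small_ref):
        clns, _ = synthetic.sample_repertoire(small_ref, 50, seed=9)
        for c in clns:
            v = small_ref.get("alpha", "V", c.v_alpha[0][0])[0]
            assert c.cdr3_alpha[0] == "C"
            assert c.cdr3_alpha[:4] == v.gapped_seq[103:107].replace(GAP, "A")
            assert re.match(r"[FW]", c.cdr3_alpha[-1])

    def test_determinism(self, small_ref):
        a, _ = synthetic.sample_repertoire(small_ref, 200, seed=10)
        b, _ = synthetic.sample_repertoire(small_ref, 200, seed=10)
        assert [c.cdr3_beta for c in a] == [c.cdr3_beta for c in b]

    def test_zeroed_joint_rejected(self, variable_ref):
        sym_a = sorted({r.gapped_seq[44] for r in variable_ref.records
                        if r.chain == "alpha" and r.seg_class == "V"})
        sym_b = sorted({r.gapped_seq[44] for r in variable_ref.records
                        if r.chain == "beta" and r.seg_class == "V"})
        zero = {(a, b): 0.0 for a in sym_a for b in sym_b}
        with pytest.raises(ValueError):
            synthetic.repertoire_joint(
                variable_ref,
                couplings=[synthetic.CouplingSpec(45, 45, zero)])


class TestLinkedPairModel:
    def test_bisection_hits_target(self):
        model = synthetic.linked_pair_model(target_mi=0.002)
        assert model.mi_couple() == pytest.approx(0.002, abs=1e-9)

    def test_joint_normalised_and_sampling_matches(self):
        model = synthetic.LinkedPairModel(w_couple=0.05)
        joint = model.joint()
        assert joint.sum() == pytest.approx(1.0)
        frame, truth = model.sample(30_000, seed=1)
        emp = frame.groupby(["a105", "b105"]).size() / len(frame)
        sym_a = sorted(frame["a105"].unique())
        sym_b = sorted(frame["b105"].unique())
        marg = joint.sum(axis=(0, 2))
        for i, sa in enumerate(sym_a):
            for j, sb in enumerate(sym_b):
                p = emp.get((sa, sb), 0.0)
                sd = (marg[i, j] * (1 - marg[i, j]) / 30_000) ** 0.5
                assert abs(p - marg[i, j]) < 5 * sd + 1e-4


class TestToyComplexes:
    def test_same_seed_byte_identical(self, small_ref, tmp_path):
        model = synthetic.GeometryModel(noise_sigma_deg=2.0)
        p1, _, _ = synthetic.make_toy_complexes(small_ref, model, 2,
                                                tmp_path / "a", seed=12)
        p2, _, _ = synthetic.make_toy_complexes(small_ref, model, 2,
                                                tmp_path / "b", seed=12)
        for a, b in zip(p1, p2):
            assert filecmp.cmp(a, b, shallow=False)

    def test_noise_free_angles_recovered_from_files(self, small_ref, tmp_path):
        from tcrpair.geometry import inter_chain_angles, principal_frame
        from tcrpair.structures import clean_and_map_complex

        model = synthetic.GeometryModel(noise_sigma_deg=0.0, class_offsets={})
        paths, roles, truth = synthetic.make_toy_complexes(
            small_ref, model, 2, tmp_path, seed=13)
        for path, row in zip(paths, truth["structures"]):
            cx = clean_and_map_complex(path, roles, small_ref)
            frames = {}
            for key, ch in (("a", cx.alpha), ("b", cx.beta)):
                coords = np.array([x for r in ch.residues if r.imgt is not None
                                   for x in r.atoms.values()])
                by = ch.by_imgt()
                flank = np.array([by[p].ca for p in range(104, 112) if p in by])
                frames[key] = principal_frame(coords, flank.mean(axis=0))
            rec = inter_chain_angles(frames["a"], frames["b"])
            # PDB coordinates are quantised to 1e-3 A, which bounds the
            # achievable angle precision through the file round trip
            assert np.allclose(rec.degrees(), row["angles_deg"], atol=5e-3)

    def test_ground_truth_sidecar_written(self, small_ref, tmp_path):
        model = synthetic.GeometryModel()
        synthetic.make_toy_complexes(small_ref, model, 1, tmp_path, seed=14)
        with open(tmp_path / "ground_truth.json") as fh:
            truth = json.load(fh)
        assert truth["designated_contacts"] == [[45, 45], [46, 46]]
        assert truth["structures"][0]["label"]

    def test_gapped_reference_rejected(self, tmp_path):
        ref = synthetic.make_reference(n_gap_genes=1, seed=15)
        with pytest.raises(ValueError, match="ungapped"):
            synthetic.make_toy_complexes(ref, synthetic.GeometryModel(), 1,
                                         tmp_path, seed=16)
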