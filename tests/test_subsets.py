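import math

import numpy as np
import pytest

from tcrpair import synthetic
from tcrpair.pairing import PairCountMatrix
from tcrpair.reference import SYMBOL_INDEX, SYMBOLS
from tcrpair.repertoire import WeightedGeneCombo, resolve_gene_calls
from tcrpair.subsets import (TrioRecord, match_subset, round_weights,
                             spectratype, subset_pair_contrast,
                             trio_components, trio_enrichment)


def combo(va="TRAV1", ja="TRAJ1", vb="TRBV1", jb="TRBJ1", w=1.0):
    return WeightedGeneCombo(va, ja, vb, jb, w)


class TestRoundWeights:
    def test_integers_untouched(self):
        np.testing.assert_array_equal(round_weights([2.0, 3.0, 5.0]), [2, 3, 5])

    def test_largest_remainder_preserves_total(self):
        w = np.array([0.6, 0.6, 0.6, 0.2])
        out = round_weights(w)
        assert out.sum() == round(w.sum())
        assert out.tolist() == [1, 1, 0, 0]


def exact_hypergeom_upper(k, big_n, big_k, n):
    """Enumeration oracle: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    total = math.comb(big_n, n)
    return sum(math.comb(big_k, x) * math.comb(big_n - big_k, n - x)
               for x in range(k, min(big_k, n) + 1)) / total


def test_hypergeometric_p_matches_enumeration_oracle():
    from scipy import stats

    rng = np.random.default_rng(0)
    for _ in range(200):
        big_n = int(rng.integers(2, 50))
        big_k = int(rng.integers(1, big_n + 1))
        n = int(rng.integers(1, big_n + 1))
        k = int(rng.integers(0, min(big_k, n) + 1))
        sp = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        assert sp == pytest.approx(exact_hypergeom_upper(k, big_n, big_k, n),
                                   abs=1e-12)


def test_exact_p_5_5_10():
    assert exact_hypergeom_upper(5, 10, 5, 5) == pytest.approx(1 / 252)


class TestTrioEnrichment:
    def test_counts_and_expected(self):
        combos = [combo(w=4.0)] * 5 + [combo(vb="TRBV2", w=4.0)] * 5
        records = trio_enrichment(combos, min_count=10)
        r = next(r for r in records if r.kind == "VaJaVb"
                 and r.genes == ("TRAV1", "TRAJ1", "TRBV1"))
        assert (r.k, r.big_k, r.n, r.big_n) == (20, 40, 20, 40)
        assert r.expected == pytest.approx(20.0)
        assert math.log2(r.k / r.expected) == pytest.approx(0.0)

    def test_holm_is_monotone_and_above_raw(self):
        rng = np.random.default_rng(1)
        combos = [combo(va=f"TRAV{rng.integers(1, 4)}",
                        vb=f"TRBV{rng.integers(1, 4)}", w=3.0)
                  for _ in range(200)]
        records = trio_enrichment(combos, min_count=1)
        for r in records:
            assert r.adj_p >= r.p_value - 1e-15
            assert r.adj_p <= 1.0

    def test_planted_trio_attains_smallest_adjusted_p(self):
        from tcrpair import validation

        res = validation.trio_discovery_study(seed=5, n=30_000)
        assert res["planted_trio_is_min_adj_p"] == 1
        assert res["planted_component_pure"] == 1


class TestTrioGraph:
    def _records(self, quartets, kinds):
        out = []
        for q, kind in zip(quartets, kinds):
            slots = {"JaVbJb": (1, 2, 3), "VaVbJb": (0, 2, 3),
                     "VaJaJb": (0, 1, 3), "VaJaVb": (0, 1, 2)}[kind]
            out.append(TrioRecord(kind=kind,
                                  genes=tuple(q[s] for s in slots),
                                  k=20, big_k=30, n=30, big_n=100,
                                  expected=9.0, p_value=1e-6, adj_p=1e-4))
        return out

    def test_wildcard_compatible_trios_connect(self):
        q = ("TRAV1-2", "TRAJ33", "TRBV6-4", "TRBJ2-1")
        recs = self._records([q, q], ["VaJaVb", "VaVbJb"])
        graph = trio_components(recs)
        assert len(graph.components) == 1
        assert len(graph.components[0]) == 2

    def test_conflicting_slot_disconnects(self):
        q1 = ("TRAV1-2", "TRAJ33", "TRBV6-4", "TRBJ2-1")
        q2 = ("TRAV10", "TRAJ33", "TRBV6-4", "TRBJ2-1")
        recs = self._records([q1, q2], ["VaJaVb", "VaJaVb"])
        graph = trio_components(recs)
        assert len(graph.components) == 2

    def test_two_planted_populations_give_two_components(self):
        ref = synthetic.make_reference(n_v_alpha=4, n_j_alpha=3, n_v_beta=4,
                                       n_j_beta=3, seed=9)
        subsets_ = [
            synthetic.PlantedSubset(("TRAV1", "TRAJ1", "TRBV1", "TRBJ1"), 0.02),
            synthetic.PlantedSubset(("TRAV4", "TRAJ3", "TRBV4", "TRBJ3"), 0.02),
        ]
        clns, _ = synthetic.sample_repertoire(ref, 30_000, subsets=subsets_,
                                              seed=10)
        records = trio_enrichment(resolve_gene_calls(clns))
        graph = trio_components(records)
        planted_sets = [set(s.genes) for s in subsets_]
        big = [c for c in graph.components if len(c) > 1]
        hit = 0
        for comp in big:
            genes = {g for m in comp for g in m.genes}
            if any(genes <= p for p in planted_sets):
                hit += 1
        assert hit == 2


class TestSpectratype:
    def test_point_mass_length(self):
        spec = spectratype(["CAVRGGSQGNLIF"] * 5, ["CASSLGQAYEQYF"] * 5)
        assert spec.lengths_subset == {13: 1.0}
        assert spec.dominance == 1.0

    def test_pfm_consensus_recovers_motif(self):
        motif = "CAVRGGSQGNLIF"
        noisy = [motif[:5] + "A" + motif[6:], motif, motif, motif]
        spec = spectratype(noisy, [])
        assert spec.consensus() == motif
        np.testing.assert_allclose(spec.pfm.sum(axis=1), 1.0)

    def test_background_equal_subset(self):
        seqs = ["CAVRGGSQGNLIF", "CASSLGQAYEQYF"]
        spec = spectratype(seqs, seqs)
        assert spec.lengths_subset == spec.lengths_background

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            spectratype([], ["CAVRGGSQGNLIF"])


class TestContrast:
    def _matrix(self, cells):
        counts = np.zeros((len(SYMBOLS), len(SYMBOLS)))
        for (sa, sb), v in cells.items():
            counts[SYMBOL_INDEX[sa], SYMBOL_INDEX[sb]] = v
        return PairCountMatrix(108, 55, counts)

    def test_subset_equal_background_gives_zero(self):
        m = self._matrix({("Q", "Y"): 30, ("A", "G"): 70})
        out = subset_pair_contrast({(108, 55): m}, {(108, 55): m},
                                   {(108, 55): m})
        assert all(c.log2_subset_ratio == pytest.approx(0.0) for c in out)

    def test_enriched_cell_positive_log_ratio(self):
        sub = self._matrix({("Q", "Y"): 60, ("A", "G"): 40})
        bg = self._matrix({("Q", "Y"): 30, ("A", "G"): 70})
        out = subset_pair_contrast({(108, 55): sub}, {(108, 55): bg},
                                   {(108, 55): bg})
        qy = next(c for c in out if c.aa_pair == ("Q", "Y"))
        assert qy.log2_subset_ratio > 0.25

    def test_log2_threshold_frequency_conversions(self):
        assert 2 ** 0.25 - 1 == pytest.approx(0.19, abs=0.001)
        assert 2 ** 0.125 - 1 == pytest.approx(0.09, abs=0.001)

    def test_empty_subset_rejected(self):
        empty = self._matrix({})
        full = self._matrix({("Q", "Y"): 10})
        with pytest.raises(ValueError):
            subset_pair_contrast({(108, 55): empty}, {(108, 55): full},
                                 {(108, 55): full})


def test_match_subset_with_free_slots():
    c = combo(va="TRAV1-2", ja="TRAJ33", vb="TRBV6-4", jb="TRBJ2-1")
    mait = {"v_alpha": {"TRAV1-2"}, "j_alpha": {"TRAJ12", "TRAJ20", "TRAJ33"},
            "v_beta": {"TRBV6-4", "TRBV20"}}
    assert match_subset(c, mait)
    assert not match_subset(combo(va="TRAV2"), mait)
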