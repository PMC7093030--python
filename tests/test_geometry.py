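import math

import numpy as np
import pytest

from tcrpair.geometry import (ChainFrame, angle_aa_association,
                              collapse_by_gene_combo, euler_zxz_to_matrix,
                              inter_chain_angles, principal_frame,
                              OrientationAngles)


@pytest.fixture()
def blob():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(60, 3)) * np.array([5.0, 2.0, 1.0])
    return pts - pts.mean(axis=0)


CENTROID = np.array([10.0, 4.0, 1.0])


class TestPrincipalFrame:
    def test_rotation_equivariance(self, blob):
        r = euler_zxz_to_matrix(*np.radians([25.0, 40.0, -60.0]))
        f0 = principal_frame(blob, CENTROID)
        f1 = principal_frame(blob @ r.T, r @ CENTROID)
        np.testing.assert_allclose(f1.axes, r @ f0.axes, atol=1e-9)

    def test_translation_invariance(self, blob):
        shift = np.array([100.0, -50.0, 3.0])
        f0 = principal_frame(blob, CENTROID)
        f1 = principal_frame(blob + shift, CENTROID + shift)
        np.testing.assert_allclose(f1.axes, f0.axes, atol=1e-12)
        np.testing.assert_allclose(f1.center, f0.center + shift, atol=1e-9)

    def test_atom_order_invariance(self, blob):
        rng = np.random.default_rng(1)
        f0 = principal_frame(blob, CENTROID)
        f1 = principal_frame(blob[rng.permutation(len(blob))], CENTROID)
        np.testing.assert_allclose(f1.axes, f0.axes, atol=1e-9)

    def test_right_handed_orthonormal(self, blob):
        f = principal_frame(blob, CENTROID)
        np.testing.assert_allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(f.axes) == pytest.approx(1.0)

    def test_symmetric_shell_flags_degenerate(self):
        # octahedron vertices: all three principal moments exactly equal
        pts = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 1], [0, 0, -1]], dtype=float)
        assert principal_frame(pts, CENTROID).degenerate

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(ValueError):
            principal_frame(np.zeros((3, 3)), CENTROID)
        line = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            principal_frame(line, CENTROID)


class TestEulerAngles:
    def test_identity_frames_give_zero(self):
        f = ChainFrame(center=np.zeros(3), axes=np.eye(3), n_atoms=4)
        rec = inter_chain_angles(f, f)
        assert rec.degrees() == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    @pytest.mark.parametrize("angles", [(30.0, 40.0, 50.0),
                                        (-120.0, 90.0, 10.0),
                                        (179.0, 1.0, -179.0)])
    def test_roundtrip_recovers_planted_angles(self, angles):
        r = euler_zxz_to_matrix(*np.radians(angles))
        base = ChainFrame(center=np.zeros(3), axes=np.eye(3), n_atoms=4)
        rot = ChainFrame(center=np.zeros(3), axes=r, n_atoms=4)
        rec = inter_chain_angles(rot, base)
        assert np.allclose(rec.degrees(), angles, atol=1e-6)

    def test_gimbal_lock_collapses_into_phi1(self):
        r = euler_zxz_to_matrix(*np.radians([20.0, 0.0, 30.0]))
        base = ChainFrame(center=np.zeros(3), axes=np.eye(3), n_atoms=4)
        rec = inter_chain_angles(
            ChainFrame(center=np.zeros(3), axes=r, n_atoms=4), base)
        assert rec.gimbal
        assert rec.phi3 == 0.0
        assert math.degrees(rec.phi1) == pytest.approx(50.0, abs=1e-6)

    def test_angle_ranges(self):
        rng = np.random.default_rng(3)
        base = ChainFrame(center=np.zeros(3), axes=np.eye(3), n_atoms=4)
        for _ in range(50):
            angles = rng.uniform(-math.pi, math.pi, 3)
            r = euler_zxz_to_matrix(*angles)
            rec = inter_chain_angles(
                ChainFrame(center=np.zeros(3), axes=r, n_atoms=4), base)
            assert 0.0 <= rec.phi2 <= math.pi
            assert -math.pi < rec.phi1 <= math.pi
            assert -math.pi < rec.phi3 <= math.pi


def rec(label, p1, p2=20.0, p3=30.0):
    return OrientationAngles(phi1=math.radians(p1), phi2=math.radians(p2),
                             phi3=math.radians(p3), label=label)


class TestCollapse:
    def test_plain_mean_within_label(self):
        out = collapse_by_gene_combo([rec("L", 10.0, p3=10.0),
                                      rec("L", 10.0, p3=20.0)])
        assert len(out) == 1
        assert math.degrees(out[0].phi3) == pytest.approx(15.0)

    def test_singleton_unchanged(self):
        out = collapse_by_gene_combo([rec("L", 33.0)])
        assert math.degrees(out[0].phi1) == pytest.approx(33.0)

    def test_wraparound_unwrap_rule(self):
        out = collapse_by_gene_combo([rec("L", 179.0), rec("L", -179.0)])
        assert abs(math.degrees(out[0].phi1)) == pytest.approx(180.0)

    def test_unlabelled_rejected(self):
        with pytest.raises(ValueError):
            collapse_by_gene_combo([OrientationAngles(0.0, 0.1, 0.0)])


class TestAssociation:
    def _collapsed(self, offsets, sigma=2.0, n_per_class=8, seed=0):
        rng = np.random.default_rng(seed)
        collapsed, symbols = [], {}
        i = 0
        for aa, off in offsets.items():
            for _ in range(n_per_class):
                label = f"L{i}"
                i += 1
                collapsed.append(OrientationAngles(
                    phi1=math.radians(rng.normal(40, sigma)),
                    phi2=math.radians(rng.normal(60, sigma)),
                    phi3=math.radians(rng.normal(30 + off, sigma)),
                    label=label))
                symbols[label] = {"a57": aa}
        return collapsed, symbols

    def test_planted_offset_flagged(self):
        collapsed, symbols = self._collapsed({"K": 30.0, "D": 0.0, "L": 0.0})
        tests = angle_aa_association(collapsed, symbols, ["a57"])
        by_angle = {t.angle_index: t for t in tests}
        assert by_angle[3].adj_p < 0.05
        assert by_angle[3].adj_p == min(t.adj_p for t in tests)

    def test_null_angles_mostly_unflagged(self):
        collapsed, symbols = self._collapsed({"K": 0.0, "D": 0.0, "L": 0.0},
                                             seed=5)
        tests = angle_aa_association(collapsed, symbols, ["a57"])
        assert all(t.adj_p > 0.05 for t in tests if t.testable)

    def test_single_class_untestable(self):
        collapsed, symbols = self._collapsed({"K": 0.0})
        tests = angle_aa_association(collapsed, symbols, ["a57"])
        assert all(not t.testable for t in tests)

    def test_adjusted_p_never_below_raw(self):
        collapsed, symbols = self._collapsed({"K": 10.0, "D": 0.0})
        for t in angle_aa_association(collapsed, symbols, ["a57"]):
            if t.testable:
                assert t.adj_p >= t.p_value - 1e-15
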