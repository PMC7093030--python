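"""Chain-orientation geometry: principal axes and inter-chain Euler angles.

Each TCR chain's variable domain is approximated as a rigid body: the
inertia tensor of its atoms (constant-domain atoms excluded) is
diagonalised about the centre of mass, giving three principal axes
ordered by ascending principal moment.  The sign of each of the first
two axes is fixed to point towards the centroid of the CDR3-flank
residues (IMGT 104-111) so frames are reproducible across structures;
the third axis completes a right-handed set.  The relative orientation
of the alpha and beta frames, after superimposing the centres of mass,
is expressed as proper z-x-z Euler angles (phi1, phi2, phi3).

Association between the amino-acid class observed at a contact position
and each Euler angle is tested by one-way ANOVA over the non-redundant
set of gene combinations (structures sharing a VaJaVbJb label collapsed
to mean angles), with Holm adjustment across all (position, angle)
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

#: Default 5-class amino-acid grouping (aliphatic, aromatic, polar,
#: basic, acidic); configurable everywhere it is consumed.
AA_CLASSES: dict[str, str] = {}
for _cls, _aas in [("aliphatic", "GAVLIP"), ("aromatic", "FWY"),
                   ("polar", "STCMNQ"), ("basic", "KRH"), ("acidic", "DE")]:
    for _a in _aas:
        AA_CLASSES[_a] = _cls

GIMBAL_TOL = 1e-6


@dataclass
class ChainFrame:
    center: np.ndarray            # centre of mass, Angstrom
    axes: np.ndarray              # 3x3 rotation matrix, axes as columns
    n_atoms: int
    degenerate: bool = False

    def __post_init__(self):
        assert np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8)


@dataclass
class OrientationAngles:
    phi1: float                   # radians, (-pi, pi]
    phi2: float                   # radians, [0, pi]
    phi3: float                   # radians, (-pi, pi]
    complex_id: str = ""
    label: str = ""               # VaJaVbJb gene combination
    gimbal: bool = False

    def degrees(self) -> tuple[float, float, float]:
        return tuple(math.degrees(a) for a in (self.phi1, self.phi2, self.phi3))


@dataclass
class AngleAssociation:
    position: str                 # variable name, e.g. 'a57'
    angle_index: int              # 1..3
    f_score: float
    p_value: float
    adj_p: float = float("nan")
    group_sizes: dict[str, int] = field(default_factory=dict)
    testable: bool = True


def principal_frame(coords: np.ndarray, cdr3_centroid: np.ndarray,
                    masses: np.ndarray | None = None) -> ChainFrame:
    """Principal-axis frame of a chain from its (masked) atom coordinates.

    ``cdr3_centroid`` anchors the axis-sign convention: the first two
    axes point towards the CDR3-flank centroid, the third enforces
    right-handedness.  Two principal moments equal within 1e-6 flag a
    degenerate (symmetric) body; the tie is then broken by the fixed
    eigenvector order, deterministically.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 4:
        raise ValueError("need at least 4 atoms to define a frame")
    m = np.ones(len(coords)) if masses is None else np.asarray(masses, float)
    com = (coords * m[:, None]).sum(axis=0) / m.sum()
    r = coords - com
    if np.linalg.matrix_rank(r, tol=1e-9) < 2:
        raise ValueError("collinear atoms cannot define a frame")
    # inertia tensor about the centre of mass
    r2 = (r ** 2).sum(axis=1)
    inertia = np.einsum("i,ijk->jk", m, r2[:, None, None] * np.eye(3)[None]) \
        - np.einsum("i,ij,ik->jk", m, r, r)
    moments, vecs = np.linalg.eigh(inertia)   # ascending moments
    degenerate = bool(np.any(np.diff(moments) < 1e-6 * max(moments[-1], 1.0)))
    toward = np.asarray(cdr3_centroid, float) - com
    axes = np.empty((3, 3))
    for i in range(2):
        v = vecs[:, i]
        if np.dot(v, toward) < 0:
            v = -v
        axes[:, i] = v
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    assert np.linalg.det(axes) > 0
    return ChainFrame(center=com, axes=axes, n_atoms=len(coords), degenerate=degenerate)


def euler_zxz_to_matrix(phi1: float, phi2: float, phi3: float) -> np.ndarray:
    """Rotation matrix of the proper z-x-z Euler composition Z(phi1) X(phi2) Z(phi3)."""
    return Rotation.from_euler("ZXZ", [phi1, phi2, phi3]).as_matrix()


def inter_chain_angles(frame_alpha: ChainFrame, frame_beta: ChainFrame,
                       complex_id: str = "", label: str = "") -> OrientationAngles:
    """z-x-z Euler angles of the alpha frame relative to the beta frame.

    Centres of mass are superimposed implicitly (only the rotation
    ``R_beta^T R_alpha`` matters).  Near gimbal lock (phi2 ~ 0 or pi)
    phi1 absorbs the total z-rotation and phi3 is set to 0, flagged.
    """
    import warnings

    r_rel = frame_beta.axes.T @ frame_alpha.axes
    rot = Rotation.from_matrix(r_rel)
    gimbal = False
    with warnings.catch_warnings():
        # gimbal lock is handled explicitly below
        warnings.simplefilter("ignore", UserWarning)
        phi1, phi2, phi3 = rot.as_euler("ZXZ")
    if phi2 < 0:   # canonicalise to phi2 in [0, pi]
        phi1, phi2, phi3 = _canonical(phi1, phi2, phi3)
    if phi2 < GIMBAL_TOL or math.pi - phi2 < GIMBAL_TOL:
        gimbal = True
        phi1 = _wrap(phi1 + (phi3 if phi2 < GIMBAL_TOL else -phi3))
        phi3 = 0.0
    return OrientationAngles(phi1=phi1, phi2=phi2, phi3=phi3,
                             complex_id=complex_id, label=label, gimbal=gimbal)


def _canonical(p1, p2, p3):
    return _wrap(p1 + math.pi), -p2, _wrap(p3 + math.pi)


def _wrap(a: float) -> float:
    a = (a + math.pi) % (2 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


def _circular_mean(values: np.ndarray) -> float:
    return math.atan2(np.mean(np.sin(values)), np.mean(np.cos(values)))


def _unwrapped_mean(values: np.ndarray) -> float:
    """Arithmetic mean after unwrapping to the branch around the circular mean."""
    center = _circular_mean(values)
    shifted = np.array([center + _wrap(v - center) for v in values])
    return _wrap(float(shifted.mean()))


def collapse_by_gene_combo(angles: list[OrientationAngles]) -> list[OrientationAngles]:
    """One observation per VaJaVbJb label with per-angle means.

    Angles are unwrapped to a common branch before averaging so that
    e.g. 179 deg and -179 deg average to 180 deg, not 0.
    """
    by_label: dict[str, list[OrientationAngles]] = {}
    for a in angles:
        if not a.label:
            raise ValueError(f"unlabelled orientation record {a.complex_id}")
        by_label.setdefault(a.label, []).append(a)
    out = []
    for label in sorted(by_label):
        group = by_label[label]
        p1 = _unwrapped_mean(np.array([g.phi1 for g in group]))
        p2 = float(np.mean([g.phi2 for g in group]))   # phi2 lives on [0, pi]
        p3 = _unwrapped_mean(np.array([g.phi3 for g in group]))
        out.append(OrientationAngles(phi1=p1, phi2=p2, phi3=p3,
                                     complex_id=";".join(g.complex_id for g in group),
                                     label=label))
    return out


def angle_aa_association(collapsed: list[OrientationAngles],
                         symbols_by_label: dict[str, dict[str, str]],
                         positions: list[str],
                         class_scheme: dict[str, str] | None = None,
                         ) -> list[AngleAssociation]:
    """One-way ANOVA of each Euler angle on amino-acid class per position.

    ``symbols_by_label`` maps a gene-combination label to its residue
    symbols per variable (e.g. ``{'a57': 'K'}``).  Positions with fewer
    than two classes holding >= 2 observations are recorded untestable.
    P-values are Holm-adjusted across all performed (position, angle)
    tests.
    """
    scheme = AA_CLASSES if class_scheme is None else class_scheme
    tests: list[AngleAssociation] = []
    for pos in positions:
        groups: dict[str, list[tuple[float, float, float]]] = {}
        for rec in collapsed:
            sym = symbols_by_label.get(rec.label, {}).get(pos)
            if sym is None or sym not in scheme:
                continue
            groups.setdefault(scheme[sym], []).append((rec.phi1, rec.phi2, rec.phi3))
        usable = {c: v for c, v in groups.items() if len(v) >= 2}
        sizes = {c: len(v) for c, v in groups.items()}
        if len(usable) < 2:
            for angle_idx in (1, 2, 3):
                tests.append(AngleAssociation(position=pos, angle_index=angle_idx,
                                              f_score=float("nan"), p_value=float("nan"),
                                              group_sizes=sizes, testable=False))
            continue
        for angle_idx in (1, 2, 3):
            samples = [np.array([v[angle_idx - 1] for v in vals])
                       for vals in usable.values()]
            f, p = stats.f_oneway(*samples)
            tests.append(AngleAssociation(position=pos, angle_index=angle_idx,
                                          f_score=float(f), p_value=float(p),
                                          group_sizes=sizes))
    performed = [t for t in tests if t.testable and np.isfinite(t.p_value)]
    if performed:
        _, adj, _, _ = multipletests([t.p_value for t in performed], method="holm")
        for t, a in zip(performed, adj):
            t.adj_p = float(a)
    return tests
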