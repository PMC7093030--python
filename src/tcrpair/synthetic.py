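"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline's input surface:

* :func:`make_reference` -- IMGT-gapped germline V/J sets with enforced
  Cys-104 and [FW]GXG anchors and a tunable fraction of variable
  positions, so both conserved and variable residue classes occur.
* :func:`sample_repertoire` -- paired clonotypes drawn from an exactly
  constructed joint over (Va,Ja) x (Vb,Jb).  Inter-chain couplings are
  expressed at the symbol level (multiplier tables over amino-acid
  pairs at designated contact positions), so the planted information is
  exactly the quantity the downstream mutual-information and network
  stages estimate; the analytic MI of each coupling is computed from
  the closed-form joint and written to the ground-truth sidecar.
  Invariant subsets and epitope groups with biased gene usage are
  injected at stated frequencies.
* :func:`make_toy_complexes` -- PDB complexes whose chains share one
  rigid template with exactly diagonal inertia, so the beta frame is the
  identity and the alpha chain's planted z-x-z rotation (base angles +
  per-amino-acid-class offsets + Gaussian noise) is recovered exactly by
  the geometry stage when noise is zero.

Everything is deterministic given (config, seed); each generator emits
a machine-readable ground-truth dict (JSON-serialisable).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AA_CLASSES, euler_zxz_to_matrix
from .reference import (AA20, GAP, J_ANCHOR_MOTIF, GeneRecord, GeneReference,
                        index_clonotype_residues)
from .repertoire import PairedClonotype

V_LENGTH = 107        # IMGT positions 1..107 (Cys-104 + 3 CDR3 flank residues)
J_LENGTH = 9          # positions 108..116, anchor Phe/Trp at 111


# ---------------------------------------------------------------------------
# germline reference generator

def make_reference(n_v_alpha: int = 3, n_j_alpha: int = 2,
                   n_v_beta: int = 3, n_j_beta: int = 2,
                   variability: float = 0.5, n_gap_genes: int = 0,
                   seed: int = 0) -> GeneReference:
    """Random germline reference with controllable per-position variability.

    ``variability`` is the fraction of V positions whose residue differs
    across genes (0 makes all genes of a chain identical).  V genes span
    IMGT 1..107 with Cys enforced at 104; J genes span 108..116 with the
    [FW]GXG anchor starting at 111.  ``n_gap_genes`` V genes per chain
    get an IMGT gap at position 10 (to exercise gap handling).
    """
    if min(n_v_alpha, n_j_alpha, n_v_beta, n_j_beta) < 1:
        raise ValueError("need at least one gene per segment class")
    rng = np.random.default_rng(seed)
    records = []
    for chain, prefix, n_v, n_j in (("alpha", "TRA", n_v_alpha, n_j_alpha),
                                    ("beta", "TRB", n_v_beta, n_j_beta)):
        variable = rng.random(V_LENGTH) < variability
        consensus = rng.choice(list(AA20), V_LENGTH)
        for g in range(n_v):
            seq = consensus.copy()
            mask = variable.copy()
            seq[mask] = rng.choice(list(AA20), int(mask.sum()))
            seq[103] = "C"                       # IMGT 104 anchor
            seq = "".join(seq)
            if g < n_gap_genes:
                seq = seq[:9] + GAP + seq[10:]
            records.append(GeneRecord(chain, "V", f"{prefix}V{g + 1}", "01", seq))
        j_variable = rng.random(3) < max(variability, 1e-9)
        j_consensus = rng.choice(list(AA20), 3)
        for g in range(n_j):
            while True:
                head = j_consensus.copy()
                head[j_variable] = rng.choice(list(AA20), int(j_variable.sum()))
                anchor = rng.choice(["F", "W"])
                x = rng.choice(list(AA20))
                tail = "".join(rng.choice(list(AA20), J_LENGTH - 7))
                seq = "".join(head) + anchor + "G" + x + "G" + tail
                # the first [FW]GXG occurrence must be the real anchor so
                # position 111 maps where intended
                if J_ANCHOR_MOTIF.search(seq).start() == 3:
                    break
            records.append(GeneRecord(chain, "J", f"{prefix}J{g + 1}", "01", seq))
    return GeneReference(records)


def set_residue(ref: GeneReference, chain: str, seg_class: str, name: str,
                position: int, aa: str) -> None:
    """Overwrite one residue of one germline record (planting helper)."""
    rec = ref.get(chain, seg_class, name)[0]
    pos_map = rec.positions()
    if position not in pos_map:
        raise KeyError(f"{name} does not cover IMGT position {position}")
    if seg_class == "V":
        i = position - 1
    else:
        i = position - min(pos_map)
    rec.gapped_seq = rec.gapped_seq[:i] + aa + rec.gapped_seq[i + 1:]


def write_reference_tsv(ref: GeneReference, path) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tclass\tname\tallele\tgapped_seq\n")
        for rec in ref.records:
            fh.write(f"{rec.chain}\t{rec.seg_class}\t{rec.name}\t"
                     f"{rec.allele}\t{rec.gapped_seq}\n")


# ---------------------------------------------------------------------------
# paired repertoire generator

@dataclass
class CouplingSpec:
    """Symbol-level inter-chain coupling at one contact position pair.

    The baseline joint over gene combinations is reweighted by
    ``multipliers[(sym_alpha, sym_beta)]`` (default 1) where the symbols
    are the germline residues the genes place at the two positions.
    """

    alpha_pos: int
    beta_pos: int
    multipliers: dict[tuple[str, str], float]

    def factor(self, sym_a: str, sym_b: str) -> float:
        m = self.multipliers.get((sym_a, sym_b), 1.0)
        if m < 0:
            raise ValueError("negative coupling multiplier")
        return m


@dataclass
class PlantedSubset:
    """An invariant population: fixed gene quartet, fixed-length motif CDR3s."""

    genes: tuple[str, str, str, str]      # (Va, Ja, Vb, Jb)
    frequency: float
    cdr3_alpha_middle: str = "GGS"        # middle between the germline flanks
    cdr3_beta_middle: str = "TGEL"

    def __post_init__(self):
        if not 0 < self.frequency < 1:
            raise ValueError("subset frequency must be in (0, 1)")


@dataclass
class EpitopeSpec:
    """An antigen-specific group with optionally biased beta V usage."""

    name: str
    n_records: int
    v_beta_bias: dict[str, float] = field(default_factory=dict)


def _usage(ref: GeneReference, chain: str, seg_class: str,
           override: dict[str, float] | None) -> dict[str, float]:
    genes = ref.genes(chain, seg_class)
    if override:
        total = sum(override.get(g, 0.0) for g in genes)
        if total <= 0:
            raise ValueError("usage override sums to zero over reference genes")
        return {g: override.get(g, 0.0) / total for g in genes}
    # power-law default: realistic skew, deterministic
    raw = {g: 1.0 / (i + 1) for i, g in enumerate(genes)}
    total = sum(raw.values())
    return {g: w / total for g, w in raw.items()}


def _germline_symbol(ref: GeneReference, chain: str, v: str, j: str,
                     pos: int) -> str:
    rec = ref.get(chain, "J" if pos >= 108 else "V", j if pos >= 108 else v)[0]
    return rec.positions().get(pos, GAP)


def _mutual_information(joint: np.ndarray) -> float:
    """MI (nats) of a 2-D joint by direct summation."""
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log(joint / (pa * pb)), 0.0)
    return float(terms.sum())


def repertoire_joint(ref: GeneReference,
                     usage: dict[str, dict[str, float]] | None = None,
                     couplings: list[CouplingSpec] | None = None):
    """Closed-form joint over (Va, Ja, Vb, Jb) gene combinations.

    Returns (combos, probabilities, ground_truth) where ground truth
    holds the analytic mutual information of each coupling's symbol
    pair and of the full alpha-vs-beta gene partition.
    """
    usage = usage or {}
    dists = {
        ("alpha", "V"): _usage(ref, "alpha", "V", usage.get("v_alpha")),
        ("alpha", "J"): _usage(ref, "alpha", "J", usage.get("j_alpha")),
        ("beta", "V"): _usage(ref, "beta", "V", usage.get("v_beta")),
        ("beta", "J"): _usage(ref, "beta", "J", usage.get("j_beta")),
    }
    keys = [sorted(dists[k]) for k in (("alpha", "V"), ("alpha", "J"),
                                       ("beta", "V"), ("beta", "J"))]
    combos = list(itertools.product(*keys))
    probs = np.array([
        dists[("alpha", "V")][va] * dists[("alpha", "J")][ja]
        * dists[("beta", "V")][vb] * dists[("beta", "J")][jb]
        for va, ja, vb, jb in combos])
    for spec in couplings or []:
        factors = np.array([
            spec.factor(_germline_symbol(ref, "alpha", va, ja, spec.alpha_pos),
                        _germline_symbol(ref, "beta", vb, jb, spec.beta_pos))
            for va, ja, vb, jb in combos])
        probs = probs * factors
    if probs.sum() <= 0:
        raise ValueError("coupling multipliers drive the joint to zero")
    probs = probs / probs.sum()

    truth = {"couplings": []}
    for spec in couplings or []:
        syms_a = sorted({_germline_symbol(ref, "alpha", va, ja, spec.alpha_pos)
                         for va, ja, vb, jb in combos})
        syms_b = sorted({_germline_symbol(ref, "beta", vb, jb, spec.beta_pos)
                         for va, ja, vb, jb in combos})
        joint = np.zeros((len(syms_a), len(syms_b)))
        for (va, ja, vb, jb), p in zip(combos, probs):
            ia = syms_a.index(_germline_symbol(ref, "alpha", va, ja, spec.alpha_pos))
            ib = syms_b.index(_germline_symbol(ref, "beta", vb, jb, spec.beta_pos))
            joint[ia, ib] += p
        truth["couplings"].append({
            "alpha_pos": spec.alpha_pos, "beta_pos": spec.beta_pos,
            "mi_nats": _mutual_information(joint),
            "symbols_alpha": syms_a, "symbols_beta": syms_b,
            "symbol_joint": joint.tolist(),
        })
    n_a = len(keys[0]) * len(keys[1])
    gene_joint = probs.reshape(n_a, -1)
    truth["gene_mi_nats"] = _mutual_information(gene_joint)
    return combos, probs, truth


def scale_coupling(base: dict[tuple[str, str], float], ref: GeneReference,
                   alpha_pos: int, beta_pos: int, target_mi: float,
                   usage=None, tol: float = 1e-10) -> CouplingSpec:
    """Exponent-scale a multiplier table so the planted MI hits a target.

    Searches ``multipliers ** t`` by bisection on t >= 0; the resulting
    spec's analytic MI equals ``target_mi`` within ``tol``.
    """

    def mi_at(t: float) -> float:
        spec = CouplingSpec(alpha_pos, beta_pos,
                            {k: v ** t for k, v in base.items()})
        _, _, truth = repertoire_joint(ref, usage=usage, couplings=[spec])
        return truth["couplings"][0]["mi_nats"]

    hi = 1.0
    while mi_at(hi) < target_mi:
        hi *= 2
        if hi > 64:
            raise ValueError("base multipliers cannot reach the target MI")
    lo = 0.0
    while hi - lo > 1e-12:
        mid = (lo + hi) / 2
        if mi_at(mid) < target_mi:
            lo = mid
        else:
            hi = mid
        if abs(mi_at(mid) - target_mi) < tol:
            break
    t = (lo + hi) / 2
    return CouplingSpec(alpha_pos, beta_pos, {k: v ** t for k, v in base.items()})


def sample_repertoire(ref: GeneReference, n: int,
                      usage: dict[str, dict[str, float]] | None = None,
                      couplings: list[CouplingSpec] | None = None,
                      subsets: list[PlantedSubset] | None = None,
                      epitopes: list[EpitopeSpec] | None = None,
                      cdr3_middle_len: tuple[int, int] = (2, 6),
                      seed: int = 0):
    """Draw a paired repertoire from the closed-form joint.

    Returns (clonotypes, ground_truth).  Baseline clones sample
    (Va, Ja, Vb, Jb) from the coupling-reweighted joint -- no rejection,
    so the generator's distribution is known exactly.  Subset clones
    replace a ``frequency`` fraction with fixed gene quartets and
    fixed-length CDR3s; epitope clones are appended with biased Vb
    usage and carry the epitope label.  CDR3s are germline 4+4 flanks
    around a random middle (excluded from all indexed analyses).
    """
    rng = np.random.default_rng(seed)
    combos, probs, truth = repertoire_joint(ref, usage, couplings)
    subsets = subsets or []
    epitopes = epitopes or []
    total_subset_freq = sum(s.frequency for s in subsets)
    if total_subset_freq >= 1:
        raise ValueError("subset frequencies sum to >= 1")

    def make_cdr3(chain: str, v: str, j: str, middle: str | None) -> str:
        first4 = "".join(_germline_symbol(ref, chain, v, j, p)
                         for p in range(104, 108)).replace(GAP, "A")
        last4 = "".join(_germline_symbol(ref, chain, v, j, p)
                        for p in range(108, 112)).replace(GAP, "A")
        if middle is None:
            length = rng.integers(cdr3_middle_len[0], cdr3_middle_len[1] + 1)
            middle = "".join(rng.choice(list(AA20), length))
        return first4 + middle + last4

    clonotypes = []
    subset_counts = [0] * len(subsets)
    u = rng.random(n)
    combo_draws = rng.choice(len(combos), size=n, p=probs)
    for i in range(n):
        chosen = None
        acc = 0.0
        for si, s in enumerate(subsets):
            acc += s.frequency
            if u[i] < acc:
                chosen = si
                break
        if chosen is not None:
            s = subsets[chosen]
            subset_counts[chosen] += 1
            va, ja, vb, jb = s.genes
            cdr3a = make_cdr3("alpha", va, ja, s.cdr3_alpha_middle)
            cdr3b = make_cdr3("beta", vb, jb, s.cdr3_beta_middle)
        else:
            va, ja, vb, jb = combos[combo_draws[i]]
            cdr3a = make_cdr3("alpha", va, ja, None)
            cdr3b = make_cdr3("beta", vb, jb, None)
        clonotypes.append(PairedClonotype(
            clonotype_id=f"c{i}", v_alpha=[(va, 1.0)], j_alpha=[(ja, 1.0)],
            cdr3_alpha=cdr3a, v_beta=[(vb, 1.0)], j_beta=[(jb, 1.0)],
            cdr3_beta=cdr3b, count=1.0))

    for spec in epitopes:
        ep_usage = dict(usage or {})
        if spec.v_beta_bias:
            ep_usage["v_beta"] = spec.v_beta_bias
        ep_combos, ep_probs, _ = repertoire_joint(ref, ep_usage, couplings)
        draws = rng.choice(len(ep_combos), size=spec.n_records, p=ep_probs)
        for k, d in enumerate(draws):
            va, ja, vb, jb = ep_combos[d]
            clonotypes.append(PairedClonotype(
                clonotype_id=f"{spec.name}-{k}",
                v_alpha=[(va, 1.0)], j_alpha=[(ja, 1.0)],
                cdr3_alpha=make_cdr3("alpha", va, ja, None),
                v_beta=[(vb, 1.0)], j_beta=[(jb, 1.0)],
                cdr3_beta=make_cdr3("beta", vb, jb, None),
                count=1.0, epitope=spec.name))

    truth.update({
        "n_baseline": n,
        "subsets": [{"genes": list(s.genes), "frequency": s.frequency,
                     "observed": c} for s, c in zip(subsets, subset_counts)],
        "epitopes": [{"name": e.name, "n_records": e.n_records,
                      "v_beta_bias": e.v_beta_bias} for e in epitopes],
        "seed": seed,
    })
    return clonotypes, truth


# ---------------------------------------------------------------------------
# residue-level dependency generator (germline linkage + weak coupling)

@dataclass
class LinkedPairModel:
    """Closed-form model of germline-linked residues with a weak coupling.

    Four variables emulate the structure the two-phase learner is built
    for: ``a10``/``b10`` are framework residues bijective with the V
    gene of their chain (strong germline linkage), while ``a105`` and
    ``b105`` are CDR3-flank residues with per-record randomness:
    ``a105`` copies a class of the alpha V gene with probability
    ``w_intra`` (else uniform), and ``b105`` copies a class of the beta
    V gene with probability ``w_intra``, copies an image of ``a105``
    with probability ``w_couple`` (the weak inter-chain dependency), and
    is uniform otherwise.  The full joint is an explicit 4-way tensor,
    so every mutual information (marginal or gene-conditional) is exact.
    """

    n_genes: int = 8
    n_sym_a: int = 4
    n_sym_b: int = 6
    w_intra: float = 0.45
    w_couple: float = 0.02

    def joint(self) -> np.ndarray:
        """P(Valpha, a105, Vbeta, b105) as an exact tensor."""
        g, ka, kb = self.n_genes, self.n_sym_a, self.n_sym_b
        p_a = np.full((g, ka), (1.0 - self.w_intra) / ka)
        for v in range(g):
            p_a[v, v * ka // g] += self.w_intra
        p_b = np.zeros((g, ka, kb))
        for v in range(g):
            for sa in range(ka):
                row = np.full(kb, (1.0 - self.w_intra - self.w_couple) / kb)
                row[v * kb // g] += self.w_intra
                row[sa] += self.w_couple          # injective image of a105
                p_b[v, sa] = row
        joint = np.zeros((g, ka, g, kb))
        for va in range(g):
            for vb in range(g):
                joint[va, :, vb, :] = (1 / g) * (1 / g) * \
                    p_a[va][:, None] * p_b[vb]
        return joint

    def mi_couple(self) -> float:
        """Exact I(a105; b105) in nats."""
        j = self.joint().sum(axis=(0, 2))
        return _mutual_information(j)

    def mi_couple_given_vbeta(self) -> float:
        """Exact I(a105; b105 | Vbeta) in nats."""
        j = self.joint().sum(axis=0)            # (a105, Vbeta, b105)
        out = 0.0
        for vb in range(self.n_genes):
            block = j[:, vb, :]
            out += block.sum() * _mutual_information(block)
        return out

    def mi_intra_alpha(self) -> float:
        """Exact I(Valpha; a105) in nats."""
        j = self.joint().sum(axis=(2, 3))
        return _mutual_information(j)

    def sample(self, n: int, seed: int = 0):
        """Draw n records; returns (DataFrame of symbols, exact-MI dict)."""
        import pandas as pd

        rng = np.random.default_rng(seed)
        joint = self.joint()
        flat = joint.reshape(-1)
        draws = rng.choice(flat.size, size=n, p=flat / flat.sum())
        va, sa, vb, sb = np.unravel_index(draws, joint.shape)
        sym_gene = list(AA20[: self.n_genes])
        sym_a = list("DEKR")[: self.n_sym_a]
        sym_b = list("FGHIWY")[: self.n_sym_b]
        frame = pd.DataFrame({
            "a10": [sym_gene[v] for v in va],
            "a105": [sym_a[s] for s in sa],
            "b10": [sym_gene[v] for v in vb],
            "b105": [sym_b[s] for s in sb],
        })
        truth = {"mi_couple_nats": self.mi_couple(),
                 "mi_couple_given_vbeta_nats": self.mi_couple_given_vbeta(),
                 "mi_intra_alpha_nats": self.mi_intra_alpha()}
        return frame, truth


def linked_pair_model(target_mi: float, w_intra: float = 0.45,
                      n_genes: int = 8) -> LinkedPairModel:
    """Bisect the coupling weight so I(a105; b105) equals ``target_mi``."""
    lo, hi = 0.0, 1.0 - w_intra - 1e-6
    if LinkedPairModel(n_genes=n_genes, w_intra=w_intra,
                       w_couple=hi).mi_couple() < target_mi:
        raise ValueError("target MI unreachable at this intra weight")
    for _ in range(80):
        mid = (lo + hi) / 2
        m = LinkedPairModel(n_genes=n_genes, w_intra=w_intra, w_couple=mid)
        if m.mi_couple() < target_mi:
            lo = mid
        else:
            hi = mid
    return LinkedPairModel(n_genes=n_genes, w_intra=w_intra,
                           w_couple=(lo + hi) / 2)


# ---------------------------------------------------------------------------
# toy structure generator

@dataclass
class GeometryModel:
    """Planted inter-chain geometry for toy complexes.

    Angles in degrees.  ``class_offsets`` maps an (chain, IMGT position)
    to per-amino-acid-class (d_phi1, d_phi2, d_phi3) offsets applied on
    top of the base angles; the residue at that position is determined
    by the structure's sampled genes.  ``contact_pairs`` are the
    (alpha position, beta position) pairs guaranteed to satisfy the
    5 A / 15 A rules; generation fails if a draw violates them.
    """

    base_angles_deg: tuple[float, float, float] = (30.0, 40.0, 50.0)
    noise_sigma_deg: float = 5.0
    class_offsets: dict[tuple[str, int], dict[str, tuple[float, float, float]]] = \
        field(default_factory=dict)
    contact_pairs: tuple[tuple[int, int], ...] = ((45, 45), (46, 46))
    # close enough that the designated contacts stay under the 5 A rule
    # for any rotation the default angle model can draw
    chain_separation: float = 3.5


def _template_offsets(positions: list[int], contact_positions: set[int],
                      flank_positions: set[int]) -> dict[int, np.ndarray]:
    """Rigid template with exactly diagonal inertia and anchored landmarks.

    Contact positions sit within 0.5 A of the centre of mass; CDR3-flank
    positions cluster in the (+x, +y) octant so the axis-sign convention
    resolves identically for every chain built on the template.
    """
    rng = np.random.default_rng(20240123)   # template shape is a fixed constant
    offsets = {}
    others = [p for p in positions if p not in contact_positions | flank_positions]
    for p in sorted(contact_positions):
        k = p % 7
        offsets[p] = np.array([0.3 * math.cos(k), 0.3 * math.sin(k), 0.1 * (k % 3 - 1)])
    for i, p in enumerate(sorted(flank_positions)):
        offsets[p] = np.array([14.0 + i * 0.7, 5.0 + (i % 3) * 0.5, (i % 2) * 0.8])
    for p in others:
        offsets[p] = np.array([rng.uniform(-18, 18), rng.uniform(-7, 7),
                               rng.uniform(-3, 3)])
    pts = np.array([offsets[p] for p in positions])
    pts -= pts.mean(axis=0)
    # rotate into the principal frame so the inertia tensor is exactly diagonal
    r2 = (pts ** 2).sum(axis=1)
    inertia = np.einsum("i,jk->jk", r2, np.eye(3)) - pts.T @ pts
    moments, vecs = np.linalg.eigh(inertia)
    if np.any(np.diff(moments) < 1e-3):
        raise RuntimeError("degenerate template inertia; adjust extents")
    pts = pts @ vecs
    flank_idx = [i for i, p in enumerate(positions) if p in flank_positions]
    centroid = pts[flank_idx].mean(axis=0)
    for axis in (0, 1):
        if abs(centroid[axis]) < 1.0:
            raise RuntimeError("flank centroid too close to a principal plane")
        if centroid[axis] < 0:
            pts[:, axis] *= -1
    return {p: pts[i] for i, p in enumerate(positions)}


def _pin(clonotype_genes, ref, cdr3a, cdr3b):
    va, ja, vb, jb = clonotype_genes
    return PairedClonotype(clonotype_id="s", v_alpha=[(va, 1.0)],
                           j_alpha=[(ja, 1.0)], cdr3_alpha=cdr3a,
                           v_beta=[(vb, 1.0)], j_beta=[(jb, 1.0)],
                           cdr3_beta=cdr3b, count=1.0)


def make_toy_complexes(ref: GeneReference, geometry: GeometryModel,
                       n_structures: int, out_dir, seed: int = 0):
    """Write toy TCR complexes as PDB files plus a ground-truth table.

    Both chains are built on one shared rigid template (per-IMGT-index
    Calpha plus a side-chain proxy CB); the beta chain sits at the
    template pose and the alpha chain, translated by the chain
    separation, is rotated about its centre of mass by z-x-z Euler
    angles = base + class offsets + Gaussian noise.  Each complex also
    carries a 3-residue peptide placeholder and a Zn HETATM so the
    cleanup path has something to remove.  Requires an ungapped
    reference (equal position sets across genes).

    Returns (pdb_paths, roles, ground_truth).
    """
    import os

    rng = np.random.default_rng(seed)
    v_names = {c: ref.genes(c, "V") for c in ("alpha", "beta")}
    j_names = {c: ref.genes(c, "J") for c in ("alpha", "beta")}
    for rec in ref.records:
        if GAP in rec.gapped_seq:
            raise ValueError("toy complexes need an ungapped reference")
    positions = sorted(set(range(1, 104)) | set(range(104, 112))
                       | set(range(112, 108 + J_LENGTH)))
    contact_positions = {p for pair in geometry.contact_pairs for p in pair}
    flanks = set(range(104, 112))
    template = _template_offsets(positions, contact_positions, flanks)

    sep = np.array([0.0, geometry.chain_separation, 0.0])
    cb_shift = np.array([0.0, 0.0, 0.8])
    os.makedirs(out_dir, exist_ok=True)
    paths, truth_rows = [], []
    contact_truth: set[tuple[int, int]] = set()
    for s in range(n_structures):
        genes = (str(rng.choice(v_names["alpha"])), str(rng.choice(j_names["alpha"])),
                 str(rng.choice(v_names["beta"])), str(rng.choice(j_names["beta"])))
        va, ja, vb, jb = genes
        cdr3a = "".join(_germline_symbol(ref, "alpha", va, ja, p)
                        for p in list(range(104, 112)))
        cdr3b = "".join(_germline_symbol(ref, "beta", vb, jb, p)
                        for p in list(range(104, 112)))
        pinned = _pin(genes, ref, cdr3a, cdr3b)
        amap = index_clonotype_residues(pinned, ref, "alpha")
        bmap = index_clonotype_residues(pinned, ref, "beta")
        a_extra = {p: ref.get("alpha", "J", ja)[0].positions()[p]
                   for p in range(112, 108 + J_LENGTH)}
        b_extra = {p: ref.get("beta", "J", jb)[0].positions()[p]
                   for p in range(112, 108 + J_LENGTH)}
        a_seq = {**amap.positions, **a_extra}
        b_seq = {**bmap.positions, **b_extra}

        angles = np.array(geometry.base_angles_deg, float)
        offset_note = {}
        for (chain, pos), table in geometry.class_offsets.items():
            sym = (a_seq if chain == "alpha" else b_seq).get(pos, GAP)
            cls = AA_CLASSES.get(sym)
            if cls in table:
                angles = angles + np.array(table[cls], float)
                offset_note[f"{chain}:{pos}"] = [sym, cls]
        if geometry.noise_sigma_deg > 0:
            angles = angles + rng.normal(0, geometry.noise_sigma_deg, 3)
        rot = euler_zxz_to_matrix(*np.radians(angles))

        beta_atoms = {p: (template[p], template[p] + cb_shift) for p in positions}
        alpha_com = sep  # template offsets are centred, CB shift is uniform
        alpha_atoms = {}
        for p in positions:
            ca = rot @ template[p] + sep
            cb = rot @ (template[p] + cb_shift) + sep
            alpha_atoms[p] = (ca, cb)
        for ia, ib in geometry.contact_pairs:
            d_atoms = min(np.linalg.norm(x - y)
                          for x in alpha_atoms[ia] for y in beta_atoms[ib])
            d_ca = np.linalg.norm(alpha_atoms[ia][0] - beta_atoms[ib][0])
            if d_atoms >= 5.0 or d_ca >= 15.0:
                raise ValueError(
                    f"structure {s}: designated contact ({ia},{ib}) violated "
                    f"(closest {d_atoms:.2f} A, Calpha {d_ca:.2f} A)")
        for ia in positions:
            for ib in positions:
                if min(np.linalg.norm(x - y) for x in alpha_atoms[ia]
                       for y in beta_atoms[ib]) < 5.0:
                    contact_truth.add((ia, ib))

        path = os.path.join(out_dir, f"toy_{s:03d}.pdb")
        _write_pdb(path, a_seq, alpha_atoms, b_seq, beta_atoms)
        paths.append(path)
        truth_rows.append({
            "complex_id": f"toy_{s:03d}", "genes": list(genes),
            "label": ":".join(genes), "angles_deg": [float(a) for a in angles],
            "base_angles_deg": list(geometry.base_angles_deg),
            "class_offsets_applied": offset_note,
            "imgt_alpha": {str(k): v for k, v in a_seq.items()},
            "imgt_beta": {str(k): v for k, v in b_seq.items()},
        })
    roles = {"tcr_alpha": "A", "tcr_beta": "B", "peptide": "P"}
    truth = {"structures": truth_rows, "roles": roles, "seed": seed,
             "contact_pairs_lt5A": sorted(contact_truth),
             "designated_contacts": [list(p) for p in geometry.contact_pairs]}
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths, roles, truth


_AA3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR"}


def _write_pdb(path, a_seq, alpha_atoms, b_seq, beta_atoms) -> None:
    lines = []
    serial = 1

    def emit(chain_id, seq, atoms):
        nonlocal serial
        for p in sorted(atoms):
            res3 = _AA3.get(seq.get(p, "G"), "GLY")
            for name, xyz in zip(("CA", "CB"), atoms[p]):
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} {chain_id}{p:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {name[0]:>2s}")
                serial += 1
        lines.append(f"TER   {serial:5d}      {res3:>3s} {chain_id}{max(atoms):4d}")
        serial += 1

    emit("A", a_seq, alpha_atoms)
    emit("B", b_seq, beta_atoms)
    # peptide placeholder far from the TCR dimer
    for i in range(3):
        xyz = (60.0 + 3.8 * i, 0.0, 0.0)
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY P{i + 1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C")
        serial += 1
    lines.append(
        f"HETATM{serial:5d} ZN    ZN Z   1    {70.0:8.3f}{0.0:8.3f}{0.0:8.3f}"
        f"  1.00  0.00          ZN")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
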