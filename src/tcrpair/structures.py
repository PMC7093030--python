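"""TCR:pMHC structure cleanup, IMGT mapping and inter-chain contact maps.

A complex is reduced to one chain per role (TCR alpha, TCR beta,
peptide, MHC alpha, MHC beta / beta2-microglobulin); ions, ligands and
waters are removed, and the highest-occupancy conformer is kept for
alternate locations.  TCR chain residues are assigned IMGT indices by
the best-matching germline V (prefix) and J (suffix) reference,
anchored on Cys-104 and the J [FW]GXG motif; residues between the V and
J matches (the CDR3 middle) stay unindexed.

Contacts follow a two-threshold rule: a residue index pair is a
*candidate* if its closest-atom distance is below 5 Angstrom in at
least one complex, and its *contact frequency* is the fraction of
complexes (among those where both residues are resolved with Calpha
atoms) in which the Calpha distance is below 15 Angstrom.  The looser
Calpha rule compensates for incompletely resolved side chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from scipy import stats
from scipy.spatial.distance import cdist

from .reference import GeneReference, PositionProfile

logger = logging.getLogger(__name__)

ROLES = ("tcr_alpha", "tcr_beta", "peptide", "mhc_alpha", "mhc_beta")

CLOSEST_ATOM_THR = 5.0   # Angstrom, candidate-contact rule
CA_THR = 15.0            # Angstrom, contact-frequency rule


class ComplexRejected(ValueError):
    """Structure could not be mapped onto the germline reference."""


@dataclass
class StructResidue:
    resseq: int
    icode: str
    aa: str                      # one-letter code
    atoms: dict[str, np.ndarray]
    imgt: int | None = None

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    def coords(self) -> np.ndarray:
        return np.array(list(self.atoms.values()))


@dataclass
class StructChain:
    chain_id: str
    residues: list[StructResidue]
    v_gene: str | None = None
    j_gene: str | None = None
    cdr3: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def by_imgt(self) -> dict[int, StructResidue]:
        return {r.imgt: r for r in self.residues if r.imgt is not None}


@dataclass
class StructureComplex:
    complex_id: str
    chains: dict[str, StructChain]    # role -> chain

    @property
    def alpha(self) -> StructChain:
        return self.chains["tcr_alpha"]

    @property
    def beta(self) -> StructChain:
        return self.chains["tcr_beta"]

    @property
    def label(self) -> str:
        a, b = self.alpha, self.beta
        return f"{a.v_gene}:{a.j_gene}:{b.v_gene}:{b.j_gene}"


@dataclass
class ContactMap:
    frequencies: dict[tuple[int, int], float]
    n_observed: dict[tuple[int, int], int]
    n_resolved: dict[tuple[int, int], int]
    n_structures: int

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.frequencies)


def _extract_chain(model, chain_id: str) -> StructChain:
    chain = model[chain_id]
    residues = []
    for res in chain:
        hetflag, resseq, icode = res.id
        if hetflag != " ":
            continue                      # ions, ligands, waters
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.is_disordered():
                atom = max(atom.disordered_get_list(), key=lambda a: a.get_occupancy())
            atoms[atom.get_name()] = atom.get_coord().astype(float)
        aa = seq1(res.get_resname(), undef_code="X")
        residues.append(StructResidue(resseq=resseq, icode=icode.strip(),
                                      aa=aa, atoms=atoms))
    return StructChain(chain_id=chain_id, residues=residues)


def _best_window(seq: str, query: str, offsets) -> tuple[float, int]:
    """Best (identity fraction, offset) of ``query`` slid along ``seq``."""
    best = (-1.0, 0)
    for off in offsets:
        window = seq[off:off + len(query)]
        if len(window) < len(query):
            continue
        ident = sum(a == b for a, b in zip(window, query)) / len(query)
        if ident > best[0]:
            best = (ident, off)
    return best


def _assign_imgt(chain: StructChain, ref: GeneReference, which: str,
                 identity_thr: float) -> None:
    seq = chain.sequence
    candidates = []
    for rec in ref.records:
        if rec.chain != which:
            continue
        ungapped = rec.ungapped
        if rec.seg_class == "V":
            ident, off = _best_window(seq, ungapped, range(0, max(len(seq) - len(ungapped) + 1, 1)))
        else:
            start = max(len(seq) - len(ungapped) - 12, 0)
            ident, off = _best_window(seq, ungapped, range(start, len(seq) - len(ungapped) + 1))
        candidates.append((rec.seg_class, ident, off, rec))
    for seg_class, attr in (("V", "v_gene"), ("J", "j_gene")):
        cands = sorted([c for c in candidates if c[0] == seg_class],
                       key=lambda c: (-c[1], c[3].name))
        if not cands or cands[0][1] < identity_thr:
            raise ComplexRejected(
                f"chain {chain.chain_id}: no {seg_class} gene above identity "
                f"{identity_thr} (best {cands[0][1]:.2f} {cands[0][3].name})"
                if cands else f"chain {chain.chain_id}: empty {seg_class} reference")
        if len(cands) > 1 and cands[1][1] == cands[0][1]:
            chain.flags.append(f"ambiguous-{seg_class}-match")
            logger.info("chain %s: tied %s matches, kept %s by name order",
                        chain.chain_id, seg_class, cands[0][3].name)
        _, _, off, rec = cands[0]
        setattr(chain, attr, rec.name)
        nongap = [i + 1 for i, aa in enumerate(rec.gapped_seq) if aa != "."] \
            if rec.seg_class == "V" else sorted(rec.positions())
        for i, pos in enumerate(nongap):
            if off + i < len(chain.residues):
                chain.residues[off + i].imgt = pos
    by_imgt = chain.by_imgt()
    if 104 in by_imgt and 111 in by_imgt:
        i0 = chain.residues.index(by_imgt[104])
        i1 = chain.residues.index(by_imgt[111])
        chain.cdr3 = seq[i0:i1 + 1]


def clean_and_map_complex(pdb_path, roles: dict[str, str], ref: GeneReference,
                          complex_id: str | None = None,
                          identity_thr: float = 0.8) -> StructureComplex:
    """Load a PDB file, keep one chain per role, and IMGT-index the TCR chains.

    ``roles`` maps each role in :data:`ROLES` (TCR roles mandatory,
    others optional) to a chain id.  HETATM records never survive; only
    the first model is used when several are present.
    """
    parser = PDBParser(QUIET=True)
    cid = complex_id or str(pdb_path)
    structure = parser.get_structure(cid, pdb_path)
    model = next(iter(structure))         # single copy: first model only
    chains: dict[str, StructChain] = {}
    for role, chain_id in roles.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        chains[role] = _extract_chain(model, chain_id)
    for role in ("tcr_alpha", "tcr_beta"):
        if role not in chains:
            raise ValueError(f"role assignment missing {role}")
    _assign_imgt(chains["tcr_alpha"], ref, "alpha", identity_thr)
    _assign_imgt(chains["tcr_beta"], ref, "beta", identity_thr)
    return StructureComplex(complex_id=cid, chains=chains)


def _min_atom_distance(res_a: StructResidue, res_b: StructResidue) -> float:
    return float(cdist(res_a.coords(), res_b.coords()).min())


def _residue_min_distances(cx: StructureComplex) -> dict[tuple[int, int], float]:
    """Closest-atom distance for every indexed alpha x beta residue pair."""
    out: dict[tuple[int, int], float] = {}
    a_res, b_res = cx.alpha.by_imgt(), cx.beta.by_imgt()
    if not a_res or not b_res:
        return out
    a_idx, a_coords = [], []
    for ia, ra in a_res.items():
        for xyz in ra.atoms.values():
            a_idx.append(ia)
            a_coords.append(xyz)
    b_idx, b_coords = [], []
    for ib, rb in b_res.items():
        for xyz in rb.atoms.values():
            b_idx.append(ib)
            b_coords.append(xyz)
    dist = cdist(np.array(a_coords), np.array(b_coords))
    a_keys = sorted(set(a_idx))
    b_keys = sorted(set(b_idx))
    a_map = {k: i for i, k in enumerate(a_keys)}
    b_map = {k: i for i, k in enumerate(b_keys)}
    mins = np.full((len(a_keys), len(b_keys)), np.inf)
    rows = np.array([a_map[i] for i in a_idx])
    cols = np.array([b_map[i] for i in b_idx])
    np.minimum.at(mins, (rows[:, None], cols[None, :]), dist)
    for ia in a_keys:
        for ib in b_keys:
            out[(ia, ib)] = float(mins[a_map[ia], b_map[ib]])
    return out


def candidate_contacts(complexes: list[StructureComplex],
                       threshold: float = CLOSEST_ATOM_THR) -> set[tuple[int, int]]:
    """Residue index pairs with closest-atom distance < threshold in >= 1 complex."""
    if not complexes:
        raise ValueError("need at least one complex")
    out: set[tuple[int, int]] = set()
    for cx in complexes:
        for pair, d in _residue_min_distances(cx).items():
            if d < threshold:
                out.add(pair)
    return out


def contact_frequency_map(complexes: list[StructureComplex],
                          candidates: set[tuple[int, int]],
                          ca_threshold: float = CA_THR) -> ContactMap:
    """Per-candidate fraction of complexes with Calpha distance < threshold.

    A complex enters a pair's denominator only when both residues are
    resolved with a Calpha atom; pairs resolved nowhere are dropped with
    a warning.
    """
    n_obs = {p: 0 for p in candidates}
    n_res = {p: 0 for p in candidates}
    for cx in complexes:
        a_res = cx.alpha.by_imgt()
        b_res = cx.beta.by_imgt()
        for ia, ib in candidates:
            ra, rb = a_res.get(ia), b_res.get(ib)
            if ra is None or rb is None or ra.ca is None or rb.ca is None:
                continue
            n_res[(ia, ib)] += 1
            if np.linalg.norm(ra.ca - rb.ca) < ca_threshold:
                n_obs[(ia, ib)] += 1
    freqs = {}
    for p in sorted(candidates):
        if n_res[p] == 0:
            logger.warning("contact pair %s resolved in no complex; dropped", p)
            continue
        freqs[p] = n_obs[p] / n_res[p]
    return ContactMap(frequencies=freqs, n_observed={p: n_obs[p] for p in freqs},
                      n_resolved={p: n_res[p] for p in freqs},
                      n_structures=len(complexes))


def deduplicate_complexes(complexes: list[StructureComplex],
                          max_hamming: int = 1) -> list[StructureComplex]:
    """Drop structures with identical or nearly identical CDR3 pairs.

    Near-identity is a Hamming distance <= ``max_hamming`` between
    equal-length concatenated CDR3 alpha+beta strings; the first
    occurrence (input order) is kept.
    """
    kept: list[StructureComplex] = []
    keys: list[str] = []
    for cx in complexes:
        key = (cx.alpha.cdr3 or "") + "|" + (cx.beta.cdr3 or "")
        dup = False
        for prev in keys:
            if prev == key:
                dup = True
            elif len(prev) == len(key) and \
                    sum(a != b for a, b in zip(prev, key)) <= max_hamming:
                dup = True
            if dup:
                break
        if not dup:
            kept.append(cx)
            keys.append(key)
    return kept


@dataclass
class InformativeSelection:
    residues_alpha: list[int]
    residues_beta: list[int]
    pairs: list[tuple[int, int]]
    pearson_alpha: tuple[float, float]   # (R, p) contact frequency vs information
    pearson_beta: tuple[float, float]


def select_informative_residues(cmap: ContactMap,
                                profiles_alpha: list[PositionProfile],
                                profiles_beta: list[PositionProfile],
                                contact_thr: float = 0.75,
                                info_thr: float = 0.75) -> InformativeSelection:
    """Frequently contacted (> contact_thr) yet variable (< info_thr) residues.

    A residue's contact probability is the maximum frequency over the
    candidate pairs it participates in.  Also reports the per-chain
    Pearson correlation between contact frequency and information
    content over all contacting residues.
    """
    info_a = {p.position: p.info for p in profiles_alpha}
    info_b = {p.position: p.info for p in profiles_beta}
    freq_a: dict[int, float] = {}
    freq_b: dict[int, float] = {}
    for (ia, ib), f in cmap.frequencies.items():
        freq_a[ia] = max(freq_a.get(ia, 0.0), f)
        freq_b[ib] = max(freq_b.get(ib, 0.0), f)

    def select(freqs, infos):
        return sorted(pos for pos, f in freqs.items()
                      if f > contact_thr and infos.get(pos, 1.0) < info_thr)

    sel_a, sel_b = select(freq_a, info_a), select(freq_b, info_b)
    pairs = sorted((ia, ib) for (ia, ib), f in cmap.frequencies.items()
                   if ia in set(sel_a) and ib in set(sel_b) and f > contact_thr)
    if not pairs:
        logger.warning("informative-residue selection is empty")

    def pearson(freqs, infos):
        xs = [(f, infos[pos]) for pos, f in sorted(freqs.items()) if pos in infos]
        if len(xs) < 3:
            return (float("nan"), float("nan"))
        arr = np.array(xs)
        if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
            return (float("nan"), float("nan"))
        r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
        return (float(r), float(p))

    return InformativeSelection(residues_alpha=sel_a, residues_beta=sel_b, pairs=pairs,
                                pearson_alpha=pearson(freq_a, info_a),
                                pearson_beta=pearson(freq_b, info_b))


def write_contact_map_tsv(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("alpha_pos\tbeta_pos\tn_contact\tn_total\tfrequency\n")
        for (ia, ib) in cmap.pairs():
            fh.write(f"{ia}\t{ib}\t{cmap.n_observed[(ia, ib)]}\t"
                     f"{cmap.n_resolved[(ia, ib)]}\t{cmap.frequencies[(ia, ib)]:.6g}\n")
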