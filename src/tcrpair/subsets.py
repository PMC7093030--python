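"""Invariant T-cell subset discovery from alpha-beta pairing biases.

Two complementary detectors are provided.  The contrast detector
compares amino-acid pair probabilities at contact residues between a
gene-defined subset (e.g. the MAIT VaJaVb trio) and its background
(same definition with one slot freed), on base-2 log scale, against the
overall observed/expected enrichment in the full dataset -- subsets
driven by restricted gene choice light up on the first axis while
staying moderate on the second.  The trio detector tests every observed
3-of-4 gene combination (JaVbJb, VaVbJb, VaJaJb, VaJaVb) for
co-occurrence of its alpha and beta parts with an upper-tail
hypergeometric test (expected count K*n/N under random pairing), Holm
adjustment across all tested trios, then clusters significant trios
into populations via wildcard-compatible gene sets, and spectratypes
the discovered populations (CDR3 length distributions and a position
frequency matrix at the dominant length).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pairing import PairCountMatrix, expected_counts
from .reference import SYMBOLS, SYMBOL_INDEX

logger = logging.getLogger(__name__)

TRIO_KINDS = ("JaVbJb", "VaVbJb", "VaJaJb", "VaJaVb")

#: Which of the four gene slots (Va, Ja, Vb, Jb) each trio kind specifies.
_KIND_SLOTS = {
    "JaVbJb": (1, 2, 3),
    "VaVbJb": (0, 2, 3),
    "VaJaJb": (0, 1, 3),
    "VaJaVb": (0, 1, 2),
}
#: Alpha-side slot indices per kind (the rest are the beta part).
_ALPHA_SLOTS = {0, 1}


@dataclass
class SubsetContrast:
    pair: tuple[int, int]
    aa_pair: tuple[str, str]
    log2_subset_ratio: float      # subset vs background pair probability
    log2_overall_ratio: float     # n_O / n_E in the full dataset


@dataclass
class TrioRecord:
    kind: str
    genes: tuple[str, ...]        # genes at the specified slots, kind order
    k: int                        # reads with the full trio
    big_k: int                    # reads with the alpha part
    n: int                        # reads with the beta part
    big_n: int                    # total reads
    expected: float
    p_value: float
    adj_p: float = float("nan")

    @property
    def log2_ratio(self) -> float:
        if self.expected <= 0 or self.k == 0:
            return float("nan")
        return float(np.log2(self.k / self.expected))

    def gene_quartet(self) -> tuple[str | None, ...]:
        """(Va, Ja, Vb, Jb) with None at the unspecified (wildcard) slot."""
        out: list[str | None] = [None, None, None, None]
        for slot, gene in zip(_KIND_SLOTS[self.kind], self.genes):
            out[slot] = gene
        return tuple(out)


@dataclass
class TrioGraph:
    graph: nx.Graph
    components: list[list[TrioRecord]]
    labels: list[str]


@dataclass
class Spectratype:
    lengths_subset: dict[int, float]
    lengths_background: dict[int, float]
    dominant_length: int
    dominance: float              # modal length share in the subset
    pfm: np.ndarray               # (dominant_length, 21) columns over SYMBOLS

    def consensus(self) -> str:
        return "".join(SYMBOLS[i] for i in self.pfm.argmax(axis=1))


def round_weights(weights: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of fractional read weights to integers.

    Preserves the rounded total count; needed because the
    hypergeometric test operates on integer reads.
    """
    weights = np.asarray(weights, float)
    floors = np.floor(weights).astype(int)
    remainder = int(round(weights.sum())) - int(floors.sum())
    if remainder > 0:
        order = np.argsort(-(weights - floors), kind="stable")
        floors[order[:remainder]] += 1
    return floors


def subset_pair_contrast(subset_matrices: dict[tuple[int, int], PairCountMatrix],
                         background_matrices: dict[tuple[int, int], PairCountMatrix],
                         overall_matrices: dict[tuple[int, int], PairCountMatrix],
                         pseudo_scale: float = 0.5) -> list[SubsetContrast]:
    """Base-2 log contrast of amino-acid pair probabilities, subset vs background.

    For each contact pair and amino-acid pair: log2((p_subset + eps) /
    (p_background + eps)) with eps = pseudo_scale / n keeping ratios
    finite, joined with the overall dataset's log2(n_O / n_E).
    """
    out = []
    for pair, sub_m in subset_matrices.items():
        bg_m = background_matrices[pair]
        ov_m = overall_matrices[pair]
        if sub_m.n_total == 0:
            raise ValueError(f"empty subset at contact {pair}")
        p_sub = sub_m.counts / sub_m.n_total
        p_bg = bg_m.counts / bg_m.n_total
        eps_sub = pseudo_scale / sub_m.n_total
        eps_bg = pseudo_scale / bg_m.n_total
        n_e = expected_counts(ov_m)
        for i, sa in enumerate(SYMBOLS):
            for j, sb in enumerate(SYMBOLS):
                if sub_m.counts[i, j] == 0 and bg_m.counts[i, j] == 0:
                    continue
                ratio = (p_sub[i, j] + eps_sub) / (p_bg[i, j] + eps_bg)
                if ov_m.counts[i, j] > 0 and n_e[i, j] > 0:
                    overall = float(np.log2(ov_m.counts[i, j] / n_e[i, j]))
                else:
                    overall = float("nan")
                out.append(SubsetContrast(pair=pair, aa_pair=(sa, sb),
                                          log2_subset_ratio=float(np.log2(ratio)),
                                          log2_overall_ratio=overall))
    return out


def trio_enrichment(combos, min_count: int = 10) -> list[TrioRecord]:
    """Hypergeometric enrichment of every observed 3-of-4 gene trio.

    Weighted combos are expanded to integer pseudo-reads by
    largest-remainder rounding.  For a trio with alpha part observed in
    K reads and beta part in n reads out of N total, the observed
    co-occurrence k is scored with the upper tail P(X >= k),
    X ~ Hypergeom(N, K, n); Holm adjustment spans all tested trios and
    only trios with k >= min_count are reported.
    """
    combos = list(combos)
    reads = round_weights(np.array([c.weight for c in combos]))
    big_n = int(reads.sum())
    if big_n == 0:
        raise ValueError("no reads after rounding")

    records: list[TrioRecord] = []
    for kind in TRIO_KINDS:
        slots = _KIND_SLOTS[kind]
        a_slots = tuple(s for s in slots if s in _ALPHA_SLOTS)
        b_slots = tuple(s for s in slots if s not in _ALPHA_SLOTS)
        trio_counts: dict[tuple[str, ...], int] = {}
        a_counts: dict[tuple[str, ...], int] = {}
        b_counts: dict[tuple[str, ...], int] = {}
        for combo, r in zip(combos, reads):
            if r == 0:
                continue
            genes = combo.genes
            trio = tuple(genes[s] for s in slots)
            a_part = tuple(genes[s] for s in a_slots)
            b_part = tuple(genes[s] for s in b_slots)
            trio_counts[trio] = trio_counts.get(trio, 0) + int(r)
            a_counts[a_part] = a_counts.get(a_part, 0) + int(r)
            b_counts[b_part] = b_counts.get(b_part, 0) + int(r)
        for trio, k in sorted(trio_counts.items()):
            big_k = a_counts[tuple(trio[i] for i, s in enumerate(slots) if s in _ALPHA_SLOTS)]
            n = b_counts[tuple(trio[i] for i, s in enumerate(slots) if s not in _ALPHA_SLOTS)]
            expected = big_k * n / big_n
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
            records.append(TrioRecord(kind=kind, genes=trio, k=k, big_k=big_k,
                                      n=n, big_n=big_n, expected=expected, p_value=p))
    if records:
        _, adj, _, _ = multipletests([r.p_value for r in records], method="holm")
        for rec, a in zip(records, adj):
            rec.adj_p = float(a)
    kept = [r for r in records if r.k >= min_count]
    kept.sort(key=lambda r: (r.adj_p, r.p_value, -r.k))
    logger.info("trio enrichment: %d trios tested, %d with >= %d reads",
                len(records), len(kept), min_count)
    return kept


def _compatible(q1: tuple[str | None, ...], q2: tuple[str | None, ...]) -> bool:
    """Gene quartets match when every slot both specify agrees (None = wildcard)."""
    return all(a == b for a, b in zip(q1, q2) if a is not None and b is not None)


def trio_components(records: list[TrioRecord], adj_p_thr: float = 0.05,
                    min_count: int = 10) -> TrioGraph:
    """Cluster significant trios into populations by wildcard gene-set overlap."""
    nodes = [r for r in records if r.adj_p < adj_p_thr and r.k >= min_count]
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    quartets = [r.gene_quartet() for r in nodes]
    for i, j in itertools.combinations(range(len(nodes)), 2):
        if _compatible(quartets[i], quartets[j]):
            g.add_edge(i, j)
    components, labels = [], []
    for comp in sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c))):
        members = [nodes[i] for i in sorted(comp)]
        components.append(members)
        slot_names = []
        for slot in range(4):
            genes = [q[slot] for q in (m.gene_quartet() for m in members)
                     if q[slot] is not None]
            if genes:
                vals, counts = np.unique(genes, return_counts=True)
                slot_names.append(str(vals[counts.argmax()]))
        labels.append("+".join(slot_names))
    return TrioGraph(graph=g, components=components, labels=labels)


def spectratype(subset_cdr3s: list[str], background_cdr3s: list[str],
                weights: np.ndarray | None = None) -> Spectratype:
    """CDR3 length distribution of a subset vs its background, plus a PFM.

    The position frequency matrix is built over subset sequences of the
    dominant (modal) subset length; each column sums to 1.
    """
    if not subset_cdr3s:
        raise ValueError("empty subset")
    w = np.ones(len(subset_cdr3s)) if weights is None else np.asarray(weights, float)

    def length_dist(seqs, wts):
        dist: dict[int, float] = {}
        for s, ww in zip(seqs, wts):
            dist[len(s)] = dist.get(len(s), 0.0) + ww
        total = sum(dist.values())
        return {ln: v / total for ln, v in sorted(dist.items())}

    sub_dist = length_dist(subset_cdr3s, w)
    bg_dist = length_dist(background_cdr3s, np.ones(len(background_cdr3s))) \
        if background_cdr3s else {}
    dominant = max(sub_dist, key=lambda ln: (sub_dist[ln], -ln))
    pfm = np.zeros((dominant, len(SYMBOLS)))
    for s, ww in zip(subset_cdr3s, w):
        if len(s) != dominant:
            continue
        for i, aa in enumerate(s):
            pfm[i, SYMBOL_INDEX[aa]] += ww
    col_tot = pfm.sum(axis=1, keepdims=True)
    pfm = np.where(col_tot > 0, pfm / np.where(col_tot > 0, col_tot, 1.0), 0.0)
    return Spectratype(lengths_subset=sub_dist, lengths_background=bg_dist,
                       dominant_length=dominant, dominance=sub_dist[dominant],
                       pfm=pfm)


#: Canonical invariant-subset gene definitions (configurable).
MAIT_DEFINITION = {
    "v_alpha": {"TRAV1-2"},
    "j_alpha": {"TRAJ12", "TRAJ20", "TRAJ33"},
    "v_beta": {"TRBV6-4", "TRBV20"},
}
INKT_DEFINITION = {
    "v_alpha": {"TRAV10"},
    "j_alpha": {"TRAJ18"},
    "v_beta": {"TRBV25-1"},
}


def match_subset(combo, definition: dict[str, set[str]]) -> bool:
    """Does a gene combo satisfy a subset definition (missing slots are free)?"""
    slots = {"v_alpha": combo.v_alpha, "j_alpha": combo.j_alpha,
             "v_beta": combo.v_beta, "j_beta": combo.j_beta}
    return all(slots[k] in allowed for k, allowed in definition.items())
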