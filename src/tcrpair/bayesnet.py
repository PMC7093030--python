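"""Constrained discrete Bayesian-network learning over residue positions.

Each variable is the amino acid (or IMGT gap) at one indexed position of
the alpha or beta chain.  Structure is learned by greedy hill climbing
on the AIC network score ``LL - k`` (log-likelihood minus parameter
count, nats), with hard edge constraints: whitelisted edges are always
present and never deleted or reversed, blacklisted edges are never
added.  The two-phase procedure decouples intra- from inter-chain
structure: intra-chain dependencies carry orders of magnitude more
information (gene linkage) and would otherwise crowd out the weak
inter-chain signal under the AIC penalty, so inter-chain edges are
learned separately with intra-chain edges blacklisted, then whitelisted
into the final model.

Pairing information is measured on fitted models: the entropy of the
joint network over both chains, minus the entropies of the two
single-chain networks obtained by deleting inter-chain edges and
refitting.  For a common underlying distribution the difference is
minus the inter-chain mutual information; with separately structured
fitted models either sign can occur.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .reference import GAP


def var_name(chain: str, position: int) -> str:
    return f"{'a' if chain == 'alpha' else 'b'}{position}"


def chain_of(variable: str) -> str:
    return "alpha" if variable.startswith("a") else "beta"


class DiscreteDataset:
    """Weighted records of symbols over named categorical variables.

    Records are aggregated to unique configurations with summed weights
    on construction, which makes every downstream score independent of
    record order.
    """

    def __init__(self, frame: pd.DataFrame, weights=None,
                 alphabets: dict[str, list[str]] | None = None):
        self.variables = list(frame.columns)
        w = np.ones(len(frame)) if weights is None else np.asarray(weights, float)
        if np.any(w <= 0):
            raise ValueError("record weights must be positive")
        agg = frame.copy()
        agg["__w"] = w
        agg = agg.groupby(self.variables, sort=True, as_index=False)["__w"].sum()
        self.configs = agg[self.variables].reset_index(drop=True)
        self.weights = agg["__w"].to_numpy()
        self.alphabets = {}
        for v in self.variables:
            observed = sorted(set(self.configs[v]))
            extra = alphabets.get(v, []) if alphabets else []
            self.alphabets[v] = sorted(set(observed) | set(extra))
            bad = set(self.configs[v]) - set(self.alphabets[v])
            if bad:
                raise ValueError(f"symbols {bad} of {v} outside declared alphabet")
        self._codes = {
            v: self.configs[v].map({s: i for i, s in enumerate(self.alphabets[v])}).to_numpy()
            for v in self.variables
        }

    @property
    def n_total(self) -> float:
        return float(self.weights.sum())

    def card(self, v: str) -> int:
        return len(self.alphabets[v])

    def family_counts(self, child: str, parents: tuple[str, ...]) -> np.ndarray:
        """Weighted contingency over (parent configurations, child symbols)."""
        cards = [self.card(p) for p in parents]
        q = int(np.prod(cards)) if parents else 1
        idx = np.zeros(len(self.weights), dtype=np.int64)
        for p, c in zip(parents, cards):
            idx = idx * c + self._codes[p]
        table = np.zeros((q, self.card(child)))
        np.add.at(table, (idx, self._codes[child]), self.weights)
        return table


@dataclass
class NetScore:
    log_lik: float
    n_params: float
    aic: float


def _family_ll(table: np.ndarray) -> float:
    n_pa = table.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(table > 0, table * np.log(table / n_pa), 0.0)
    return float(ll.sum())


class _Scorer:
    """AIC family-score cache: score(X | Pa) = LL_family - (|A_X|-1) * q."""

    def __init__(self, data: DiscreteDataset):
        self.data = data
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, child: str, parents) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            table = self.data.family_counts(child, key[1])
            k = (self.data.card(child) - 1) * table.shape[0]
            self._cache[key] = _family_ll(table) - k
        return self._cache[key]

    def total(self, graph: nx.DiGraph) -> float:
        return sum(self.family(v, tuple(graph.predecessors(v))) for v in graph)


def score_network(dag: nx.DiGraph, data: DiscreteDataset) -> NetScore:
    """AIC network score of a DAG on a dataset (maximised form LL - k)."""
    ll = 0.0
    k = 0.0
    for v in dag:
        parents = tuple(sorted(dag.predecessors(v)))
        table = data.family_counts(v, parents)
        ll += _family_ll(table)
        k += (data.card(v) - 1) * table.shape[0]
    return NetScore(log_lik=ll, n_params=k, aic=ll - k)


def _normalize_edges(edges) -> set[tuple[str, str]]:
    return {(u, v) for u, v in edges}


def learn_structure(data: DiscreteDataset, whitelist=(), blacklist=()) -> nx.DiGraph:
    """Greedy AIC hill climbing with hard edge constraints.

    Starts from the whitelist-only graph; the single best AIC-improving
    add/delete/reverse move is applied until a local optimum.  Fully
    deterministic: ties are broken lexicographically by
    (from, to, move-type).
    """
    whitelist = _normalize_edges(whitelist)
    blacklist = _normalize_edges(blacklist)
    if whitelist & blacklist:
        raise ValueError("whitelist and blacklist overlap")
    g = nx.DiGraph()
    g.add_nodes_from(data.variables)
    g.add_edges_from(whitelist)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("whitelist is cyclic")
    scorer = _Scorer(data)
    variables = data.variables
    tol = 1e-9

    while True:
        moves: list[tuple[float, str, str, str]] = []
        for u, v in itertools.permutations(variables, 2):
            if g.has_edge(u, v):
                protected = (u, v) in whitelist
                if not protected:
                    base = scorer.family(v, tuple(g.predecessors(v)))
                    new_parents = tuple(p for p in g.predecessors(v) if p != u)
                    delta = scorer.family(v, new_parents) - base
                    moves.append((delta, u, v, "delete"))
                    if (v, u) not in blacklist and not g.has_edge(v, u):
                        g.remove_edge(u, v)
                        creates_cycle = nx.has_path(g, u, v)
                        g.add_edge(u, v)
                        if not creates_cycle:
                            d2 = (scorer.family(v, new_parents) - base
                                  + scorer.family(u, tuple(sorted(set(g.predecessors(u)) | {v})))
                                  - scorer.family(u, tuple(g.predecessors(u))))
                            moves.append((d2, u, v, "reverse"))
            else:
                if (u, v) in blacklist:
                    continue
                if nx.has_path(g, v, u):
                    continue
                base = scorer.family(v, tuple(g.predecessors(v)))
                delta = scorer.family(v, tuple(sorted(set(g.predecessors(v)) | {u}))) - base
                moves.append((delta, u, v, "add"))
        if not moves:
            break
        top = max(m[0] for m in moves)
        # score-equivalent moves (e.g. the two orientations of one new
        # edge) differ only by rounding noise; treat them as exact ties
        # so the lexicographic rule, not bit noise, decides
        near = [m for m in moves if top - m[0] <= 1e-6 * (1 + abs(top))]
        best = min(near, key=lambda m: (m[1], m[2], m[3]))
        if top <= tol:
            break
        _, u, v, kind = best
        if kind == "add":
            g.add_edge(u, v)
        elif kind == "delete":
            g.remove_edge(u, v)
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)
        assert nx.is_directed_acyclic_graph(g)
    for u, v in whitelist:
        assert g.has_edge(u, v)
    for u, v in blacklist:
        assert not g.has_edge(u, v)
    return g


def inter_chain_pairs(variables) -> set[tuple[str, str]]:
    """All ordered pairs of variables lying on different chains."""
    return {(u, v) for u, v in itertools.permutations(variables, 2)
            if chain_of(u) != chain_of(v)}


def intra_chain_pairs(variables) -> set[tuple[str, str]]:
    return {(u, v) for u, v in itertools.permutations(variables, 2)
            if chain_of(u) == chain_of(v)}


def two_phase_structure(data: DiscreteDataset,
                        contact_pairs) -> nx.DiGraph:
    """Two-step learning: intra-chain first, then inter-chain on contacts only.

    ``contact_pairs`` are unordered (alpha-variable, beta-variable)
    pairs from the structural contact selection; edges in either
    direction across a contact are allowed.  Phase A blacklists every
    inter-chain edge; phase B blacklists every intra-chain edge and
    every non-contact inter-chain edge; the final network is learned
    with phase-B edges whitelisted and non-contact inter-chain edges
    blacklisted.
    """
    variables = data.variables
    inter = inter_chain_pairs(variables)
    intra = intra_chain_pairs(variables)
    allowed = set()
    for a, b in contact_pairs:
        allowed.add((a, b))
        allowed.add((b, a))
    phase_a = learn_structure(data, blacklist=inter)
    if not allowed & inter:
        import logging
        logging.getLogger(__name__).warning(
            "no contact pairs supplied; final graph equals the intra-chain phase")
        return phase_a
    phase_b = learn_structure(data, blacklist=intra | (inter - allowed))
    non_contact = inter - allowed
    return learn_structure(data, whitelist=set(phase_b.edges()),
                           blacklist=non_contact - set(phase_b.edges()))


@dataclass
class BayesNet:
    """A fitted discrete network: DAG plus conditional probability tables."""

    graph: nx.DiGraph
    alphabets: dict[str, list[str]]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]    # (q parent configs, |alphabet|), rows sum to 1
    pseudocount: float
    n_fit: float

    def nodes(self):
        return list(self.graph.nodes)

    def _parent_index(self, node: str, assignment: dict[str, str]) -> int:
        idx = 0
        for p in self.parents[node]:
            idx = idx * len(self.alphabets[p]) + self.alphabets[p].index(assignment[p])
        return idx

    def node_prob(self, node: str, symbol: str, assignment: dict[str, str]) -> float:
        row = self.cpts[node][self._parent_index(node, assignment)]
        return float(row[self.alphabets[node].index(symbol)])

    def to_json(self) -> str:
        payload = {
            "nodes": list(self.graph.nodes),
            "edges": sorted(self.graph.edges),
            "alphabets": self.alphabets,
            "parents": {n: list(p) for n, p in self.parents.items()},
            "cpts": {n: t.tolist() for n, t in self.cpts.items()},
            "pseudocount": self.pseudocount,
            "n_fit": self.n_fit,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BayesNet":
        d = json.loads(text)
        g = nx.DiGraph()
        g.add_nodes_from(d["nodes"])
        g.add_edges_from(map(tuple, d["edges"]))
        return cls(graph=g, alphabets=d["alphabets"],
                   parents={n: tuple(p) for n, p in d["parents"].items()},
                   cpts={n: np.array(t) for n, t in d["cpts"].items()},
                   pseudocount=d["pseudocount"], n_fit=d["n_fit"])


def fit_parameters(dag: nx.DiGraph, data: DiscreteDataset,
                   pseudocount: float = 0.5) -> BayesNet:
    """Fit CPTs by Laplace-smoothed weighted counts.

    Row for parent configuration pa: (n(x, pa) + pc) / (n(pa) + pc|A|);
    with pseudocount 0 a zero-mass row falls back to uniform.
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("graph is not a DAG")
    parents = {v: tuple(sorted(dag.predecessors(v))) for v in dag}
    cpts = {}
    for v in dag:
        table = data.family_counts(v, parents[v])
        sm = table + pseudocount
        totals = sm.sum(axis=1, keepdims=True)
        cpt = np.where(totals > 0, sm / np.where(totals > 0, totals, 1.0),
                       1.0 / table.shape[1])
        empty = totals[:, 0] == 0
        cpt[empty] = 1.0 / table.shape[1]
        cpts[v] = cpt
    return BayesNet(graph=dag.copy(), alphabets={v: list(data.alphabets[v]) for v in dag},
                    parents=parents, cpts=cpts, pseudocount=pseudocount,
                    n_fit=data.n_total)


def log_likelihood(net: BayesNet, record: dict[str, str]) -> float:
    """Log probability (nats) of one joint symbol assignment under the net."""
    ll = 0.0
    for v in net.nodes():
        p = net.node_prob(v, record[v], record)
        if p == 0:
            return float("-inf")
        ll += math.log(p)
    return ll


def log_likelihoods(net: BayesNet, frame: pd.DataFrame) -> np.ndarray:
    """Vectorised per-record log-likelihoods for a symbol DataFrame."""
    n = len(frame)
    total = np.zeros(n)
    codes = {v: frame[v].map({s: i for i, s in enumerate(net.alphabets[v])}).to_numpy()
             for v in net.nodes() if v in frame.columns}
    for v in net.nodes():
        idx = np.zeros(n, dtype=np.int64)
        for p in net.parents[v]:
            idx = idx * len(net.alphabets[p]) + codes[p]
        probs = net.cpts[v][idx, codes[v]]
        with np.errstate(divide="ignore"):
            total += np.log(probs)
    return total


def split_networks(net: BayesNet, data: DiscreteDataset,
                   pseudocount: float | None = None) -> tuple[BayesNet, BayesNet]:
    """Remove inter-chain edges and refit each chain's component."""
    pc = net.pseudocount if pseudocount is None else pseudocount
    out = []
    for chain in ("alpha", "beta"):
        nodes = [v for v in net.nodes() if chain_of(v) == chain]
        sub = nx.DiGraph()
        sub.add_nodes_from(nodes)
        sub.add_edges_from((u, v) for u, v in net.graph.edges
                           if u in set(nodes) and v in set(nodes))
        sub_data = DiscreteDataset(data.configs[nodes], data.weights,
                                   alphabets={v: data.alphabets[v] for v in nodes})
        out.append(fit_parameters(sub, sub_data, pc))
    return out[0], out[1]


def _ancestors_closed(net: BayesNet, targets: set[str]) -> list[str]:
    closed = set(targets)
    frontier = set(targets)
    while frontier:
        nxt = set()
        for v in frontier:
            nxt |= set(net.parents[v])
        nxt -= closed
        closed |= nxt
        frontier = nxt
    return list(nx.topological_sort(net.graph.subgraph(closed)))


def _marginal(net: BayesNet, targets: tuple[str, ...], state_limit: int) -> np.ndarray | None:
    """Exact joint marginal over ``targets`` by enumeration of their ancestor set."""
    order = _ancestors_closed(net, set(targets))
    n_states = int(np.prod([len(net.alphabets[v]) for v in order]))
    if n_states > state_limit:
        return None
    cards = {v: len(net.alphabets[v]) for v in order}
    shape = tuple(cards[t] for t in targets)
    marg = np.zeros(shape)
    for combo in itertools.product(*(range(cards[v]) for v in order)):
        assign = dict(zip(order, combo))
        p = 1.0
        for v in order:
            idx = 0
            for par in net.parents[v]:
                idx = idx * cards[par] + assign[par]
            p *= net.cpts[v][idx, assign[v]]
            if p == 0:
                break
        if p > 0:
            marg[tuple(assign[t] for t in targets)] += p
    return marg


def _ancestral_sample(net: BayesNet, n: int, rng: np.random.Generator) -> pd.DataFrame:
    order = list(nx.topological_sort(net.graph))
    cols = {}
    for v in order:
        cards = [len(net.alphabets[p]) for p in net.parents[v]]
        idx = np.zeros(n, dtype=np.int64)
        for p, c in zip(net.parents[v], cards):
            idx = idx * c + cols[p]
        cum = np.cumsum(net.cpts[v][idx], axis=1)
        u = rng.random(n)[:, None]
        cols[v] = (u > cum[:, :-1]).sum(axis=1) if cum.shape[1] > 1 else np.zeros(n, int)
        cols[v] = np.minimum(cols[v], len(net.alphabets[v]) - 1)
    return pd.DataFrame({v: [net.alphabets[v][i] for i in cols[v]] for v in order})


def model_entropy(net: BayesNet, state_limit: int = 10 ** 6,
                  mc_samples: int = 10 ** 6, seed: int = 0) -> tuple[float, float]:
    """Entropy (nats) of the joint distribution the fitted net defines.

    ``H = sum_X sum_pa P(pa) H(X | pa)`` with the parent-set marginals
    computed exactly by ancestor enumeration when feasible, otherwise by
    seeded ancestral Monte-Carlo.  Returns (entropy, standard error);
    the standard error is 0.0 for the exact path.
    """
    h = 0.0
    mc_terms = []
    rng = np.random.default_rng(seed)
    sample = None
    for v in net.nodes():
        parents = net.parents[v]
        cpt = net.cpts[v]
        with np.errstate(divide="ignore", invalid="ignore"):
            h_rows = -np.sum(np.where(cpt > 0, cpt * np.log(cpt), 0.0), axis=1)
        if not parents:
            h += float(h_rows[0])
            continue
        marg = _marginal(net, parents, state_limit)
        if marg is not None:
            h += float(np.sum(marg.reshape(-1) * h_rows))
        else:
            if sample is None:
                sample = _ancestral_sample(net, mc_samples, rng)
            idx = np.zeros(len(sample), dtype=np.int64)
            for p in parents:
                codes = sample[p].map({s: i for i, s in enumerate(net.alphabets[p])})
                idx = idx * len(net.alphabets[p]) + codes.to_numpy()
            vals = h_rows[idx]
            h += float(vals.mean())
            mc_terms.append(float(vals.std(ddof=1) / np.sqrt(len(vals))))
    se = float(np.sqrt(np.sum(np.square(mc_terms)))) if mc_terms else 0.0
    return h, se


@dataclass
class EntropyReport:
    h_alpha: float
    h_beta: float
    h_joint: float
    delta: float = field(init=False)

    def __post_init__(self):
        self.delta = self.h_joint - self.h_alpha - self.h_beta


def pairing_information(full: BayesNet, alpha_net: BayesNet,
                        beta_net: BayesNet, **entropy_kw) -> EntropyReport:
    """Entropy budget of chain pairing: H_joint - H_alpha - H_beta.

    All three entropies come from fitted models; because the single-chain
    nets are refitted after edge removal the difference is an estimate
    whose sign is not constrained the way a single distribution's mutual
    information would be.
    """
    h_joint, _ = model_entropy(full, **entropy_kw)
    h_a, _ = model_entropy(alpha_net, **entropy_kw)
    h_b, _ = model_entropy(beta_net, **entropy_kw)
    return EntropyReport(h_alpha=h_a, h_beta=h_b, h_joint=h_joint)


def dataset_from_combos(combos, ref, positions) -> DiscreteDataset:
    """Build a residue dataset from weighted gene combos.

    ``positions`` is an iterable of (chain, IMGT position); variables
    are named ``a<pos>`` / ``b<pos>``.  Alphabets are the symbols the
    reference can place at the position plus the gap.
    """
    import logging

    positions = list(positions)
    v_cache: dict[tuple[str, str], str] = {}
    j_cache: dict[tuple[str, str], dict[int, str]] = {}

    def symbol(chain: str, v: str, j: str, cdr3: str, pos: int) -> str:
        # same residue assignment as index_clonotype_residues, resolved
        # directly: V germline below 104, CDR3 flanks at 104-111, J
        # germline above 111
        if pos <= 103:
            key = (chain, v)
            if key not in v_cache:
                v_cache[key] = ref.get(chain, "V", v)[0].gapped_seq
            seq = v_cache[key]
            return seq[pos - 1] if pos <= len(seq) else GAP
        if 104 <= pos <= 107:
            return cdr3[pos - 104]
        if 108 <= pos <= 111:
            return cdr3[pos - 112]
        key = (chain, j)
        if key not in j_cache:
            j_cache[key] = ref.get(chain, "J", j)[0].positions()
        return j_cache[key].get(pos, GAP)

    rows = []
    weights = []
    n_skipped = 0
    for combo in combos:
        c = combo.clonotype
        if len(c.cdr3_alpha) < 8 or len(c.cdr3_beta) < 8:
            n_skipped += 1
            continue
        rows.append([symbol(ch, combo.v_alpha if ch == "alpha" else combo.v_beta,
                            combo.j_alpha if ch == "alpha" else combo.j_beta,
                            c.cdr3_alpha if ch == "alpha" else c.cdr3_beta, pos)
                     for ch, pos in positions])
        weights.append(combo.weight)
    if n_skipped:
        logging.getLogger(__name__).info(
            "dataset_from_combos: %d combos skipped (CDR3 < 8 aa)", n_skipped)
    columns = [var_name(ch, pos) for ch, pos in positions]
    alphabets = {}
    for (ch, pos), col in zip(positions, columns):
        symbols = {GAP}
        for rec in ref.records:
            if rec.chain == ch:
                symbols |= set(rec.positions().get(pos, GAP))
        alphabets[col] = sorted(symbols)
    frame = pd.DataFrame(rows, columns=columns)
    return DiscreteDataset(frame, weights, alphabets=alphabets)
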