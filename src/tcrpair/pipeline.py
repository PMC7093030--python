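"""Stage orchestration: run the whole analysis end-to-end on files.

Stages (each independently runnable, each depending only on prior
stages' outputs): ``simulate`` (synthetic inputs), ``contacts``
(structure cleanup + contact map), ``variability`` (position profiles +
informative-residue selection), ``pairstats`` (amino-acid pairing
statistics), ``bn`` (two-phase Bayesian network + entropy budget),
``geometry`` (Euler angles + ANOVA), ``selection`` (epitope shuffle
tests), ``subsets`` (trio enrichment, clustering, spectratypes), and
``all``.  Thresholds default to the published analysis values
(5 A / 15 A contact rules, 0.75/0.75 selection, 30-record epitope
minimum, 10-read trio minimum, adjusted P < 0.05).

Configuration is a flat ``key=value`` text file with ``#`` comments and
an ``include=<path>`` mechanism; the resolved configuration and output
checksums are written into every stage manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import bayesnet, geometry, pairing, selection, structures, subsets, synthetic
from .reference import build_profiles, load_gene_reference, write_profiles_tsv
from .repertoire import read_epitope_groups, read_paired_clonotypes, \
    resolve_gene_calls, write_paired_clonotypes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "contacts", "variability", "pairstats", "bn",
          "geometry", "selection", "subsets")

DEFAULTS = {
    "out_dir": "tcrpair_out",
    "seed": "0",
    # synthetic inputs
    "n_clonotypes": "10000",
    "n_structures": "20",
    "n_v_alpha": "3", "n_j_alpha": "2", "n_v_beta": "3", "n_j_beta": "2",
    "reference_variability": "0.5",
    "coupling_mi_nats": "0.05",
    # published thresholds
    "closest_atom_thr": "5.0",
    "ca_thr": "15.0",
    "contact_thr": "0.75",
    "info_thr": "0.75",
    "min_group": "30",
    "min_count": "10",
    "adj_p_thr": "0.05",
    "pseudocount": "0.5",
    "n_global_shuffle": "10000",
    "identity_thr": "0.8",
    "dedup_hamming": "1",
}

DEPENDENCIES = {
    "contacts": ["reference.tsv", "structures/ground_truth.json"],
    "variability": ["reference.tsv", "contact_map.tsv"],
    "pairstats": ["repertoire.tsv", "selected_pairs.tsv"],
    "bn": ["repertoire.tsv", "selected_pairs.tsv"],
    "geometry": ["structures/ground_truth.json", "selected_pairs.tsv"],
    "selection": ["repertoire.tsv", "bn_inter.json"],
    "subsets": ["repertoire.tsv"],
}


def read_config(path=None, overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULTS)
    if path:
        cfg.update(_parse_config_file(path))
    cfg.update({k: str(v) for k, v in (overrides or {}).items()})
    return cfg


def _parse_config_file(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "include":
                out.update(_parse_config_file(
                    os.path.join(os.path.dirname(str(path)), value)))
            else:
                out[key] = value
    return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _manifest(stage: str, cfg: dict, outputs: list[str]) -> None:
    out_dir = cfg["out_dir"]
    payload = {"stage": stage, "config": cfg,
               "outputs": {os.path.relpath(p, out_dir): _sha256(p)
                           for p in outputs if os.path.exists(p)}}
    with open(os.path.join(out_dir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(payload, fh, indent=1)


def _check_deps(stage: str, cfg: dict) -> None:
    for rel in DEPENDENCIES.get(stage, []):
        if not os.path.exists(os.path.join(cfg["out_dir"], rel)):
            raise FileNotFoundError(
                f"stage '{stage}' needs {rel}; run the producing stage first "
                f"(simulate/contacts/variability)")


def run_stage(stage: str, cfg: dict) -> list[str]:
    """Run one pipeline stage; returns the paths it wrote."""
    if stage == "all":
        written = []
        for s in STAGES:
            written += run_stage(s, cfg)
        return written
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ('all',)}")
    os.makedirs(cfg["out_dir"], exist_ok=True)
    _check_deps(stage, cfg)
    outputs = getattr(_Stages(cfg), stage)()
    _manifest(stage, cfg, outputs)
    return outputs


class _Stages:
    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.out = cfg["out_dir"]
        self.seed = int(cfg["seed"])

    def _p(self, name: str) -> str:
        return os.path.join(self.out, name)

    # -- simulate ----------------------------------------------------------
    def simulate(self) -> list[str]:
        cfg = self.cfg
        ref = synthetic.make_reference(
            n_v_alpha=int(cfg["n_v_alpha"]), n_j_alpha=int(cfg["n_j_alpha"]),
            n_v_beta=int(cfg["n_v_beta"]), n_j_beta=int(cfg["n_j_beta"]),
            variability=float(cfg["reference_variability"]), seed=self.seed)
        synthetic.write_reference_tsv(ref, self._p("reference.tsv"))
        # plant a coupling between positions 45 (alpha) and 45 (beta)
        base = {("Y", "W"): 4.0, ("Y", "F"): 0.25}
        synthetic.set_residue(ref, "alpha", "V", ref.genes("alpha", "V")[0], 45, "Y")
        synthetic.set_residue(ref, "beta", "V", ref.genes("beta", "V")[0], 45, "W")
        synthetic.set_residue(ref, "beta", "V", ref.genes("beta", "V")[-1], 45, "F")
        synthetic.write_reference_tsv(ref, self._p("reference.tsv"))
        coupling = synthetic.scale_coupling(base, ref, 45, 45,
                                            float(cfg["coupling_mi_nats"]))
        subset = synthetic.PlantedSubset(
            genes=(ref.genes("alpha", "V")[-1], ref.genes("alpha", "J")[-1],
                   ref.genes("beta", "V")[-1], ref.genes("beta", "J")[-1]),
            frequency=0.01)
        epitopes = [
            synthetic.EpitopeSpec("EPITOPE-A", 120,
                                  {ref.genes("beta", "V")[0]: 0.9,
                                   ref.genes("beta", "V")[1]: 0.1}),
            synthetic.EpitopeSpec("EPITOPE-B", 80),
        ]
        clonotypes, truth = synthetic.sample_repertoire(
            ref, int(cfg["n_clonotypes"]), couplings=[coupling],
            subsets=[subset], epitopes=epitopes, seed=self.seed)
        write_paired_clonotypes(clonotypes, self._p("repertoire.tsv"))
        with open(self._p("repertoire_truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)
        geom = synthetic.GeometryModel(
            class_offsets={("alpha", 57): {"basic": (0.0, 0.0, 30.0)}})
        struct_ref = synthetic.make_reference(
            n_v_alpha=int(cfg["n_v_alpha"]), n_j_alpha=int(cfg["n_j_alpha"]),
            n_v_beta=int(cfg["n_v_beta"]), n_j_beta=int(cfg["n_j_beta"]),
            variability=float(cfg["reference_variability"]), seed=self.seed)
        for i, cls_aa in enumerate(["K", "D", "L"]):
            genes = struct_ref.genes("alpha", "V")
            synthetic.set_residue(struct_ref, "alpha", "V",
                                  genes[i % len(genes)], 57, cls_aa)
        synthetic.write_reference_tsv(struct_ref, self._p("structure_reference.tsv"))
        synthetic.make_toy_complexes(struct_ref, geom,
                                     int(cfg["n_structures"]),
                                     self._p("structures"), seed=self.seed)
        return [self._p("reference.tsv"), self._p("repertoire.tsv"),
                self._p("repertoire_truth.json"),
                self._p("structure_reference.tsv"),
                self._p("structures/ground_truth.json")]

    def _load_complexes(self):
        ref = load_gene_reference(self._p("structure_reference.tsv"))
        with open(self._p("structures/ground_truth.json")) as fh:
            truth = json.load(fh)
        roles = truth["roles"]
        out = []
        for row in truth["structures"]:
            path = self._p(os.path.join("structures", row["complex_id"] + ".pdb"))
            out.append(structures.clean_and_map_complex(
                path, roles, ref, complex_id=row["complex_id"],
                identity_thr=float(self.cfg["identity_thr"])))
        return out

    # -- contacts ----------------------------------------------------------
    def contacts(self) -> list[str]:
        complexes = self._load_complexes()
        cands = structures.candidate_contacts(
            complexes, threshold=float(self.cfg["closest_atom_thr"]))
        cmap = structures.contact_frequency_map(
            complexes, cands, ca_threshold=float(self.cfg["ca_thr"]))
        structures.write_contact_map_tsv(cmap, self._p("contact_map.tsv"))
        return [self._p("contact_map.tsv")]

    # -- variability -------------------------------------------------------
    def variability(self) -> list[str]:
        struct_ref = load_gene_reference(self._p("structure_reference.tsv"))
        cmap = self._read_contact_map()
        written = []
        profiles = {}
        for chain in ("alpha", "beta"):
            profs = build_profiles(struct_ref, chain)
            path = self._p(f"profiles_{chain}.tsv")
            write_profiles_tsv(profs, path)
            profiles[chain] = profs
            written.append(path)
        sel = structures.select_informative_residues(
            cmap, profiles["alpha"], profiles["beta"],
            contact_thr=float(self.cfg["contact_thr"]),
            info_thr=float(self.cfg["info_thr"]))
        with open(self._p("selected_pairs.tsv"), "w") as fh:
            fh.write("alpha_pos\tbeta_pos\n")
            for ia, ib in sel.pairs:
                fh.write(f"{ia}\t{ib}\n")
        with open(self._p("selection_summary.json"), "w") as fh:
            json.dump({"residues_alpha": sel.residues_alpha,
                       "residues_beta": sel.residues_beta,
                       "pearson_alpha": list(sel.pearson_alpha),
                       "pearson_beta": list(sel.pearson_beta)}, fh, indent=1)
        return written + [self._p("selected_pairs.tsv"),
                          self._p("selection_summary.json")]

    def _read_contact_map(self) -> structures.ContactMap:
        df = pd.read_csv(self._p("contact_map.tsv"), sep="\t")
        freqs = {(int(r.alpha_pos), int(r.beta_pos)): float(r.frequency)
                 for r in df.itertuples()}
        return structures.ContactMap(
            frequencies=freqs,
            n_observed={(int(r.alpha_pos), int(r.beta_pos)): int(r.n_contact)
                        for r in df.itertuples()},
            n_resolved={(int(r.alpha_pos), int(r.beta_pos)): int(r.n_total)
                        for r in df.itertuples()},
            n_structures=int(self.cfg["n_structures"]))

    def _selected_pairs(self) -> list[tuple[int, int]]:
        df = pd.read_csv(self._p("selected_pairs.tsv"), sep="\t")
        return [(int(r.alpha_pos), int(r.beta_pos)) for r in df.itertuples()]

    def _dataset(self):
        ref = load_gene_reference(self._p("reference.tsv"))
        clonotypes = read_paired_clonotypes(self._p("repertoire.tsv"))
        combos = resolve_gene_calls([c for c in clonotypes if c.epitope is None])
        pairs = self._selected_pairs() or [(45, 45)]
        positions = sorted({("alpha", a) for a, _ in pairs}
                           | {("beta", b) for _, b in pairs})
        data = bayesnet.dataset_from_combos(combos, ref, positions)
        contact_vars = [(bayesnet.var_name("alpha", a), bayesnet.var_name("beta", b))
                        for a, b in pairs]
        return ref, clonotypes, combos, data, contact_vars, positions

    # -- pairstats ---------------------------------------------------------
    def pairstats(self) -> list[str]:
        ref, _, combos, data, _, _ = self._dataset()
        pairs = self._selected_pairs() or [(45, 45)]
        rows = []
        tables = []
        from .reference import index_clonotype_residues
        from .repertoire import PairedClonotype

        def maps(combo):
            c = combo.clonotype
            pinned = PairedClonotype("x", [(combo.v_alpha, 1)], [(combo.j_alpha, 1)],
                                     c.cdr3_alpha, [(combo.v_beta, 1)],
                                     [(combo.j_beta, 1)], c.cdr3_beta, 1)
            return (index_clonotype_residues(pinned, ref, "alpha"),
                    index_clonotype_residues(pinned, ref, "beta"))

        for a, b in pairs:
            m = pairing.pair_counts(combos, (a, b), maps=maps)
            tables.append(pairing.pair_table(m))
            st = pairing.dependence_stats(m)
            rows.append({"alpha_pos": a, "beta_pos": b, "chi2": st.chi2,
                         "dof": st.dof, "p": st.p_value, "mi_nats": st.mi_nats,
                         "g_stat": st.g_stat, "n_total": m.n_total})
        pd.concat(tables).to_csv(self._p("pair_cells.tsv"), sep="\t", index=False)
        pd.DataFrame(rows).to_csv(self._p("pair_summary.tsv"), sep="\t", index=False)
        return [self._p("pair_cells.tsv"), self._p("pair_summary.tsv")]

    # -- bn ----------------------------------------------------------------
    def bn(self) -> list[str]:
        _, _, _, data, contact_vars, _ = self._dataset()
        pc = float(self.cfg["pseudocount"])
        dag = bayesnet.two_phase_structure(data, contact_vars)
        full = bayesnet.fit_parameters(dag, data, pc)
        inter_only = bayesnet.learn_structure(
            data, blacklist=bayesnet.intra_chain_pairs(data.variables)
            | (bayesnet.inter_chain_pairs(data.variables)
               - {p for ab in contact_vars for p in (ab, ab[::-1])}))
        inter_net = bayesnet.fit_parameters(inter_only, data, pc)
        a_net, b_net = bayesnet.split_networks(full, data)
        report = bayesnet.pairing_information(full, a_net, b_net)
        with open(self._p("bn_full.json"), "w") as fh:
            fh.write(full.to_json())
        with open(self._p("bn_inter.json"), "w") as fh:
            fh.write(inter_net.to_json())
        with open(self._p("entropy.json"), "w") as fh:
            json.dump({"h_alpha": report.h_alpha, "h_beta": report.h_beta,
                       "h_joint": report.h_joint, "delta": report.delta,
                       "n_records": data.n_total}, fh, indent=1)
        return [self._p("bn_full.json"), self._p("bn_inter.json"),
                self._p("entropy.json")]

    # -- geometry ----------------------------------------------------------
    def geometry(self) -> list[str]:
        complexes = self._load_complexes()
        complexes = structures.deduplicate_complexes(
            complexes, max_hamming=int(self.cfg["dedup_hamming"]))
        angles = []
        symbols_by_label: dict[str, dict[str, str]] = {}
        for cx in complexes:
            frames = {}
            for role, chain in (("tcr_alpha", cx.alpha), ("tcr_beta", cx.beta)):
                by_imgt = chain.by_imgt()
                coords = np.array([a for r in chain.residues if r.imgt is not None
                                   for a in r.atoms.values()])
                flank = np.array([by_imgt[p].ca for p in range(104, 112)
                                  if p in by_imgt and by_imgt[p].ca is not None])
                frames[role] = geometry.principal_frame(coords, flank.mean(axis=0))
            rec = geometry.inter_chain_angles(frames["tcr_alpha"], frames["tcr_beta"],
                                              complex_id=cx.complex_id, label=cx.label)
            angles.append(rec)
            sym = {}
            for chain, tag in ((cx.alpha, "a"), (cx.beta, "b")):
                for p, res in chain.by_imgt().items():
                    sym[f"{tag}{p}"] = res.aa
            symbols_by_label.setdefault(cx.label, sym)
        collapsed = geometry.collapse_by_gene_combo(angles)
        with open(self._p("angles.tsv"), "w") as fh:
            fh.write("complex_id\tlabel\tphi1_deg\tphi2_deg\tphi3_deg\n")
            for a in angles:
                d = a.degrees()
                fh.write(f"{a.complex_id}\t{a.label}\t{d[0]:.4f}\t{d[1]:.4f}\t{d[2]:.4f}\n")
        positions = sorted({f"a{p}" for p in range(40, 66)}
                           | {v for s in symbols_by_label.values() for v in s})
        assoc = geometry.angle_aa_association(collapsed, symbols_by_label,
                                              sorted(positions))
        rows = [{"position": t.position, "angle": t.angle_index, "F": t.f_score,
                 "p": t.p_value, "adj_p": t.adj_p, "testable": t.testable}
                for t in assoc]
        pd.DataFrame(rows).to_csv(self._p("angle_association.tsv"),
                                  sep="\t", index=False)
        return [self._p("angles.tsv"), self._p("angle_association.tsv")]

    # -- selection ---------------------------------------------------------
    def selection(self) -> list[str]:
        ref = load_gene_reference(self._p("reference.tsv"))
        with open(self._p("bn_inter.json")) as fh:
            net = bayesnet.BayesNet.from_json(fh.read())
        groups = read_epitope_groups(self._p("repertoire.tsv"),
                                     min_group=int(self.cfg["min_group"]))
        from .reference import index_clonotype_residues

        def to_symbols(c):
            amap = index_clonotype_residues(c, ref, "alpha")
            bmap = index_clonotype_residues(c, ref, "beta")
            return {v: (amap if v.startswith("a") else bmap).symbol(int(v[1:]))
                    for v in net.nodes()}

        rows = []
        kw = dict(net=net, to_symbols=to_symbols,
                  n_global=int(self.cfg["n_global_shuffle"]), seed=self.seed)
        real = selection.shuffle_pairs(groups, mode="real", **kw)
        within = selection.shuffle_pairs(groups, mode="within-group", **kw)
        global_ = selection.shuffle_pairs(groups, mode="global", **kw)
        for r, w, g in zip(real, within, global_):
            for other in (w, g):
                ks = selection.compare_ll_distributions(r, other)
                rows.append({"epitope": ks.epitope, "vs": other.mode,
                             "D": ks.d_stat, "p": ks.p_value})
        pd.DataFrame(rows).to_csv(self._p("ks_summary.tsv"), sep="\t", index=False)
        return [self._p("ks_summary.tsv")]

    # -- subsets -----------------------------------------------------------
    def subsets(self) -> list[str]:
        clonotypes = read_paired_clonotypes(self._p("repertoire.tsv"))
        combos = resolve_gene_calls(clonotypes)
        records = subsets.trio_enrichment(combos,
                                          min_count=int(self.cfg["min_count"]))
        rows = [{"kind": r.kind, "genes": "+".join(r.genes), "k": r.k,
                 "K": r.big_k, "n": r.n, "N": r.big_n, "expected": r.expected,
                 "p": r.p_value, "adj_p": r.adj_p, "log2_ratio": r.log2_ratio}
                for r in records]
        pd.DataFrame(rows).to_csv(self._p("trio_enrichment.tsv"),
                                  sep="\t", index=False)
        graph = subsets.trio_components(records,
                                        adj_p_thr=float(self.cfg["adj_p_thr"]),
                                        min_count=int(self.cfg["min_count"]))
        comp_rows = []
        for label, members in zip(graph.labels, graph.components):
            for m in members:
                comp_rows.append({"component": label, "kind": m.kind,
                                  "genes": "+".join(m.genes), "adj_p": m.adj_p})
        pd.DataFrame(comp_rows).to_csv(self._p("trio_components.tsv"),
                                       sep="\t", index=False)
        written = [self._p("trio_enrichment.tsv"), self._p("trio_components.tsv")]
        if graph.components:
            top = graph.components[0]
            quartet = top[0].gene_quartet()
            sub = [c for c in clonotypes if _matches_quartet(c, quartet)]
            bg = [c for c in clonotypes if c not in sub]
            if sub:
                spec = subsets.spectratype([c.cdr3_alpha for c in sub],
                                           [c.cdr3_alpha for c in bg])
                with open(self._p("spectratype_alpha.json"), "w") as fh:
                    json.dump({"lengths_subset": spec.lengths_subset,
                               "lengths_background": spec.lengths_background,
                               "dominant_length": spec.dominant_length,
                               "dominance": spec.dominance,
                               "consensus": spec.consensus()}, fh, indent=1)
                written.append(self._p("spectratype_alpha.json"))
        return written


def _matches_quartet(clonotype, quartet) -> bool:
    genes = (clonotype.best_gene("alpha", "V"), clonotype.best_gene("alpha", "J"),
             clonotype.best_gene("beta", "V"), clonotype.best_gene("beta", "J"))
    return all(q is None or g == q for g, q in zip(genes, quartet))
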