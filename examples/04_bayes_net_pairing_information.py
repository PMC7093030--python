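"""How much information do inter-chain contacts carry about pairing?

Fits the two-phase Bayesian network (intra-chain structure first, then
inter-chain edges restricted to contact pairs) on a synthetic
repertoire with a planted coupling, and compares the entropy of the
joint model with the entropies of the two single-chain models obtained
by cutting inter-chain edges and refitting.  The difference
H_ab - H_a - H_b estimates minus the pairing information; for
independent chains it is ~0.
"""

from tcrpair import bayesnet as bn
from tcrpair import synthetic
from tcrpair.repertoire import resolve_gene_calls

ref = synthetic.make_reference(n_v_alpha=4, n_v_beta=4, variability=1.0,
                               seed=7)
sym_a = sorted({r.gapped_seq[44] for r in ref.records
                if r.chain == "alpha" and r.seg_class == "V"})
sym_b = sorted({r.gapped_seq[44] for r in ref.records
                if r.chain == "beta" and r.seg_class == "V"})
coupling = synthetic.scale_coupling({(sym_a[0], sym_b[0]): 4.0}, ref,
                                    45, 45, target_mi=0.05)

positions = [("alpha", 45), ("alpha", 46), ("beta", 45), ("beta", 46)]
contacts = [("a45", "b45"), ("a46", "b46")]

for label, couplings in (("independent chains", []),
                         ("planted 0.05-nat coupling", [coupling])):
    clns, _ = synthetic.sample_repertoire(ref, 50_000, couplings=couplings,
                                          seed=2)
    data = bn.dataset_from_combos(resolve_gene_calls(clns), ref, positions)
    dag = bn.two_phase_structure(data, contacts)
    full = bn.fit_parameters(dag, data)
    a_net, b_net = bn.split_networks(full, data)
    rep = bn.pairing_information(full, a_net, b_net)
    inter = [e for e in dag.edges if e[0][0] != e[1][0]]
    print(f"{label}:")
    print(f"  inter-chain edges learned: {inter}")
    print(f"  H_a = {rep.h_alpha:.3f}, H_b = {rep.h_beta:.3f}, "
          f"H_ab = {rep.h_joint:.3f}  ->  delta = {rep.delta:+.4f} nats")

print()
print("delta ~ 0 means chain pairing adds no information beyond the single")
print("chains; with the planted coupling delta drops by about its MI.")
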