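# tcrpair

Are the α and β chains of the T-cell receptor free to pair with each
other, or do inter-chain contacts constrain which combinations occur?
`tcrpair` is a Python library for answering that question from two
kinds of data: TCR:peptide:MHC crystal structures (which residues of
the two chains actually touch) and paired-chain repertoire sequencing
(which amino-acid combinations occur at those residues across many
clones).  It is aimed at computational immunologists working with
paired αβ repertoires, antigen-specific TCR databases, or TCR
structural models.

## What it computes

All modules share one residue coordinate system: IMGT numbering of the
variable domain, with the conserved CDR3 cysteine at position 104, the
J-gene Phe/Trp anchor of the `[FW]GXG` motif at position 111, and only
the CDR3 flanks (104–107 from the V side, 108–111 from the J side)
indexed — the hypervariable CDR3 middle is excluded throughout.

* **Contact maps** (`tcrpair.structures`) — candidate contacts are
  residue pairs with closest-atom distance < 5 Å in at least one
  complex; contact frequency counts Cα distances < 15 Å across the
  structure set.  Residues that are frequently contacted (frequency
  > 0.75) yet variable in amino-acid content (information content
  I = 1 − H[p]/log 20 below 0.75) are selected for pairing analysis.
* **Pairing statistics** (`tcrpair.pairing`) — observed vs expected
  amino-acid pair counts under random pairing (n_E = row·col/n_T), a
  95% band for n_O/n_E from the binomial normal approximation
  (sd = √(n_E(1 − n_E/n_T))), χ², mutual information in nats, and the
  identity G = 2·n_T·MI.
* **Bayesian networks** (`tcrpair.bayesnet`) — discrete networks over
  per-position residue variables, learned by hill climbing on the AIC
  score (LL − k) with hard whitelist/blacklist edge constraints.  The
  two-phase procedure learns intra-chain structure first, then
  inter-chain edges restricted to structural contacts, so weak
  inter-chain signal is not crowded out by gene linkage.  Pairing
  information is measured as H<sub>αβ</sub> − H<sub>α</sub> −
  H<sub>β</sub> over fitted models.
* **Chain geometry** (`tcrpair.geometry`) — per-chain principal-axis
  frames from the inertia tensor (constant domain excluded), relative
  orientation as z-x-z Euler angles, collapse to unique V/J gene
  combinations, and ANOVA of each angle on amino-acid class.
* **Selection analysis** (`tcrpair.selection`) — pair log-likelihood
  distributions of real vs within-group-shuffled vs globally shuffled
  epitope-specific TCRs, compared by two-sample Kolmogorov–Smirnov.
* **Invariant subsets** (`tcrpair.subsets`) — hypergeometric enrichment
  of 3-of-4 gene trios (expected = K·n/N under random pairing, Holm
  correction), wildcard clustering of significant trios, subset
  contrast on base-2 log scale, and CDR3 spectratyping.
* **Synthetic data** (`tcrpair.synthetic`) — generators for gapped
  germline references, paired repertoires with exactly known couplings,
  planted invariant subsets and epitope biases, and toy PDB complexes
  with controllable inter-chain rotations.  Every generator emits a
  ground-truth sidecar.

## A worked example

```bash
python examples/04_bayes_net_pairing_information.py
```

```
independent chains:
  inter-chain edges learned: []
  H_a = 1.246, H_b = 1.245, H_ab = 2.490  ->  delta = +0.0000 nats
planted 0.05-nat coupling:
  inter-chain edges learned: [('a45', 'b45'), ('a46', 'b46')]
  H_a = 1.311, H_b = 1.133, H_ab = 2.396  ->  delta = -0.0487 nats
```

With independent chains the two-phase learner finds no inter-chain
edges and the joint model's entropy equals the sum of the single-chain
entropies: pairing carries no information.  With a coupling of 0.05
nats planted at one contact pair, the learner recovers the edge and the
entropy budget drops by almost exactly the planted mutual information.
The other scripts in `examples/` walk through the contact map, the
observed/expected band, chain-orientation ANOVA, selection distortion
and invariant-subset discovery in the same style.

A file-based pipeline is available as a thin CLI over the same
functions:

```bash
tcrpair all --config my.cfg --seed 1 --out run1
```

with stages `simulate`, `contacts`, `variability`, `pairstats`, `bn`,
`geometry`, `selection`, `subsets`.

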