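# Methods

This note documents the models behind `tcrpair`, the conventions and
defaults, what the synthetic-data generators emulate (and do not), and
the numerical choices that a user extending the package should know
about.

## Residue coordinate system

All positional analyses share one coordinate system: IMGT numbering of
the immunoglobulin-fold variable domain.  V-gene residues are numbered
by their IMGT alignment; alignment gaps are kept as an explicit symbol
`'.'` and treated as a 21st category alongside the 20 amino acids.
The conserved CDR3 cysteine sits at position 104 and the J-gene Phe/Trp
anchor of the `[FW]GXG` motif at position 111.  Of the CDR3 itself only
the flanks are indexed: positions 104–107 take the first four CDR3
residues (germline V side) and 108–111 the last four (germline J side).
The CDR3 middle forms a flexible loop with no meaningful cross-clone
alignment and is excluded from every indexed analysis; clonotypes with
CDR3 shorter than 8 residues cannot supply disjoint 4+4 flanks and are
excluded rather than double-counted.

Per-position variability is summarised by the information content

> I = 1 − H[p] / log 20,

where H is the Shannon entropy of the 21-symbol probability vector.
The normaliser is deliberately log 20, not log 21, so a position
uniform over the 20 amino acids scores exactly 0 while a position whose
spread includes the gap symbol can score slightly negative
(1 − log 21/log 20 ≈ −0.016).  Negative values are meaningful ("more
variable than a uniform residue") and are never clamped.  Entropies and
log-likelihoods are reported in nats throughout; the one exception is
enrichment log-ratios, which use base 2 because the thresholds 0.25 and
0.125 then convert to the intuitive ~19% and ~9% frequency increases.

Multi-allele genes are collapsed by keeping one record per distinct
gapped sequence and splitting the gene's usage weight equally across
its records; allele suffixes (`*01`) are stripped for all combination
analyses.

## Structures and contacts

Complexes are reduced to one chain per role (TCRα, TCRβ, peptide, MHC
chains); HETATM records (ions, ligands, waters) are removed, the first
model is used when several are present, and for alternate locations the
highest-occupancy conformer is kept.  TCR chains are assigned IMGT
indices by the best-identity germline match — V genes slid as a prefix
window, J genes as a suffix window anchored by the `[FW]GXG` motif —
with a configurable identity threshold (default 0.8) below which the
complex is rejected.  Ties between equally good germline matches are
broken deterministically by gene name and flagged.

Contacts follow a two-threshold rule.  A residue index pair is a
*candidate* if its closest-atom distance is below 5 Å in at least one
complex; its *contact frequency* is the fraction of complexes — among
those where both residues are resolved with Cα atoms — whose Cα
distance is below 15 Å.  The loose Cα criterion compensates for
incompletely resolved side chains; a residue lacking its Cα is skipped
for the frequency rule but still eligible for the closest-atom rule.
Residues are selected for pairing analysis when their contact
probability (the maximum frequency over their candidate pairs) exceeds
0.75 while their information content is below 0.75: contacted *and*
variable.  All four thresholds are configuration with these defaults.

For orientation analyses, near-duplicate structures are removed by
exact CDR3α+CDR3β string match, with "nearly identical" operationalised
as Hamming distance ≤ 1 at equal length (configurable); the subsequent
collapse of angle observations by VαJαVβJβ gene combination removes the
remaining redundancy, so validation studies that already collapse by
label skip the string-level deduplication.

## Pairing statistics

At a contact pair, observed weighted counts n_O over 21×21 amino-acid
(plus gap) combinations are compared with n_E = (row marginal × column
marginal)/n_T.  The null band for n_O/n_E uses the binomial normal
approximation: sd = √(n_E (1 − n_E/n_T)), interval 1 ± z·sd/n_E.  Two
calibration caveats, both documented by the validation studies rather
than hidden: (i) the normal approximation degrades below n_E ≈ 10, and
(ii) when n_E is estimated from the observed marginals the band is
*conservative* — the marginal fit absorbs part of the deviance, exactly
the effect that removes degrees of freedom from a contingency χ² — so
roughly 3% rather than 5% of null cells fall outside.  Scored against
exact expected counts (available for the generator, where the joint is
known in closed form) the band covers at its nominal level.

χ² is computed over cells with positive expectation, with degrees of
freedom (r−1)(c−1) over non-empty rows and columns; mutual information
uses the plug-in estimator in nats with 0·log 0 = 0, and the identity
G = 2·n_T·MI holds exactly by construction.  Fractional (weighted)
counts are accepted everywhere; χ² p-values are then computed on the
continuous statistic.  The delta-method standard error
SE = √((E[log²r] − MI²)/n_T) accompanies MI estimates.

## Gene-call weighting

Short-read paired sequencing often leaves several scored V (or J)
candidates per chain.  A clonotype's count is split across candidate
(Vα, Jα, Vβ, Jβ) combinations proportionally to the product of the four
slot scores — the product rule makes the split independent across
slots, and total weight is conserved exactly.  An all-zero slot falls
back to a uniform split and is flagged.  For the hypergeometric trio
test, which needs integer reads, fractional weights are converted by
largest-remainder rounding, preserving the rounded total.

## Bayesian networks

Variables are residue positions (per chain); alphabets are the symbols
the reference can place at the position plus the gap, extended by any
symbol observed in data.  Structure is learned by greedy hill climbing
on the AIC network score in its maximised form LL − k (the same optimum
as the textbook 2k − 2LL), with k = Σ (|alphabet|−1)·(#parent
configurations).  Moves are single-edge additions, deletions and
reversals; whitelisted edges are never deleted or reversed and
blacklisted edges never added; the search is fully deterministic —
records are aggregated to weighted counts before scoring (order
invariance) and score ties, including the exact-tie case of the two
orientations of a fresh edge where floating-point noise would otherwise
decide, are broken lexicographically by (from, to, move-type) within a
relative tolerance of 1e-6.  On every dataset over ≤3 variables with
alphabets ≤4 in the seeded validation battery, hill climbing attains
the exhaustive-search AIC optimum.

The two-phase procedure decouples intra- from inter-chain structure:
intra-chain dependencies (gene linkage) carry orders of magnitude more
information than inter-chain contacts and would absorb the AIC budget,
leaving weak inter-chain edges unaffordable.  Phase A learns with all
inter-chain edges blacklisted; phase B learns with all intra-chain
edges blacklisted and inter-chain edges restricted to structural
contact pairs; the final network is learned with phase-B edges
whitelisted and non-contact inter-chain edges blacklisted.  With no
contact pairs the final graph is the phase-A graph (warning).

CPTs are fitted with Laplace pseudocount 0.5 (rare V/J combinations
make unsmoothed estimates fragile); zero-mass parent configurations get
uniform rows.  Model entropy is the chain-rule sum
Σ_X Σ_pa P(pa)·H(X|pa), with parent-set marginals computed exactly by
enumeration of the parent set's ancestor closure when its joint state
space has ≤10⁶ states, else by seeded ancestral Monte Carlo (10⁶
samples default) with a reported standard error.

Pairing information is ΔH = H<sub>αβ</sub> − H<sub>α</sub> −
H<sub>β</sub>, where the single-chain entropies come from networks
obtained by deleting inter-chain edges and refitting each chain on its
own data.  Because the three entropies belong to *differently
structured fitted models*, ΔH is not a mutual information and its sign
is not constrained: smoothing mass spread over the joint model's larger
parameter space can push ΔH slightly positive even for independent
chains.  The package therefore also reports the plug-in mutual
information at each contact pair as the model-consistent measure of
planted or real coupling; on generator data with a coupling of exact MI
m, ΔH ≈ −m and the plug-in estimate recovers m within sampling error.

## Chain geometry

Each chain's variable domain is treated as a rigid body: the inertia
tensor of its atoms about the centre of mass (unit masses; atoms of
residues without an assigned IMGT index — the constant domain — are
excluded) is diagonalised, axes ordered by ascending principal moment.
Axis signs are fixed by pointing the first two axes towards the
centroid of the CDR3-flank residues (104–111) and completing a
right-handed set, which makes frames reproducible across structures;
two moments equal within 1e-6 (relative) flag a degenerate body with a
deterministic tie-break.  Relative orientation is the proper z-x-z
Euler decomposition of R<sub>β</sub>ᵀR<sub>α</sub> with φ2 ∈ [0, π];
near gimbal lock (φ2 < 1e-6) φ1 absorbs the total z-rotation, φ3 := 0,
flagged.

Structures sharing a VαJαVβJβ combination are collapsed to one
observation with per-angle means; angles are first unwrapped to the
branch around their circular mean so that 179° and −179° average to
180°, not 0°.  Association between the amino-acid class at a position
and each angle is tested by one-way ANOVA (five classes by default:
aliphatic GAVLIP, aromatic FWY, polar STCMNQ, basic KRH, acidic DE —
configurable), requiring at least two classes with two observations,
with Holm adjustment across all (position, angle) tests performed.
ANOVA treats angles linearly; this is adequate away from the ±180°
seam, where the synthetic studies operate, but a caveat for real data
concentrated near the seam.

## Selection analysis

Pair log-likelihoods are evaluated under the network restricted to
inter-chain contacts only, which minimises the V/J usage bias that
intra-chain structure would encode (the full network is available via
configuration).  Within-group shuffles permute β chains against fixed α
chains inside one epitope group, preserving both single-chain
multisets; global shuffles draw 10,000 (α, β) pairs with replacement
from the pooled dataset per epitope.  Distributions are compared by
two-sample Kolmogorov–Smirnov; samples under 5 values are flagged
unreliable.  Epitope groups require at least 30 paired records.

## Invariant subsets

Every observed 3-of-4 gene trio (JαVβJβ, VαVβJβ, VαJαJβ, VαJαVβ) is
tested for α/β co-occurrence: with the α part in K reads, the β part in
n reads, and k joint occurrences out of N total, the upper-tail
hypergeometric probability P(X ≥ k), X ~ Hypergeom(N, K, n), is
computed and Holm-adjusted across all tested trios; the expected count
is K·n/N.  The minimum-support filter (10 reads) applies to reporting,
not testing, mirroring a display threshold rather than a family
reduction.  Significant trios become nodes of a graph with edges
between trios whose gene quartets agree on every slot both specify
(missing slots are wildcards); connected components are candidate
populations, labelled by their most frequent gene names.  Subset
contrast compares amino-acid pair probabilities between a gene-defined
subset and its background with smoothing ε = 0.5/n, on base-2 logs,
against the overall observed/expected enrichment.  Discovered
populations are spectratyped: CDR3 length distributions per chain and a
position frequency matrix at the dominant length.

## Synthetic data: what it emulates, and what not

The generators define the study conditions for every validation:

* **Reference** — V genes spanning IMGT 1–107 with Cys-104 enforced,
  J genes spanning 108–116 with the `[FW]GXG` anchor at 111 (the
  generator resamples any J whose first motif occurrence would fall
  elsewhere); a variability knob sets the fraction of positions that
  differ across genes, so conserved and variable residue classes both
  occur; optional IMGT gaps at position 10.
* **Repertoires** — gene quartets drawn from an explicitly constructed
  joint: independent per-slot usage (power-law by default — real V
  usage is strongly skewed — or user-supplied), reweighted by
  symbol-level coupling multipliers at designated contact positions.
  No rejection sampling is involved, so the joint, and hence the exact
  mutual information of every planted coupling, is known in closed
  form; a bisection utility scales a multiplier table to hit a target
  MI exactly.  CDR3s are germline 4+4 flanks around a random middle.
  Planted invariant subsets replace a stated fraction of clones with a
  fixed quartet and fixed-length motif CDR3s; epitope groups are
  appended with biased β V usage.
* **Mixed-dependency datasets** (`LinkedPairModel`) — for studies of
  the two-phase learner, a four-variable closed-form model with
  framework residues bijective to the V genes (strong germline
  linkage) and CDR3-flank residues carrying per-record randomness plus
  a weak cross-chain copy channel; all marginal and gene-conditional
  MIs are exact tensor computations.
* **Toy complexes** — both chains share one rigid template (Cα plus a
  CB side-chain proxy per indexed residue) whose inertia tensor is
  made exactly diagonal and whose CDR3-flank cluster fixes the axis
  signs, so the β frame is the identity and a planted z-x-z rotation
  of the α chain (base angles + per-class offsets at designated
  positions + Gaussian noise) is recovered exactly by the geometry
  stage.  Designated contact pairs sit near the rotation centre with a
  3.5 Å chain separation, so the 5 Å/15 Å rules hold for any rotation
  the default model draws; generation fails loudly otherwise.  PDB
  output quantises coordinates to 10⁻³ Å, which bounds file-round-trip
  angle recovery at ~10⁻³ degrees; exact recovery (10⁻⁶ and better) is
  asserted on the in-memory path.

What the generators do *not* emulate: real germline sequence homology
(genes are random strings around anchors), V–J pairing biases within a
chain, somatic hypermutation or sequencing error, CDR3 length/antigen
dependence, biophysically meaningful structures, and MHC context.
Passing validation therefore shows the *machinery* is correct and
calibrated under known truth — not that real repertoires are free of
the confounders these omissions represent.

## Validation study sizes

Chosen so the full suite runs in minutes on one CPU while keeping
comfortable statistical margins: entropy-budget and band studies use
10⁵ records (band calibration pools 4 replicates); the two-phase study
uses 2·10⁴ records with the coupling scaled to n·MI = 25, placing it
far above phase-B's acceptance threshold yet far below the
single-phase penalty; geometry uses 30 structures (≈10 per class,
offset 30°, noise 5°); trio discovery plants a 1% subset in 10⁵ reads;
selection uses a 300-record biased group against 19 null replicates.

## Known limitations

* ΔH compares differently structured models (see above); treat it as a
  diagnostic, not an information measure.
* The contact-band is conservative with estimated marginals; confidence
  statements about single cells should use the χ²/MI summaries.
* Hill climbing finds local optima; the exhaustive-equivalence
  guarantee is only verified for small variable sets, and no random
  restarts are used (determinism is preferred).
* The structure mapper assumes chains laid out V-then-J with a
  recognisable germline prefix/suffix; heavily engineered or truncated
  constructs may be rejected.
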