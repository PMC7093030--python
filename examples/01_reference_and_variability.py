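"""Position-wise amino-acid variability of germline TCR genes.

Builds a small synthetic germline reference, computes the per-position
probability profile over all aligned V and J genes of the alpha chain,
and prints the information content I = 1 - H[p]/log(20) for a few
positions.  I near 1 means the residue is conserved across genes; I
near 0 means it is free to vary -- the residues worth watching for
pairing signal are the contacted ones with low I.
"""

from tcrpair import synthetic
from tcrpair.reference import build_profiles

ref = synthetic.make_reference(variability=0.5, seed=0)
profiles = build_profiles(ref, "alpha")

print("position  region       top-symbol  p(top)  information")
for prof in profiles:
    if prof.position in (20, 45, 57, 104, 111):
        top = prof.probs.argmax()
        from tcrpair.reference import SYMBOLS
        print(f"{prof.position:8d}  {prof.region:11s}  {SYMBOLS[top]:10s}"
              f"  {prof.probs[top]:.3f}   {prof.info:+.3f}")

print()
print("Position 104 is the invariant CDR3 cysteine (I = 1); positions with")
print("I well below 1 differ between genes and can carry pairing information.")
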