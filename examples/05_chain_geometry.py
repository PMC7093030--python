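"""Chain orientation angles and residue-class association.

Generates toy complexes in which the alpha chain is rotated relative to
the beta chain by z-x-z Euler angles, with an extra +30 deg phi3 offset
whenever the residue at alpha position 57 is basic.  Recovers the
angles from the structures via inertia-tensor principal frames and
tests which positions associate with each angle by ANOVA over
amino-acid classes.
"""

import tempfile

from tcrpair import validation

with tempfile.TemporaryDirectory() as tmp:
    res = validation.geometry_association_study(seed=0, out_dir=tmp)

print(f"collapsed gene combinations: {res['n_collapsed']}")
print(f"(position, angle) tests performed: {res['n_tested']}")
print(f"adjusted p at the planted (alpha57, phi3): {res['planted_adj_p']:.2e}")
print(f"planted test attains the smallest adjusted p: "
      f"{bool(res['planted_is_min'])}")
print()
print("The basic-residue offset at alpha-57 shifts phi3 by 30 deg against")
print("5 deg of angular noise, so the ANOVA flags exactly that position.")
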