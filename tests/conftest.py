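import pytest

from tcrpair import synthetic
from tcrpair.repertoire import PairedClonotype


@pytest.fixture(scope="session")
def small_ref():
    """3 Valpha / 2 Jalpha / 3 Vbeta / 2 Jbeta, mixed variability."""
    return synthetic.make_reference(seed=0)


@pytest.fixture(scope="session")
def variable_ref():
    """Fully variable positions, 4 V genes per chain."""
    return synthetic.make_reference(n_v_alpha=4, n_v_beta=4,
                                    variability=1.0, seed=7)


def make_clonotype(ref, v_a="TRAV1", j_a="TRAJ1", v_b="TRBV1", j_b="TRBJ1",
                   middle_a="GGS", middle_b="TGE", count=1.0, epitope=None,
                   cid="c0"):
    """Clonotype whose CDR3 flanks are the germline residues of its genes."""
    def cdr3(chain, v, j, middle):
        first = "".join(synthetic._germline_symbol(ref, chain, v, j, p)
                        for p in range(104, 108)).replace(".", "A")
        last = "".join(synthetic._germline_symbol(ref, chain, v, j, p)
                       for p in range(108, 112)).replace(".", "A")
        return first + middle + last

    return PairedClonotype(
        clonotype_id=cid,
        v_alpha=[(v_a, 1.0)], j_alpha=[(j_a, 1.0)],
        cdr3_alpha=cdr3("alpha", v_a, j_a, middle_a),
        v_beta=[(v_b, 1.0)], j_beta=[(j_b, 1.0)],
        cdr3_beta=cdr3("beta", v_b, j_b, middle_b),
        count=count, epitope=epitope)


@pytest.fixture()
def clonotype_factory(small_ref):
    def factory(**kw):
        return make_clonotype(small_ref, **kw)
    return factory
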