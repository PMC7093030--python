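"""Frequentist amino-acid pairing statistics at inter-chain contact residues.

For a contacting (alpha-position, beta-position) pair, the observed
count ``n_O[a, b]`` of amino-acid combinations across a paired
repertoire is compared with the count ``n_E[a, b] = row[a] * col[b] /
n_T`` expected under random pairing of the two chains.  The sampling
band for the ratio ``n_O / n_E`` under the null uses the normal
approximation of the binomial: sd = sqrt(n_E (1 - n_E/n_T)),
interval 1 +/- z * sd / n_E.  Dependence is summarised per pair by the
chi-squared statistic, mutual information (nats) and the G-statistic,
with ``G = 2 n_T MI`` holding exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reference import GAP, SYMBOLS, SYMBOL_INDEX


@dataclass
class PairCountMatrix:
    alpha_pos: int
    beta_pos: int
    counts: np.ndarray  # (21, 21) weighted observed counts over SYMBOLS x SYMBOLS

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class DependenceStats:
    chi2: float
    dof: int
    p_value: float
    mi_nats: float
    g_stat: float


def pair_counts(records, pair: tuple[int, int],
                maps=None) -> PairCountMatrix:
    """Accumulate weighted amino-acid pair counts at one contact.

    ``records`` is an iterable of ``(alpha ResidueIndexMap, beta
    ResidueIndexMap, weight)`` triples, or of WeightedGeneCombo objects
    when ``maps`` is a callable returning the two maps for a combo.
    Gaps count as the 21st symbol.
    """
    a_pos, b_pos = pair
    counts = np.zeros((len(SYMBOLS), len(SYMBOLS)))
    for rec in records:
        if maps is not None:
            amap, bmap = maps(rec)
            weight = rec.weight
        else:
            amap, bmap, weight = rec
        sa = amap.symbol(a_pos)
        sb = bmap.symbol(b_pos)
        counts[SYMBOL_INDEX[sa], SYMBOL_INDEX[sb]] += weight
    return PairCountMatrix(alpha_pos=a_pos, beta_pos=b_pos, counts=counts)


def expected_counts(m: PairCountMatrix) -> np.ndarray:
    """Expected counts under random pairing: outer product of marginals / total."""
    n_t = m.n_total
    if n_t <= 0:
        raise ValueError("empty pair-count matrix")
    return np.outer(m.row_marginals, m.col_marginals) / n_t


def ratio_ci(n_e_cell: float, n_t: float, level: float = 0.95) -> tuple[float, float]:
    """Null band for the observed/expected ratio of one cell.

    Binomial-approximation sd = sqrt(n_E (1 - n_E/n_T)); the interval is
    1 +/- z * sd / n_E.  A zero expected count has no defined band and
    returns (nan, nan).
    """
    if n_e_cell <= 0:
        return (float("nan"), float("nan"))
    if n_e_cell > n_t:
        raise ValueError("expected count exceeds total")
    z = stats.norm.ppf(0.5 + level / 2.0)
    sd = np.sqrt(n_e_cell * (1.0 - n_e_cell / n_t))
    half = z * sd / n_e_cell
    return (1.0 - half, 1.0 + half)


def dependence_stats(m: PairCountMatrix) -> DependenceStats:
    """Chi-squared, mutual information (nats) and G for one contact pair.

    Rows/columns with zero marginal are dropped from the degrees of
    freedom; weighted (fractional) counts are used as-is and the
    chi-squared p-value is computed on the continuous statistic.
    """
    n_t = m.n_total
    if n_t <= 0:
        raise ValueError("empty pair-count matrix")
    rows = m.row_marginals > 0
    cols = m.col_marginals > 0
    sub = m.counts[np.ix_(rows, cols)]
    n_e = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / n_t
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum(np.where(n_e > 0, (sub - n_e) ** 2 / n_e, 0.0)))
        p_joint = sub / n_t
        ratio = np.where(sub > 0, p_joint / (n_e / n_t), 1.0)
        mi = float(np.sum(np.where(sub > 0, p_joint * np.log(ratio), 0.0)))
    mi = max(mi, 0.0)
    r, c = sub.shape
    dof = max((r - 1) * (c - 1), 0)
    if dof == 0:
        return DependenceStats(0.0, 0, 1.0, 0.0, 0.0)
    p = float(stats.chi2.sf(chi2, dof))
    return DependenceStats(chi2=chi2, dof=dof, p_value=p,
                           mi_nats=mi, g_stat=2.0 * n_t * mi)


def mi_standard_error(m: PairCountMatrix) -> float:
    """Delta-method standard error of the plug-in mutual information.

    SE = sqrt((E[log^2 r] - MI^2) / n_T) with r the pointwise
    joint-to-product ratio; the usual first-order approximation for a
    multinomial sample.
    """
    n_t = m.n_total
    if n_t <= 0:
        raise ValueError("empty pair-count matrix")
    p = m.counts / n_t
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.where(p > 0, np.log(p / (pa * pb)), 0.0)
    mi = float(np.sum(p * log_r))
    var = float(np.sum(p * log_r ** 2)) - mi ** 2
    return float(np.sqrt(max(var, 0.0) / n_t))


def pair_table(m: PairCountMatrix, level: float = 0.95):
    """Long-format per-cell table: observed, expected, log2 ratio, band flag."""
    import pandas as pd

    n_e = expected_counts(m)
    n_t = m.n_total
    rows = []
    for i, sa in enumerate(SYMBOLS):
        for j, sb in enumerate(SYMBOLS):
            o, e = m.counts[i, j], n_e[i, j]
            if o == 0 and e == 0:
                continue
            lo, hi = ratio_ci(e, n_t, level)
            ratio = o / e if e > 0 else np.nan
            rows.append({
                "alpha_pos": m.alpha_pos, "beta_pos": m.beta_pos,
                "aa_alpha": sa if sa != GAP else "gap",
                "aa_beta": sb if sb != GAP else "gap",
                "n_O": o, "n_E": e,
                "log2_ratio": np.log2(ratio) if e > 0 and o > 0 else np.nan,
                "in_band": bool(lo <= ratio <= hi) if e > 0 else False,
            })
    return pd.DataFrame(rows)
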