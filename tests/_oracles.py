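"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorized code paths: scalar loops,
textbook formulae, and exact combinatorics, so an agreement between a
pipeline result and its oracle is evidence rather than tautology.
"""

import math
from fractions import Fraction

from scipy import stats


def welch_t_p(a, b):
    """Two-sided Welch t-test p-value from the textbook formula (scalar path)."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def pearson_r(x, y):
    """Pearson correlation from the direct covariance formula, scalar loop."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    sxx = sum((x[i] - mx) ** 2 for i in range(n))
    syy = sum((y[i] - my) ** 2 for i in range(n))
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def naive_rif(study, regulator, target_rows):
    """RIF1 and RIF2 for one regulator by a term-by-term Python loop.

    ``target_rows`` is an iterable of dicts with gene_id, x_j, x_jS, x_jC, d_j.
    Correlations are recomputed here from raw values via :func:`pearson_r`.
    """
    s_cols = study.samples("S")
    c_cols = study.samples("C")
    reg_s = study.values.loc[regulator, s_cols].tolist()
    reg_c = study.values.loc[regulator, c_cols].tolist()
    rif1_sum = 0.0
    rif2_sum = 0.0
    n = 0
    for row in target_rows:
        g = row["gene_id"]
        if g == regulator:
            r_s, r_c = 1.0, 1.0
        else:
            r_s = pearson_r(reg_s, study.values.loc[g, s_cols].tolist())
            r_c = pearson_r(reg_c, study.values.loc[g, c_cols].tolist())
        dc = r_s - r_c
        rif1_sum += row["x_j"] * row["d_j"] * dc**2
        rif2_sum += (row["x_jS"] * r_s) ** 2 - (row["x_jC"] * r_c) ** 2
        n += 1
    return rif1_sum / n, rif2_sum / n


def hypergeom_upper_tail(b, N, B, n):
    """P(X >= b) for X ~ Hypergeometric(N, B, n) by exact pmf summation."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for k in range(b, min(B, n) + 1):
        if n - k > N - B:
            continue
        total += Fraction(math.comb(B, k) * math.comb(N - B, n - k), denom)
    return float(total)
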