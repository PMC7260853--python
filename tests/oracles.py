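"""Independent brute-force oracles used to freeze expected test values.

Deliberately avoids the package under test and scipy.stats: matrix
inversion is explicit cofactor algebra, and tail probabilities are
computed by numerical integration of hand-written density functions.
"""

from __future__ import annotations

import math

from scipy.integrate import quad


def inverse_by_cofactors(m):
    """Explicit cofactor inverse for 1x1 or 2x2 matrices (lists of lists)."""
    n = len(m)
    if n == 1:
        return [[1.0 / m[0][0]]]
    if n == 2:
        det = m[0][0] * m[1][1] - m[0][1] * m[1][0]
        return [
            [m[1][1] / det, -m[0][1] / det],
            [-m[1][0] / det, m[0][0] / det],
        ]
    raise NotImplementedError("oracle handles p <= 2 only")


def f_pdf(x: float, d1: float, d2: float) -> float:
    if x <= 0:
        return 0.0
    log_b = (
        math.lgamma(d1 / 2) + math.lgamma(d2 / 2) - math.lgamma((d1 + d2) / 2)
    )
    log_num = (d1 / 2) * math.log(d1 / d2) + (d1 / 2 - 1) * math.log(x)
    log_den = ((d1 + d2) / 2) * math.log1p(d1 * x / d2)
    return math.exp(log_num - log_den - log_b)


def f_sf_numeric(x: float, d1: float, d2: float) -> float:
    """Upper-tail F probability via adaptive quadrature."""
    if x <= 0:
        return 1.0
    val, _ = quad(f_pdf, x, math.inf, args=(d1, d2), limit=200)
    return val


def t_pdf(x: float, df: float) -> float:
    log_c = (
        math.lgamma((df + 1) / 2)
        - math.lgamma(df / 2)
        - 0.5 * math.log(df * math.pi)
    )
    return math.exp(log_c - ((df + 1) / 2) * math.log1p(x * x / df))


def t_sf_numeric(x: float, df: float) -> float:
    val, _ = quad(t_pdf, x, math.inf, args=(df,), limit=200)
    return val


def _mean(rows):
    n = len(rows)
    p = len(rows[0])
    return [sum(r[j] for r in rows) / n for j in range(p)]


def _scatter(rows, mean):
    p = len(mean)
    s = [[0.0] * p for _ in range(p)]
    for r in rows:
        for i in range(p):
            for j in range(p):
                s[i][j] += (r[i] - mean[i]) * (r[j] - mean[j])
    return s


def hotelling_oracle(x1, x2):
    """Two-sample Hotelling T² via explicit loops and cofactor inversion.

    x1, x2: lists of equal-length coordinate tuples.  Returns
    (t2, f_stat, df1, df2, p_value) with the F tail from quadrature.
    """
    n1, n2 = len(x1), len(x2)
    p = len(x1[0])
    m1, m2 = _mean(x1), _mean(x2)
    s1, s2 = _scatter(x1, m1), _scatter(x2, m2)
    pooled = [
        [(s1[i][j] + s2[i][j]) / (n1 + n2 - 2) for j in range(p)]
        for i in range(p)
    ]
    inv = inverse_by_cofactors(pooled)
    d = [m1[j] - m2[j] for j in range(p)]
    quad_form = sum(d[i] * inv[i][j] * d[j] for i in range(p) for j in range(p))
    t2 = n1 * n2 / (n1 + n2) * quad_form
    df1 = p
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    return t2, f_stat, df1, df2, f_sf_numeric(f_stat, df1, df2)


def t_test_oracle(a, b, tails="two-sided"):
    """Unpaired pooled-variance Student t with quadrature p-value."""
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss = sum((v - m1) ** 2 for v in a) + sum((v - m2) ** 2 for v in b)
    df = n1 + n2 - 2
    sp2 = ss / df
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if tails == "two-sided":
        p = 2 * t_sf_numeric(abs(t), df)
    elif tails == "greater":
        p = t_sf_numeric(t, df)
    elif tails == "less":
        p = 1.0 - t_sf_numeric(t, df)
    else:
        raise ValueError(tails)
    return t, df, p
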