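"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: the Fisher oracle
enumerates every margin-fixed 2x2 table with exact multinomial integer
weights, and the KS oracle scans every sample point for the ECDF
sup-difference.
"""

from fractions import Fraction
from math import factorial


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of margin-fixed tables.

    Each table's probability is proportional to the multinomial weight
    N! / (n11! n12! n21! n22!); p sums the weights of all tables no more
    probable than the observed one.  Exact integer arithmetic throughout.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    N = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0

    def weight(n11, n12, n21, n22):
        return factorial(N) // (factorial(n11) * factorial(n12)
                                * factorial(n21) * factorial(n22))

    tables = []
    for n11 in range(N + 1):
        n12, n21 = r1 - n11, c1 - n11
        n22 = r2 - n21
        if min(n12, n21, n22) >= 0:
            tables.append(weight(n11, n12, n21, n22))
        else:
            tables.append(None)
    w_obs = tables[a]
    num = sum(w for w in tables if w is not None and w <= w_obs)
    den = sum(w for w in tables if w is not None)
    return float(Fraction(num, den))


def ks_D_bruteforce(x, y) -> float:
    """Sup of |ECDF_x - ECDF_y| evaluated at every sample point."""
    x, y = sorted(x), sorted(y)
    best = 0.0
    for t in x + y:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best
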