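"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the HWE oracle
enumerates every feasible heterozygote count in exact integer/rational
arithmetic, and the ANOVA/t oracles are plain-arithmetic textbook formulas.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial


def hwe_exact_p_bruteforce(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact conditional HWE p by full enumeration in exact arithmetic.

    Conditions on (n, minor-allele count); weighs each feasible het count k
    by the number of genotype configurations ways(k) = n!/(s! k! t!) * 2^k,
    and sums outcomes with ways(k) <= ways(observed) — an exact integer
    comparison, since all outcomes share the denominator C(2n, n_a).
    """
    n = n_hom_minor + n_het + n_hom_major
    n_a = 2 * n_hom_minor + n_het
    if n_a > n:  # make n_a the minor-allele count
        n_a = 2 * n - n_a
    if n == 0:
        raise ValueError("no typed genotypes")
    if n_a == 0:
        return 1.0

    def ways(k: int) -> int:
        s = (n_a - k) // 2
        t = n - s - k
        return factorial(n) // (factorial(s) * factorial(k) * factorial(t)) * 2 ** k

    feasible = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    w_obs = ways(n_het)
    total = sum(ways(k) for k in feasible if ways(k) <= w_obs)
    return float(Fraction(total, comb(2 * n, n_a)))


def anova_f_bruteforce(groups: list[list[float]]) -> tuple[float, int, int]:
    """One-way ANOVA F and dfs from the textbook sum-of-squares identities."""
    all_vals = [v for g in groups for v in g]
    n, k = len(all_vals), len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df1, df2 = k - 1, n - k
    return (ssb / df1) / (ssw / df2), df1, df2


def pooled_t_bruteforce(a: list[float], b: list[float]) -> tuple[float, int]:
    """Student's pooled-variance two-sample t and df, plain arithmetic."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
    return t, df
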