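"""Independent reference implementations used as test oracles.

Everything here is deliberately naive and separate from the package's own
code paths: a recursive boolean evaluator over explicit truth assignments,
a binomial tail-inversion for the exact interval, and a brute-force
itertools enumeration of margin-fixed contingency tables.
"""

from __future__ import annotations

import itertools
from math import comb, lgamma

from altoscreen.rules import And, Any, Atom, Or, PicAtom


def naive_eval(rule, atom_truth: dict) -> bool:
    """Recursive two-valued evaluation; atoms looked up in a truth table.

    Question atoms are keyed by their identifier string, picture atoms by
    ``pic:X``.
    """
    if isinstance(rule, Atom):
        return bool(atom_truth.get(rule.question.value, False))
    if isinstance(rule, PicAtom):
        return bool(atom_truth.get(f"pic:{rule.selection}", False))
    if isinstance(rule, And):
        return all(naive_eval(c, atom_truth) for c in rule.children)
    if isinstance(rule, (Or, Any)):
        return any(naive_eval(c, atom_truth) for c in rule.children)
    raise TypeError(rule)


def cp_interval_by_bisection(k: int, n: int, alpha: float = 0.05, tol: float = 1e-12):
    """Clopper-Pearson bounds by bisecting the binomial tail sums.

    lower solves P(X >= k | p) = alpha/2, upper solves P(X <= k | p) =
    alpha/2, with the conventional 0 and 1 at the boundaries.
    """

    def tail_ge(p):  # P(X >= k)
        return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))

    def tail_le(p):  # P(X <= k)
        return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(0, k + 1))

    def bisect(fn, target, lo=0.0, hi=1.0):
        # fn monotone increasing in p for tail_ge, decreasing for tail_le
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if fn(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    lower = 0.0 if k == 0 else bisect(lambda p: tail_ge(p), alpha / 2)
    upper = 1.0 if k == n else bisect(lambda p: -tail_le(p), -alpha / 2)
    return lower, upper


def brute_force_fisher(table) -> float:
    """Freeman-Halton p by plain itertools enumeration over all cells."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)

    def logfact(x):
        return lgamma(x + 1)

    const = (
        sum(logfact(r) for r in rows)
        + sum(logfact(c) for c in cols)
        - logfact(total)
    )

    def logp(flat):
        return const - sum(logfact(x) for x in flat)

    obs = logp([x for row in table for x in row])
    nr, nc = len(rows), len(cols)
    free_cells = [(i, j) for i in range(nr - 1) for j in range(nc - 1)]
    p = 0.0
    from math import exp

    ranges = [range(min(rows[i], cols[j]) + 1) for i, j in free_cells]
    for combo in itertools.product(*ranges):
        grid = [[0] * nc for _ in range(nr)]
        for (i, j), v in zip(free_cells, combo):
            grid[i][j] = v
        ok = True
        for i in range(nr - 1):
            rest = rows[i] - sum(grid[i][: nc - 1])
            if rest < 0:
                ok = False
                break
            grid[i][nc - 1] = rest
        if ok:
            for j in range(nc):
                rest = cols[j] - sum(grid[i][j] for i in range(nr - 1))
                if rest < 0:
                    ok = False
                    break
                grid[nr - 1][j] = rest
        if not ok:
            continue
        lp = logp([x for row in grid for x in row])
        if lp <= obs + 1e-12:
            p += exp(lp)
    return p
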