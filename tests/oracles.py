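"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: exact rational arithmetic for the conditional
two-library test, exhaustive enumeration for collinear chains, set and
partition brute force elsewhere.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


# ---------------------------------------------------------------------------
# exact conditional two-library test (rational arithmetic)
# ---------------------------------------------------------------------------

def ac_pmf_exact(x: int, k: int, N1: int, N2: int) -> Fraction:
    """p(k | x) as an exact rational for integer library sizes."""
    rho = Fraction(N2, N1)
    return rho**k * comb(x + k, k) / (1 + rho) ** (x + k + 1)


def ac_lower_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    """P(Y <= y | x) by direct exact summation."""
    if y < 0:
        return Fraction(0)
    return sum(ac_pmf_exact(x, k, N1, N2) for k in range(y + 1))


def ac_upper_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    """P(Y >= y | x) via the total-probability identity (the distribution
    sums to one analytically)."""
    return 1 - ac_lower_exact(x, y - 1, N1, N2)


def ac_two_sided_exact(x: int, y: int, N1: int, N2: int) -> Fraction:
    lo = ac_lower_exact(x, y, N1, N2)
    hi = ac_upper_exact(x, y, N1, N2)
    return min(Fraction(1), 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# exhaustive collinear-chain search
# ---------------------------------------------------------------------------

def _valid_step(a, b, orientation: str, max_gap: int) -> bool:
    da = b[0] - a[0]
    db = b[1] - a[1]
    if da <= 0 or da > max_gap or abs(db) > max_gap:
        return False
    return db > 0 if orientation == "forward" else db < 0


def _all_chains(points, orientation, max_gap):
    """Every maximal-extension chain over the points (DFS)."""
    chains = []

    def extend(chain):
        extended = False
        last = chain[-1]
        for p in points:
            if p in chain:
                continue
            if _valid_step(last, p, orientation, max_gap):
                extend(chain + [p])
                extended = True
        if not extended:
            chains.append(chain)

    for p in points:
        extend([p])
    return chains


def best_chain_exhaustive(points, orientation, max_gap):
    """Longest chain, ties broken by lexicographically smallest
    (rank_a, rank_b) sequence; None if no chain of length >= 2 exists."""
    chains = [c for c in _all_chains(points, orientation, max_gap) if len(c) >= 2]
    if not chains:
        return None
    best_len = max(len(c) for c in chains)
    return min(c for c in chains if len(c) == best_len)


def chain_blocks_exhaustive(points, min_size, max_gap):
    """Greedy longest-first block extraction by exhaustive search, mirroring
    the documented selection criterion with independent machinery.

    ``points`` are (rank_a, rank_b) tuples on one chromosome pair; returns a
    list of (orientation, chain) in extraction order.
    """
    points = list(dict.fromkeys(points))
    blocks = []
    while True:
        best = None
        for orient_rank, orientation in enumerate(("forward", "reverse")):
            chain = best_chain_exhaustive(points, orientation, max_gap)
            if chain is None or len(chain) < min_size:
                continue
            key = (-len(chain), chain[0][0], chain[0][1], orient_rank)
            if best is None or key < best[0]:
                best = (key, orientation, chain)
        if best is None:
            return blocks
        _, orientation, chain = best
        blocks.append((orientation, chain))
        points = [p for p in points if p not in set(chain)]


# ---------------------------------------------------------------------------
# brute-force set membership patterns
# ---------------------------------------------------------------------------

def membership_counts_bruteforce(sets):
    """Pattern -> count over the union, enumerated gene by gene."""
    union = set().union(*sets)
    counts = {}
    for gene in union:
        key = "".join("1" if gene in s else "0" for s in sets)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# exhaustive two-group partition by within-cluster sum of squares
# ---------------------------------------------------------------------------

def best_two_partition(matrix):
    """Exhaustive bipartition of the rows minimizing total within-cluster
    sum of squared distances to the cluster mean (<= ~12 rows)."""
    import numpy as np

    n = len(matrix)
    best = None
    for r in range(1, n // 2 + 1):
        for left in combinations(range(n), r):
            right = tuple(i for i in range(n) if i not in left)
            wss = 0.0
            for group in (left, right):
                sub = matrix[list(group)]
                wss += ((sub - sub.mean(axis=0)) ** 2).sum()
            if best is None or wss < best[0]:
                best = (wss, frozenset(left), frozenset(right))
    return {best[1], best[2]}


# ---------------------------------------------------------------------------
# exact hypergeometric upper tail
# ---------------------------------------------------------------------------

def hypergeom_upper_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for overlap of a size-n draw with a size-K class."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)), total
    )
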