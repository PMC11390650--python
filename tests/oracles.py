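"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the library code paths they check: the chain
oracle materialises the full per-base target→query map by walking block
lines, the Fisher oracle enumerates the hypergeometric support, and the
matching oracle solves the 1:1 assignment exactly with the Hungarian
algorithm.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from orthosplice.liftover import Chain


def expand_chain_per_base(chain: Chain) -> dict[int, tuple[str, int | str, bool]]:
    """Materialise the target→query base map of one chain.

    Every target position in [t_start, t_end) maps either to a forward-strand
    query position or to the string "gap".
    """
    flip = chain.q_strand == "-"
    mapping: dict[int, tuple[str, int | str, bool]] = {}
    t = chain.t_start
    q = chain.q_start
    for block in chain.blocks:
        for k in range(block.size):
            q_pos = q + k
            if flip:
                q_pos = chain.q_size - 1 - q_pos
            mapping[t + k] = (chain.q_name, q_pos, flip)
        for k in range(block.dt):
            mapping[t + block.size + k] = (chain.q_name, "gap", flip)
        t += block.size + block.dt
        q += block.size + block.dq
    return mapping


def fisher_two_sided_by_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by summing hypergeometric point masses.

    Sums P(X=x) over the support for every table at least as extreme
    (pmf(x) <= pmf(a), with a small relative tolerance for float ties).
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def fisher_enumeration_margin_grid(n: int, row1: int, col1: int) -> np.ndarray:
    """Two-sided Fisher p for every table with the given margins.

    Returns an array indexed by a - max(0, row1+col1-n) over the support.
    """
    if n == 0:
        return np.array([1.0])
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    return np.array([
        pmf[pmf <= p_obs * (1 + 1e-7)].sum() for p_obs in pmf
    ])


def optimal_assignment_pairs(sources, targets, tolerance: int,
                             gene_map=None) -> set[tuple[str, str]]:
    """Exact minimum-total-offset 1:1 assignment (maximum cardinality first).

    Infeasible pairs get a cost large enough that the Hungarian solution
    never prefers an infeasible edge over leaving events unmatched.
    """
    big = 10 ** 9
    ns, nt = len(sources), len(targets)
    dim = ns + nt  # pad so every event can stay unmatched at zero cost
    cost = np.full((dim, dim), 0.0)
    cost[:ns, :nt] = big
    for i, s in enumerate(sources):
        expect = gene_map.get(s.gene_id) if gene_map else None
        for j, t in enumerate(targets):
            if (s.chrom, s.strand, s.event_type) != (t.chrom, t.strand, t.event_type):
                continue
            if expect is not None and t.gene_id != expect:
                continue
            offs = [abs(tb - sb) for sb, tb in zip(s.boundaries, t.boundaries)]
            if max(offs) <= tolerance:
                # matching an extra pair always beats not matching it
                cost[i, j] = sum(offs) - big
    rows, cols = linear_sum_assignment(cost)
    matched = set()
    for i, j in zip(rows, cols):
        if i < ns and j < nt and cost[i, j] < 0:
            matched.add((sources[i].event_id, targets[j].event_id))
    return matched
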