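"""Independent brute-force oracles used by the test suite.

These deliberately avoid sharing recurrences or code paths with the
implementations they check: exhaustive enumeration, exact integer
combinatorics, and dense dynamic programs written from the textbook
definitions.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

NEG = float("-inf")


# --------------------------------------------------------------------------
# coding: exhaustive frame-path enumeration (up to two frameshifts)

def best_framepath_score(M: np.ndarray, penalty: float) -> float:
    """Best local frame-path score with at most two frame switches.

    Enumerates every (start, end, switch positions, frame labels)
    combination through explicit segment-sum tensors and max-plus products
    rather than a positional recurrence.  With the default penalty the
    optimum never uses more than two switches on short sequences, which
    callers assert separately.
    """
    n = M.shape[0]
    if n == 0:
        return 0.0
    C = np.zeros((n + 1, 3))
    C[1:] = np.cumsum(M, axis=0)
    # S[f][i, j] = sum of M[i:j, f] for j > i, else -inf
    S = []
    idx = np.arange(n + 1)
    invalid = idx[None, :] <= idx[:, None]
    for f in range(3):
        seg = C[None, :, f] - C[:, None, f]
        seg = np.where(invalid, NEG, seg)
        S.append(seg)

    def maxplus(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        out = np.full_like(A, NEG)
        for t in range(n + 1):
            cand = A[:, t][:, None] + B[t, :][None, :]
            np.maximum(out, cand, out=out)
        return out

    best0 = max(S[f].max() for f in range(3))
    best1 = NEG
    pair_products = {}
    for f0 in range(3):
        for f1 in range(3):
            if f0 == f1:
                continue
            prod = maxplus(S[f0], S[f1])
            pair_products[(f0, f1)] = prod
            best1 = max(best1, prod.max())
    best2 = NEG
    for (f0, f1), prod in pair_products.items():
        for f2 in range(3):
            if f2 == f1:
                continue
            best2 = max(best2, maxplus(prod, S[f2]).max())
    return max(best0, best1 - penalty, best2 - 2 * penalty)


# --------------------------------------------------------------------------
# orthology: exhaustive clique enumeration

def enumerate_assignments(edges) -> dict:
    """Assign each gene to its best valid clique by exhaustive search.

    Enumerates every species subset x gene combination, keeps the
    pairwise-complete ones, and picks per gene the set maximising
    (size, summed bit score, smallest species subset) -- the same contract
    as the implementation, recomputed from scratch.
    """
    edge_map = {}
    genes_by_species: dict[str, set] = {}
    for e in edges:
        edge_map[frozenset(((e.species_a, e.gene_a),
                            (e.species_b, e.gene_b)))] = e.bit_sum
        genes_by_species.setdefault(e.species_a, set()).add(e.gene_a)
        genes_by_species.setdefault(e.species_b, set()).add(e.gene_b)
    species = sorted(genes_by_species)
    valid_sets = []
    for r in range(2, len(species) + 1):
        for subset in itertools.combinations(species, r):
            pools = [sorted(genes_by_species[sp]) for sp in subset]
            for genes in itertools.product(*pools):
                members = list(zip(subset, genes))
                bits = []
                ok = True
                for pair in itertools.combinations(members, 2):
                    b = edge_map.get(frozenset(pair))
                    if b is None:
                        ok = False
                        break
                    bits.append(b)
                if ok:
                    valid_sets.append((members, sum(bits)))
    assignment: dict = {}
    for members, bit in valid_sets:
        subset = tuple(sorted(sp for sp, _ in members))
        for g in members:
            incumbent = assignment.get(g)
            cand = (len(members), bit, subset, members)
            if incumbent is None:
                assignment[g] = cand
                continue
            ilen, ibit, isub, _ = incumbent
            if (len(members), bit) > (ilen, ibit) or (
                    (len(members), bit) == (ilen, ibit) and subset < isub):
                assignment[g] = cand
    return {g: frozenset(v[3]) for g, v in assignment.items()}


# --------------------------------------------------------------------------
# Fisher: exact two-sided p via integer combinatorics

def fisher_exact_int(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided Fisher p with exact integer table comparisons."""
    k = a + b
    if k == 0 or n1 + n2 == 0 or k == n1 + n2:
        return 1.0
    lo, hi = max(0, k - n2), min(k, n1)
    nums = {x: comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    total = comb(n1 + n2, k)
    acc = sum(v for v in nums.values() if v <= obs)
    return acc / total


# --------------------------------------------------------------------------
# alignment: dense affine-gap local DP from the textbook definition

def dense_local_affine(a: str, b: str, score, gap_open: float,
                       gap_extend: float) -> float:
    """Full O(mn) affine local alignment; gap of length k costs
    gap_open + k*gap_extend."""
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - first, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - first, F[i - 1, j] - gap_extend)
            H[i, j] = max(0.0,
                          H[i - 1, j - 1] + score(a[i - 1], b[j - 1]),
                          E[i, j], F[i, j])
    return float(H.max())
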