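"""Brute-force oracle implementations shared by the test modules.

These deliberately use naive per-column loops and textbook formulas,
independent of the package's vectorized code paths.
"""

import math
from itertools import combinations

import numpy as np

from mitodemes.mito_data import Alignment


def random_alignment(rng, n, L, p_mut=0.15, p_n=0.0, prefix="s"):
    """Random alignment: shared ancestral sequence plus i.i.d. flips."""
    anc = rng.integers(0, 4, size=L)
    mat = np.tile(anc, (n, 1))
    mutate = rng.random((n, L)) < p_mut
    mat[mutate] = (mat[mutate] + rng.integers(1, 4, size=mutate.sum())) % 4
    if p_n:
        mat[rng.random((n, L)) < p_n] = 5
    return Alignment([f"{prefix}{i}" for i in range(n)], mat.astype(np.uint8))


def brute_pairwise_diffs(aln_a, aln_b, i, j):
    return sum(
        1
        for col in range(aln_a.L)
        if aln_a.matrix[i, col] != 5
        and aln_b.matrix[j, col] != 5
        and aln_a.matrix[i, col] != aln_b.matrix[j, col]
    )


def brute_pi(aln):
    pairs = list(combinations(range(aln.n), 2))
    return sum(brute_pairwise_diffs(aln, aln, i, j) for i, j in pairs) / len(pairs)


def brute_tajimas_d(aln):
    n, S = aln.n, 0
    for col in range(aln.L):
        residues = {aln.matrix[i, col] for i in range(n) if aln.matrix[i, col] != 5}
        if len(residues) >= 2:
            S += 1
    if S == 0:
        return math.nan
    pi = brute_pi(aln)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def brute_fst(aln_a, aln_b):
    hw = 0.5 * (brute_pi(aln_a) + brute_pi(aln_b))
    hb = np.mean(
        [
            brute_pairwise_diffs(aln_a, aln_b, i, j)
            for i in range(aln_a.n)
            for j in range(aln_b.n)
        ]
    )
    return 1 - hw / hb if hb else 0.0
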