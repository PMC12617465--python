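"""Summary statistics for ABC, computed identically on observed and
simulated alignments.

Per population: number of haplotypes K, gene diversity H (haplotype-level),
segregating sites S, Tajima's D.  Per population pair: Hudson FST
(1 - Hw/Hb) and mean between-population pairwise differences Pi.

Distances use pairwise-complete columns (N ignored per pair); haplotype
statistics use complete-case columns (any-N columns dropped alignment-wide),
consistent with haplotype collapsing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mito_data import Alignment, NCODE, collapse_haplotypes, haplotype_diversity

STAT_NAMES_POP = ["K", "H", "S", "TAJIMAD"]
STAT_NAMES_PAIR = ["FST", "PI"]


def _nonmissing(matrix: np.ndarray) -> np.ndarray:
    return matrix != NCODE


def segregating_sites(aln: Alignment) -> int:
    """Columns with at least two distinct non-N residues."""
    return int(_segregating_mask(aln.matrix).sum())


def _segregating_mask(mat: np.ndarray) -> np.ndarray:
    """Vectorized boolean mask of segregating columns."""
    valid = mat != NCODE
    # Compare every residue against the first valid residue of its column.
    first = np.full(mat.shape[1], -1, dtype=np.int16)
    any_diff = np.zeros(mat.shape[1], dtype=bool)
    for i in range(mat.shape[0]):
        row = mat[i].astype(np.int16)
        v = valid[i]
        new = v & (first < 0)
        first[new] = row[new]
        any_diff |= v & (first >= 0) & (row != first)
    return any_diff


def gene_diversity(aln: Alignment) -> float:
    """Haplotype-level gene diversity (same estimator as Hd)."""
    if aln.n < 2:
        raise ValueError("gene diversity requires n >= 2")
    return haplotype_diversity(collapse_haplotypes(aln))


def haplotype_count(aln: Alignment) -> int:
    return collapse_haplotypes(aln).k


def pairwise_differences(matrix_a: np.ndarray, matrix_b: np.ndarray | None = None) -> np.ndarray:
    """Hamming distances on pairwise-complete columns.

    With one argument, returns the condensed upper-triangle distances of
    all within-matrix pairs; with two, the full cross matrix.
    """
    from scipy.spatial.distance import cdist, pdist

    if matrix_b is None:
        n, ncol = matrix_a.shape
        if not (matrix_a == NCODE).any():
            return pdist(matrix_a, metric="hamming") * ncol
        out = np.empty(n * (n - 1) // 2)
        k = 0
        valid = _nonmissing(matrix_a)
        for i in range(n - 1):
            vi = valid[i]
            for j in range(i + 1, n):
                both = vi & valid[j]
                out[k] = np.count_nonzero((matrix_a[i] != matrix_a[j]) & both)
                k += 1
        return out
    if not (matrix_a == NCODE).any() and not (matrix_b == NCODE).any():
        return cdist(matrix_a, matrix_b, metric="hamming") * matrix_a.shape[1]
    valid_a = _nonmissing(matrix_a)
    valid_b = _nonmissing(matrix_b)
    out = np.empty((matrix_a.shape[0], matrix_b.shape[0]))
    for i in range(matrix_a.shape[0]):
        both = valid_a[i] & valid_b
        out[i] = ((matrix_a[i][None, :] != matrix_b) & both).sum(axis=1)
    return out


def nucleotide_diversity(aln: Alignment) -> float:
    """Mean pairwise differences within the sample (pi)."""
    if aln.n < 2:
        raise ValueError("pi requires n >= 2")
    return float(pairwise_differences(aln.matrix).mean())


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(aln: Alignment) -> float:
    """Tajima's (1989) D; NaN when no segregating sites.

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard
    n-dependent constants.  Requires n >= 4.
    """
    n = aln.n
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    S = segregating_sites(aln)
    if S == 0:
        return math.nan
    pi = nucleotide_diversity(aln)
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    return float((pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)))


def pi_between(aln_a: Alignment, aln_b: Alignment) -> float:
    """Mean Hamming distance over all cross-population pairs.

    Pairs formed by the same individual (shared sample id) are excluded,
    so comparing a population with itself reduces to its within-population
    mean (and FST of a population against itself is exactly 0).
    """
    d = pairwise_differences(aln_a.matrix, aln_b.matrix)
    if aln_a.sample_ids == aln_b.sample_ids:
        # Self-comparison: the (i, i) cells pair an individual with itself
        # and are excluded, so pi_between(a, a) equals the within mean.
        if aln_a.n < 2:
            raise ValueError("self-comparison needs n >= 2")
        mask = ~np.eye(d.shape[0], dtype=bool)
        return float(d[mask].mean())
    return float(d.mean())


def pairwise_fst(aln_a: Alignment, aln_b: Alignment, floor_zero: bool = False) -> float:
    """Hudson-style sequence FST = 1 - Hw/Hb.

    Hw is the average of the two within-population mean pairwise
    differences; Hb the between-population mean.  Negative estimates are
    reported as computed unless ``floor_zero``.  Both Hw and Hb zero
    (identical monomorphic populations) returns 0.
    """
    if aln_a.n < 2 or aln_b.n < 2:
        raise ValueError("FST requires n >= 2 in both populations")
    hw = 0.5 * (nucleotide_diversity(aln_a) + nucleotide_diversity(aln_b))
    hb = pi_between(aln_a, aln_b)
    if hb == 0.0:
        return 0.0
    fst = 1.0 - hw / hb
    return max(0.0, fst) if floor_zero else float(fst)


@dataclass
class SummaryVector:
    """Fixed-order named statistic vector shared by observed and simulated
    data (the same code path computes both)."""

    values: pd.Series
    populations: list[str]

    @property
    def names(self) -> list[str]:
        return list(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        return self.values.to_frame().T


def expected_length(n_pops: int) -> int:
    return 4 * n_pops + 2 * (n_pops * (n_pops - 1) // 2)


def summarize(
    aln: Alignment,
    populations: Mapping[str, Sequence[int]],
    floor_fst: bool = False,
) -> SummaryVector:
    """Compute the full per-population and per-pair statistic vector.

    ``populations`` maps population name to row indices; order defines the
    (documented, fixed) vector ordering: K,H,S,TAJIMAD per population in
    the given order, then FST,PI per pair in combination order.
    Populations must have n >= 2.  Tajima's D for n < 4 or S = 0 is NaN
    (imputation happens at reference-table assembly).
    """
    pops = list(populations)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    # Statistics depend only on segregating columns (constant columns never
    # separate haplotypes nor add distance), so slice once for speed.  A
    # fully monomorphic alignment keeps a single column as a placeholder.
    seg = _segregating_mask(aln.matrix)
    if not seg.any():
        seg[0] = True
    sliced = Alignment(list(aln.sample_ids), aln.matrix[:, seg], aln.positions[seg])
    subsets = {}
    for p in pops:
        idx = list(populations[p])
        if len(idx) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
        subsets[p] = sliced.take(idx)

    values: dict[str, float] = {}
    for p in pops:
        sub = subsets[p]
        tab = collapse_haplotypes(sub)
        values[f"K_{p}"] = tab.k
        values[f"H_{p}"] = haplotype_diversity(tab)
        values[f"S_{p}"] = segregating_sites(sub)
        values[f"TAJIMAD_{p}"] = tajimas_d(sub) if sub.n >= 4 else math.nan
    for a, b in combinations(pops, 2):
        values[f"FST_{a}_{b}"] = pairwise_fst(subsets[a], subsets[b], floor_zero=floor_fst)
        values[f"PI_{a}_{b}"] = pi_between(subsets[a], subsets[b])

    series = pd.Series(values, dtype=float)
    assert len(series) == expected_length(len(pops))
    return SummaryVector(values=series, populations=pops)


def populations_from_metadata(metadata, sample_ids: Sequence[str]) -> dict[str, list[int]]:
    """Group row indices by metadata group label, in first-seen order."""
    by_id = {m.sample_id: m.group for m in metadata}
    pops: dict[str, list[int]] = {}
    for i, sid in enumerate(sample_ids):
        pops.setdefault(by_id[sid], []).append(i)
    return pops
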