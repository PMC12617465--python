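"""Exploratory structure analyses: FST matrices, classical MDS,
correspondence analysis and chi-square independence tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .mito_data import Alignment
from .sumstats import pairwise_fst

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 3  # groups below this are excluded (with a warning)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.abs(np.diag(self.matrix)) == 0):
            raise ValueError("distance matrix diagonal must be exactly 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def fst_matrix(
    groups: Mapping[str, Alignment],
    floor_zero: bool = True,
    min_size: int = MIN_GROUP_SIZE,
) -> tuple[DistanceMatrix, pd.DataFrame]:
    """All pairwise FST values between groups.

    Groups with fewer than ``min_size`` samples are excluded with a
    warning.  Returns the (optionally zero-floored) distance matrix for
    downstream MDS plus the raw unfloored values as a DataFrame.
    """
    kept = {}
    for name, aln in groups.items():
        if aln.n < max(2, min_size):
            logger.warning("group %s excluded from FST matrix (n=%d)", name, aln.n)
            continue
        kept[name] = aln
    labels = list(kept)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups of sufficient size")
    k = len(labels)
    raw = np.zeros((k, k))
    for (i, a), (j, b) in combinations(enumerate(labels), 2):
        f = pairwise_fst(kept[a], kept[b])
        raw[i, j] = raw[j, i] = f
    dist = np.maximum(raw, 0.0) if floor_zero else raw.copy()
    np.fill_diagonal(dist, 0.0)
    return (
        DistanceMatrix(labels, dist),
        pd.DataFrame(raw, index=labels, columns=labels),
    )


@dataclass
class MDSResult:
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all n, descending
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"MDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def classical_mds(D: DistanceMatrix, k: int = 2) -> MDSResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers B = -1/2 J D^2 J, eigendecomposes and returns the top-k
    coordinates scaled by sqrt(eigenvalue).  When D is Euclidean-embeddable
    in k dimensions the pairwise coordinate distances reproduce D exactly;
    negative eigenvalues are reported in ``eigenvalues``.
    """
    n = len(D.labels)
    if k >= n:
        raise ValueError(f"k={k} must be < number of points ({n})")
    D2 = D.matrix**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))
    return MDSResult(coordinates=coords, eigenvalues=eigvals, labels=list(D.labels))


@dataclass
class CAResult:
    """Correspondence analysis in row-principal normalization."""

    row_coordinates: pd.DataFrame
    col_coordinates: pd.DataFrame
    inertia: np.ndarray  # per axis
    total_inertia: float


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    """Correspondence analysis of a nonnegative contingency table.

    SVD of the standardized residuals (P - r c^T) / sqrt(r c^T); axes are
    ordered by inertia; total inertia equals chi-square / n.  Rows are in
    principal coordinates, columns in principal coordinates as well
    (symmetric scaling of the same SVD); zero row/column margins raise.
    """
    counts = table.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("contingency table must be nonnegative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("contingency table is empty")
    P = counts / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r == 0).any():
        bad = table.index[np.where(r == 0)[0]].tolist()
        raise ValueError(f"zero row margin for {bad}")
    if (c == 0).any():
        bad = table.columns[np.where(c == 0)[0]].tolist()
        raise ValueError(f"zero column margin for {bad}")
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    inertia = sv**2
    # Principal coordinates.
    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None]
    axes = [f"CA{i + 1}" for i in range(len(sv))]
    return CAResult(
        row_coordinates=pd.DataFrame(row_coords, index=table.index, columns=axes),
        col_coordinates=pd.DataFrame(col_coords, index=table.columns, columns=axes),
        inertia=inertia,
        total_inertia=float(inertia.sum()),
    )


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    dof: int
    mode: str


def chi_square_independence(
    table: pd.DataFrame,
    mode: str = "asymptotic",
    n_permutations: int = 9999,
    seed: int = 0,
) -> ChiSquareResult:
    """Pearson chi-square test of row/column independence.

    ``asymptotic`` uses the chi-square distribution with (r-1)(c-1) df;
    ``monte_carlo`` samples tables with both margins fixed and returns
    p = (1 + #{chi2_perm >= chi2_obs}) / (B + 1) — recommended for sparse
    haplogroup tables.
    """
    counts = table.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("table has a zero margin")
    stat, p_asym, dof, _ = stats.chi2_contingency(counts, correction=False)
    if mode == "asymptotic":
        return ChiSquareResult(float(stat), float(p_asym), int(dof), mode)
    if mode != "monte_carlo":
        raise ValueError("mode must be 'asymptotic' or 'monte_carlo'")
    rng = np.random.default_rng(seed)
    rt = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
    perms = rt.rvs(n_permutations, random_state=rng)
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    perm_stats = ((perms - expected) ** 2 / expected).sum(axis=(1, 2))
    p = (1.0 + np.sum(perm_stats >= stat - 1e-12)) / (n_permutations + 1.0)
    return ChiSquareResult(float(stat), float(p), int(dof), mode)
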