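"""Data model and I/O for aligned mitogenomes and sample metadata.

Sequences are assumed pre-aligned to the rCRS coordinate system, so that
column ``i`` of the alignment (1-based) is rCRS nucleotide position ``i``.
The module provides hotspot/indel masking, haplotype collapsing, gene
(haplotype) diversity and haplogroup contingency tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Residue byte codes. Gap and N are first-class symbols.
_ALPHABET = np.frombuffer(b"ACGT-N", dtype="S1")
_CODE = {b: i for i, b in enumerate(b"ACGT-N")}

A, C, G, T, GAP, NCODE = range(6)

#: rCRS length in base pairs.
RCRS_LENGTH = 16_569

METADATA_COLUMNS = [
    "sample_id",
    "group",
    "geogroup",
    "age_bp",
    "age_low",
    "age_high",
    "haplogroup",
]


def encode_sequences(seqs: Iterable[str]) -> np.ndarray:
    """Encode an iterable of equal-length sequence strings to a uint8 matrix.

    Unknown characters are mapped to N (with a warning logged once per call).
    """
    rows = []
    saw_unknown = False
    for s in seqs:
        raw = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
        row = np.full(raw.shape, NCODE, dtype=np.uint8)
        for byte, code in _CODE.items():
            row[raw == byte] = code
        known = np.zeros(raw.shape, dtype=bool)
        for byte in _CODE:
            known |= raw == byte
        if not known.all():
            saw_unknown = True
        rows.append(row)
    if saw_unknown:
        logger.warning("unknown residue characters encountered; mapped to N")
    return np.asarray(rows, dtype=np.uint8)


def decode_sequences(matrix: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    return ["".join(chr(b"ACGT-N"[c]) for c in row) for row in matrix]


class AlignmentError(ValueError):
    """Raised when FASTA records cannot form a rectangular alignment."""


@dataclass
class Alignment:
    """A rectangular haploid alignment in rCRS coordinates.

    Attributes
    ----------
    sample_ids:
        Unique sample identifiers, one per row.
    matrix:
        ``(n, L)`` uint8 matrix over the 6-symbol code {A,C,G,T,-,N}.
    positions:
        1-based original rCRS coordinate of each column.  After masking,
        columns are dropped but their coordinates remain traceable here.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentError("sample_ids / matrix row mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("sample_ids must be unique")
        if self.matrix.shape[1] < 1:
            raise AlignmentError("alignment must have at least one column")
        if self.positions is None:
            self.positions = np.arange(1, self.matrix.shape[1] + 1)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape[0] != self.matrix.shape[1]:
            raise AlignmentError("positions / matrix column mismatch")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_sequences(cls, sample_ids: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal record lengths: {sorted(lengths)}")
        return cls(list(sample_ids), encode_sequences(seqs))

    def sequences(self) -> list[str]:
        return decode_sequences(self.matrix)

    def take(self, row_indices: Sequence[int]) -> "Alignment":
        """Row subset preserving column coordinates."""
        idx = np.asarray(row_indices, dtype=int)
        return Alignment(
            [self.sample_ids[i] for i in idx],
            self.matrix[idx],
            self.positions.copy(),
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation: analysis group, geogroup, age and haplogroup."""

    sample_id: str
    group: str
    geogroup: str | None = None
    age_bp: float = 0.0
    age_ci95: tuple[float, float] | None = None
    haplogroup: str | None = None

    def __post_init__(self) -> None:
        if self.age_bp < 0:
            raise ValueError(f"{self.sample_id}: age_bp must be >= 0")
        if self.age_ci95 is not None:
            lo, hi = self.age_ci95
            if not (lo <= self.age_bp <= hi):
                raise ValueError(
                    f"{self.sample_id}: age_bp {self.age_bp} outside 95% range [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class MaskPolicy:
    """Columns excluded from all sequence comparisons.

    ``excluded_positions`` are 1-based rCRS coordinates; ``exclude_indels``
    drops every column containing a gap in any sequence (whole-column drop,
    which keeps haplotype identity transitive).
    """

    excluded_positions: frozenset[int] = frozenset()
    exclude_indels: bool = True

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.excluded_positions):
            raise ValueError("mask positions must be >= 1")


def default_mask() -> MaskPolicy:
    """The standard mitogenome hotspot mask.

    Excludes the 16519 hotspot transition, the poly-C regions around
    np309 (303-315) and np16189 (16182-16194), and all indel columns.
    """
    positions = {16519} | set(range(303, 316)) | set(range(16182, 16195))
    return MaskPolicy(frozenset(positions), exclude_indels=True)


def apply_mask(aln: Alignment, policy: MaskPolicy) -> Alignment:
    """Drop masked columns (and, optionally, all columns containing a gap)."""
    keep = ~np.isin(aln.positions, list(policy.excluded_positions))
    if policy.exclude_indels:
        keep &= ~(aln.matrix == GAP).any(axis=0)
    return Alignment(list(aln.sample_ids), aln.matrix[:, keep], aln.positions[keep])


def complete_columns(aln: Alignment) -> np.ndarray:
    """Boolean mask of columns with no N anywhere (complete-case columns)."""
    return ~(aln.matrix == NCODE).any(axis=0)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with counts, sorted by count desc then id."""

    haplotype_ids: list[str]
    counts: np.ndarray
    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.haplotype_ids)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "HaplotypeTable":
        """Build an anonymous table directly from a count composition."""
        order = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
        ids = [f"H{j + 1}" for j in range(len(counts))]
        sorted_counts = [counts[i] for i in order]
        return cls(ids, np.asarray(sorted_counts), {h: [] for h in ids})


def collapse_haplotypes(aln: Alignment, policy: MaskPolicy | None = None) -> HaplotypeTable:
    """Collapse sequences identical on all unmasked, complete-case columns.

    Columns containing N in any sequence are dropped alignment-wide before
    comparison so that haplotype identity is transitive.
    """
    if aln.n == 0:
        raise AlignmentError("cannot collapse an empty alignment")
    if policy is not None:
        aln = apply_mask(aln, policy)
    mat = aln.matrix[:, complete_columns(aln)]
    groups: dict[bytes, list[str]] = {}
    for sid, row in zip(aln.sample_ids, mat):
        groups.setdefault(row.tobytes(), []).append(sid)
    entries = []
    for ids in groups.values():
        rep = min(ids)
        entries.append((rep, len(ids), sorted(ids)))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return HaplotypeTable(
        [e[0] for e in entries],
        np.asarray([e[1] for e in entries]),
        {e[0]: e[2] for e in entries},
    )


def haplotype_diversity(tab: HaplotypeTable) -> float:
    """Unbiased gene diversity Hd = n/(n-1) * (1 - sum p_i^2).

    The probability that two sequences drawn without replacement carry
    different haplotypes.
    """
    n = tab.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = tab.frequencies
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


#: Prefix-collapse map from fine haplogroup labels to macrohaplogroups.
#: Longest matching prefix wins; extend or replace via the `macro_map`
#: argument of :func:`haplogroup_frequency_table`.
DEFAULT_MACRO_MAP: dict[str, str] = {
    "U5": "U5",
    "U2": "U2-U3-U4",
    "U3": "U2-U3-U4",
    "U4": "U2-U3-U4",
    "U6": "U6",
    "U8": "U8b/K",
    "K": "U8b/K",
    "H1": "H1",
    "H2": "H2",
    "H3": "H3",
    "H5": "H5",
    "HV0": "HV0-V",
    "V": "HV0-V",
    "HV": "HV",
    "H": "H",
    "J1": "J1",
    "J2": "J2",
    "J": "J",
    "T1": "T1",
    "T2": "T2",
    "T": "T",
    "N1": "N1-I",
    "I": "N1-I",
    "X2": "X2-W",
    "W": "X2-W",
    "X": "X2-W",
    "L1": "L1",
    "L2": "L2",
    "L3": "L3",
    "L4": "L4",
    "M1": "M1",
    "R": "R",
    "N": "N",
    "U": "U",
}


def macrohaplogroup(label: str, macro_map: Mapping[str, str] | None = None) -> str:
    """Collapse a fine haplogroup label to its macrohaplogroup by longest prefix."""
    mapping = DEFAULT_MACRO_MAP if macro_map is None else macro_map
    for prefix in sorted(mapping, key=len, reverse=True):
        if label.startswith(prefix):
            return mapping[prefix]
    return label


def haplogroup_frequency_table(
    meta: Sequence[SampleMetadata],
    grouping: str = "group",
    macro_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Contingency table of macrohaplogroup counts per group (or geogroup).

    Returns the table and the list of sample ids lacking a haplogroup
    label (excluded from the table).
    """
    if grouping not in ("group", "geogroup"):
        raise ValueError("grouping must be 'group' or 'geogroup'")
    rows = []
    missing = []
    for m in meta:
        label = m.haplogroup
        if label is None or label == "":
            missing.append(m.sample_id)
            continue
        key = m.group if grouping == "group" else (m.geogroup or "unknown")
        rows.append((key, macrohaplogroup(label, macro_map)))
    if not rows:
        return pd.DataFrame(), missing
    df = pd.DataFrame(rows, columns=[grouping, "macrohaplogroup"])
    table = pd.crosstab(df[grouping], df["macrohaplogroup"])
    return table, missing


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    Symbols are upper-cased; anything outside {A,C,G,T,-,N} becomes N with
    a logged warning.  Unequal record lengths raise :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    return Alignment.from_sequences(ids, [str(r.seq) for r in records])


def write_fasta(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the tab-separated metadata table.

    Expected columns: sample_id, group, geogroup, age_bp, age_low,
    age_high, haplogroup (empty cells allowed in the last four).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out = []
    for _, row in df.iterrows():
        ci = None
        if pd.notna(row.get("age_low")) and pd.notna(row.get("age_high")):
            ci = (float(row["age_low"]), float(row["age_high"]))
        hap = row.get("haplogroup")
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                geogroup=None if pd.isna(row.get("geogroup")) else str(row["geogroup"]),
                age_bp=float(row.get("age_bp", 0.0)),
                age_ci95=ci,
                haplogroup=None if pd.isna(hap) else str(hap),
            )
        )
    return out


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in meta:
        lo, hi = (m.age_ci95 if m.age_ci95 is not None else (np.nan, np.nan))
        rows.append(
            {
                "sample_id": m.sample_id,
                "group": m.group,
                "geogroup": m.geogroup or "",
                "age_bp": m.age_bp,
                "age_low": lo,
                "age_high": hi,
                "haplogroup": m.haplogroup or "",
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
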