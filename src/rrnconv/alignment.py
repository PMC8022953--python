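"""Aligned multicopy gene families and their heterologous-site structure.

A bacterial genome typically carries several near-identical copies of each
rRNA operon (seven in *Escherichia coli*).  Gene conversion between these
copies is only detectable at *heterologous sites*: alignment columns where
the copies differ from one another.  This module reads pre-aligned
multi-FASTA files of the copies of a single region (e.g. the 16S gene, the
23S gene, or the 23S-5S intergenic spacer), validates them, indexes the
heterologous columns, and computes pairwise percent-identity statistics.

Coordinates are 1-based, inclusive, on alignment columns throughout the
package.  Gaps are a fifth character state: a gap aligned to a base counts
as a difference, two aligned gaps count as a match, and the denominator of
percent identity is always the full alignment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "AlignmentShapeError",
    "AlphabetError",
    "OperonIdentityError",
    "OperonAlignment",
    "HeterologousSiteIndex",
    "IdentityMatrix",
    "load_region_alignment",
    "heterologous_sites",
    "mean_pairwise_identity",
    "encode_sequence",
    "decode_row",
]

#: Character states, in encoding order.  Gap is a first-class fifth state.
ALPHABET = "ACGT-N"

GAP_CODE = 4
N_CODE = 5

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
# RNA input: U maps to T.
_ENCODE[ord("U")] = 3
_ENCODE[ord("u")] = 3
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


class AlignmentShapeError(ValueError):
    """Rows of an alignment do not all have the same length."""


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, U, -, N}."""


class OperonIdentityError(ValueError):
    """Operon labels are missing, duplicated, or do not match the records."""


def encode_sequence(seq: str, *, allow_n: bool = False) -> np.ndarray:
    """Encode a gapped sequence string into uint8 state codes."""
    raw = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[raw]
    bad = codes == 255
    if not allow_n:
        bad |= codes == N_CODE
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise AlphabetError(
            f"illegal character {seq[pos]!r} at column {pos + 1}; "
            f"allowed characters are {ALPHABET if allow_n else ALPHABET[:-1]} (case-insensitive, U->T)"
        )
    return codes


def decode_row(codes: np.ndarray) -> str:
    """Decode a uint8 state-code row back to a string."""
    return _DECODE[codes].tobytes().decode()


@dataclass(frozen=True)
class OperonAlignment:
    """Gapped sequences of the copies of one gene region.

    Parameters
    ----------
    region_id:
        Region label, e.g. ``"16S"``, ``"23S"`` or ``"spacer"``.
    operon_ids:
        Ordered copy labels, e.g. ``("rrnA", ..., "rrnH")``.
    data:
        uint8 matrix of shape ``(n_copies, n_columns)`` with state codes
        indexing into :data:`ALPHABET`.
    kind:
        ``"gene"`` for subunit genes, ``"spacer"`` for the biallelic
        intergenic spacer whose two alleles swap as whole units.
    """

    region_id: str
    operon_ids: tuple[str, ...]
    data: np.ndarray
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise AlignmentShapeError("alignment data must be a 2-D matrix")
        if self.n_rows < 2:
            raise AlignmentShapeError("an operon family needs at least 2 copies")
        if self.n_columns < 1:
            raise AlignmentShapeError("alignment must have at least 1 column")
        if len(self.operon_ids) != self.n_rows:
            raise OperonIdentityError("one operon label is required per row")
        if len(set(self.operon_ids)) != len(self.operon_ids):
            raise OperonIdentityError("operon labels must be unique")
        if self.kind not in ("gene", "spacer"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.data.dtype != np.uint8:
            object.__setattr__(self, "data", self.data.astype(np.uint8))

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def row(self, operon_id: str) -> np.ndarray:
        return self.data[self.row_index(operon_id)]

    def row_index(self, operon_id: str) -> int:
        try:
            return self.operon_ids.index(operon_id)
        except ValueError:
            raise OperonIdentityError(f"unknown operon {operon_id!r}") from None

    def sequences(self) -> dict[str, str]:
        """Decoded gapped sequences keyed by operon label."""
        return {op: decode_row(self.data[i]) for i, op in enumerate(self.operon_ids)}

    @classmethod
    def from_sequences(
        cls,
        region_id: str,
        seqs: Mapping[str, str] | Sequence[tuple[str, str]],
        *,
        kind: str = "gene",
        allow_n: bool = False,
    ) -> "OperonAlignment":
        items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
        lengths = {len(s) for _, s in items}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"ragged alignment for region {region_id!r}: row lengths {sorted(lengths)}"
            )
        data = np.vstack([encode_sequence(s, allow_n=allow_n) for _, s in items])
        return cls(region_id, tuple(k for k, _ in items), data, kind=kind)


@dataclass(frozen=True)
class HeterologousSiteIndex:
    """Sorted 1-based columns where at least two copies differ.

    ``alleles_at[pos]`` maps operon label -> character state at the column.
    Gap counts as a distinct state; columns containing N are excluded.
    """

    positions: tuple[int, ...]
    alleles_at: dict[int, dict[str, str]] = field(repr=False)

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, pos: int) -> bool:
        return pos in self.alleles_at


@dataclass(frozen=True)
class IdentityMatrix:
    """Pairwise percent identities over the full alignment length."""

    operon_ids: tuple[str, ...]
    percent: np.ndarray  # (n, n), symmetric, diagonal 100

    @property
    def mean(self) -> float:
        """Arithmetic mean over the n(n-1)/2 unordered pairs."""
        n = len(self.operon_ids)
        iu = np.triu_indices(n, k=1)
        return float(self.percent[iu].mean())

    def pair(self, a: str, b: str) -> float:
        i = self.operon_ids.index(a)
        j = self.operon_ids.index(b)
        return float(self.percent[i, j])


def load_region_alignment(
    path: str | Path,
    region_id: str,
    expected_operons: Iterable[str],
    *,
    kind: str = "gene",
    allow_n: bool = False,
) -> OperonAlignment:
    """Read an aligned multi-FASTA file and validate it against the family.

    Records may appear in any order in the file; rows are returned in
    ``expected_operons`` order.  Raises :class:`OperonIdentityError` when a
    label is missing or duplicated, :class:`AlignmentShapeError` when rows
    are ragged, and :class:`AlphabetError` on illegal characters.
    """
    path = Path(path)
    expected = list(expected_operons)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise OperonIdentityError(f"duplicate record id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    missing = [op for op in expected if op not in records]
    if missing:
        raise OperonIdentityError(f"missing operon record(s) {missing} in {path}")
    return OperonAlignment.from_sequences(
        region_id, [(op, records[op]) for op in expected], kind=kind, allow_n=allow_n
    )


def heterologous_sites(aln: OperonAlignment) -> HeterologousSiteIndex:
    """Index the columns at which the copies are not all identical.

    A column is heterologous when it carries >= 2 distinct states among the
    rows, gap counting as a state of its own (length polymorphism in the
    spacer is allelic, and small indels inside genes are treated by the
    same machinery).  Columns containing N in any row are never indexed.
    """
    data = aln.data
    varying = (data != data[0]).any(axis=0)
    varying &= ~(data == N_CODE).any(axis=0)
    cols = np.flatnonzero(varying)
    alleles = {
        int(c) + 1: {op: ALPHABET[data[i, c]] for i, op in enumerate(aln.operon_ids)}
        for c in cols
    }
    return HeterologousSiteIndex(tuple(int(c) + 1 for c in cols), alleles)


def mean_pairwise_identity(aln: OperonAlignment) -> IdentityMatrix:
    """Percent identity for every unordered pair of copies.

    identity(a, b) = (columns where a and b carry the identical character,
    aligned gap pairs included) / alignment length x 100.  Using the full
    alignment length as the denominator makes identities over concatenated
    regions the column-length-weighted average of the per-region values.
    """
    n = aln.n_rows
    pct = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            matches = int((aln.data[i] == aln.data[j]).sum())
            pct[i, j] = pct[j, i] = 100.0 * matches / aln.n_columns
    return IdentityMatrix(aln.operon_ids, pct)


def concatenate_alignments(alns: Sequence[OperonAlignment], region_id: str = "concat") -> OperonAlignment:
    """Column-wise concatenation of regions sharing the same copy labels."""
    first = alns[0]
    for a in alns[1:]:
        if a.operon_ids != first.operon_ids:
            raise OperonIdentityError("regions to concatenate must share operon labels")
    return OperonAlignment(
        region_id, first.operon_ids, np.hstack([a.data for a in alns]), kind="gene"
    )
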