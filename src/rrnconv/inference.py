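"""Parsimonious reconstruction of gene conversion events.

Given the ancestral alignment of an operon family and the sequence of one
copy in an evolved clone, every difference from the ancestor must be
explained by gene conversions that copied sequence from another
(*donor*) copy into this (*recipient*) copy, since no de novo rRNA point
mutations are expected at mutation-accumulation timescales.  The most
parsimonious explanation is the smallest set of events such that each
event has at least one donor whose ancestral sequence matches the evolved
recipient across the whole stretch it covers.

Each event carries

* its *changed positions* — the alignment columns it altered,
* a maximal *donor candidate set* — every copy whose ancestral states
  match the evolved recipient at all columns the event must span,
* a *minimum extent* — first to last changed column, and
* a *maximum extent* — the changed run extended outward column by column
  through donor-matching sequence until every donor candidate disagrees
  with the evolved recipient, or the region boundary is reached.

The greedy left-to-right partition implemented here is optimal because
donor compatibility is antitone in the window (a window's donor set only
shrinks as the window grows), so closing an event as late as possible
never costs an extra event; :func:`min_events_oracle` is an independent
dynamic-programming check used by the test-suite.

The 23S-5S intergenic spacer is treated separately: its two divergent
alleles swap as whole units, so a spacer event always covers the entire
region and is detected by allele classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import OperonAlignment, decode_row, encode_sequence

__all__ = [
    "NovelAlleleError",
    "SpacerUnclassifiedError",
    "GeneConversionEvent",
    "SpacerAllele",
    "EventSet",
    "infer_events_for_recipient",
    "infer_events_for_family",
    "infer_event_extents",
    "classify_spacer_allele",
    "min_events_oracle",
    "greedy_event_partition",
    "events_to_frame",
    "events_from_frame",
]


class NovelAlleleError(ValueError):
    """A changed position matches no other copy: not explicable by conversion."""


class SpacerUnclassifiedError(ValueError):
    """A spacer sequence matches neither reference allele exactly."""


class OracleSizeError(ValueError):
    """Instance exceeds the exhaustive oracle's size guard."""


@dataclass(frozen=True)
class GeneConversionEvent:
    """One inferred conversion of ``recipient`` from any of ``donor_candidates``."""

    lineage_id: str
    region_id: str
    recipient: str
    changed_positions: tuple[int, ...]
    donor_candidates: frozenset[str]
    min_extent: tuple[int, int]
    max_extent: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.changed_positions:
            raise ValueError("an event must change at least one position")
        if not self.donor_candidates:
            raise ValueError("an event needs at least one donor candidate")
        if self.recipient in self.donor_candidates:
            raise ValueError("recipient cannot be its own donor")
        lo, hi = self.min_extent
        Lo, Hi = self.max_extent
        if not (Lo <= lo <= hi <= Hi):
            raise ValueError("min_extent must be contained in max_extent")

    @property
    def min_size(self) -> int:
        return self.min_extent[1] - self.min_extent[0] + 1

    @property
    def max_size(self) -> int:
        return self.max_extent[1] - self.max_extent[0] + 1


@dataclass(frozen=True)
class SpacerAllele:
    """One of the two reference alleles of the biallelic spacer."""

    allele_id: str
    sequence: str  # ungapped


@dataclass
class EventSet:
    """A collection of inferred events with count bookkeeping."""

    events: list[GeneConversionEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def extend(self, events: Iterable[GeneConversionEvent]) -> None:
        self.events.extend(events)

    def counts_by_region(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.region_id] = out.get(e.region_id, 0) + 1
        return out

    def counts_by_recipient(self, operon_ids: Sequence[str] | None = None) -> dict[str, int]:
        out = {op: 0 for op in operon_ids} if operon_ids else {}
        for e in self.events:
            out[e.recipient] = out.get(e.recipient, 0) + 1
        return out

    def counts_by_lineage_region(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for e in self.events:
            key = (e.lineage_id, e.region_id)
            out[key] = out.get(key, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)


# ---------------------------------------------------------------------------
# Core greedy partition over candidate columns
# ---------------------------------------------------------------------------

def _match_mask(anc_col: np.ndarray, state: int, recipient: int) -> int:
    """Bitmask of non-recipient copies whose ancestral state equals ``state``."""
    mask = 0
    for d in range(anc_col.shape[0]):
        if d != recipient and anc_col[d] == state:
            mask |= 1 << d
    return mask


def greedy_event_partition(
    anc_cols: np.ndarray,
    ev_cols: np.ndarray,
    recipient: int,
    region_of: np.ndarray | None = None,
) -> list[tuple[list[int], int]]:
    """Minimum-cardinality partition of the changed columns into events.

    Parameters
    ----------
    anc_cols:
        ``(n_copies, m)`` ancestral states at the candidate columns (all
        columns at which the ancestral family varies).
    ev_cols:
        ``(m,)`` evolved recipient states at the same columns.
    recipient:
        Row index of the recipient copy.
    region_of:
        Optional ``(m,)`` region ids; events never span a region boundary.

    Returns
    -------
    list of ``(changed_column_indices, donor_bitmask)``, left to right.
    The donor bitmask is the maximal set compatible with every changed
    column of the event *and* every intervening candidate column.
    """
    m = anc_cols.shape[1]
    changed = [c for c in range(m) if ev_cols[c] != anc_cols[recipient, c]]
    events: list[tuple[list[int], int]] = []
    cur_cols: list[int] = []
    cur_mask = 0
    for c in changed:
        mc = _match_mask(anc_cols[:, c], int(ev_cols[c]), recipient)
        if mc == 0:
            raise NovelAlleleError(
                f"changed state at candidate column index {c} matches no other copy"
            )
        start_new = not cur_cols
        if cur_cols:
            prev = cur_cols[-1]
            if region_of is not None and region_of[c] != region_of[prev]:
                start_new = True
            else:
                newmask = cur_mask
                for x in range(prev + 1, c):  # intervening unchanged columns
                    newmask &= _match_mask(anc_cols[:, x], int(ev_cols[x]), recipient)
                    if newmask == 0:
                        break
                newmask &= mc
                if newmask == 0:
                    start_new = True
                else:
                    cur_mask = newmask
        if start_new:
            if cur_cols:
                events.append((cur_cols, cur_mask))
            cur_cols = [c]
            cur_mask = mc
        else:
            cur_cols.append(c)
    if cur_cols:
        events.append((cur_cols, cur_mask))
    return events


def min_events_oracle(
    anc_cols: np.ndarray,
    ev_cols: np.ndarray,
    recipient: int,
    region_of: np.ndarray | None = None,
    *,
    max_changed: int = 8,
    max_copies: int = 4,
) -> int:
    """Exact minimum event count by exhaustive search over contiguous groups.

    Independent of the greedy path: dynamic programming over all ways to
    split the changed columns into contiguous donor-consistent windows,
    with feasibility re-checked column by column.  Guarded to small
    instances; raises :class:`OracleSizeError` beyond the guard.
    """
    if anc_cols.shape[0] > max_copies:
        raise OracleSizeError(f"oracle limited to {max_copies} copies")
    m = anc_cols.shape[1]
    changed = [c for c in range(m) if ev_cols[c] != anc_cols[recipient, c]]
    if len(changed) > max_changed:
        raise OracleSizeError(f"oracle limited to {max_changed} changed positions")
    k = len(changed)
    if k == 0:
        return 0

    def feasible(i: int, j: int) -> bool:
        # one donor matching the evolved recipient at every candidate column
        # between changed[i] and changed[j] inclusive, same region throughout
        lo, hi = changed[i], changed[j]
        if region_of is not None and not (region_of[lo:hi + 1] == region_of[lo]).all():
            return False
        for d in range(anc_cols.shape[0]):
            if d == recipient:
                continue
            if (anc_cols[d, lo:hi + 1] == ev_cols[lo:hi + 1]).all():
                return True
        return False

    best = [0] * (k + 1)
    for j in range(1, k + 1):
        best[j] = min(
            best[i] + 1 for i in range(j) if feasible(i, j - 1)
        ) if any(feasible(i, j - 1) for i in range(j)) else 10 ** 9
        if best[j] >= 10 ** 9:
            raise NovelAlleleError("some changed window has no compatible donor")
    return best[k]


# ---------------------------------------------------------------------------
# Extents
# ---------------------------------------------------------------------------

def infer_event_extents(
    ancestor: OperonAlignment,
    evolved_row: np.ndarray | str,
    changed_run: Sequence[int],
    donors: Iterable[str],
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Minimum and maximum extents of a conversion, in 1-based columns.

    The minimum extent spans first to last changed position.  The maximum
    extent is grown outward one column at a time: a donor stays in play
    while its ancestral state matches the evolved recipient at every
    column traversed so far; growth stops at the first column where no
    donor remains, or at the region boundary.
    """
    run = sorted(int(p) for p in changed_run)
    if not run:
        raise ValueError("changed_run must be non-empty")
    donor_idx = [ancestor.row_index(d) for d in donors]
    if not donor_idx:
        raise ValueError("donor set must be non-empty")
    ev = encode_sequence(evolved_row) if isinstance(evolved_row, str) else np.asarray(evolved_row)
    anc = ancestor.data
    lo, hi = run[0], run[-1]

    def grow(start_col: int, step: int) -> int:
        surviving = set(donor_idx)
        col = start_col
        edge = start_col - step  # last column inside the extent
        while 1 <= col <= ancestor.n_columns:
            surviving = {d for d in surviving if anc[d, col - 1] == ev[col - 1]}
            if not surviving:
                return edge
            edge = col
            col += step
        return edge

    return (lo, hi), (grow(lo - 1, -1) if lo > 1 else lo, grow(hi + 1, +1) if hi < ancestor.n_columns else hi)


# ---------------------------------------------------------------------------
# Full-alignment inference
# ---------------------------------------------------------------------------

def _candidate_columns(ancestor: OperonAlignment, ev: np.ndarray, r: int) -> np.ndarray:
    anc = ancestor.data
    varies = (anc != anc[0]).any(axis=0)
    changed = ev != anc[r]
    return np.flatnonzero(varies | changed)


def infer_events_for_recipient(
    ancestor: OperonAlignment,
    evolved_row: np.ndarray | str,
    recipient: str,
    *,
    lineage_id: str = "",
) -> list[GeneConversionEvent]:
    """Most parsimonious events explaining one evolved copy.

    Raises :class:`NovelAlleleError` when a changed position matches no
    other ancestral copy (such a change cannot arise by conversion).
    """
    ev = encode_sequence(evolved_row) if isinstance(evolved_row, str) else np.asarray(evolved_row)
    if ev.shape[0] != ancestor.n_columns:
        raise ValueError("evolved row length must equal the ancestral alignment length")
    r = ancestor.row_index(recipient)

    if ancestor.kind == "spacer":
        return _infer_spacer_events(ancestor, ev, recipient, lineage_id=lineage_id)

    cand = _candidate_columns(ancestor, ev, r)
    anc_cols = ancestor.data[:, cand]
    ev_cols = ev[cand]
    parts = greedy_event_partition(anc_cols, ev_cols, r)
    events = []
    for idx_list, mask in parts:
        positions = tuple(int(cand[i]) + 1 for i in idx_list)
        donors = frozenset(
            ancestor.operon_ids[d] for d in range(ancestor.n_rows) if mask >> d & 1
        )
        min_ext, max_ext = infer_event_extents(ancestor, ev, positions, donors)
        events.append(
            GeneConversionEvent(
                lineage_id=lineage_id,
                region_id=ancestor.region_id,
                recipient=recipient,
                changed_positions=positions,
                donor_candidates=donors,
                min_extent=min_ext,
                max_extent=max_ext,
            )
        )
    return events


def _infer_spacer_events(
    ancestor: OperonAlignment, ev: np.ndarray, recipient: str, *, lineage_id: str
) -> list[GeneConversionEvent]:
    # The spacer swaps as one unit: an evolved copy either equals its own
    # ancestral allele (no event) or another copy's allele (one event
    # spanning the whole region).
    r = ancestor.row_index(recipient)
    diff = np.flatnonzero(ev != ancestor.data[r])
    if diff.size == 0:
        return []
    donors = frozenset(
        op
        for i, op in enumerate(ancestor.operon_ids)
        if i != r and (ancestor.data[i] == ev).all()
    )
    if not donors:
        raise NovelAlleleError(
            f"evolved spacer of {recipient} matches no other copy's ancestral allele"
        )
    whole = (1, ancestor.n_columns)
    return [
        GeneConversionEvent(
            lineage_id=lineage_id,
            region_id=ancestor.region_id,
            recipient=recipient,
            changed_positions=tuple(int(c) + 1 for c in diff),
            donor_candidates=donors,
            min_extent=whole,
            max_extent=whole,
        )
    ]


def infer_events_for_family(
    ancestor: OperonAlignment,
    evolved: OperonAlignment,
    *,
    lineage_id: str = "",
) -> EventSet:
    """Infer events for every copy of one region in one evolved clone."""
    if evolved.operon_ids != ancestor.operon_ids:
        raise ValueError("evolved family must carry the ancestral operon labels")
    if evolved.n_columns != ancestor.n_columns:
        raise ValueError("evolved family must share the ancestral alignment shape")
    out = EventSet()
    for op in ancestor.operon_ids:
        out.extend(
            infer_events_for_recipient(
                ancestor, evolved.row(op), op, lineage_id=lineage_id
            )
        )
    return out


def classify_spacer_allele(evolved_spacer: str, alleles: tuple[SpacerAllele, SpacerAllele]) -> str:
    """Match an ungapped spacer sequence to one of the two reference alleles."""
    a, b = alleles
    if a.sequence == b.sequence:
        raise ValueError("reference alleles must be distinct")
    seq = evolved_spacer.upper().replace("-", "")
    if seq == a.sequence.upper():
        return a.allele_id
    if seq == b.sequence.upper():
        return b.allele_id
    raise SpacerUnclassifiedError(
        f"spacer sequence (length {len(seq)}) matches neither allele "
        f"({a.allele_id}: {len(a.sequence)} bp, {b.allele_id}: {len(b.sequence)} bp)"
    )


# ---------------------------------------------------------------------------
# Round-trip application (used by tests and by the identity analysis)
# ---------------------------------------------------------------------------

def apply_event_min_extent(
    ancestor: OperonAlignment, row: np.ndarray, event: GeneConversionEvent
) -> np.ndarray:
    """Copy any donor candidate's ancestral states over the event's min extent."""
    donor = sorted(event.donor_candidates)[0]
    d = ancestor.row_index(donor)
    lo, hi = event.min_extent
    out = row.copy()
    out[lo - 1: hi] = ancestor.data[d, lo - 1: hi]
    return out


# ---------------------------------------------------------------------------
# TSV encoding of events
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "lineage", "region", "recipient", "changed_positions", "donors",
    "min_start", "min_end", "max_start", "max_end",
]


def events_to_frame(events: Iterable[GeneConversionEvent]) -> pd.DataFrame:
    rows = [
        {
            "lineage": e.lineage_id,
            "region": e.region_id,
            "recipient": e.recipient,
            "changed_positions": ",".join(map(str, e.changed_positions)),
            "donors": ",".join(sorted(e.donor_candidates)),
            "min_start": e.min_extent[0],
            "min_end": e.min_extent[1],
            "max_start": e.max_extent[0],
            "max_end": e.max_extent[1],
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def events_from_frame(df: pd.DataFrame) -> list[GeneConversionEvent]:
    events = []
    for rec in df.to_dict("records"):
        events.append(
            GeneConversionEvent(
                lineage_id=str(rec["lineage"]),
                region_id=str(rec["region"]),
                recipient=str(rec["recipient"]),
                changed_positions=tuple(
                    int(p) for p in str(rec["changed_positions"]).split(",") if p
                ),
                donor_candidates=frozenset(str(rec["donors"]).split(",")),
                min_extent=(int(rec["min_start"]), int(rec["min_end"])),
                max_extent=(int(rec["max_start"]), int(rec["max_end"])),
            )
        )
    return events
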