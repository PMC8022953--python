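"""Simulation of gene conversions on an operon family.

Simulated conversions mimic the observed ones: each draws a template
event (with replacement) from the set of experimentally inferred
conversions in the region being analysed and picks a uniform size between
that event's minimum and maximum extents, with a 50 bp floor — the
minimum tract for efficient RecA-mediated homologous recombination in
*E. coli*.  Location, recipient and donor are uniform.  Conversions are
applied sequentially, donors contributing their *current* (possibly
previously converted) sequence, so later events can hide, revert or
propagate earlier ones — the physical process whose losses the rate
correction must account for.

:func:`count_min_events` then asks: given only the ancestral and final
sequences, how many conversions are needed at minimum to explain the
differences?  This observable count is almost always below the number of
events truly applied, because events between already-identical stretches
are silent and overlapping events mask each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _kernels
from .alignment import OperonAlignment
from .inference import (
    EventSet,
    GeneConversionEvent,
    NovelAlleleError,
    greedy_event_partition,
    min_events_oracle,
)

__all__ = [
    "SIZE_FLOOR",
    "SizeSampler",
    "SimulatedConversion",
    "LineageState",
    "CompressedFamily",
    "sample_conversion",
    "apply_conversions",
    "count_min_events",
    "count_min_events_oracle",
]

#: Minimum simulated conversion size (bp) in gene regions.
SIZE_FLOOR = 50


class SamplerConfigurationError(ValueError):
    """No usable size template (every template maximum is below the floor)."""


@dataclass(frozen=True)
class SimulatedConversion:
    """A concrete simulated event: ``recipient`` copies ``donor`` over a window."""

    region_id: str
    recipient: str
    donor: str
    start: int  # 1-based column
    size: int   # columns

    def __post_init__(self) -> None:
        if self.recipient == self.donor:
            raise ValueError("donor must differ from recipient")
        if self.start < 1 or self.size < 1:
            raise ValueError("start and size must be positive")

    @property
    def end(self) -> int:
        return self.start + self.size - 1


@dataclass(frozen=True)
class SizeSampler:
    """Size templates for one or more regions, taken from observed events.

    Each template is a ``(region_id, min_size, max_size)`` triple from one
    observed conversion.  Pooling templates across regions preserves the
    observed regional weighting of events: the chosen template's region
    fixes the simulated event's region.
    """

    region_ids: tuple[str, ...]
    min_sizes: tuple[int, ...]
    max_sizes: tuple[int, ...]
    floor: int = SIZE_FLOOR

    def __post_init__(self) -> None:
        if not self.region_ids:
            raise SamplerConfigurationError("sampler needs at least one template")
        if not (len(self.region_ids) == len(self.min_sizes) == len(self.max_sizes)):
            raise ValueError("template arrays must have equal length")
        for lo, hi in zip(self.min_sizes, self.max_sizes):
            if lo > hi:
                raise ValueError("template min_size must not exceed max_size")

    def __len__(self) -> int:
        return len(self.region_ids)

    @classmethod
    def from_pairs(
        cls, region_id: str, pairs: Sequence[tuple[int, int]], *, floor: int = SIZE_FLOOR
    ) -> "SizeSampler":
        return cls(
            tuple(region_id for _ in pairs),
            tuple(int(a) for a, _ in pairs),
            tuple(int(b) for _, b in pairs),
            floor=floor,
        )

    @classmethod
    def from_events(
        cls,
        events: Iterable[GeneConversionEvent],
        regions: Sequence[str] | None = None,
        *,
        floor: int = SIZE_FLOOR,
    ) -> "SizeSampler":
        """Pool (min_size, max_size) templates from observed events."""
        rids, lows, highs = [], [], []
        for e in events:
            if regions is not None and e.region_id not in regions:
                continue
            rids.append(e.region_id)
            lows.append(e.min_size)
            highs.append(e.max_size)
        return cls(tuple(rids), tuple(lows), tuple(highs), floor=floor)

    def restricted(self, regions: Sequence[str]) -> "SizeSampler":
        keep = [i for i, r in enumerate(self.region_ids) if r in regions]
        return SizeSampler(
            tuple(self.region_ids[i] for i in keep),
            tuple(self.min_sizes[i] for i in keep),
            tuple(self.max_sizes[i] for i in keep),
            floor=self.floor,
        )

    def draw_size(self, template_index: int, rng: np.random.Generator) -> int:
        """Uniform size between the template's extents, floored."""
        lo = max(self.min_sizes[template_index], self.floor)
        hi = max(self.max_sizes[template_index], lo)
        return int(rng.integers(lo, hi + 1))

    def validate_floor(self, region_id: str) -> None:
        """Gene-region templates must leave a usable range above the floor."""
        highs = [h for r, h in zip(self.region_ids, self.max_sizes) if r == region_id]
        if highs and all(h < self.floor for h in highs):
            raise SamplerConfigurationError(
                f"every size template for gene region {region_id!r} has a maximum "
                f"below the {self.floor} bp floor"
            )


def sample_conversion(
    sampler: SizeSampler, aln: OperonAlignment, rng: np.random.Generator
) -> SimulatedConversion:
    """Draw one simulated conversion for a single region.

    In gene regions the size is resampled from the observed templates; in
    the biallelic spacer every conversion spans the whole region.
    """
    templates = [i for i, r in enumerate(sampler.region_ids) if r == aln.region_id]
    if not templates:
        raise SamplerConfigurationError(f"no size templates for region {aln.region_id!r}")
    t = templates[int(rng.integers(len(templates)))]
    if aln.kind == "spacer":
        size, start = aln.n_columns, 1
    else:
        if aln.n_columns < sampler.floor:
            raise SamplerConfigurationError(
                f"region {aln.region_id!r} is shorter than the {sampler.floor} bp floor"
            )
        sampler.validate_floor(aln.region_id)
        size = min(sampler.draw_size(t, rng), aln.n_columns)
        start = int(rng.integers(1, aln.n_columns - size + 2))
    recip = int(rng.integers(aln.n_rows))
    donor = int(rng.integers(aln.n_rows - 1))
    if donor >= recip:
        donor += 1
    return SimulatedConversion(
        region_id=aln.region_id,
        recipient=aln.operon_ids[recip],
        donor=aln.operon_ids[donor],
        start=start,
        size=size,
    )


@dataclass
class LineageState:
    """Current full sequences of every copy of every region, plus an event log."""

    ancestors: dict[str, OperonAlignment]
    current: dict[str, np.ndarray]
    log: list[SimulatedConversion] = field(default_factory=list)

    @classmethod
    def from_ancestors(cls, ancestors: Sequence[OperonAlignment] | dict[str, OperonAlignment]) -> "LineageState":
        if not isinstance(ancestors, dict):
            ancestors = {a.region_id: a for a in ancestors}
        return cls(ancestors, {rid: a.data.copy() for rid, a in ancestors.items()})

    def alignment(self, region_id: str) -> OperonAlignment:
        """The current family of one region, as an alignment."""
        anc = self.ancestors[region_id]
        return OperonAlignment(region_id, anc.operon_ids, self.current[region_id].copy(), kind=anc.kind)


def apply_conversions(state: LineageState, convs: Iterable[SimulatedConversion]) -> LineageState:
    """Apply conversions in order; donors contribute their current sequence."""
    for cv in convs:
        anc = state.ancestors[cv.region_id]
        if cv.end > anc.n_columns:
            raise ValueError(
                f"conversion window [{cv.start},{cv.end}] exceeds region "
                f"{cv.region_id!r} of length {anc.n_columns}"
            )
        mat = state.current[cv.region_id]
        r = anc.row_index(cv.recipient)
        d = anc.row_index(cv.donor)
        mat[r, cv.start - 1: cv.end] = mat[d, cv.start - 1: cv.end]
        state.log.append(cv)
    return state


def _final_matrix(final_rows: OperonAlignment | np.ndarray) -> np.ndarray:
    return final_rows.data if isinstance(final_rows, OperonAlignment) else np.asarray(final_rows)


def count_min_events(
    ancestor: OperonAlignment, final_rows: OperonAlignment | np.ndarray, region_id: str | None = None
) -> int:
    """Smallest number of conversions that explain the final family.

    The same greedy partition as event inference, summed over recipients.
    Zero iff the final family equals the ancestor.  Raises
    :class:`~rrnconv.inference.NovelAlleleError` if a change matches no
    ancestral copy, which cannot arise from pure conversion simulation.
    """
    final = _final_matrix(final_rows)
    if final.shape != ancestor.data.shape:
        raise ValueError("ancestral and final families must have equal shape")
    anc = ancestor.data
    varies = (anc != anc[0]).any(axis=0) | (final != anc).any(axis=0)
    cand = np.flatnonzero(varies)
    anc_cols = anc[:, cand]
    total = 0
    for r in range(ancestor.n_rows):
        total += len(greedy_event_partition(anc_cols, final[r, cand], r))
    return total


def count_min_events_oracle(
    ancestor: OperonAlignment,
    final_rows: OperonAlignment | np.ndarray,
    region_id: str | None = None,
    *,
    max_changed: int = 8,
    max_copies: int = 4,
) -> int:
    """Exact minimum event count by exhaustive search (small instances only)."""
    final = _final_matrix(final_rows)
    anc = ancestor.data
    varies = (anc != anc[0]).any(axis=0) | (final != anc).any(axis=0)
    cand = np.flatnonzero(varies)
    anc_cols = anc[:, cand]
    total = 0
    for r in range(ancestor.n_rows):
        total += min_events_oracle(
            anc_cols, final[r, cand], r, max_changed=max_changed, max_copies=max_copies
        )
    return total


# ---------------------------------------------------------------------------
# Compressed representation for the Monte-Carlo machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompressedFamily:
    """Heterologous-column summary of a family, ready for the numba kernels.

    Gene regions keep one column per ancestral heterologous site.  The
    biallelic spacer is collapsed to a single column whose states are
    whole-region allele codes: spacer conversions swap complete alleles,
    so one allele column is an exact summary of the region.
    """

    operon_ids: tuple[str, ...]
    region_ids: tuple[str, ...]
    region_kinds: tuple[str, ...]
    region_lengths: np.ndarray        # (n_regions,) alignment columns
    het_positions: np.ndarray         # (M,) 1-based positions within their region
    col_region: np.ndarray            # (M,) region index per compressed column
    region_het_lo: np.ndarray         # (n_regions,) slice bounds into het arrays
    region_het_hi: np.ndarray
    anc: np.ndarray                   # (n_copies, M) ancestral states

    @property
    def n_copies(self) -> int:
        return self.anc.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region_index(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    @classmethod
    def from_alignments(cls, alignments: Sequence[OperonAlignment]) -> "CompressedFamily":
        first = alignments[0]
        for a in alignments[1:]:
            if a.operon_ids != first.operon_ids:
                raise ValueError("all regions must share the same operon labels")
        pos_parts, anc_parts, col_region = [], [], []
        lo, his, los = 0, [], []
        for ri, a in enumerate(alignments):
            if a.kind == "spacer":
                # collapse rows to allele codes on a single column
                codes: dict[bytes, int] = {}
                col = np.empty(a.n_rows, dtype=np.uint8)
                for i in range(a.n_rows):
                    key = a.data[i].tobytes()
                    col[i] = codes.setdefault(key, len(codes))
                pos = np.array([1], dtype=np.int64)
                anc_part = col[:, None]
            else:
                het = np.flatnonzero((a.data != a.data[0]).any(axis=0))
                pos = het.astype(np.int64) + 1
                anc_part = a.data[:, het]
            pos_parts.append(pos)
            anc_parts.append(anc_part)
            col_region.append(np.full(pos.shape[0], ri, dtype=np.int64))
            los.append(lo)
            lo += pos.shape[0]
            his.append(lo)
        return cls(
            operon_ids=first.operon_ids,
            region_ids=tuple(a.region_id for a in alignments),
            region_kinds=tuple(a.kind for a in alignments),
            region_lengths=np.array([a.n_columns for a in alignments], dtype=np.int64),
            het_positions=np.concatenate(pos_parts),
            col_region=np.concatenate(col_region),
            region_het_lo=np.array(los, dtype=np.int64),
            region_het_hi=np.array(his, dtype=np.int64),
            anc=np.ascontiguousarray(np.hstack(anc_parts)),
        )

    def template_arrays(self, sampler: SizeSampler) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sampler templates as kernel-ready arrays (region idx, min, max)."""
        reg = np.array([self.region_index(r) for r in sampler.region_ids], dtype=np.int64)
        return (
            reg,
            np.asarray(sampler.min_sizes, dtype=np.int64),
            np.asarray(sampler.max_sizes, dtype=np.int64),
        )

    def count_events(self, state: np.ndarray) -> np.ndarray:
        """Greedy minimal observable events per region for one lineage state."""
        out = np.zeros(self.n_regions, dtype=np.int64)
        status = _kernels.count_events_by_region(self.anc, state, self.col_region, out)
        if status < 0:
            raise NovelAlleleError("final state contains a change matching no copy")
        return out


def simulate_lineage_batch(
    family: CompressedFamily,
    sampler: SizeSampler,
    n_events: np.ndarray,
    seeds: np.ndarray,
    n_lineages: int,
) -> np.ndarray:
    """Kernel wrapper: observable event counts per (replicate, region).

    ``n_events`` and ``seeds`` are flat ``(n_replicates * n_lineages,)``
    arrays; lineage ``i`` reseeds its stream from ``seeds[i]`` so that the
    same seeds give common random numbers across candidate rates.
    """
    for rid, kind in zip(family.region_ids, family.region_kinds):
        if kind == "gene" and rid in sampler.region_ids:
            sampler.validate_floor(rid)
    tmpl_region, tmpl_min, tmpl_max = family.template_arrays(sampler)
    is_spacer = np.array(
        [1 if k == "spacer" else 0 for k in family.region_kinds], dtype=np.int64
    )
    counts = _kernels.simulate_batch(
        family.anc,
        family.col_region,
        family.het_positions,
        family.region_het_lo,
        family.region_het_hi,
        family.region_lengths,
        is_spacer,
        tmpl_region,
        tmpl_min,
        tmpl_max,
        np.asarray(n_events, dtype=np.int64),
        np.asarray(seeds, dtype=np.int64),
        n_lineages,
        sampler.floor,
    )
    if (counts[:, 0] == -1).any():
        raise NovelAlleleError("simulation produced an inexplicable state")
    return counts
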