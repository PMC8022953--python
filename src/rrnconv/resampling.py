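"""Conditional resampling null for per-operon and per-site event counts.

To ask whether particular operons or particular heterologous sites are
converted more or less often than chance would predict, simulated
conversions are drawn one at a time — random template size, location,
recipient, donor, random lineage — until the *observable* event count
across the lineage set equals the empirically observed count.  The
minimal-event reconstruction of each replicate's final sequences (the
observable events, not the raw draws) is then tallied per category, and
the 2.5/97.5% quantiles over replicates form the null envelope.

Empirical two-sided p-values are twice the smaller tail proportion,
ties included ("as or more extreme"), capped at 1, with a Bonferroni
adjustment over the categories of the kind under test (the copies for
the per-operon test, the ancestral heterologous columns for the
per-site test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import EventSet, GeneConversionEvent
from .rates import MAExperimentConfig
from .simulator import CompressedFamily, SizeSampler

__all__ = [
    "ResamplingSummary",
    "ResamplingConvergenceError",
    "conditional_resample",
    "conditional_resample_one",
    "reconstruct_events",
    "category_null_counts",
    "category_null_summary",
    "empirical_pvalues",
]


class ResamplingConvergenceError(RuntimeError):
    """The draw cap was reached before hitting the target observable count."""


@dataclass(frozen=True)
class ResamplingSummary:
    """Per-category observed counts against the conditional null."""

    category_kind: str  # "operon" | "site"
    table: pd.DataFrame  # category, observed, null_mean, q025, q975, p_raw, p_adjusted
    n_replicates: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] < alpha]


def _draw_conversion_compressed(
    family: CompressedFamily, sampler: SizeSampler, rng: np.random.Generator
) -> tuple[int, int, int, int, int]:
    """(region_idx, recipient, donor, het_lo, het_hi) of one random event."""
    t = int(rng.integers(len(sampler)))
    rg = family.region_index(sampler.region_ids[t])
    length = int(family.region_lengths[rg])
    if family.region_kinds[rg] == "spacer":
        start, size = 1, length
    else:
        size = min(sampler.draw_size(t, rng), length)
        start = int(rng.integers(1, length - size + 2))
    recip = int(rng.integers(family.n_copies))
    donor = int(rng.integers(family.n_copies - 1))
    if donor >= recip:
        donor += 1
    a, b = int(family.region_het_lo[rg]), int(family.region_het_hi[rg])
    clo = a + int(np.searchsorted(family.het_positions[a:b], start))
    chi = a + int(np.searchsorted(family.het_positions[a:b], start + size - 1, side="right"))
    return rg, recip, donor, clo, chi


def conditional_resample_one(
    target_observed: int,
    n_lineages: int,
    family: CompressedFamily,
    sampler: SizeSampler,
    rng: np.random.Generator,
    *,
    max_draws: int = 1_000_000,
) -> EventSet:
    """One replicate: draw events until the observable total hits the target."""
    if target_observed < 0:
        raise ValueError("target must be non-negative")
    states = np.broadcast_to(family.anc, (n_lineages,) + family.anc.shape).copy()
    counts = np.zeros(n_lineages, dtype=np.int64)
    total = 0
    draws = 0
    while total != target_observed:
        if draws >= max_draws:
            raise ResamplingConvergenceError(
                f"observable total stuck at {total} after "
                f"{draws} draws (target {target_observed})"
            )
        lin = int(rng.integers(n_lineages))
        _, recip, donor, clo, chi = _draw_conversion_compressed(family, sampler, rng)
        saved = states[lin, recip, clo:chi].copy()
        states[lin, recip, clo:chi] = states[lin, donor, clo:chi]
        new_count = family.count_events(states[lin]).sum()
        draws += 1
        if total - counts[lin] + new_count > target_observed:
            # a single draw can create two observable events and overshoot;
            # reject it so the walk conditions on hitting the target exactly
            states[lin, recip, clo:chi] = saved
            continue
        total += new_count - counts[lin]
        counts[lin] = new_count
    out = EventSet()
    for lin in range(n_lineages):
        out.extend(reconstruct_events(family, states[lin], f"L{lin + 1:02d}"))
    return out


def conditional_resample(
    target_observed: int,
    cfg: MAExperimentConfig,
    family: CompressedFamily,
    sampler: SizeSampler,
    rng: np.random.Generator | None = None,
    *,
    max_draws: int = 1_000_000,
) -> list[EventSet]:
    """``cfg.n_replicates`` conditionally resampled observable event sets."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    return [
        conditional_resample_one(
            target_observed, cfg.n_lineages, family, sampler, stream, max_draws=max_draws
        )
        for stream in rng.spawn(cfg.n_replicates)
    ]


def reconstruct_events(
    family: CompressedFamily, state: np.ndarray, lineage_id: str
) -> list[GeneConversionEvent]:
    """Minimal-event reconstruction of a compressed lineage state.

    Mirrors full-alignment inference on the heterologous columns;
    positions are reported in region coordinates.  Maximum extents are
    grown outward through the surviving donor candidates exactly as in
    :func:`rrnconv.inference.infer_event_extents` (only heterologous
    columns can block growth).
    """
    from .inference import greedy_event_partition  # shared core

    events: list[GeneConversionEvent] = []
    anc = family.anc
    for r in range(family.n_copies):
        for idx_list, mask in greedy_event_partition(
            anc, state[r], r, region_of=family.col_region
        ):
            rg = int(family.col_region[idx_list[0]])
            region_id = family.region_ids[rg]
            length = int(family.region_lengths[rg])
            donors = frozenset(
                family.operon_ids[d] for d in range(family.n_copies) if mask >> d & 1
            )
            if family.region_kinds[rg] == "spacer":
                positions = (1,)
                min_ext = max_ext = (1, length)
            else:
                positions = tuple(int(family.het_positions[i]) for i in idx_list)
                min_ext = (positions[0], positions[-1])
                a, b = int(family.region_het_lo[rg]), int(family.region_het_hi[rg])
                max_ext = (
                    _grow(family, state[r], mask, idx_list[0], -1, a, b, 1, length),
                    _grow(family, state[r], mask, idx_list[-1], +1, a, b, 1, length),
                )
            events.append(
                GeneConversionEvent(
                    lineage_id=lineage_id,
                    region_id=region_id,
                    recipient=family.operon_ids[r],
                    changed_positions=positions,
                    donor_candidates=donors,
                    min_extent=min_ext,
                    max_extent=max_ext,
                )
            )
    return events


def _grow(family, ev_row, mask, idx, step, a, b, region_start, region_end):
    """Edge of the max extent in one direction, in region coordinates."""
    anc = family.anc
    surviving = mask
    i = idx + step
    while a <= i < b:
        m = 0
        for d in range(family.n_copies):
            if surviving >> d & 1 and anc[d, i] == ev_row[i]:
                m |= 1 << d
        if m == 0:
            # blocked just past the previous heterologous column
            return int(family.het_positions[i]) - step
        surviving = m
        i += step
    return region_start if step < 0 else region_end


def category_null_counts(
    event_sets: Sequence[EventSet], category_kind: str, family: CompressedFamily
) -> tuple[list, np.ndarray]:
    """Per-replicate category counts under the conditional null.

    Operon categories count events by recipient.  Site categories are the
    ancestral heterologous columns of the gene regions; an event counts
    at a column iff the column is among its changed positions.
    """
    if category_kind == "operon":
        categories: list = list(family.operon_ids)
        index = {op: i for i, op in enumerate(categories)}
        key = lambda e: [index[e.recipient]]
    elif category_kind == "site":
        categories = [
            (family.region_ids[int(family.col_region[i])], int(family.het_positions[i]))
            for i in range(family.het_positions.shape[0])
            if family.region_kinds[int(family.col_region[i])] == "gene"
        ]
        index = {cat: i for i, cat in enumerate(categories)}
        key = lambda e: [
            index[(e.region_id, p)] for p in e.changed_positions if (e.region_id, p) in index
        ]
    else:
        raise ValueError(f"unknown category kind {category_kind!r}")
    counts = np.zeros((len(event_sets), len(categories)), dtype=np.int64)
    for rep, es in enumerate(event_sets):
        for e in es:
            for i in key(e):
                counts[rep, i] += 1
    return categories, counts


def category_null_summary(
    event_sets: Sequence[EventSet], category_kind: str, family: CompressedFamily
) -> tuple[list, np.ndarray, pd.DataFrame]:
    """Null mean and 2.5/97.5% quantiles per category (no p-values yet)."""
    if len(event_sets) < 2:
        raise ValueError("at least 2 replicates are required")
    categories, counts = category_null_counts(event_sets, category_kind, family)
    table = pd.DataFrame(
        {
            "category": [str(c) if category_kind == "operon" else f"{c[0]}:{c[1]}" for c in categories],
            "null_mean": counts.mean(axis=0),
            "q025": np.quantile(counts, 0.025, axis=0),
            "q975": np.quantile(counts, 0.975, axis=0),
        }
    )
    return categories, counts, table


def empirical_pvalues(
    observed_counts: np.ndarray | Sequence[int],
    null_counts: np.ndarray,
    n_categories: int | None = None,
    *,
    category_kind: str = "operon",
    categories: Sequence | None = None,
) -> ResamplingSummary:
    """Two-sided empirical p-values with Bonferroni adjustment.

    ``p_raw = min(1, 2 min[P(null >= obs), P(null <= obs)])`` with ties
    counted as extreme; ``p_adjusted = min(1, p_raw x n_categories)``.
    """
    null_counts = np.asarray(null_counts)
    if null_counts.ndim != 2 or null_counts.shape[0] == 0:
        raise ValueError("null_counts must be a non-empty (replicates x categories) matrix")
    observed = np.asarray(observed_counts)
    if observed.shape[0] != null_counts.shape[1]:
        raise ValueError("one observed count per category is required")
    n_cat = n_categories if n_categories is not None else null_counts.shape[1]
    upper = (null_counts >= observed[None, :]).mean(axis=0)
    lower = (null_counts <= observed[None, :]).mean(axis=0)
    p_raw = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    p_adj = np.minimum(1.0, p_raw * n_cat)
    labels = (
        [str(c) if not isinstance(c, tuple) else f"{c[0]}:{c[1]}" for c in categories]
        if categories is not None
        else [str(i) for i in range(null_counts.shape[1])]
    )
    table = pd.DataFrame(
        {
            "category": labels,
            "observed": observed,
            "null_mean": null_counts.mean(axis=0),
            "q025": np.quantile(null_counts, 0.025, axis=0),
            "q975": np.quantile(null_counts, 0.975, axis=0),
            "p_raw": p_raw,
            "p_adjusted": p_adj,
        }
    )
    return ResamplingSummary(category_kind, table, null_counts.shape[0])
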