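"""Synthetic operon families and simulated mutation-accumulation lineages.

The generator emulates the architecture of the *E. coli* rRNA operon
family: seven copies, two gene regions of 1542 and 2904 alignment columns
(16S- and 23S-sized) with ~99.6% mean pairwise identity, and a biallelic
intergenic spacer with 186 bp and 92 bp alleles split four/three among
the copies.  Heterologous columns are placed uniformly at a density
solved analytically from the target identity for the allele-partition
scheme (biallelic with a uniform minor-copy count, occasionally
triallelic), so the realized identity matches the target without
rejection sampling.

Mutation-accumulation lineages are then simulated under a known
per-genome conversion rate — event counts Poisson in the generation
span, events drawn from a size-template sampler and applied sequentially
— with the full ground-truth event log recorded, so that every pipeline
stage can be tested against known truth without any external data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import ALPHABET, OperonAlignment
from .inference import SpacerAllele
from .rates import MAExperimentConfig
from .simulator import (
    LineageState,
    SimulatedConversion,
    SizeSampler,
    apply_conversions,
)

__all__ = [
    "FamilySpec",
    "SyntheticFamily",
    "GroundTruth",
    "generate_operon_family",
    "simulate_ma_lineages",
    "default_size_sampler",
    "DEFAULT_OPERON_IDS",
]

#: The seven E. coli rRNA operons (there is no rrnF).
DEFAULT_OPERON_IDS = ("rrnA", "rrnB", "rrnC", "rrnD", "rrnE", "rrnG", "rrnH")

#: Largest synthetic maximum-extent template, matching the largest
#: contiguous stretch the observed conversions could have covered.
MAX_TEMPLATE_SPAN = 2137


@dataclass(frozen=True)
class FamilySpec:
    """Architecture of a synthetic multicopy family."""

    n_copies: int = 7
    gene_lengths: tuple[tuple[str, int], ...] = (("16S", 1542), ("23S", 2904))
    spacer_lengths: tuple[int, int] = (186, 92)
    target_identity: float = 99.6     # mean pairwise %, concatenated gene regions
    p_triallelic: float = 0.1
    spacer_split: tuple[int, int] = (4, 3)  # copies carrying (long, short)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 2:
            raise ValueError("a family needs at least 2 copies")
        if not (0 < self.target_identity <= 100):
            raise ValueError("target identity must be in (0, 100]")
        if any(length <= 0 for _, length in self.gene_lengths):
            raise ValueError("region lengths must be positive")
        if sum(self.spacer_split) != self.n_copies:
            raise ValueError("spacer allele split must cover every copy")


@dataclass(frozen=True)
class SyntheticFamily:
    """A generated ancestral family plus its spacer allele references."""

    spec: FamilySpec
    alignments: dict[str, OperonAlignment]
    spacer_alleles: tuple[SpacerAllele, SpacerAllele]
    operon_ids: tuple[str, ...]

    @property
    def gene_alignments(self) -> list[OperonAlignment]:
        return [a for a in self.alignments.values() if a.kind == "gene"]

    @property
    def all_alignments(self) -> list[OperonAlignment]:
        return list(self.alignments.values())


@dataclass
class GroundTruth:
    """Per-lineage applied-conversion logs of a simulated MA experiment."""

    logs: dict[str, list[SimulatedConversion]] = field(default_factory=dict)

    def true_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for lineage, log in self.logs.items():
            per_region: dict[str, int] = {}
            for cv in log:
                per_region[cv.region_id] = per_region.get(cv.region_id, 0) + 1
            out[lineage] = per_region
        return out

    def total_events(self) -> int:
        return sum(len(log) for log in self.logs.values())


def _expected_mismatch_per_column(n: int, p_triallelic: float) -> float:
    """Expected pairwise mismatch fraction of one heterologous column.

    Biallelic columns draw a minor-copy count k uniformly on
    1..floor(n/2) and contribute k(n-k)/C(n,2); triallelic columns use an
    iid-uniform allele assignment conditioned on all three alleles being
    present, whose expectation is enumerated over multinomial counts.
    """
    pairs = n * (n - 1) / 2
    kmax = n // 2
    bi = sum(k * (n - k) / pairs for k in range(1, kmax + 1)) / kmax
    if p_triallelic == 0:
        return bi
    num = 0.0
    den = 0.0
    for counts in itertools.product(range(1, n - 1), repeat=2):
        k0, k1 = counts
        k2 = n - k0 - k1
        if k2 < 1:
            continue
        w = math.factorial(n) / (
            math.factorial(k0) * math.factorial(k1) * math.factorial(k2)
        )
        same = sum(k * (k - 1) / 2 for k in (k0, k1, k2))
        num += w * (1 - same / pairs)
        den += w
    tri = num / den
    return (1 - p_triallelic) * bi + p_triallelic * tri


def _draw_partition(n: int, p_triallelic: float, rng: np.random.Generator) -> np.ndarray:
    """Allele index per copy for one heterologous column."""
    if n >= 3 and rng.random() < p_triallelic:
        while True:
            assign = rng.integers(0, 3, size=n)
            if len(np.unique(assign)) == 3:
                return assign
    k = int(rng.integers(1, n // 2 + 1))
    assign = np.zeros(n, dtype=np.int64)
    assign[rng.choice(n, size=k, replace=False)] = 1
    return assign


def generate_operon_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate an ancestral family matching the spec's architecture."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_copies
    operon_ids = (
        DEFAULT_OPERON_IDS if n == len(DEFAULT_OPERON_IDS) else tuple(f"copy{i + 1}" for i in range(n))
    )
    total_cols = sum(length for _, length in spec.gene_lengths)
    q = _expected_mismatch_per_column(n, spec.p_triallelic)
    frac = (100.0 - spec.target_identity) / 100.0
    m = int(round(frac * total_cols / q))
    if m > total_cols:
        raise ValueError(
            f"target identity {spec.target_identity}% needs {m} heterologous "
            f"columns but only {total_cols} columns exist"
        )
    het_concat = rng.choice(total_cols, size=m, replace=False) if m else np.array([], dtype=int)

    alignments: dict[str, OperonAlignment] = {}
    offset = 0
    for region_id, length in spec.gene_lengths:
        base = rng.integers(0, 4, size=length).astype(np.uint8)
        data = np.tile(base, (n, 1))
        cols = het_concat[(het_concat >= offset) & (het_concat < offset + length)] - offset
        for c in np.sort(cols):
            assign = _draw_partition(n, spec.p_triallelic, rng)
            # allele 0 keeps the base state; the rest get distinct other states
            states = {0: data[0, c]}
            others = [s for s in range(4) if s != data[0, c]]
            rng.shuffle(others)
            for a in range(1, int(assign.max()) + 1):
                states[a] = others[a - 1]
            data[:, c] = [states[int(a)] for a in assign]
        alignments[region_id] = OperonAlignment(region_id, operon_ids, data, kind="gene")
        offset += length

    long_len, short_len = spec.spacer_lengths
    bases = "ACGT"
    long_seq = "".join(bases[i] for i in rng.integers(0, 4, size=long_len))
    short_seq = "".join(bases[i] for i in rng.integers(0, 4, size=short_len))
    alleles = (SpacerAllele("long", long_seq), SpacerAllele("short", short_seq))
    width = max(long_len, short_len)
    long_row = long_seq + "-" * (width - long_len)
    short_row = short_seq + "-" * (width - short_len)
    carriers_long = set(rng.choice(n, size=spec.spacer_split[0], replace=False).tolist())
    rows = [
        (operon_ids[i], long_row if i in carriers_long else short_row) for i in range(n)
    ]
    alignments["spacer"] = OperonAlignment.from_sequences("spacer", rows, kind="spacer")
    return SyntheticFamily(spec, alignments, alleles, operon_ids)


def default_size_sampler(
    family: SyntheticFamily,
    seed: int = 0,
    template_counts: Mapping[str, int] | None = None,
) -> SizeSampler:
    """Synthetic size templates mimicking the observed spread of extents.

    Most observed conversions changed a single base (point-like minimum
    extents) but could have been far larger; templates therefore pair a
    small minimum with a wide maximum, capped at the largest contiguous
    span the observed events could have covered (2137 columns) and at the
    region length.  The default number of templates per region follows
    the observed regional event weighting (7 : 27 : 4).
    """
    rng = np.random.default_rng(seed)
    counts = dict(template_counts or {"16S": 7, "23S": 27, "spacer": 4})
    rids, lows, highs = [], [], []
    for region_id, k in counts.items():
        aln = family.alignments[region_id]
        for _ in range(k):
            if aln.kind == "spacer":
                lo = hi = aln.n_columns
            else:
                lo = 1 if rng.random() < 0.6 else int(rng.integers(2, 301))
                cap = min(MAX_TEMPLATE_SPAN, aln.n_columns)
                hi = int(rng.integers(max(lo, 200), cap + 1))
            rids.append(region_id)
            lows.append(lo)
            highs.append(hi)
    return SizeSampler(tuple(rids), tuple(lows), tuple(highs))


def simulate_ma_lineages(
    family: SyntheticFamily | Sequence[OperonAlignment],
    true_rate: float,
    cfg: MAExperimentConfig,
    sampler: SizeSampler,
    seed: int | None = None,
) -> tuple[dict[str, dict[str, OperonAlignment]], GroundTruth]:
    """Simulate MA lineages at a known rate, with ground-truth event logs.

    Each lineage draws its event count from Poisson(rate x generations)
    and applies the events sequentially; replaying a returned log from
    the ancestor reproduces the evolved family exactly.
    """
    if true_rate < 0:
        raise ValueError("rate must be non-negative")
    alignments = (
        family.all_alignments if isinstance(family, SyntheticFamily) else list(family)
    )
    by_region = {a.region_id: a for a in alignments}
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    evolved: dict[str, dict[str, OperonAlignment]] = {}
    truth = GroundTruth()
    for lineage in range(cfg.n_lineages):
        lineage_id = f"L{lineage + 1:02d}"
        stream = rng.spawn(1)[0]
        n_events = int(stream.poisson(true_rate * cfg.generations))
        state = LineageState.from_ancestors(by_region)
        convs = [_draw_conversion_full(sampler, by_region, stream) for _ in range(n_events)]
        apply_conversions(state, convs)
        evolved[lineage_id] = {rid: state.alignment(rid) for rid in by_region}
        truth.logs[lineage_id] = list(state.log)
    return evolved, truth


def _draw_conversion_full(
    sampler: SizeSampler,
    by_region: Mapping[str, OperonAlignment],
    rng: np.random.Generator,
) -> SimulatedConversion:
    t = int(rng.integers(len(sampler)))
    aln = by_region[sampler.region_ids[t]]
    if aln.kind == "spacer":
        size, start = aln.n_columns, 1
    else:
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
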