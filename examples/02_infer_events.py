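"""Simulate one mutation-accumulation experiment and re-infer its events.

Lineages accumulate gene conversions at a known per-genome rate; the
inference step then reconstructs, per evolved copy, the most
parsimonious event set with donor candidates and minimum/maximum
extents.  The observable count is below the true count because
conversions between already-identical stretches are silent and later
events can hide earlier ones — the gap the rate estimator corrects for.
"""

from rrnconv import (
    FamilySpec,
    MAExperimentConfig,
    default_size_sampler,
    generate_operon_family,
    infer_events_for_family,
    simulate_ma_lineages,
)
from rrnconv.inference import EventSet, events_to_frame

family = generate_operon_family(FamilySpec(seed=1))
sampler = default_size_sampler(family, seed=1)
cfg = MAExperimentConfig(n_lineages=15, n_replicates=1, seed=4)
evolved, truth = simulate_ma_lineages(family, 3.6e-4, cfg, sampler, seed=4)

events = EventSet()
for lineage_id, fam in evolved.items():
    for region_id, aln in fam.items():
        events.extend(
            infer_events_for_family(family.alignments[region_id], aln, lineage_id=lineage_id).events
        )

print(f"true events applied: {truth.total_events()}")
print(f"observable (inferred) events: {len(events)}  {events.counts_by_region()}")
print(events_to_frame(events.events).head(8).to_string(index=False))
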