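"""Published tallies from the *E. coli* B mutation-accumulation study.

Fifteen lineages of *E. coli* B (derived from REL606 via the REL1206
clone) were propagated for about 13,750 generations of daily
single-colony bottlenecks; Sanger sequencing of all seven rRNA operons
in the endpoint clones revealed 38 gene conversions and no de novo point
mutations.  These printed tallies are the real-data inputs the rate and
resampling analyses consume; the full per-event table (positions and
extents of each conversion) is part of the study's supplementary
material and is not redistributed here.

Note: the study's running text reports both "11" and "10" conversions
for the rrnC operon in different places; the explicit per-operon tally
(which sums to the stated 34 subunit events) is used here and the
discrepancy is documented in the methods note.
"""

from __future__ import annotations

__all__ = [
    "OPERON_IDS",
    "N_LINEAGES",
    "GENERATIONS",
    "REGION_OBSERVED_COUNTS",
    "SUBUNIT_OPERON_OBSERVED_COUNTS",
    "TOTAL_OBSERVED_EVENTS",
]

#: The seven rRNA operons of E. coli B (no rrnF exists).
OPERON_IDS = ("rrnA", "rrnB", "rrnC", "rrnD", "rrnE", "rrnG", "rrnH")

#: Mutation-accumulation design.
N_LINEAGES = 15
GENERATIONS = 13750

#: Observed conversions per region: 7 in 16S, 27 in 23S, 4 whole-spacer swaps.
REGION_OBSERVED_COUNTS = {"16S": 7, "23S": 27, "spacer": 4}

#: Observed subunit (16S+23S) conversions per recipient operon; sums to 34.
SUBUNIT_OPERON_OBSERVED_COUNTS = {
    "rrnA": 4,
    "rrnB": 9,
    "rrnC": 11,
    "rrnD": 4,
    "rrnE": 3,
    "rrnG": 0,
    "rrnH": 3,
}

TOTAL_OBSERVED_EVENTS = sum(REGION_OBSERVED_COUNTS.values())
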