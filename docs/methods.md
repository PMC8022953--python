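# Methods

## Problem and model

A seven-copy rRNA operon family evolves under allelic gene conversion:
an event copies a window of sequence from a *donor* operon into a
*recipient* operon, non-reciprocally. In a mutation-accumulation (MA)
experiment of `L` lineages and `t` generations, the number of
conversions per lineage is modelled as Poisson(`r·t`) with `r` the
per-genome per-generation conversion rate (defaults `L = 15`,
`t = 13,750`). Conversions are only *observable* where the family is
heterologous: an event between identical stretches is silent, and later
events can hide or revert earlier ones. All analyses work in 1-based,
inclusive alignment-column coordinates; gaps are a fifth character
state, so small indels between copies are handled by the same machinery
as substitutions. The 23S–5S intergenic spacer is a special region: two
divergent alleles (186 bp and 92 bp here) with almost no homology
between them, treated as swapping in whole units.

## Event inference

For one evolved copy, the changed columns (vs. the ancestral copy) must
each match at least one other ancestral copy — a change matching none
cannot arise by conversion and raises a novel-allele error. The most
parsimonious reconstruction is the minimum-cardinality partition of the
changed columns into contiguous groups such that each group has a donor
whose ancestral states equal the evolved recipient's at *every* column
the group spans (including unchanged columns between changed ones). A
greedy left-to-right sweep that extends the current event while its
donor set stays non-empty is provably optimal here, because the donor
set of a window only shrinks as the window grows; the test-suite still
verifies it against an exhaustive dynamic-programming oracle on ~700
random small instances.

Each event reports:

- `min_extent` — first to last changed column;
- `max_extent` — the changed run grown outward one column at a time; a
  donor candidate survives while it matches the evolved recipient at
  every traversed column, and growth stops when no donor survives or at
  the region boundary. With multiple donors this is a surviving-set
  scan per direction; it upper-bounds the extent achievable by any
  single donor, and the two readings coincide when donors agree over
  the flanks (the typical case at 99.6% identity);
- a maximal donor candidate set (adding any other copy breaks
  compatibility at some spanned column).

Spacer events always span the whole region, with donors the copies
carrying the matching allele.

## Simulation and observable-event counting

Simulated conversions mimic the observed ones: a template event is
drawn with replacement from the observed set of the region under
analysis, the size is uniform between that template's minimum and
maximum extents, with a 50 bp floor (the approximate minimum tract for
efficient RecA-mediated recombination in *E. coli*; a template whose
maximum lies below the floor yields exactly 50 bp). Location is uniform
inside the region, the recipient is uniform over the copies and the
donor uniform over the rest. Events apply sequentially and donors
contribute their *current* sequence, so conversion chains propagate
earlier events — required for the hidden/reverted-event correction.
Pooling templates across regions preserves the observed regional
weighting of events; the chosen template fixes the simulated event's
region.

Counting uses the same greedy parsimony as inference, summed over
recipients and regions. Because conversion can only move existing
per-column alleles between copies, simulation and counting run on the
compressed matrix of ancestral heterologous columns (an exact change of
representation), with the spacer collapsed to a single allele-code
column; the hot loops are numba kernels cross-checked against the pure
Python reference. In rare configurations a single extra conversion can
*split* an earlier event's changed run and raise the minimal count by
two; consequently "observable ≤ true count" holds in all but
pathological nestings (it held in every seeded test run).

## Rate estimation

The likelihood of the observed total `k` at candidate rate `r` is the
Monte-Carlo probability P̂(total = k) over `n` replicate simulated
experiments (default `n = 10,000`; reduced-replicate mode is
first-class for desk-scale work). The ML rate maximises P̂ over
{0} ∪ a 60-point log-spaced grid spanning `k/(L·t)` ÷30 to ×30, with
one local refinement around the argmax; grid ties break to the smallest
rate. The 95% CI is

- lower: the largest rate with P(total ≥ k) ≤ 2.5%,
- upper: the smallest rate with P(total ≤ k) ≤ 2.5%,

each located by bisection. Common random numbers couple all candidate
rates: one fixed uniform per (replicate, lineage) drives the Poisson
count through its quantile function, and one fixed per-lineage seed
drives the event stream, so raising the rate only appends events. This
makes the simulated totals monotone in the rate by construction and the
tail probabilities clean step functions for the bisection.

The regional rate test compares two free per-region rates against a
single shared per-genome rate applied to both regions (each region
simulated with its own templates). The statistic `2(lnL1 − lnL0)` is
referred to χ²(1); with Monte-Carlo likelihoods this reference is
approximate, and a likelihood estimated as zero is floored at
`1/(n+1)` with the p-value flagged as a bound. Type-I error at the 5%
level is verified by simulation in the acceptance suite.

## Conditional resampling null

To test per-operon and per-site variation, conversions are drawn one at
a time (uniform lineage, then a simulated conversion as above) until
the observable total across the lineage set equals the empirically
observed count; the minimal-event reconstruction of the final sequences
— the observable events, not the raw draws — is tallied. Because one
draw can occasionally raise the minimal count by two, a draw that would
overshoot the target is rejected and drawing continues, conditioning
the walk on hitting the target exactly; a draw cap (default 10⁶)
guards non-convergence. Operon categories count events by recipient;
site categories are individual ancestral heterologous columns of the
gene regions, and an event counts at a column only if the column is
among its *changed* positions (covering a column without changing it
does not count — an interpretation choice). Empirical p-values are
twice the smaller tail proportion including ties, capped at 1, with a
Bonferroni factor equal to the number of categories of the kind under
test (7 for operons, the heterologous-column count for sites).

## Identity tracking

Percent identity of a copy pair is the fraction of columns with the
identical character over the *full* alignment length — aligned gap
pairs match, gap-vs-base mismatches. This makes identity over
concatenated regions the column-length-weighted mean of per-region
identities. Per lineage, the delta is the evolved minus ancestral mean
pairwise identity of the concatenated gene regions. The trend across
lineages is a two-sided Wilcoxon signed-rank test; zero deltas are
dropped (their count is reported), the exact null distribution is used
up to n = 25 and the normal approximation above, and an all-zero input
returns p = 1 with a degenerate flag.

## Synthetic data

The generator emulates the *E. coli* family architecture: 7 copies
named rrnA–rrnE, rrnG, rrnH; gene regions of 1542 and 2904 columns;
target mean pairwise identity 99.6%; a biallelic spacer of 186 and
92 bp random, mutually divergent alleles split 4/3 among the copies.
Heterologous columns are placed uniformly at a density solved
analytically: a biallelic column draws its minor-copy count uniformly
on 1..3 (expected pairwise mismatch 28/63), 10% of columns are
triallelic (iid-uniform assignment conditioned on all three alleles
present), and the column count is `(1 − identity/100)·columns / q`
with `q` the scheme's expected mismatch. Realized identity lands
within ±0.1 percentage points of target across seeds without rejection
sampling. Default synthetic size templates pair small minimum extents
(60% singletons) with wide maxima capped at 2137 columns — the largest
contiguous stretch the observed conversions could have covered — with
per-region template counts following the observed 7 : 27 : 4 weighting.

What the synthetic family does not emulate: the real operons' specific
allele geography (clustered heterologous sites, recombination-hotspot
motifs such as the Chi-like site, unequal donor availability along the
chromosome) and any point-mutation process (none was observed in the
experiment, and none is simulated). Passing tests on synthetic data
therefore validate the machinery and its statistical calibration, not
the real family's particular rate values.

## Problem sizes and numerical choices

The packaged analyses and tests run at reduced Monte-Carlo sizes chosen
as a desk-scale default: 1,000–2,000 likelihood replicates per
candidate rate (10,000 remains the production default in
`MAExperimentConfig`), 1,000 conditional-resampling replicates in the
acceptance script, 50 repetitions for parameter-recovery checks and 120
for LRT calibration. CI bisection stops at 1% relative width; the
per-event size floor, grid span and refinement counts are set in
`GridPolicy`/`SizeSampler` and documented above. All randomness flows
from one master seed through spawned numpy generators; per-lineage
kernel streams reseed numba's RNG from derived 31-bit seeds.

## Known limitations

- Real-data reproduction requires the original seven-operon alignments
  and the per-event observed table; the package validates and consumes
  such inputs (aligned FASTA + region map + events TSV) but does not
  redistribute them, so shipped analyses run on the synthetic stand-in
  and on the published count tallies. The published running text gives
  both 11 and 10 as the rrnC event count; the explicit per-operon tally
  (11, summing to 34) is used and the inconsistency is noted rather
  than resolved.
- The χ²(1) reference for the simulated LRT and the surviving-set
  maximum extent are approximations, as discussed above.
- No probabilistic donor assignment, no event ordering/timing within a
  lineage, no crossover/reciprocal exchange, and no FDR alternatives to
  Bonferroni.
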