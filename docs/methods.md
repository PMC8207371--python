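# Methods

## Problem and data model

Colonial bats are usually studied through roost co-occupancy: two
animals detected at the same roost on the same day are assumed to
associate ("gambit of the group"). Antennas placed *inside* roosts
allow a sharper question — do cohabiting animals actually roost
together? `roostnet` operationalizes both association definitions from
one detection stream and tests their agreement.

A detection is a `(timestamp, tag_id, antenna_id)` triple. Antennas
have a role: `entry` antennas span roost entrances and record
passages; `ceiling` antennas cover patches of attic ceiling and record
roosting presence. The two roles never mix: a doorway co-passage is
not co-roosting, and a ceiling scan is not evidence of entry on a
particular antenna's side. Timestamps are naive site-local wall clock.

**Roost-day.** Days are calendar dates by default. Because nocturnal
activity can span midnight, an event's *roost-day* is the date after
subtracting a configurable `day_rollover_hour` (default 0). All
shipped analyses use the default; the parameter exists because no
universal convention fixes where a bat's "day" begins.

## Association matrices

- *Cohabitation*: `w_ij` = number of `(roost-day, roost)` cells in
  which both tags have ≥ 1 entry-antenna scan. Units: days.
- *Intraroost*: `w_ij` = number of distinct
  `(roost-day, ceiling antenna, 5-min bin)` cells containing both
  tags. Bins are fixed clock-aligned 300-second windows anchored at
  roost-day midnight (index 0–287) — a partition, not a sliding
  window. Units: 5-minute bins. A tag read at two antennas within one
  bin counts in both cells; the movement between reads is real.

Each matrix's node list is every tag with at least one contributing
detection *for that matrix's data source*. The sets legitimately
differ (a bat only ever read in the doorway has no intraroost node),
which mirrors the differing node counts seen in field reports. Both
matrices are symmetric, integer, zero-diagonal by construction, and
invariant to event order and duplicate scans.

Dichotomization uses threshold 1 by default — any nonzero association
is a tie — because the downstream statistics are defined on binary
networks. Raw counts are kept; association indices that correct for
sampling effort (simple ratio, half-weight) are a deliberate
non-feature, as the analysis is built on raw day/bin counts.

## Network statistics

On a binary matrix with `n` nodes and `T` ties: density `2T/n(n−1)`;
degree centrality `d_i` = row sum, reported as the mean over all nodes
*including isolates*; Freeman centralization
`Σ_i (d_max − d_i)/((n−1)(n−2))`; diameter = the maximum *finite*
geodesic distance. Field networks contain isolates and disconnected
fragments, so infinite distances are excluded — the only convention
under which diameters of such networks are computable numbers.
Degenerate inputs raise: density needs `n ≥ 2`, centralization
`n ≥ 3`, diameter at least one tie; the pipeline catches these,
reports NaN and logs the condition rather than aborting a run.
Shortest paths use `scipy.sparse.csgraph`; the test suite checks
equivalence against a hand-written Floyd–Warshall oracle and networkx
over exhaustively enumerated 4- and 5-node graphs and sampled 6/7-node
graphs.

The summary table reports density and centralization to 2 decimals and
mean degree to 1, with a full-precision companion CSV; the identity
`mean degree = density × (n−1)` holds exactly in the full-precision
output.

## QAP

Dyadic observations sharing a node are not independent, so the
similarity of two networks cannot be tested dyad-by-dyad. The
quadratic assignment procedure permutes *node labels*: each iteration
draws one uniform relabeling and applies it to one matrix's rows and
columns simultaneously, preserving that matrix's entire topology while
breaking the correspondence between the two. Similarity is measured
over the `n(n−1)/2` unordered dyads as (i) Pearson/phi correlation,
(ii) simple-matching percentage, and (iii) Jaccard percentage; all
three are reported because "percent similarity" is ambiguous across
software traditions. For binary matrices with fixed tie totals all
three are monotone in the both-tied count, so they share one
permutation p-value.

Numerical choices: the Monte-Carlo p-value uses the add-one estimator
`(1 + #{perm ≥ obs})/(1 + P)`, which is a valid p-value and never
zero; ties with the observed statistic count toward rejection
(conservative); comparisons use a 1e-9 tolerance so float jitter
cannot flip a tie; the two-sided p doubles the smaller tail, capped at
1. Exhaustive mode (n ≤ 8) enumerates all `n!` relabelings and reports
exact proportions. A zero-variance dyad vector (e.g., a complete
network) leaves the phi statistic undefined; the result flags this
with NaN/absent p-values instead of guessing, and the matching
statistic remains available. One integer seed drives the whole test.

Matrices are aligned over the union of node sets by default — a bat
undetected by one data source simply has no ties there; intersection
alignment is available for sensitivity analysis. Only bivariate QAP
correlation is implemented; multivariate QAP regression is out of
scope.

## Colony simulator

The generator emulates the data-collection design the package targets:
a 10 June–15 August maternity season, 2 roost buildings, 300 bats of
which 22% (~66) are tagged, 8 zones per roost of which 6 host ceiling
antennas (partial spatial coverage), 3 subgroups, daily roost
switching with probability 0.15, zone cohesion 0.8, entry detection
0.95 per passage, and a 10-hour contiguous daytime residency block
from 06:00 (bats roost by day; one block is the simplest model
consistent with 5-minute binning).

Two mechanisms make the output realistically imperfect:

- **Site fidelity.** Each bat draws a daily attendance probability
  from Beta(μc, (1−μ)c) with mean μ = 0.6 and concentration c = 1.5;
  off-site days are spent at unmonitored natural roosts and emit
  nothing. Without this heterogeneity every tagged dyad shares
  roost-days over a 67-day season and the cohabitation network is
  complete — a density of exactly 1 leaves the QAP phi statistic
  undefined and matches no field dataset. The U-shaped Beta captures
  animals tagged in earlier seasons that rarely return. μ = 1 switches
  the mechanism off.
- **Ceiling misses.** Per occupied 5-min bin at a covered zone, a scan
  is emitted with probability 0.05, i.i.d. Bernoulli. The true field
  rate is unknown (tag-to-antenna orientation sharply reduces read
  range), so the value is an exposed parameter, not a claim. Tag
  collision is not simulated; the targeted readers are anti-collision.

Subgroup home zones are distinct whenever `n_subgroups ≤
zones_per_roost` (subgroups occupy different attic areas); the same
zone indices anchor a subgroup in every roost. Untagged bats exist in
ground truth but emit no detections. Identical (config, seed) yields
byte-identical logs.

**What the simulator does not emulate:** births/deaths/dispersal
within a season, energetics or weather-driven roost choice, movement
between distant sites, read-range physics, or reader downtime. Passing
recovery tests therefore show the *pipeline* is sound — planted
structure in, measured structure out — not that any particular field
colony behaves like the generator.

## Validation design

- Metric oracle equivalence: exhaustive enumeration of all graphs on
  4–5 nodes and uniform samples of 6–7-node edge sets against a
  brute-force Floyd–Warshall/direct-summation oracle and networkx;
  closed forms (star, complete, edgeless); the degree identity on
  1,000 random graphs.
- QAP: exact-vs-Monte-Carlo agreement on ≤ 7-node fixtures; p =
  1/(P+1) on identical rigid inputs; type-I error within 3 binomial
  standard errors of the nominal 5% over 1,000 independent-graph
  replicates (n = 40, tie probability 0.3, 199 permutations each).
- Recovery: with zone cohesion 0.9 and full ceiling coverage, the
  intraroost network is assortative by planted subgroup in 20/20
  seeds, and QAP against the planted co-subgroup matrix gives
  p < 0.01 in ≥ 19/20.
- Structural pattern: under the default partial-coverage conditions,
  cohabitation density exceeds intraroost density and intraroost
  diameter exceeds cohabitation diameter in ≥ 18/20 seeds.

Problem sizes (default 300-bat colony, 67-day season, 20-seed
replicate batteries, 199–10,000 permutations) were chosen so the whole
battery runs on a laptop in a couple of minutes while leaving the
binomial checks adequately powered.

## Known limitations

- Cohabitation under the default simulator is denser (≈ 0.98) than
  typical field values; modeling within-season tag loss or permanent
  emigration would lower it but add parameters the analysis does not
  need.
- The intraroost measure is conditional on antenna placement: a dyad
  roosting together in an uncovered zone is invisible, which the
  simulator reproduces by design (partial coverage) — a measurement
  property, not a bug.
- QAP tests association between matrices, not causation; a shared
  driver (e.g., roost preference) can produce correlated networks
  without social preference.
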