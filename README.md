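# roostnet

Social-network analysis of PIT-tagged bats at their roosts. `roostnet`
converts timestamped RFID detection logs from antennas inside roost
buildings into two dyadic association networks, compares them with a
quadratic assignment procedure (QAP) permutation test, and summarizes
each with standard whole-network statistics. It is aimed at behavioral
ecologists who monitor colonies with entryway and ceiling antennas and
want to know whether animals that *cohabit* a roost actually *roost
together* inside it.

## The two networks

From a detection log (`timestamp,tag_id,antenna_id`) and an antenna
registry (`antenna_id,roost_id,role` with role `entry` or `ceiling`),
the package builds, per calendar year inside a study window:

- **Cohabitation network** — for bats *i*, *j*, the weight
  `w_ij` = number of days both were detected at an entryway antenna of
  the same roost on the same day (frequency of cohabitation, in days).
- **Intraroost network** — `w_ij` = number of distinct 5-minute bins in
  which both were scanned at the *same ceiling antenna* on the same day
  (time roosting together, in 5-min units). Raw 4 Hz scans are
  collapsed into clock-aligned 300-s bins first.

Any bat detected at least once by a network's data source is a node of
that network, so the two node sets may differ; alignment (union or
intersection) puts them over one ordered node list for comparison.

On the dichotomized networks (any association = tie) four statistics
are reported: density `2T / n(n-1)`, the longest finite geodesic
(diameter), Freeman degree centralization
`Σ_i (d_max − d_i) / ((n−1)(n−2))`, and mean degree centrality
(isolates included).

The **QAP test** measures dyadic similarity between the two binary
matrices — Pearson/phi correlation plus simple-matching and Jaccard
percentages — and obtains its null distribution by jointly permuting
one matrix's rows and columns by random node relabelings (10,000 by
default; exact enumeration available for ≤ 8 nodes). The add-one
estimator `p = (1 + #{perm ≥ obs}) / (1 + P)` is never zero.

A fission–fusion **colony simulator** with planted subgroup structure
(Markov daily roost choice, subgroup home zones, heterogeneous site
fidelity, imperfect entry and per-bin ceiling detection) generates
detection logs plus the ground truth needed to validate the whole
pipeline without field data.

## Worked example

```bash
python examples/03_network_metrics.py
python examples/04_qap_test.py
```

prints, for the default simulated season (seed 1):

```
network        nodes  density  diam  centralization  avg degree
cohabitation      66     0.98     2            0.02        64.0
intraroost        65     0.24     4            0.22        15.1

aligned nodes: 66
dyadic Pearson (phi): 0.068
simple matching:      24.4% of dyads agree
Jaccard:              23.2% of tied dyads shared
p (>= observed, 10000 permutations): 0.0014
```

Read: almost every tagged dyad shared the building on some day
(density 0.98, diameter 2), but only a quarter of dyads were ever
detected roosting at the same antenna (density 0.24, diameter 4,
far lower mean degree). The two networks are nevertheless correlated
beyond chance (p ≈ 0.001): bats tied inside the roost are also tied by
cohabitation, while the converse mostly fails. Cohabitation alone
overstates how connected a colony is — which is exactly the inference
hazard this package exists to quantify.

The same analysis runs end to end from the shell:

```bash
roostnet run --seed 1 --out runs/demo           # simulated colony
roostnet run --detections log.csv --antennas antennas.csv \
    --start 2017-06-10 --end 2017-08-15 --out runs/field
```

writing per year: both weighted matrices (square CSV + edge list),
dichotomized matrices, the summary table, the QAP result JSON, and
aligned heat-map CSVs sharing one node order with the diagonal masked.

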