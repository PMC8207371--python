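"""Build the two association matrices from a simulated detection log.

The cohabitation matrix counts the days each dyad used the same roost
(entryway antennas only); the intraroost matrix counts the 5-minute
bins each dyad shared at the same ceiling antenna.
"""

from roostnet import (
    ColonyConfig,
    bin_detections,
    build_cohabitation,
    build_intraroost,
    daily_presence,
    simulate_colony,
)
from roostnet.simulate import antenna_registry_for

config = ColonyConfig(seed=1)
events, _ = simulate_colony(config)
registry = antenna_registry_for(config)
window = config.season

presence = daily_presence(events, registry, window)
bins = bin_detections(events, registry, window)
coh = build_cohabitation(presence)
intra = build_intraroost(bins)

print(f"presence triples (tag, day, roost): {len(presence)}")
print(f"occupancy triples (tag, day, antenna, bin): {len(bins)}")
print(f"cohabitation network: {coh.n_nodes} bats, "
      f"max weight {coh.weights.max()} shared days")
print(f"intraroost network:   {intra.n_nodes} bats, "
      f"max weight {intra.weights.max()} shared 5-min bins "
      f"(= {intra.weights.max() * 5} min)")
# The node lists can differ: a bat read only while passing the doorway
# appears in the cohabitation network but not the intraroost one.
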