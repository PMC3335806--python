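"""Differential calls, SOM clustering and cofactor regulation deltas.

Calls regulated transcripts (p < 0.01 and fold change >= 1.5 at any of
2/6/24 h), clusters their time-course profiles with a self-organizing
map, and partitions two regulated sets into lost/gained/conserved.
"""

import numpy as np

from cistromekit.expression import (
    call_regulated,
    regulated_directions,
    regulation_delta,
    som_cluster,
    transcriptome_overlap,
)
from cistromekit.simulate import SimConfig, simulate_study

data = simulate_study(SimConfig(seed=1))

regulated = {}
for line in ("cellA", "cellB"):
    calls = call_regulated(data.expression[line])
    regulated[line] = regulated_directions(calls)
    ups = sum(1 for d in regulated[line].values() if d == "up")
    print(f"{line}: {len(regulated[line])} regulated transcripts "
          f"({ups} up, {len(regulated[line]) - ups} down)")

overlap = transcriptome_overlap(set(regulated["cellA"]), set(regulated["cellB"]))
print(f"transcriptome overlap: {overlap['common']} common transcripts = "
      f"{overlap['pct_of_union']}% of the union")

# SOM over the regulated time-course profiles of cellA
table = data.expression["cellA"]
profiles = {
    t: list(table[table.transcript_id == t].sort_values("timepoint").log2_fc)
    for t in regulated["cellA"]
}
som = som_cluster(profiles, grid=(3, 3), seed=1)
sizes = np.bincount(list(som.labels.values()), minlength=9)
print(f"SOM cluster sizes (3x3 grid): {sizes.tolist()}")

delta = regulation_delta(set(regulated["cellA"]), set(regulated["cellB"]))
print(f"treating cellB as the altered condition: lost {len(delta.lost)}, "
      f"gained {len(delta.gained)}, conserved {len(delta.conserved)}")
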