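"""Ward clustering of per-station community composition.

Simulates trawl catches at eight stations spanning two habitat types with
different dominant taxa (a sand-dollar-dominated bed vs a hermit-crab /
sand-lance assemblage), plus one station whose tow hits a dense monospecific
"jackpot".  The station x taxon matrix is standardized (column z-scores),
clustered with Ward's minimum variance method, and cut into two groups.
"""

import pandas as pd

from towcam.community import cut_tree, standardize, to_newick, ward_cluster
from towcam.diversity import hills_n2
from towcam.simulate import generate_trawl_catches

SANDY = {"plain sand dollar": 12.0, "hermit crab sp.": 2.0,
         "forbes sea star": 1.0, "moon snail": 0.5}
MIXED = {"plain sand dollar": 1.0, "hermit crab sp.": 6.0,
         "american sand lance": 4.0, "chestnut astarte clam": 3.0,
         "forbes sea star": 1.0, "moon snail": 0.5}

frames = []
for i, comp in enumerate(4 * [SANDY] + 4 * [MIXED]):
    jackpot = ("BT1", "plain sand dollar", 3.0) if i == 0 else None
    catches = generate_trawl_catches(comp, n_stations=1, effort=300,
                                     jackpot=jackpot, seed=10 + i)
    frames.append(pd.DataFrame(
        [(f"BT{i + 1}", c.taxon, c.count) for c in catches],
        columns=["station", "taxon", "count"]))
matrix = (pd.concat(frames)
          .pivot(index="station", columns="taxon", values="count")
          .fillna(0.0))

for station, row in matrix.iterrows():
    print(f"{station}: N2 = {hills_n2(row):.2f}")

dend = ward_cluster(standardize(matrix))
groups = cut_tree(dend, 2)
print("\n2-group cut:", {s: int(g) for s, g in groups.items()})
print("\nNewick:", to_newick(dend))
# BT1-BT4 (sand-dollar habitat) and BT5-BT8 (mixed habitat) form the two
# clusters; the jackpot tow BT1 shows the lowest N2 (one dominant taxon).
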