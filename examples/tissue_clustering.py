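"""Hierarchical clustering of tissue editing profiles.

Two heart-like tissues share an editing profile; three artery-like
tissues share a different, higher one. Average-linkage clustering on
per-tissue mean editing recovers the two clades.
"""

import numpy as np

import rnaedit as re_

rng = np.random.default_rng(3)
heart = rng.uniform(0.15, 0.35, 25)
artery = rng.uniform(0.6, 0.9, 25)
em = re_.simulate_editing_matrix(
    {
        "ventricle": (heart, 5), "appendage": (heart, 5),
        "aorta": (artery, 5), "tibial artery": (artery, 5), "coronaries": (artery, 5),
    },
    depth=80, rng=rng, kappa=200.0,
)
Z, labels, newick = re_.cluster_tissues(em)
print("tissues:", ", ".join(labels))
print("first merge:", {labels[int(Z[0, 0])], labels[int(Z[0, 1])]})
print("newick:", newick)
# The first merge joins the two tissues with the most similar editing
# profiles; the newick string encodes the full ultrametric dendrogram.
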