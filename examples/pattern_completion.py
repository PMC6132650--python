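"""Autoassociative pattern completion from a half cue.

Stores ten sparse random patterns in a diluted recurrent network
(N=1000 units, 200 synapses per unit) and retrieves each one from half
of its active units.  The printed overlap is the Pearson correlation
between the completed state and the stored pattern: 1.0 means perfect
completion.
"""

import numpy as np

from hipposim.attractor import AttractorConfig, build_mask, recall, store_patterns
from hipposim.patterns import PatternSet, degrade_cue, make_sparse_binary

rng = np.random.default_rng(0)
N, C, a, p = 1000, 200, 0.05, 10

mask = build_mask(N, C, rng)
stored = PatternSet(np.vstack([make_sparse_binary(N, a, seed=rng)
                               for _ in range(p)]))
weights = store_patterns(mask, stored)
config = AttractorConfig(a=a)

print(f"{p} patterns stored in N={N}, C={C}, a={a}")
print("pattern  cue-overlap  final-overlap  retrieved")
for i in range(p):
    cue = degrade_cue(stored.patterns[i], keep_fraction=0.5, seed=rng)
    res = recall(weights, cue, config, stored=stored)
    print(f"  {i:2d}      {res.trajectory[0][i]:.3f}        "
          f"{res.best_overlap:.3f}       {res.best_label == stored.labels[i]}")
print("\nA 50% cue starts at overlap ~0.7 and the recurrent dynamics "
      "complete it to ~1.0.")
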