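"""The closed-form calculus: sparseness, capacity, connectivity.

Evaluates the analytic quantities that frame the whole model at the rat
anatomy: how sparse the codes are, how many memories the CA3 recurrent
network can hold, and how dilute the wiring is.
"""

import numpy as np

from hipposim.metrics import (
    backprojection_fanin,
    connectivity_fraction,
    crc_capacity,
    round_sigfig,
    sparseness,
)

# population sparseness of three archetypal codes
uniform = np.full(100, 10.0)           # everyone fires at 10 spikes/s
one_hot = np.zeros(100)
one_hot[0] = 50.0                      # a single "grandmother cell"
graded = np.array([1.0, 2.0, 3.0, 4.0])

print(f"sparseness, uniform firing : {sparseness(uniform):.3f}")
print(f"sparseness, one-hot        : {sparseness(one_hot):.3f}")
print(f"sparseness, graded (1,2,3,4): {sparseness(graded):.4f}")

# storage capacity of the CA3 recurrent network, rat numbers
p_max = crc_capacity(C_RC=12_000, a=0.02, k=0.235)
print(f"\nCA3 capacity at C=12,000, a=0.02: {p_max:,.0f} memories")
print("  (~36,000: sparse codes buy capacity — at a=0.2 it would be "
      f"{crc_capacity(C_RC=12_000, a=0.2, k=0.235):,.0f})")

# anatomy: how dilute is the wiring?
mossy = connectivity_fraction(46, 10**6)
rc = connectivity_fraction(12_000, 6 * 10**5)
print(f"\nmossy-fibre connectivity   : {mossy:.4f}% (~{round_sigfig(mossy, 1)}%)")
print(f"recurrent connectivity     : {rc:.1f}% of the bilateral CA3 pool")

# the backprojection fan-in needed for faithful recall to neocortex
print(f"backprojection fan-in (equal sparseness): "
      f"{backprojection_fanin(C_RC=12_000, a_nc=0.02, a_CA3=0.02):,.0f} "
      "synapses per neocortical neuron")
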