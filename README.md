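# hipposim

A rate-coded simulator of the attractor-network theory of
hippocampo-cortical episodic memory, for computational neuroscientists
who want the theory's quantitative claims as runnable, testable code.

The theory holds that the hippocampus stores episodic memories — an
object (or odour, or reward) bound to a place — as attractor states of
the CA3 recurrent network, and recalls them to the neocortex through
back-projecting pattern associations.  The package implements each
computational stage as an explicit numerical model:

* **Sparseness and capacity calculus.**  Population sparseness
  *a* = (Σᵢ rᵢ/N)² / (Σᵢ rᵢ²/N), and the storage capacity of an
  autoassociator with C modifiable recurrent synapses per neuron,
  *p*ₘₐₓ ≅ k·C / (a·ln(1/a)).  At the rat anatomy (C = 12,000,
  a = 0.02, k = 0.235) this gives ≈ 36,000 memories.
* **Diluted autoassociation (CA3).**  Fixed in-degree random wiring,
  covariance (LTP + heterosynaptic LTD) learning
  ΔJᵢⱼ ∝ (rᵢ − ⟨r⟩)(rⱼ − ⟨r⟩), and iterative recall under global
  inhibition, including Monte-Carlo capacity measurement and
  adaptation-driven sequence replay.
* **Competitive learning (dentate gyrus, CA1).**  Pattern separation of
  overlapping inputs, the grid-cell → place-cell transformation, and
  CA1 recoding of multi-part events; plus the mossy-fibre randomizing
  expansion into CA3.
* **Continuous attractors.**  Activity bubbles at arbitrary trained
  locations, mixed continuous + discrete memories with object ↔ place
  cross-recall, ordered traversal recall (the "method of loci"), and a
  multi-scale ring path integrator.
* **The full circuit.**  Neocortex → parahippocampal → entorhinal →
  DG → CA3 → CA1 → backprojections, with the theory's storage/recall
  routing (mossy-dominated storage under cholinergic suppression of the
  recurrents; perforant-path-cued recall) and its pathway-knockout
  predictions.

## A worked example

```bash
python examples/pattern_completion.py
```

stores ten sparse random patterns in a diluted recurrent network
(N = 1000 units, C = 200 synapses each, sparseness 0.05) and cues each
with half of its active units:

```
10 patterns stored in N=1000, C=200, a=0.05
pattern  cue-overlap  final-overlap  retrieved
   0      0.698        1.000       True
   1      0.698        1.000       True
   ...
```

The cue starts at Pearson overlap ≈ 0.7 with the stored pattern; the
recurrent dynamics complete it to 1.0 — retrieval of the whole memory
from a part, the defining operation of an autoassociative memory.

The other example scripts each demonstrate one capability and print a
short interpretation: `capacity_calculus.py` (the closed-form numbers),
`object_place_memory.py` (mixed attractor cross-recall and traversal),
`grid_to_place.py` (competitive formation of place fields),
`episodic_recall.py` (the full circuit and its knockout predictions),
`sequence_and_pathint.py` (temporal order and ring path integration).

There is also a small CLI for config-driven experiment runs:

```bash
hipposim run --experiment mixed-recall --seed 1 --out results/
```

which writes a CSV result table and a JSON manifest (seed, parameters,
version) sufficient to reproduce the table bit-identically.

## Layout

```
src/hipposim/
  metrics.py      closed-form sparseness / capacity / connectivity
  patterns.py     seeded generators for every synthetic input
  attractor.py    diluted autoassociation: storage, completion, sequences
  cann.py         continuous and mixed attractors, ring path integration
  competitive.py  dentate/CA1 competitive learning, mossy expansion
  system.py       the end-to-end hippocampo-cortical model
  io.py           delimited-text and archive I/O, manifests
  cli.py          experiment runners and the command-line shell
docs/methods.md   the model, its assumptions, parameters and limitations
examples/         one narrative script per capability
```
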