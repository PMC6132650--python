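# Methods

This note documents the models implemented in `hipposim`, the choices
made where the underlying theory leaves the numerics open, and what the
synthetic-data experiments do and do not establish.

## The model family

All networks are rate-coded: the state of a population of N units is a
nonnegative firing-rate vector (spikes/s).  Dynamics are synchronous
discrete-time updates; there are no spikes, membrane time constants or
theta-cycle timing anywhere in the package.  Global inhibition is
modelled throughout as winner-take-all sparsification: after each
update the `ceil(a·N)` most driven units remain active and the rest are
silenced, which pins the population sparseness at the target `a`.

**Sparseness.**  `a = (Σ rᵢ/N)² / (Σ rᵢ²/N)` ranges from 1/N (one
active unit) to 1 (uniform firing) and equals the active fraction
exactly for binary patterns.  It is the single parameter coupling the
analytic capacity formula to every simulated network.

**Capacity.**  `p_max ≅ k·C/(a·ln(1/a))` for an autoassociator with C
modifiable recurrent synapses per neuron.  The scaling factor k depends
weakly on the rate distribution and connectivity and is known only to
be roughly 0.2–0.3; the package's default k = 0.235 is the value in
that range at which the canonical worked example (C = 12,000, a = 0.02)
reproduces the quoted ≈ 36,000 memories.  k is a calibration of the
analytic formula, not a fitted simulation parameter.

## Diluted autoassociation (CA3)

*Wiring.*  Each of N units draws exactly C presynaptic partners
uniformly without replacement, excluding itself; pair-connection
probability C/(N−1), no duplicate synapses.

*Learning.*  Covariance rule `ΔJᵢⱼ = (α/C)(rᵢ−⟨r⟩)(rⱼ−⟨r⟩)` on masked
synapses, the rate-model composite of associative LTP and
heterosynaptic LTD; subtracting the pattern mean removes the bias of
positive-only rates.

*Recall.*  Iterated `h = J·r` with three deliberate mechanisms:

1. **Saturating transfer.**  All winners fire at the common peak rate
   (a threshold-linear transfer driven into saturation).  With graded
   within-winner rates the Poisson spread of the diluted in-degree
   (CV ≈ 1/√(Ca)) caps the Pearson overlap with a binary stored
   pattern near 0.95, so a stored pattern would never test as an exact
   fixed point; with the saturating transfer it is one.  A
   `saturation_quantile < 1` recovers graded rates when wanted.
2. **Divisive normalization.**  Each unit's recurrent drive is divided
   by its total active presynaptic input (shunting inhibition).  At
   small Ca the active in-degree varies strongly across units and would
   otherwise dominate the drive; normalization scores units by the mean
   strength of their active synapses.
3. **Persistent cue.**  The retrieval cue remains as an external input
   of relative strength 0.3 during completion, modelling the cue
   pathway staying active while the recurrents complete the pattern.

Retrieval is scored by Pearson correlation with each stored pattern;
the declared success criterion is overlap ≥ 0.9 with the correct
pattern and a ≥ 0.2 margin over the runner-up.  Ties in winner
selection break by unit index.

*Measured capacity.*  `measure_capacity` bisects the largest load p at
which ≥ 90% of stored patterns are retrieved (overlap ≥ 0.9) from a
50%-of-active-units cue.  This operationalization is stricter than the
analytic criterion, so only the *structure* of the capacity formula is
comparable with the analytic prediction, not the constant k.  An
important empirical finding of the package's own pilots: the linearity
of measured capacity in C emerges only once Ca ≳ 10–15 active inputs
per neuron.  Below that (e.g. C = 100 at a = 0.05, Ca = 5) retrieval is
limited by in-degree noise rather than crosstalk and measured capacity
grows superlinearly with C; the capacity-scaling property test
therefore runs at C ∈ {300, 450, 600} where the analytic regime holds.

*Sequence replay.*  Consecutive stored patterns are linked by forward
hetero-associative weights of relative strength ε, and each unit
carries a subtractive adaptation variable (`adapt ← adapt·e^(−1/τ) +
Δ·r`).  The frozen defaults ε = 0.8, Δ = 0.1, τ = 10 steps were chosen
by pilot search as the centre of the region where five stored
attractors replay in storage order across arbitrary wiring seeds; with
ε = 0 and no adaptation the network provably stays in its starting
attractor.

## Competitive learning (dentate gyrus, CA1)

A single layer with unit-norm weight rows; per presentation the most
activated units move toward the (normalized) input and are
renormalized.  Competition is soft (update proportional to activation)
except where noted.  Two initializations: random uniform, or rows
sampled from the training inputs (seeding each unit on a real input).

**Grid → place.**  Grid cells are square periodic lattices of Gaussian
bumps (σ = extent/(3f)) with random phase *and random lattice
orientation* per cell.  Orientation matters: with a shared axis, whole
frequency-subpopulations re-align at lattice offsets and the population
vector repeats across the environment, so no decoder — competitive or
otherwise — can assign a unique place; with independent orientations
the joint code is location-unique.  The frozen transformation config
(200 output units, hard single-winner training, input-sample
initialization, learning rate 0.2, 5 epochs, one-winner-per-location
readout) yields ≈ 80% single-field units on the two-frequency (4, 7
cycles) fixture.  Field statistics follow standard place-field
analysis: Gaussian-smooth the rate map (σ = 1 lattice cell), threshold
at half the peak, count connected components of ≥ 3 cells.

**Mossy expansion.**  Each CA3 unit sums its few (46 at full scale)
mossy afferents; feedforward inhibition (top-k thresholding) lets
exactly `ceil(a·N)` units fire.  Drive ties are broken by a
pseudo-random order keyed to the mask wiring — breaking ties by unit
index would spuriously correlate the outputs of unrelated inputs.  The
decorrelation fixture models two similar events as graded patterns on
the *same* 10% support with independent gamma(1.2) rates (the same
sparse dentate place units engaged at different rates), which puts
their Pearson correlation near 0.5; thresholding the summed drive at
a_CA3 = 0.01 then yields CA3 correlations below 0.1.  Binary
same-support pairs decorrelate far less (≈ 0.2) because the shared
active-count component survives any thresholding — rate variability is
doing real work in this mechanism.

**CA1 recoding.**  A competitive net trained on full multi-part CA3
events; because a subpart alone still ranks the same winners highest,
any single subpart retrieves the combined CA1 code.

## Continuous and mixed attractors

Units tile a ring (spacing 1) with Gaussian tuning of width σ; Hebbian
learning over a dense tiling of training positions gives symmetric
weights that fall off as exp(−d²/4σ²), minus a uniform inhibition
constant (0.3 of the peak).  Bubble dynamics keep the top
`bubble_k ≈ 2σ` units with graded rates; the bubble centre is the
rate-weighted circular mean.  Translation equivariance and single-
bubble survival follow from the symmetric distance-dependent weights.

Mixed memories concatenate 1000 continuous units with 500 discrete
(object) units; each complete memory is stored by the covariance rule,
binding bump and object by co-activity.  Recall clamps the cued part
and lets the other settle under its own inhibition pool.  The canonical
fixture uses σ = 50 and `bubble_k = 4σ` so that neighbouring memories'
fields genuinely overlap (a midway cue is ambiguous, and rate noise
picks exactly one winner) and the recalled bubble spans the stored
tuning width.  The fixture stores 2 memories by default (at locations
300 and 500) and 5 for load tests; traversal recall clamps a moving
locus cue and reports the dominant object code wherever the match
exceeds 0.5.

Path integration is modelled at the ring-phase level only: each ring of
size s advances its phase by displacement/s (mod 1), and position is
decoded by brute-force minimum joint circular distance over the
unambiguous range (the product of the ring sizes).  Bubble-shifting by
asymmetric weights inside a CANN is deliberately not simulated.

## The end-to-end circuit

Desk scale: populations divide by the scale factor (default 1000:
DG 1000, CA3 300), but connection in-degrees divide by its *square
root* (C_RC 120, C_pp 126, with floors C_mf ≥ 5 and a cap at 40% of
the presynaptic pool).  Naive division of in-degrees leaves a few
synapses per neuron and no functioning network; root scaling preserves
the pathway ordering while degrading the √C retrieval signal-to-noise
gracefully.  Stage sizes follow the convergence/divergence funnel with
geometric factor 2 around CA3: neocortex 4800 (two banks of 2400) →
PHG 2400 → EC 1200 → CA3 300 → CA1 600 → EC → PHG → neocortex.

The forward funnel keeps the object and spatial streams segregated
(object bank → perirhinal half of PHG → lateral EC; space bank →
parahippocampal half → medial EC), converging only at DG and CA3 — as
in the anatomy.  This is what makes a one-bank cue usable: an
object-only cue leaves the spatial stream silent instead of corrupting
both.  Place encodings are sliding-window codes (stride 15 units per
unit distance), so nearby places share most of their units and the
burden of separating spatial memories falls on the dentate/mossy
pathway — exactly the regime in which the theory's mossy predictions
have teeth.

**Storage.**  Forward pass to EC and DG; the CA3 state is selected over
three iterations of `5·mf + 0.3·pp + ach_gain·rc` (peak-normalized
drives), so the mossy drive dominates and the ACh-suppressed recurrent
drive (default gain 0.2) perturbs it only marginally — zeroing the
recurrents changes the stored pattern by < 1% of units, while full
recurrent efficacy (ach_gain = 1) measurably degrades pattern
separation.  The recurrents, the perforant path (EC → CA3), the
Schaffer collaterals (CA3 → CA1) and every backprojection stage then
learn by the same covariance rule.

**Recall.**  The cue's EC pattern drives CA3 through the *learned*
perforant path; completion runs the attractor recall above; CA1, EC,
PHG and both neocortical banks are reinstated through the learned
pattern associations with per-bank inhibition.  Two safeguards keep
unfamiliar cues from completing into stored attractors: an inhibitory
floor on the perforant-path drive calibrated to 0.3 of the stored
events' own drive, and an ignition requirement that at least half the
target CA3 population clear that floor.  Backprojection in-degrees use
the fan-in requirement `C_HBP = C_RC·a_nc/a_CA3` as a lower bound but
run at the 40% dilution cap — at desk scale more synapses strictly
reduce finite-size drive noise, and the fan-in formula is a capacity
condition, not an optimum.

All stage states are binary (saturated winners): covariance-rule
pattern association is then exact up to ranking errors, which is what
lets the reinstatement chain lose at most a few percent of overlap per
stage at a load of ten events.

## What the synthetic data does and does not show

The generators produce exactly the statistical structure the theory
assumes: sparse binary or graded codes with independent or controlled
correlations, Gaussian spatial tuning, periodic grid maps, and events
whose object codes are unrelated while their place codes overlap
smoothly.  Real dentate, CA3 and entorhinal codes violate all of these
in ways the package does not model: lognormal rate distributions with
long tails, spatially non-uniform connectivity, grid modules with
shared orientations and discrete scale ratios, theta-paced dynamics,
and behaviourally correlated (not independent) events.  Passing tests
therefore establish that the *mechanisms* behave as the theory claims
under its own idealizations — not that the quantitative values (e.g.
the capacity constant k) transfer to biological tissue.

## Known limitations

* Spiking dynamics, settling-time and theta-cycle claims are out of
  scope; noise enters only as rate-level perturbations.
* The capacity operationalization is criterion-dependent; absolute
  measured capacities are well below k·C/(a·ln(1/a)) and only the
  scaling structure is asserted, and only in the Ca ≳ 10 regime (see
  above).
* Acetylcholine is a single scalar gain on the recurrent drive during
  storage; no receptor pharmacology.
* The grid system is a generator of inputs, not a model of grid-cell
  formation; path integration is phase arithmetic, not attractor
  dynamics.
* Consolidation/semantic learning in the neocortex is not modelled;
  the neocortical banks are static pattern stores.
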