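"""Continuous attractor networks (CANNs) and mixed object-place memories.

A CANN stores a continuous variable (place, spatial view, head direction)
in a population of units with overlapping Gaussian tuning: recurrent
weights set up by associative learning reflect the distance between the
units' preferred locations, so a localized "bubble" of activity can be
maintained at any trained location, held in place by global inhibition.

The same associative machinery can bind a continuous pattern to a
discrete one: a memory consisting of a spatial bump plus a binary object
code is stored as a single pattern in one weight matrix, after which the
place can be recalled from the object and the object from the place.
Moving an external locus cue along the space reads out the objects
stored along a path in order — the mechanism offered for the classical
"method of loci" mnemonic.

A minimal multi-scale ring path integrator is also provided: a set of
ring attractors of distinct sizes whose phases advance with self-motion,
with position decoded from the joint phase vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from hipposim.metrics import pattern_overlap
from hipposim.patterns import MixedPattern, as_rng, make_gaussian_bump

__all__ = [
    "CannConfig",
    "MixedCannConfig",
    "Bubble",
    "RingSystem",
    "build_cann",
    "settle_bubble",
    "describe_bubble",
    "store_mixed",
    "standard_object_place_fixture",
    "recall_place_from_object",
    "recall_object_from_place",
    "traverse_recall",
    "ring_path_integration",
]


@dataclass
class CannConfig:
    """Parameters of a continuous attractor network.

    ``sigma`` is the tuning width in state-space units (unit spacing = 1);
    ``inhibition`` the uniform subtractive constant on the weights (global
    inhibitory feedback); ``bubble_k`` the number of units kept active by
    global inhibition each step (defaults to ``round(2*sigma)``, which
    holds the activity-packet mass roughly constant); ``steps`` the number
    of settling iterations.
    """

    n_units: int = 1000
    sigma: float = 20.0
    topology: str = "ring"
    inhibition: float = 0.3
    steps: int = 100
    bubble_k: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 10:
            raise ValueError("n_units must be >= 10")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.topology not in ("ring", "line"):
            raise ValueError("topology must be 'ring' or 'line'")

    @property
    def k(self) -> int:
        return self.bubble_k if self.bubble_k is not None else max(3, round(2 * self.sigma))


@dataclass
class Bubble:
    """A localized packet of activity on the continuous dimension."""

    center: float
    width: float
    mass: float
    pattern: np.ndarray | None = field(repr=False, default=None)

    @property
    def exists(self) -> bool:
        return self.mass > 0


def _circular_center(r: np.ndarray, n: int) -> tuple[float, float]:
    """Rate-weighted circular mean and dispersion of a ring activity
    profile, in unit coordinates."""
    ang = 2 * np.pi * np.arange(n) / n
    w = r / r.sum()
    z = np.sum(w * np.exp(1j * ang))
    center = (np.angle(z) % (2 * np.pi)) * n / (2 * np.pi)
    R = abs(z)  # resultant length; dispersion = sqrt(-2 ln R)
    width = math.sqrt(max(-2.0 * math.log(max(R, 1e-12)), 0.0)) * n / (2 * np.pi)
    return float(center), float(width)


def describe_bubble(r: np.ndarray, topology: str = "ring") -> Bubble:
    """Summarize an activity profile as a :class:`Bubble` (center, width,
    mass); an all-zero profile yields the no-bubble flag (mass 0)."""
    r = np.asarray(r, dtype=float)
    if not r.any():
        return Bubble(center=float("nan"), width=0.0, mass=0.0, pattern=r)
    if topology == "ring":
        c, w = _circular_center(r, r.size)
    else:
        wts = r / r.sum()
        c = float(np.sum(wts * np.arange(r.size)))
        w = float(np.sqrt(np.sum(wts * (np.arange(r.size) - c) ** 2)))
    return Bubble(center=c, width=w, mass=float(r.sum()), pattern=r)


def build_cann(config: CannConfig,
               training_positions: np.ndarray | None = None) -> np.ndarray:
    """Recurrent weights from associative learning over a continuous space.

    Each unit i has a Gaussian tuning curve centred on its preferred
    location (unit spacing 1).  Training visits every position in
    ``training_positions`` (default: every unit's preferred location — a
    dense tiling of the space) and accumulates the Hebbian co-activation
    ``w_ij = sum_x r_i(x) r_j(x)``; a uniform inhibition constant is then
    subtracted and the diagonal zeroed.  On a ring the result depends
    only on the circular distance |i - j|.
    """
    n = config.n_units
    if training_positions is None:
        training_positions = np.arange(n, dtype=float)
    R = np.empty((n, len(training_positions)))
    for col, x in enumerate(training_positions):
        R[:, col] = make_gaussian_bump(n, float(x), config.sigma, config.topology)
    W = R @ R.T
    W /= W.max()
    W -= config.inhibition
    np.fill_diagonal(W, 0.0)
    return W


def _bubble_inhibit(h: np.ndarray, k: int) -> np.ndarray:
    """Graded threshold-linear rates for the k most driven units,
    normalized to peak 1 (global inhibition holding packet mass constant)."""
    order = np.argsort(-h, kind="stable")
    winners = order[:k]
    thr = h[order[k]] if k < h.size else min(float(h.min()), 0.0)
    r = np.zeros(h.size)
    g = np.maximum(h[winners] - thr, 0.0)
    if g.max() <= 0:
        return r
    r[winners] = g / g.max()
    return r


def settle_bubble(weights: np.ndarray, cue: np.ndarray | float,
                  config: CannConfig) -> Bubble:
    """Let the network settle and report the surviving activity packet.

    ``cue`` is either a position (a Gaussian bump is applied there) or an
    arbitrary rate profile.  Iterates ``h = W r`` with global inhibition
    for ``config.steps`` steps; with symmetric distance-dependent weights
    a single contiguous bubble survives, centred wherever it was started.
    An all-zero cue returns the no-bubble flag.
    """
    n = config.n_units
    if np.isscalar(cue):
        r = make_gaussian_bump(n, float(cue), config.sigma, config.topology)
    else:
        r = np.asarray(cue, dtype=float).copy()
    if not r.any():
        return describe_bubble(np.zeros(n), config.topology)
    for _ in range(config.steps):
        h = weights @ r
        r = _bubble_inhibit(h, config.k)
        if not r.any():
            break
    return describe_bubble(r, config.topology)


# ---------------------------------------------------------------------------
# Mixed continuous + discrete memories


@dataclass
class MixedCannConfig(CannConfig):
    """CANN configuration extended with a discrete (object) population.

    The canonical geometry is 1000 continuous units plus 500 discrete
    units; each stored memory binds a spatial bump to a binary subset of
    the discrete units.  ``disc_k`` is the number of discrete units kept
    active during discrete recall (the stored subset size).
    """

    n_disc: int = 500
    disc_k: int = 25
    recall_steps: int = 30


def store_mixed(memories: list[MixedPattern],
                config: MixedCannConfig,
                mask: np.ndarray | None = None) -> np.ndarray:
    """One weight matrix binding continuous and discrete parts.

    Each complete memory (bump + object subset, concatenated over
    ``n_units + n_disc`` units) is stored with the covariance rule; the
    spatial and object representations are bound simply by being
    simultaneously active at storage.  ``mask``, if given, restricts the
    support (boolean, True = synapse exists); the diagonal is always
    zeroed.  Storing zero memories returns zero weights.
    """
    n_tot = config.n_units + config.n_disc
    W = np.zeros((n_tot, n_tot))
    for mem in memories:
        v = mem.full
        if v.size != n_tot:
            raise ValueError("memory size does not match configuration")
        d = v - v.mean()
        W += np.outer(d, d) / n_tot
    if mask is not None:
        W = W * mask
    np.fill_diagonal(W, 0.0)
    return W


def standard_object_place_fixture(centers: tuple[float, ...] = (300.0, 500.0),
                                  seed: int | np.random.Generator | None = 0,
                                  sigma: float = 50.0,
                                  ) -> tuple[list[MixedPattern], MixedCannConfig, np.ndarray]:
    """The canonical mixed-memory network: 1000 continuous + 500 discrete
    units, one memory per centre (default: locations 300 and 500), each
    bound to a random 25-unit object subset.

    The tuning width of 50 units makes neighbouring memories' spatial
    fields genuinely overlap, so a cue midway between two stored
    locations is ambiguous rather than simply unfamiliar.
    Returns (memories, config, trained weights).
    """
    from hipposim.patterns import make_mixed_memory

    cfg = MixedCannConfig(n_units=1000, sigma=sigma, n_disc=500, disc_k=25,
                          recall_steps=30, bubble_k=round(4 * sigma))
    rng = as_rng(seed)
    memories = [
        make_mixed_memory(c, rng.choice(cfg.n_disc, size=cfg.disc_k, replace=False),
                          N_cont=cfg.n_units, N_disc=cfg.n_disc, sigma=sigma,
                          label=f"memory@{c:g}")
        for c in centers
    ]
    weights = store_mixed(memories, cfg)
    return memories, cfg, weights


def _mixed_recall(weights: np.ndarray, cont0: np.ndarray, disc0: np.ndarray,
                  config: MixedCannConfig, clamp: str,
                  noise_sd: float = 0.0,
                  seed: int | np.random.Generator | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Shared recall loop with separate inhibition pools for the
    continuous and discrete populations; ``clamp`` pins one part to the
    cue ('disc', 'cont', or 'none')."""
    nc = config.n_units
    rng = as_rng(seed)
    r = np.concatenate([cont0, disc0])
    for _ in range(config.recall_steps):
        h = weights @ r
        if noise_sd > 0:
            h = h + rng.normal(0.0, noise_sd * max(float(np.abs(h).max()), 1e-12), h.size)
        cont = _bubble_inhibit(h[:nc], config.k)
        disc = _bubble_inhibit(h[nc:], config.disc_k)
        if clamp == "disc":
            disc = disc0
        elif clamp == "cont":
            cont = cont0
        r = np.concatenate([cont, disc])
    return r[:nc], r[nc:]


def recall_place_from_object(weights: np.ndarray, discrete_cue: np.ndarray,
                             config: MixedCannConfig,
                             clamp: bool = True) -> Bubble:
    """Retrieve the continuous (place) part of a memory from its object.

    The discrete cue (possibly partial) is applied and the continuous
    population settles under the cross- and recurrent weights; the
    surviving bubble marks the location bound to that object.
    """
    cont0 = np.zeros(config.n_units)
    cont, _ = _mixed_recall(weights, cont0, np.asarray(discrete_cue, float),
                            config, clamp="disc" if clamp else "none")
    return describe_bubble(cont, config.topology)


def recall_object_from_place(weights: np.ndarray, location: float | np.ndarray,
                             config: MixedCannConfig,
                             noise_sd: float = 0.0,
                             seed: int | np.random.Generator | None = None,
                             ) -> np.ndarray:
    """Retrieve the discrete (object) part of a memory from a location.

    A bump cue at ``location`` drives the discrete population, whose own
    attractor dynamics settle on a single stored subset.  With a cue
    midway between two stored locations the added rate noise picks
    exactly one winner rather than a mixture.
    """
    if np.isscalar(location):
        cont0 = make_gaussian_bump(config.n_units, float(location),
                                   config.sigma, config.topology)
    else:
        cont0 = np.asarray(location, dtype=float)
    _, disc = _mixed_recall(weights, cont0, np.zeros(config.n_disc),
                            config, clamp="cont", noise_sd=noise_sd, seed=seed)
    return disc


def traverse_recall(weights: np.ndarray, path: list[float],
                    memories: list[MixedPattern],
                    config: MixedCannConfig,
                    match_threshold: float = 0.5) -> list[str]:
    """Read out stored objects in order while a locus cue moves along a path.

    At each path location the continuous cue is clamped, the discrete
    population settles, and its state is matched against the stored
    object codes; a label is recorded when the match exceeds
    ``match_threshold``.  Returns the de-duplicated label order — the
    items recalled "in the first place, in the second place, ...".  A
    path through unpopulated territory yields no labels.
    """
    labels: list[str] = []
    for x in path:
        disc = recall_object_from_place(weights, float(x), config)
        if not disc.any():
            continue
        best, best_ov = None, match_threshold
        for mem in memories:
            if mem.discrete.std() == 0 or disc.std() == 0:
                continue
            ov = pattern_overlap(disc, mem.discrete)
            if ov > best_ov:
                best, best_ov = mem.label, ov
        if best is not None:
            if not labels or labels[-1] != best:
                labels.append(best)
    seen: list[str] = []
    for v in labels:
        if v not in seen:
            seen.append(v)
    return seen


# ---------------------------------------------------------------------------
# Multi-scale ring path integration


@dataclass
class RingSystem:
    """A set of ring attractors with distinct spatial periods.

    ``sizes`` are the distances covered by one full cycle of each ring;
    ``phases`` the current phase of each ring in [0, 1).  Position within
    a range smaller than the product of the ring sizes is uniquely
    encoded by the joint phase vector (a residue-number-style code).
    """

    sizes: list[float]
    phases: list[float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.sizes)) != len(self.sizes) or any(s <= 0 for s in self.sizes):
            raise ValueError("ring sizes must be distinct and positive")
        if self.phases is None:
            self.phases = [0.0] * len(self.sizes)
        if len(self.phases) != len(self.sizes):
            raise ValueError("one phase per ring required")


def ring_path_integration(rings: RingSystem, velocities: list[float],
                          decode_range: float | None = None,
                          resolution: float = 0.05) -> float:
    """Integrate self-motion on the rings and decode the position.

    Each displacement advances every ring's phase by
    ``displacement / size`` (mod 1); after the full velocity sequence
    the position is decoded by brute-force minimum joint circular phase
    distance over a grid of candidate positions in ``[0, decode_range)``
    (default: the product of the ring sizes, the unambiguous range).
    The ring phases are updated in place.
    """
    for v in velocities:
        for i, s in enumerate(rings.sizes):
            rings.phases[i] = (rings.phases[i] + v / s) % 1.0
    if decode_range is None:
        decode_range = float(np.prod(rings.sizes))
    candidates = np.arange(0.0, decode_range, resolution)
    cost = np.zeros_like(candidates)
    for s, ph in zip(rings.sizes, rings.phases):
        d = np.abs((candidates / s - ph + 0.5) % 1.0 - 0.5)
        cost += d**2
    return float(candidates[np.argmin(cost)])
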