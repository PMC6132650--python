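"""Seeded generators for every synthetic input the simulator consumes.

The universal currency is the *rate pattern*: a 1-D NumPy array of
nonnegative firing rates (spikes/s) over a population of N units.  On top
of that this module builds sparse binary and graded patterns, Gaussian
bumps on a ring or line, mixed continuous+discrete memories, periodic
grid-cell rate maps, episodic events, degraded retrieval cues, and the
anatomical parameter block (population sizes and per-neuron connection
counts) with its desk-scale reduction.

Every generator takes either an integer seed or a ``numpy.random.Generator``
and is bit-reproducible for a given seed and parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

RatePattern = np.ndarray  # 1-D nonnegative float array, spikes/s

__all__ = [
    "RatePattern",
    "PatternSet",
    "MixedPattern",
    "SpatialMap",
    "GridCellSpec",
    "EpisodicEvent",
    "AnatomyConfig",
    "as_rng",
    "make_sparse_binary",
    "make_graded",
    "make_gaussian_bump",
    "make_mixed_memory",
    "make_grid_population",
    "make_grid_map",
    "make_correlated_pair",
    "degrade_cue",
]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce a seed or Generator into a ``numpy.random.Generator``."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PatternSet:
    """An ordered collection of equal-length rate patterns with labels."""

    patterns: np.ndarray  # shape (p, N)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        if not self.labels:
            self.labels = [f"pattern_{i}" for i in range(len(self.patterns))]
        if len(self.labels) != len(self.patterns):
            raise ValueError("one label per pattern required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if np.any(self.patterns < 0):
            raise ValueError("rates must be nonnegative")

    def __len__(self) -> int:
        return len(self.patterns)

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]


@dataclass
class MixedPattern:
    """A memory with a continuous (Gaussian bump) and a discrete part.

    The continuous part lives on units ``0..N_cont-1`` and represents a
    location in a continuous space (e.g. a place or spatial view); the
    discrete part is a binary subset of units ``N_cont..N_cont+N_disc-1``
    and represents the object or event present at that location.  The two
    are bound by being co-active when the memory is stored.
    """

    continuous: np.ndarray
    discrete: np.ndarray
    center: float
    label: str = ""

    @property
    def full(self) -> np.ndarray:
        """Concatenated rate vector over all N_cont + N_disc units."""
        return np.concatenate([self.continuous, self.discrete])

    @property
    def n_cont(self) -> int:
        return self.continuous.size


@dataclass
class SpatialMap:
    """A 2-D firing-rate map over an (X, Y) environment.

    ``values[iy, ix]`` is the rate at lattice cell (ix, iy); ``extent`` is
    the side length of the (square) environment in arbitrary units.
    """

    values: np.ndarray
    extent: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("spatial map must be a 2-D lattice with dims >= 2")
        if np.any(self.values < 0):
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class GridCellSpec:
    """Parameters of one periodic (grid-cell-like) spatial tuning curve."""

    frequency: int  # cycles across the environment
    phase: tuple[float, float] = (0.0, 0.0)  # offset in environment units
    sigma: float | None = None  # bump width; default extent/(3*frequency)

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class EpisodicEvent:
    """One episodic event: an object at a place (optionally with reward/time).

    Exactly one spatial coordinate must be given: ``place`` (a continuous
    location, rodent-style) or ``view`` (a discrete spatial-view index,
    primate-style).
    """

    object_id: str
    place: float | None = None
    view: int | None = None
    reward_id: str | None = None
    time_index: int | None = None

    def __post_init__(self) -> None:
        if not self.object_id:
            raise ValueError("object_id is required")
        if (self.place is None) == (self.view is None):
            raise ValueError("exactly one of place or view must be given")


@dataclass(frozen=True)
class AnatomyConfig:
    """Population sizes and per-neuron connection counts of the circuit.

    Defaults are the rat values: 10^6 dentate granule cells, 3x10^5 CA3
    pyramidal cells, 46 mossy-fibre inputs per CA3 cell, ~12,000 recurrent
    collateral synapses per CA3 cell, and ~4,000 direct perforant-path
    inputs per CA3 cell.

    ``scale`` is a uniform divisor applied to the population sizes for
    desk-scale simulation.  Connection in-degrees are divided by
    ``sqrt(scale)`` rather than ``scale``: the retrieval signal-to-noise of
    a diluted attractor grows like sqrt(C), so root scaling keeps reduced
    networks functional while preserving the dilution ordering of the
    pathways.  Floors (C_mf >= 5, C_RC and C_pp >= 10) and the cap
    C_RC <= 0.4*N_CA3 keep the scaled wiring well posed.
    """

    N_DG: int = 1_000_000
    N_CA3: int = 300_000
    C_mf: int = 46
    C_RC: int = 12_000
    C_pp: int = 4_000
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.scaled_C_mf < 1:
            raise ValueError("scaled C_mf must be >= 1")
        if self.scaled_C_RC >= self.scaled_N_CA3:
            raise ValueError("scaled C_RC must be < scaled N_CA3")

    @property
    def scaled_N_DG(self) -> int:
        return max(50, round(self.N_DG / self.scale))

    @property
    def scaled_N_CA3(self) -> int:
        return max(50, round(self.N_CA3 / self.scale))

    @property
    def scaled_C_mf(self) -> int:
        return max(5, round(self.C_mf / math.sqrt(self.scale)))

    @property
    def scaled_C_RC(self) -> int:
        c = max(10, round(self.C_RC / math.sqrt(self.scale)))
        return min(c, int(0.4 * self.scaled_N_CA3))

    @property
    def scaled_C_pp(self) -> int:
        return max(10, round(self.C_pp / math.sqrt(self.scale)))


def make_sparse_binary(N: int, a: float, rate_hi: float = 30.0,
                       seed: int | np.random.Generator | None = None) -> RatePattern:
    """A binary pattern with exactly ``round(a*N)`` units at ``rate_hi``.

    The active units are chosen uniformly without replacement, so two
    independent draws overlap only at chance.  The sparseness of the
    result equals the fraction of active units exactly.
    """
    if not 0 < a <= 1:
        raise ValueError("sparseness a must lie in (0, 1]")
    n_active = round(a * N)
    if n_active < 1:
        raise ValueError(f"a*N = {a * N:.3g} rounds below 1 active unit")
    rng = as_rng(seed)
    pattern = np.zeros(N)
    pattern[rng.choice(N, size=n_active, replace=False)] = rate_hi
    return pattern


# Support expansion for graded patterns: exponential amplitudes on a support
# fraction f give sparseness f * E[x]^2/E[x^2] = f/2, so a support of 2*a*N
# units centres the search at the target sparseness.
_GRADED_SUPPORT_FACTOR = 2.0


def make_graded(N: int, a: float, rate_scale: float = 20.0,
                seed: int | np.random.Generator | None = None,
                tol: float = 1e-3) -> RatePattern:
    """A graded sparse pattern with sparseness ``a`` to within ``tol``.

    Amplitudes on a support of ``round(2*a*N)`` units are drawn from an
    exponential distribution (a conventional stand-in for the sparse,
    graded, positively skewed firing-rate distributions seen in cortex);
    a scalar exponent applied to the rates is then bisected until the
    population sparseness matches ``a`` to within ``tol``.

    Raises
    ------
    ValueError
        If the target sparseness cannot be bracketed on the support
        (``a`` too close to the one-active-unit limit), or inputs invalid.
    """
    if not 0 < a < 1:
        raise ValueError("sparseness a must lie in (0, 1)")
    n_support = round(min(_GRADED_SUPPORT_FACTOR * a, 1.0) * N)
    if n_support < 2:
        raise ValueError("support too small for a graded pattern; increase a or N")
    rng = as_rng(seed)
    support = rng.choice(N, size=n_support, replace=False)
    amps = rng.exponential(1.0, size=n_support)
    amps = np.maximum(amps, 1e-12)

    from hipposim.metrics import sparseness  # local import to avoid cycle

    def sp(beta: float) -> float:
        v = np.zeros(N)
        v[support] = amps**beta
        return sparseness(v)

    # sparseness is monotone decreasing in the exponent beta:
    # beta -> 0 gives a binary pattern (a = n_support/N), large beta
    # concentrates mass on the single largest amplitude (a -> 1/N).
    lo, hi = 1e-3, 1.0
    while sp(hi) > a:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("graded sparseness search failed to bracket target")
    if sp(lo) < a:
        raise ValueError("target sparseness exceeds the support fraction")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if abs(sp(mid) - a) <= tol * 0.5:
            lo = hi = mid
            break
        if sp(mid) > a:
            lo = mid
        else:
            hi = mid
    beta = 0.5 * (lo + hi)
    out = np.zeros(N)
    out[support] = amps**beta
    out *= rate_scale / out.max()
    if abs(sparseness(out) - a) > tol:
        raise ValueError("graded sparseness search did not converge")
    return out


def make_gaussian_bump(N: int, center: float, sigma: float,
                       topology: str = "ring") -> RatePattern:
    """Gaussian firing-rate bump over units with evenly spaced preferred
    locations.

    ``rate_i = exp(-d(i, center)^2 / (2 sigma^2))`` with ``d`` the
    wrap-around distance on a ring of circumference N, or the plain
    absolute distance on a line.  Peak rate is 1 at the unit whose
    preferred location coincides with ``center``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if topology not in ("ring", "line"):
        raise ValueError(f"topology must be 'ring' or 'line', got {topology!r}")
    i = np.arange(N, dtype=float)
    d = i - center
    if topology == "ring":
        d = (d + N / 2.0) % N - N / 2.0
    return np.exp(-(d**2) / (2.0 * sigma**2))


def make_mixed_memory(center: float, discrete_subset: Sequence[int],
                      N_cont: int = 1000, N_disc: int = 500,
                      sigma: float = 20.0, rate_hi: float = 1.0,
                      label: str = "") -> MixedPattern:
    """A mixed memory: a spatial bump bound to a discrete object code.

    The continuous part is a Gaussian bump at ``center`` on a ring of
    ``N_cont`` units (default 1000, matching the canonical fixture in
    which memory 1 sits at location 300 and memory 2 at location 500);
    the discrete part sets the units listed in ``discrete_subset``
    (indices into ``0..N_disc-1``) to ``rate_hi``.  An empty subset gives
    a purely continuous memory.
    """
    cont = make_gaussian_bump(N_cont, center, sigma, topology="ring")
    disc = np.zeros(N_disc)
    idx = np.asarray(list(discrete_subset), dtype=int)
    if idx.size:
        if idx.min() < 0 or idx.max() >= N_disc:
            raise ValueError("discrete_subset indices out of range")
        disc[idx] = rate_hi
    return MixedPattern(continuous=cont, discrete=disc, center=float(center),
                        label=label or f"memory@{center:g}")


def _lattice_map(frequency: int, phase: tuple[float, float], sigma: float,
                 orientation: float, extent: float, nx: int, ny: int) -> np.ndarray:
    """Rate map of one periodic lattice of Gaussian bumps, optionally
    rotated by ``orientation`` radians, peak-normalized to 1."""
    spacing = extent / frequency
    xs = (np.arange(nx) + 0.5) * extent / nx
    ys = (np.arange(ny) + 0.5) * extent / ny
    XX, YY = np.meshgrid(xs, ys)
    ct, st = math.cos(orientation), math.sin(orientation)
    U = ct * (XX - phase[0]) + st * (YY - phase[1])
    V = -st * (XX - phase[0]) + ct * (YY - phase[1])
    du = (U + spacing / 2.0) % spacing - spacing / 2.0
    dv = (V + spacing / 2.0) % spacing - spacing / 2.0
    values = np.exp(-(du**2 + dv**2) / (2.0 * sigma**2))
    return values / values.max()


def make_grid_population(n_cells: int, frequencies: Sequence[int],
                         extent: float = 1.0, nx: int = 50, ny: int = 50,
                         sigma_rule: Callable[[int], float] | None = None,
                         seed: int | np.random.Generator | None = None,
                         random_orientation: bool = True,
                         ) -> list[SpatialMap]:
    """A population of periodic grid-cell rate maps with random phases.

    Each cell's map is a square periodic lattice of Gaussian bumps with
    the given number of cycles across the environment, a random 2-D
    phase offset and (by default) a random lattice orientation; peak
    rate is normalized to 1.  Cells cycle through the listed spatial
    frequencies (e.g. ``[4, 7]``) so that at least two grid scales are
    represented — the combination that makes a unique place decodable
    downstream.

    Independent orientations matter downstream: with a shared lattice
    axis, whole subpopulations re-align at lattice offsets and the
    population code repeats; with random orientations the joint activity
    vector is unique to a location, which is what lets competitive
    learning carve out single-field place cells.

    ``sigma_rule`` maps a frequency to a bump width; the default is
    ``extent / (3 * frequency)``.
    """
    if n_cells < 1 or not frequencies:
        raise ValueError("need at least one cell and one frequency")
    rng = as_rng(seed)
    if sigma_rule is None:
        sigma_rule = lambda f: extent / (3.0 * f)  # noqa: E731
    maps: list[SpatialMap] = []
    for c in range(n_cells):
        f = int(frequencies[c % len(frequencies)])
        spacing = extent / f
        phase = tuple(rng.uniform(0.0, spacing, size=2))
        theta = rng.uniform(0.0, math.pi / 2) if random_orientation else 0.0
        values = _lattice_map(f, phase, sigma_rule(f), theta, extent, nx, ny)
        maps.append(SpatialMap(values=values, extent=extent))
    return maps


def make_grid_map(spec: GridCellSpec, extent: float = 1.0,
                  nx: int = 50, ny: int = 50,
                  orientation: float = 0.0) -> SpatialMap:
    """A single grid map from an explicit :class:`GridCellSpec` (zero phase
    puts a bump at the origin corner of the environment)."""
    sigma = spec.sigma if spec.sigma is not None else extent / (3.0 * spec.frequency)
    values = _lattice_map(spec.frequency, spec.phase, sigma, orientation,
                          extent, nx, ny)
    return SpatialMap(values=values, extent=extent)


def make_correlated_pair(N: int, support_fraction: float = 0.1,
                         shared_fraction: float = 1.0,
                         gamma_shape: float = 1.2,
                         seed: int | np.random.Generator | None = None,
                         ) -> tuple[RatePattern, RatePattern]:
    """Two graded sparse patterns representing similar events.

    Both patterns are active on (mostly) the same support — the way two
    episodes at the same place engage the same sparse dentate place
    units — but with independent gamma-distributed rates, so their
    Pearson correlation is set by the shared support and the rate
    variability rather than by identical firing.  With the defaults
    (10% support fully shared, gamma shape 1.2) the pairwise correlation
    is close to 0.5.
    """
    rng = as_rng(seed)
    K = round(support_fraction * N)
    s = round(shared_fraction * K)
    base = rng.choice(N, size=K, replace=False)
    rest = np.setdiff1d(np.arange(N), base)
    other = np.concatenate([base[:s], rng.choice(rest, size=K - s, replace=False)])
    p = np.zeros(N)
    q = np.zeros(N)
    p[base] = rng.gamma(gamma_shape, 1.0, size=K)
    q[other] = rng.gamma(gamma_shape, 1.0, size=K)
    return p, q


def degrade_cue(p: RatePattern, keep_fraction: float = 0.5,
                noise_sd: float = 0.0,
                seed: int | np.random.Generator | None = None) -> RatePattern:
    """A partial, optionally noisy, version of a stored pattern.

    A uniformly chosen ``keep_fraction`` of the *active* units is
    retained and the rest zeroed (so degradation is meaningful for sparse
    patterns); optional zero-mean Gaussian rate noise, truncated at zero,
    is then added to every unit.  ``keep_fraction=1, noise_sd=0`` is the
    identity; ``keep_fraction=0`` returns the all-zero pattern, which is
    a legal (if hopeless) cue rather than an error.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in [0, 1]")
    rng = as_rng(seed)
    out = np.array(p, dtype=float, copy=True)
    active = np.flatnonzero(out > 0)
    n_keep = round(keep_fraction * active.size)
    if active.size:
        drop = rng.choice(active, size=active.size - n_keep, replace=False)
        out[drop] = 0.0
    if noise_sd > 0:
        out = np.maximum(out + rng.normal(0.0, noise_sd, size=out.size), 0.0)
    return out
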