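"""Closed-form calculus of the attractor theory of hippocampal memory.

These are the analytic quantities that constrain every simulation in the
package: the population sparseness of a firing-rate vector, the storage
capacity of an autoassociative network with diluted recurrent connectivity,
the fan-in required of hippocampo-neocortical backprojections, and simple
anatomical connectivity fractions.  All functions are pure and operate on
plain numbers or NumPy arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "CapacitySpec",
    "BackprojectionSpec",
    "sparseness",
    "crc_capacity",
    "backprojection_fanin",
    "connectivity_fraction",
    "round_sigfig",
    "pattern_overlap",
]

#: Default capacity scaling factor k.  The analytic theory gives k only as
#: roughly 0.2-0.3, depending weakly on the rate distribution and the
#: connectivity pattern; 0.235 is the value within that range at which the
#: canonical worked example (C = 12,000 recurrent synapses, a = 0.02)
#: yields the quoted capacity of approximately 36,000 memories.
DEFAULT_K = 0.235


@dataclass(frozen=True)
class CapacitySpec:
    """Parameters of the recurrent-collateral capacity formula.

    Attributes
    ----------
    C_RC : int
        Number of associatively modifiable recurrent-collateral synapses
        per neuron.
    a : float
        Population sparseness of the stored representations, in (0, 1).
    k : float
        Dimensionless scaling factor, roughly 0.2-0.3.
    """

    C_RC: int
    a: float
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.C_RC < 1:
            raise ValueError(f"C_RC must be >= 1, got {self.C_RC}")
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"sparseness a must lie in (0, 1), got {self.a}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


@dataclass(frozen=True)
class BackprojectionSpec:
    """Parameters of the backprojection fan-in requirement.

    Attributes
    ----------
    C_RC : int
        Recurrent-collateral synapses per CA3 neuron.
    a_nc : float
        Sparseness of the neocortical representation, in (0, 1).
    a_CA3 : float
        Sparseness of the CA3 representation, in (0, 1).
    """

    C_RC: int
    a_nc: float
    a_CA3: float

    def __post_init__(self) -> None:
        if self.C_RC < 1:
            raise ValueError(f"C_RC must be >= 1, got {self.C_RC}")
        for name, v in (("a_nc", self.a_nc), ("a_CA3", self.a_CA3)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


def sparseness(r: ArrayLike) -> float:
    """Population sparseness ``a`` of a firing-rate vector.

    .. math:: a = \\left(\\sum_i r_i / N\\right)^2 \\Big/ \\sum_i r_i^2 / N

    ``a`` ranges from ``1/N`` (a single active neuron, a local or
    "grandmother cell" code) to 1.0 (all neurons firing at the same rate).
    For a binary pattern with a fraction ``f`` of units active at a common
    rate, ``a = f`` exactly.  The measure is invariant to rescaling all
    rates by a positive constant.

    Parameters
    ----------
    r : array_like
        Nonnegative firing rates (spikes/s); at least one must be positive.

    Returns
    -------
    float
        Sparseness in ``[1/N, 1]``.

    Raises
    ------
    ValueError
        If the input is empty, contains negative or non-finite rates, or
        is all zero.
    """
    rates = np.asarray(r, dtype=float)
    if rates.ndim != 1 or rates.size == 0:
        raise ValueError("rate pattern must be a nonempty 1-D vector")
    if not np.all(np.isfinite(rates)):
        raise ValueError("rates must be finite")
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    sum_sq = float(np.sum(rates**2))
    if sum_sq == 0.0:
        raise ValueError("sparseness is undefined for an all-zero pattern")
    n = rates.size
    return float((np.sum(rates) / n) ** 2 / (sum_sq / n))


def crc_capacity(spec: CapacitySpec | None = None, *, C_RC: int | None = None,
                 a: float | None = None, k: float = DEFAULT_K) -> float:
    """Maximum number of patterns storable in a diluted autoassociator.

    .. math:: p_{max} \\cong \\frac{C^{RC}}{a \\ln(1/a)} \\, k

    The capacity is proportional to the number of modifiable recurrent
    synapses per neuron and grows as the representation becomes sparser
    (smaller ``a``), which is why sparse codes let the network hold many
    distinct episodic memories.

    Accepts either a :class:`CapacitySpec` or the keyword arguments
    ``C_RC``, ``a``, ``k``.  Returns a real number; callers round.
    """
    if spec is None:
        if C_RC is None or a is None:
            raise ValueError("provide a CapacitySpec or C_RC and a")
        spec = CapacitySpec(C_RC=C_RC, a=a, k=k)
    return spec.k * spec.C_RC / (spec.a * math.log(1.0 / spec.a))


def backprojection_fanin(spec: BackprojectionSpec | None = None, *,
                         C_RC: int | None = None, a_nc: float | None = None,
                         a_CA3: float | None = None) -> float:
    """Backprojection synapses per neocortical neuron required for recall.

    .. math:: C^{HBP} = C^{RC} \\; a_{nc} / a_{CA3}

    For the hippocampally retrieved signal to survive multistage pattern
    association back to the neocortex, each stage must receive roughly this
    many back-projecting synapses per cell.  When neocortical and CA3
    representations are equally sparse the requirement equals ``C_RC``
    itself — hence the conclusion that the return pathway must be
    polysynaptic, with stage sizes growing gradually.
    """
    if spec is None:
        if C_RC is None or a_nc is None or a_CA3 is None:
            raise ValueError("provide a BackprojectionSpec or all keywords")
        spec = BackprojectionSpec(C_RC=C_RC, a_nc=a_nc, a_CA3=a_CA3)
    return spec.C_RC * spec.a_nc / spec.a_CA3


def connectivity_fraction(C_in: int, N_pre: int) -> float:
    """Connectivity of a pathway as a percentage.

    ``100 * C_in / N_pre``: the probability (in %) that a given presynaptic
    neuron contacts a given postsynaptic one, for a pathway with in-degree
    ``C_in`` drawn from a pool of ``N_pre`` presynaptic cells.  With 46
    mossy-fibre inputs per CA3 cell from 10^6 granule cells this is 0.0046%
    (quoted as 0.005% at one significant figure); with 12,000 recurrent
    collaterals from the bilateral pool of 6x10^5 CA3 cells it is 2%.
    """
    if N_pre <= 0:
        raise ValueError(f"N_pre must be positive, got {N_pre}")
    if not 0 <= C_in <= N_pre:
        raise ValueError(f"require 0 <= C_in <= N_pre, got C_in={C_in}, N_pre={N_pre}")
    return 100.0 * C_in / N_pre


def round_sigfig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures, half away from zero.

    Companion to :func:`connectivity_fraction` for reporting anatomy-style
    figures (e.g. 0.0046% -> 0.005%).
    """
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    factor = 10.0 ** (exponent - sig + 1)
    scaled = abs(x) / factor
    return math.copysign(math.floor(scaled + 0.5) * factor, x)


def pattern_overlap(p: ArrayLike, q: ArrayLike) -> float:
    """Pearson correlation between two rate patterns.

    Used throughout the package as the single retrieval-quality measure for
    both graded and binary patterns.  1.0 for identical patterns (up to
    affine scaling), about 0 for unrelated sparse patterns, -1.0 for
    anticorrelated ones.

    Raises
    ------
    ValueError
        If the vectors differ in length or either is constant (the
        correlation is then undefined).
    """
    a = np.asarray(p, dtype=float)
    b = np.asarray(q, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("patterns must be 1-D vectors of equal length")
    sa = a - a.mean()
    sb = b - b.mean()
    na = float(np.sqrt(np.sum(sa**2)))
    nb = float(np.sqrt(np.sum(sb**2)))
    if na == 0.0 or nb == 0.0:
        raise ValueError("correlation is undefined for a constant pattern")
    return float(np.clip(np.dot(sa, sb) / (na * nb), -1.0, 1.0))
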