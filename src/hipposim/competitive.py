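"""Competitive learning: pattern separation, grid-to-place, CA1 recoding.

Three hippocampal computations share the competitive-network machinery in
this module:

* the dentate gyrus as a competitive network that *separates* (or
  orthogonalizes) overlapping input patterns, and in doing so remaps
  periodic grid-cell inputs into single-field place cells;
* the mossy-fibre pathway, whose very sparse connectivity (~46 contacts
  per CA3 cell) acts as a randomizing expansion that decorrelates the
  patterns imposed on CA3 during storage;
* CA1, which recodes the separately-represented subparts of a CA3 event
  into one combined code that serves as an efficient retrieval cue for
  the backprojection pathway.

A competitive network here is a single layer of output units with
unit-norm weight vectors; on each presentation the most activated
("winner") units do a Hebbian update toward the input and are
renormalized, so weight vectors migrate toward input clusters.
Competition is soft: winners fire in proportion to their activation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from hipposim.attractor import ConnectivityMask
from hipposim.metrics import pattern_overlap
from hipposim.patterns import PatternSet, SpatialMap, as_rng

__all__ = [
    "CompetitiveConfig",
    "SeparationReport",
    "PlaceFieldReport",
    "train_competitive",
    "default_grid_to_place_config",
    "respond",
    "count_fields",
    "grid_to_place",
    "place_field_report",
    "mossy_expand",
    "separation_score",
    "ca1_recode",
]


@dataclass
class CompetitiveConfig:
    """Competitive network hyperparameters.

    ``winners`` output units update per presentation; output activity is
    kept at ``out_sparseness`` during inference.  Weight rows are
    renormalized to unit length after every update.  ``init`` selects
    the starting weights: 'uniform' (random positive vectors) or
    'sample' (rows drawn from the training inputs themselves, which
    seeds each unit on a real input cluster).
    """

    n_in: int
    n_out: int
    winners: int = 5
    learn_rate: float = 0.1
    epochs: int = 10
    out_sparseness: float = 0.05
    init: str = "uniform"

    def __post_init__(self) -> None:
        if not 1 <= self.winners <= self.n_out:
            raise ValueError("require 1 <= winners <= n_out")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be positive")
        if self.init not in ("uniform", "sample"):
            raise ValueError("init must be 'uniform' or 'sample'")


@dataclass
class SeparationReport:
    """Mean absolute pairwise correlation before and after a transform."""

    input_correlation: float
    output_correlation: float

    @property
    def reduction(self) -> float:
        return self.input_correlation - self.output_correlation


@dataclass
class PlaceFieldReport:
    """Per-output-unit spatial firing-field statistics."""

    field_counts: list[int]
    area_fractions: list[float]
    peak_locations: list[tuple[int, int]]
    maps: list[SpatialMap] = field(repr=False, default_factory=list)

    @property
    def n_active(self) -> int:
        return len(self.field_counts)

    @property
    def single_field_fraction(self) -> float:
        if not self.field_counts:
            return 0.0
        return sum(c == 1 for c in self.field_counts) / len(self.field_counts)

    @property
    def median_field_count(self) -> float:
        return float(np.median(self.field_counts)) if self.field_counts else 0.0


def train_competitive(inputs: PatternSet | np.ndarray, config: CompetitiveConfig,
                      seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Train a competitive network and return (n_out, n_in) weights.

    Each epoch presents the inputs in a random order; for each input the
    ``config.winners`` most activated units move toward it (soft
    competition: the update is proportional to the winner's activation)
    and are renormalized to unit length.

    Raises
    ------
    ValueError
        If any input is negative or the input set is entirely zero.
    """
    X = inputs.patterns if isinstance(inputs, PatternSet) else np.atleast_2d(inputs)
    if X.shape[1] != config.n_in:
        raise ValueError(f"input length {X.shape[1]} != n_in {config.n_in}")
    if np.any(X < 0):
        raise ValueError("inputs must be nonnegative")
    if not X.any():
        raise ValueError("input set is all zero")
    rng = as_rng(seed)
    if config.init == "sample":
        idx = rng.choice(len(X), size=config.n_out, replace=len(X) < config.n_out)
        W = X[idx].astype(float).copy()
        W[~W.any(axis=1)] = rng.uniform(0.0, 1.0, config.n_in)
    else:
        W = rng.uniform(0.0, 1.0, size=(config.n_out, config.n_in))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    for _ in range(config.epochs):
        for idx in rng.permutation(len(X)):
            x = X[idx]
            nx = np.linalg.norm(x)
            if nx == 0:
                continue
            h = W @ x
            order = np.argsort(-h, kind="stable")
            win = order[:config.winners]
            act = np.maximum(h[win], 0.0)
            if act.max() > 0:
                act = act / act.max()
            else:
                act = np.ones(win.size)
            W[win] += config.learn_rate * act[:, None] * (x / nx)[None, :]
            W[win] /= np.linalg.norm(W[win], axis=1, keepdims=True)
    return W


def default_grid_to_place_config(n_in: int) -> CompetitiveConfig:
    """Frozen hyperparameters of the canonical grid-to-place run.

    Hard (single-winner) competition with input-sample initialization
    and a one-winner-per-location readout: 200 output units tile the
    environment, and each trained unit ends up owning one compact patch
    of it — the place-field regime.  Chosen by pilot search and kept
    fixed; only the input size varies with the grid population.
    """
    return CompetitiveConfig(n_in=n_in, n_out=200, winners=1, learn_rate=0.2,
                             epochs=5, out_sparseness=1.0 / 200, init="sample")


def respond(weights: np.ndarray, x: np.ndarray,
            out_sparseness: float | None = None, n_active: int | None = None,
            ) -> np.ndarray:
    """Inference pass: graded activity of the top output units.

    Activations are ``weights @ x``; the top ``ceil(a * n_out)`` (or
    ``n_active``) units keep their graded positive activations, the rest
    are silenced.  A zero input yields zero output.
    """
    x = np.asarray(x, dtype=float)
    h = weights @ x
    if not x.any() or h.max() <= 0:
        return np.zeros(weights.shape[0])
    if n_active is None:
        a = 0.05 if out_sparseness is None else out_sparseness
        n_active = max(1, math.ceil(a * weights.shape[0]))
    order = np.argsort(-h, kind="stable")
    r = np.zeros(weights.shape[0])
    win = order[:n_active]
    r[win] = np.maximum(h[win], 0.0)
    return r


def count_fields(spatial: SpatialMap, threshold: float = 0.5,
                 min_cells: int = 3,
                 smooth_sigma: float = 1.0) -> tuple[int, float, tuple[int, int]]:
    """Number of distinct firing fields, suprathreshold area fraction and
    peak location of a rate map.

    The map is Gaussian-smoothed (``smooth_sigma`` lattice cells, the
    usual preprocessing of place-field maps); a field is a connected
    component of the region exceeding ``threshold`` times the smoothed
    peak, of at least ``min_cells`` lattice cells (smaller islands are
    speckle, not fields).
    """
    v = spatial.values
    if v.max() <= 0:
        return 0, 0.0, (0, 0)
    if smooth_sigma > 0:
        v = ndimage.gaussian_filter(v, smooth_sigma)
    above = v >= threshold * v.max()
    labelled, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(v), labelled, index=range(1, n + 1))
    n_fields = int(np.sum(np.asarray(sizes) >= min_cells))
    area = float(above.sum() / above.size)
    peak = np.unravel_index(np.argmax(v), v.shape)
    return n_fields, area, (int(peak[0]), int(peak[1]))


def grid_to_place(grid_maps: list[SpatialMap], config: CompetitiveConfig,
                  seed: int | np.random.Generator | None = None,
                  active_threshold: float = 1e-6,
                  ) -> tuple[PlaceFieldReport, np.ndarray]:
    """Transform periodic grid-cell maps into place-cell-like maps.

    Every lattice location provides one training vector (the activity of
    all grid cells at that location); a competitive network learns on
    these vectors, after which each output unit's response across the
    lattice is its spatial map.  With at least two grid frequencies
    represented, trained outputs typically develop a single compact
    firing field — the grid-to-place transformation.

    Returns the field-statistics report (over output units whose peak
    response exceeds ``active_threshold``) and the trained weights.
    """
    if len({m.values.shape for m in grid_maps}) != 1:
        raise ValueError("all grid maps must share one lattice")
    if len({m.values.tobytes() for m in grid_maps}) < 2:
        raise ValueError(
            "degenerate grid input: a single frequency and phase carries no "
            "location information; provide maps with distinct phases and at "
            "least two frequencies")
    ny, nx = grid_maps[0].values.shape
    X = np.stack([m.values.ravel() for m in grid_maps], axis=1)  # (loc, cells)
    W = train_competitive(X, config, seed=seed)
    report = place_field_report(W, grid_maps, (ny, nx),
                                config.out_sparseness, active_threshold)
    return report, W


def place_field_report(W: np.ndarray, grid_maps: list[SpatialMap],
                       shape: tuple[int, int], out_sparseness: float,
                       active_threshold: float = 1e-6) -> PlaceFieldReport:
    """Spatial maps and field statistics of a (possibly untrained)
    competitive output layer driven by grid-cell maps."""
    ny, nx = shape
    X = np.stack([m.values.ravel() for m in grid_maps], axis=1)
    n_active = max(1, math.ceil(out_sparseness * W.shape[0]))
    H = X @ W.T  # (loc, out)
    # per-location competition: silence all but the top outputs
    out = np.zeros_like(H)
    order = np.argsort(-H, axis=1, kind="stable")
    rows = np.arange(H.shape[0])[:, None]
    keep = order[:, :n_active]
    out[rows, keep] = np.maximum(H[rows, keep], 0.0)
    counts, areas, peaks, maps = [], [], [], []
    extent = grid_maps[0].extent
    for u in range(W.shape[0]):
        v = out[:, u].reshape(ny, nx)
        if v.max() <= active_threshold:
            continue
        m = SpatialMap(values=v, extent=extent)
        nf, area, peak = count_fields(m)
        counts.append(nf)
        areas.append(area)
        peaks.append(peak)
        maps.append(m)
    return PlaceFieldReport(field_counts=counts, area_fractions=areas,
                            peak_locations=peaks, maps=maps)


def mossy_expand(dg_pattern: np.ndarray, mask: ConnectivityMask,
                 a_CA3: float, rate_hi: float = 1.0) -> np.ndarray:
    """Randomizing expansion of a dentate pattern into CA3.

    Each CA3 unit sums the rates of its few mossy-fibre afferents; a
    threshold (feedforward inhibition) then lets exactly
    ``ceil(a_CA3 * N_CA3)`` units fire, ties broken by unit index.  The
    output is binary at ``rate_hi``: with so few afferents per cell, the
    identity of the winning units is essentially a random function of
    the wiring, which decorrelates even similar dentate patterns.
    Deterministic given pattern and mask: tied drives are broken by a
    pseudo-random order keyed to the mask wiring (not by unit index,
    which would correlate the outputs of unrelated inputs).
    """
    dg = np.asarray(dg_pattern, dtype=float)
    drive = dg[mask.pre].sum(axis=1)
    tie_rng = np.random.default_rng(zlib.crc32(mask.pre.tobytes()))
    drive = drive + tie_rng.uniform(0.0, 1e-9, size=mask.N)
    k = math.ceil(a_CA3 * mask.N)
    order = np.argsort(-drive, kind="stable")
    out = np.zeros(mask.N)
    out[order[:k]] = rate_hi
    return out


def separation_score(inputs: PatternSet | np.ndarray,
                     outputs: PatternSet | np.ndarray) -> SeparationReport:
    """Mean absolute pairwise correlation before vs after a transform.

    Pattern separation is the defining dentate computation: the output
    patterns should be less correlated with each other than the input
    patterns were.  Constant patterns are skipped pairwise (their
    correlation is undefined).
    """

    def mean_abs_corr(M: np.ndarray) -> float:
        vals = []
        for i in range(len(M)):
            for j in range(i + 1, len(M)):
                if M[i].std() == 0 or M[j].std() == 0:
                    continue
                vals.append(abs(pattern_overlap(M[i], M[j])))
        return float(np.mean(vals)) if vals else 0.0

    X = inputs.patterns if isinstance(inputs, PatternSet) else np.atleast_2d(inputs)
    Y = outputs.patterns if isinstance(outputs, PatternSet) else np.atleast_2d(outputs)
    return SeparationReport(input_correlation=mean_abs_corr(X),
                            output_correlation=mean_abs_corr(Y))


def ca1_recode(events: list[dict[str, np.ndarray]], config: CompetitiveConfig,
               seed: int | np.random.Generator | None = None) -> dict:
    """Combine the subparts of CA3 event patterns into single CA1 codes.

    ``events`` is a list of mappings from subpart name (e.g. 'object',
    'place') to the rate pattern of that subpart; the full CA3 event is
    their concatenation.  A competitive network is trained on the full
    events; the resulting CA1 code for each event is the network's
    response to it.  The returned dict carries the trained weights, the
    per-event CA1 codes, and for every subpart cue (the event with all
    other subparts zeroed) the overlap between its CA1 response and the
    full-event code — high overlaps mean any single subpart retrieves
    the combined representation.
    """
    if not events:
        raise ValueError("need at least one event")
    part_names = list(events[0].keys())
    full = np.vstack([np.concatenate([e[p] for p in part_names]) for e in events])
    W = train_competitive(full, config, seed=seed)
    codes = np.vstack([respond(W, f, config.out_sparseness) for f in full])
    cue_overlaps: list[dict[str, float]] = []
    for i, e in enumerate(events):
        row: dict[str, float] = {}
        for p in part_names:
            cue = np.concatenate([e[q] if q == p else np.zeros_like(e[q])
                                  for q in part_names])
            resp = respond(W, cue, config.out_sparseness)
            if resp.std() == 0 or codes[i].std() == 0:
                row[p] = 0.0
            else:
                row[p] = pattern_overlap(resp, codes[i])
        cue_overlaps.append(row)
    return {"weights": W, "codes": codes, "cue_overlaps": cue_overlaps,
            "part_names": part_names}
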