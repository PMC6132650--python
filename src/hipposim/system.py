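"""End-to-end hippocampo-cortical episodic memory model.

The model wires the package's components into the full storage/recall
loop: two neocortical banks (object and space) converge through the
parahippocampal gyrus (PHG) and entorhinal cortex (EC) onto the dentate
gyrus (DG) and CA3; CA3 stores each event in its recurrent collaterals;
CA1 recodes the CA3 event; and a multistage backprojection chain
(CA1 -> EC -> PHG -> neocortex) reinstates the neocortical activity
during recall.

Routing follows the two-pathway theory:

* **storage** - the sparse, strong mossy-fibre projection from DG
  dictates the CA3 pattern (a near-random, well-separated code), while
  acetylcholine reduces the efficacy of the recurrent collaterals
  (``ach_gain``) so that previously stored attractors do not contaminate
  the new pattern; the perforant path and the backprojection synapses
  are associatively modified in passing.
* **recall** - the mossy fibres are not needed; the perforant path
  delivers the (partial) cue to CA3, the recurrent collaterals complete
  the pattern, and the chain CA3 -> CA1 -> EC -> PHG -> neocortex
  reinstates, stage by stage via the learned pattern associations, the
  activity present when the event was stored.

All feedforward pathways are fixed sparse random projections with
winner-take-all sparsification; all learned pathways use the same
zero-mean covariance rule as the CA3 recurrent collaterals.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from hipposim.attractor import (
    AttractorConfig,
    ConnectivityMask,
    build_mask,
    build_projection_mask,
    recall,
)
from hipposim.metrics import backprojection_fanin, pattern_overlap
from hipposim.patterns import (
    AnatomyConfig,
    EpisodicEvent,
    PatternSet,
    as_rng,
    make_sparse_binary,
)

__all__ = [
    "StageSizes",
    "AblationSpec",
    "HippocampalModel",
    "StorageReport",
    "RecallReport",
    "build_model",
    "store_event",
    "recall_event",
    "object_cue",
    "place_cue",
    "ablation_experiment",
]


@dataclass(frozen=True)
class StageSizes:
    """Population sizes of the processing stages at desk scale.

    Defaults implement the convergence/divergence funnel with a
    geometric factor of 2 around CA3: neocortex (two banks) -> PHG ->
    EC -> CA3, and back out CA3 -> CA1 -> EC -> PHG -> neocortex.
    """

    n_nc_object: int = 2400
    n_nc_space: int = 2400
    n_phg: int = 2400
    n_ec: int = 1200
    n_ca1: int = 600

    @property
    def n_nc(self) -> int:
        return self.n_nc_object + self.n_nc_space


@dataclass(frozen=True)
class AblationSpec:
    """Pathway knockouts for the theory's lesion predictions."""

    mossy_off_at_storage: bool = False
    mossy_off_at_recall: bool = False
    pp_off_at_recall: bool = False

    def label(self) -> str:
        parts = [name for name, on in (
            ("mossy_off_storage", self.mossy_off_at_storage),
            ("mossy_off_recall", self.mossy_off_at_recall),
            ("pp_off_recall", self.pp_off_at_recall)) if on]
        return "+".join(parts) if parts else "intact"


@dataclass
class _Projection:
    """Masked in-degree pathway: fixed random and/or learned weights."""

    mask: ConnectivityMask
    w_fixed: np.ndarray | None = None  # (N_post, C)
    w_learned: np.ndarray | None = field(default=None, repr=False)

    def drive(self, r_pre: np.ndarray, learned: bool = False,
              fixed: bool = True) -> np.ndarray:
        x = r_pre[self.mask.pre]  # (N_post, C)
        h = np.zeros(self.mask.N)
        if fixed and self.w_fixed is not None:
            h = h + (self.w_fixed * x).sum(axis=1)
        if learned and self.w_learned is not None:
            h = h + (self.w_learned * x).sum(axis=1)
        return h

    def learn(self, r_post: np.ndarray, r_pre: np.ndarray,
              rate: float = 1.0) -> None:
        """Covariance hetero-association on the masked synapses."""
        if self.w_learned is None:
            self.w_learned = np.zeros_like(self.mask.pre, dtype=float)
        d_post = r_post - r_post.mean()
        d_pre = r_pre - r_pre.mean()
        self.w_learned += (rate / self.mask.C) * d_post[:, None] * d_pre[self.mask.pre]


def _topk(h: np.ndarray, k: int, rate_hi: float = 1.0,
          tie_key: int = 0) -> np.ndarray:
    """Winner-take-all sparsification with a keyed pseudo-random
    tie-break.  Winners fire at the common saturated rate: binary stage
    states keep the covariance-rule pattern associations exact, so the
    chain's fidelity is limited by ranking errors only.  A silent input
    (no positive drive) yields a silent output."""
    if h.max() <= 0:
        return np.zeros(h.size)
    jit = np.random.default_rng(tie_key).uniform(0.0, 1e-9, h.size)
    order = np.argsort(-(h + jit), kind="stable")
    win = order[:k]
    win = win[h[win] > 0]  # never recruit undriven units
    r = np.zeros(h.size)
    r[win] = rate_hi
    return r


@dataclass
class HippocampalModel:
    """All populations, pathways and weights of the circuit."""

    anatomy: AnatomyConfig
    sizes: StageSizes
    a: float  # representation sparseness at the cortical stages
    a_dg: float
    a_ca3: float
    seed: int
    mode: str = "storage"
    ach_gain: float = 0.2  # recurrent-collateral efficacy during storage
    g_pp_storage: float = 0.3  # weak perforant-path drive at storage
    place_stride: float = 15.0  # space-bank units per unit of distance

    # pathways (populated by build_model); the forward funnel keeps the
    # object and spatial streams segregated (perirhinal -> lateral EC and
    # parahippocampal -> medial EC) until they converge on DG and CA3
    fwd_obj_peri: _Projection | None = None
    fwd_sp_para: _Projection | None = None
    fwd_peri_lec: _Projection | None = None
    fwd_para_mec: _Projection | None = None
    fwd_ec_dg: _Projection | None = None
    mossy: _Projection | None = None
    pp: _Projection | None = None
    schaffer: _Projection | None = None
    bp_ca1_ec: _Projection | None = None
    bp_ec_phg: _Projection | None = None
    bp_phg_nc: _Projection | None = None
    rc_weights: np.ndarray | None = field(default=None, repr=False)
    rc_mask: ConnectivityMask | None = None

    # bookkeeping for evaluation
    stored_states: list = field(default_factory=list, repr=False)
    #: per-event perforant-path self-drive (top-k mean) recorded at
    #: storage; recall uses it to set the CA3 inhibitory floor that
    #: rejects unfamiliar cues
    pp_drive_calibration: list = field(default_factory=list, repr=False)
    _encodings: dict = field(default_factory=dict, repr=False)

    # -- pattern banks -----------------------------------------------------
    def encode_object(self, object_id: str) -> np.ndarray:
        key = ("obj", object_id)
        if key not in self._encodings:
            s = zlib.crc32(f"{self.seed}|obj|{object_id}".encode()) % 2**31
            self._encodings[key] = make_sparse_binary(
                self.sizes.n_nc_object, self.a, seed=s)
        return self._encodings[key]

    def encode_place(self, event: EpisodicEvent) -> np.ndarray:
        """Sliding-window code for continuous space: the active set is a
        contiguous window of units whose start shifts with the place, so
        nearby places share most of their units (the overlapping-field
        structure that makes spatial memories mutually similar and puts
        the burden of separating them on the dentate/mossy pathway).
        Discrete view indices use the same code at the view's position.
        """
        where = event.place if event.place is not None else float(event.view)
        key = ("space", where)
        if key not in self._encodings:
            n = self.sizes.n_nc_space
            k = max(1, math.ceil(self.a * n))
            start = int(round(where * self.place_stride)) % n
            idx = (start + np.arange(k)) % n
            code = np.zeros(n)
            code[idx] = 30.0
            self._encodings[key] = code
        return self._encodings[key]

    def neocortex_pattern(self, event: EpisodicEvent) -> np.ndarray:
        return np.concatenate([self.encode_object(event.object_id),
                               self.encode_place(event)])

    # -- forward pass ------------------------------------------------------
    def forward_to_ec(self, nc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Two-stream forward funnel: the object bank drives the
        perirhinal half of PHG and then lateral EC; the space bank
        drives the parahippocampal half and medial EC.  A cue missing
        one bank leaves the corresponding stream silent instead of
        corrupting both."""
        n_obj = self.sizes.n_nc_object
        half_phg = self.sizes.n_phg // 2
        half_ec = self.sizes.n_ec // 2
        k_phg = math.ceil(self.a * half_phg)
        k_ec = math.ceil(self.a * half_ec)
        peri = _topk(self.fwd_obj_peri.drive(nc[:n_obj]), k_phg, tie_key=11)
        para = _topk(self.fwd_sp_para.drive(nc[n_obj:]), k_phg, tie_key=14)
        lec = _topk(self.fwd_peri_lec.drive(peri), k_ec, tie_key=12)
        mec = _topk(self.fwd_para_mec.drive(para), k_ec, tie_key=15)
        return np.concatenate([peri, para]), np.concatenate([lec, mec])

    def dg_pattern(self, ec: np.ndarray) -> np.ndarray:
        k_dg = math.ceil(self.a_dg * self.anatomy.scaled_N_DG)
        return _topk(self.fwd_ec_dg.drive(ec), k_dg, tie_key=13)


@dataclass
class StorageReport:
    """Stage activity recorded while one event was stored."""

    states: dict
    event: EpisodicEvent


@dataclass
class RecallReport:
    """Per-stage overlap between reinstated and originally stored activity."""

    overlaps: dict  # stage name -> overlap with the cued event's stored state
    best_event_index: int | None
    success: bool
    flagged_empty_cue: bool = False


def build_model(anatomy: AnatomyConfig | None = None,
                sizes: StageSizes | None = None,
                seed: int = 0, a: float = 0.05, a_dg: float = 0.05,
                a_ca3: float = 0.1, ach_gain: float = 0.2) -> HippocampalModel:
    """Construct all masks, fixed projections and zeroed learned weights.

    The mossy in-degree, recurrent in-degree and perforant-path
    in-degree come from the (scaled) anatomy; the backprojection
    in-degree per stage follows the fan-in requirement
    ``C_HBP = C_RC * a_nc / a_CA3`` (equal sparsenesses here, so
    C_HBP = C_RC), capped at 40% of the presynaptic pool.
    Deterministic given the seed.
    """
    anatomy = anatomy or AnatomyConfig(scale=1000.0)
    sizes = sizes or StageSizes()
    n_dg, n_ca3 = anatomy.scaled_N_DG, anatomy.scaled_N_CA3
    if min(sizes.n_nc_object, sizes.n_nc_space, sizes.n_phg, sizes.n_ec,
           sizes.n_ca1, n_dg, n_ca3) < 50:
        raise ValueError("every stage needs at least 50 units")
    if anatomy.scaled_C_mf < 3:
        raise ValueError("scaled mossy in-degree must be >= 3")
    rng = as_rng(seed)

    def proj(n_post: int, n_pre: int, C: int, fixed: bool) -> _Projection:
        C = min(C, int(0.4 * n_pre))
        mask = build_projection_mask(n_post, n_pre, C, rng)
        w = rng.uniform(0.0, 1.0, size=mask.pre.shape) if fixed else None
        return _Projection(mask=mask, w_fixed=w)

    C_fwd = anatomy.scaled_C_RC  # one in-degree for the fixed forward funnels
    # the fan-in requirement is a lower bound on the backprojection
    # in-degree; at desk scale the finite-size drive noise makes more
    # synapses strictly better, so each stage uses the dilution cap
    # (40% of its presynaptic pool) but never less than C_HBP
    c_hbp_min = round(backprojection_fanin(C_RC=anatomy.scaled_C_RC, a_nc=a, a_CA3=a))

    def c_bp(n_pre: int) -> int:
        return max(c_hbp_min, int(0.4 * n_pre))
    model = HippocampalModel(
        anatomy=anatomy, sizes=sizes, a=a, a_dg=a_dg, a_ca3=a_ca3,
        seed=seed if isinstance(seed, int) else 0, ach_gain=ach_gain,
        fwd_obj_peri=proj(sizes.n_phg // 2, sizes.n_nc_object, C_fwd, True),
        fwd_sp_para=proj(sizes.n_phg // 2, sizes.n_nc_space, C_fwd, True),
        fwd_peri_lec=proj(sizes.n_ec // 2, sizes.n_phg // 2, C_fwd, True),
        fwd_para_mec=proj(sizes.n_ec // 2, sizes.n_phg // 2, C_fwd, True),
        fwd_ec_dg=proj(n_dg, sizes.n_ec, C_fwd, True),
        mossy=proj(n_ca3, n_dg, anatomy.scaled_C_mf, True),
        pp=proj(n_ca3, sizes.n_ec, anatomy.scaled_C_pp, True),
        schaffer=proj(sizes.n_ca1, n_ca3,
                      min(anatomy.scaled_C_RC, int(0.4 * n_ca3)), False),
        bp_ca1_ec=proj(sizes.n_ec, sizes.n_ca1, c_bp(sizes.n_ca1), False),
        bp_ec_phg=proj(sizes.n_phg, sizes.n_ec, c_bp(sizes.n_ec), False),
        bp_phg_nc=proj(sizes.n_nc, sizes.n_phg, c_bp(sizes.n_phg), False),
        rc_mask=build_mask(n_ca3, anatomy.scaled_C_RC, rng),
        rc_weights=np.zeros((n_ca3, n_ca3)),
    )
    return model


def _ca3_storage_state(model: HippocampalModel, dg: np.ndarray,
                       ec: np.ndarray, mossy_on: bool) -> np.ndarray:
    """CA3 pattern imposed during storage.

    Drives are peak-normalized so the gains are interpretable: the
    mossy drive (gain 5) dominates the weak perforant-path drive (gain
    ``g_pp_storage``) and the ACh-suppressed recurrent drive (gain
    ``ach_gain``).  Three synchronous iterations let the recurrent
    contribution express itself exactly to the extent ACh allows.
    """
    n_ca3 = model.anatomy.scaled_N_CA3
    k = math.ceil(model.a_ca3 * n_ca3)

    def norm(h):
        m = np.abs(h).max()
        return h / m if m > 0 else h

    h_mf = norm(model.mossy.drive(dg)) if mossy_on else np.zeros(n_ca3)
    h_pp = norm(model.pp.drive(ec, learned=False))
    r = np.zeros(n_ca3)
    tie = zlib.crc32(dg.tobytes()) % 2**31
    for _ in range(3):
        h_rc = norm(model.rc_weights @ r) if r.any() else np.zeros(n_ca3)
        h = 5.0 * h_mf + model.g_pp_storage * h_pp + model.ach_gain * h_rc
        r = _topk(h, k, tie_key=tie)
    return r


def _ca1_state(model: HippocampalModel, ca3: np.ndarray) -> np.ndarray:
    """CA1 response to a CA3 pattern: fixed recoding substrate plus the
    learned Schaffer association."""
    rng = np.random.default_rng(model.seed + 7919)
    W = rng.uniform(0.0, 1.0, size=(model.sizes.n_ca1, ca3.size))
    h = W @ ca3 / max(ca3.sum(), 1e-12)
    h = h + model.schaffer.drive(ca3, fixed=False, learned=True)
    k_ca1 = math.ceil(model.a * model.sizes.n_ca1)
    return _topk(h, k_ca1, tie_key=21)


def store_event(model: HippocampalModel, event: EpisodicEvent,
                ablation: AblationSpec | None = None) -> StorageReport:
    """Run the storage routing for one event and modify all learned
    pathways.

    Raises
    ------
    ValueError
        If the model is in recall mode.
    """
    if model.mode != "storage":
        raise ValueError("model must be in storage mode to store events")
    ablation = ablation or AblationSpec()
    nc = model.neocortex_pattern(event)
    phg, ec = model.forward_to_ec(nc)
    dg = model.dg_pattern(ec)
    ca3 = _ca3_storage_state(model, dg, ec,
                             mossy_on=not ablation.mossy_off_at_storage)
    # CA3-CA3 covariance learning stores the event as an attractor
    d = ca3 - ca3.mean()
    model.rc_weights += (1.0 / model.rc_mask.C) * np.outer(d, d) * model.rc_mask.dense()
    np.fill_diagonal(model.rc_weights, 0.0)
    # perforant path learns to map the EC cue onto the CA3 pattern
    model.pp.learn(ca3, ec)
    h_self = model.pp.drive(ec, learned=True, fixed=False)
    k_ca3 = math.ceil(model.a_ca3 * model.anatomy.scaled_N_CA3)
    model.pp_drive_calibration.append(
        float(np.sort(h_self)[::-1][:k_ca3].mean()))
    # Schaffer collaterals map CA3 to CA1
    ca1 = _ca1_state(model, ca3)
    model.schaffer.learn(ca1, ca3)
    # backprojections hetero-associate descending activity with the
    # concurrent forward-driven activity at each stage
    model.bp_ca1_ec.learn(ec, ca1)
    model.bp_ec_phg.learn(phg, ec)
    model.bp_phg_nc.learn(nc, phg)
    states = {"nc": nc, "phg": phg, "ec": ec, "dg": dg, "ca3": ca3, "ca1": ca1}
    model.stored_states.append({"event": event, "states": states})
    return StorageReport(states=states, event=event)


def recall_event(model: HippocampalModel, cue_nc: np.ndarray,
                 ablation: AblationSpec | None = None,
                 target_index: int | None = None,
                 recall_steps: int = 15,
                 novelty_threshold: float = 0.3) -> RecallReport:
    """Run the recall routing from a partial neocortical cue.

    The cue passes forward to EC; the learned perforant path maps it
    into CA3; the recurrent collaterals complete the pattern; CA1, EC,
    PHG and the neocortex are then reinstated through the learned
    pattern associations.  Per-stage overlaps are reported against the
    stored states of the cued event (``target_index``; default: the
    stored event whose completed CA3 state matches best).

    An all-zero cue yields a flagged failure report, not an exception.
    """
    if not model.stored_states:
        raise ValueError("recall requires at least one stored event")
    ablation = ablation or AblationSpec()
    n_ca3 = model.anatomy.scaled_N_CA3
    if not np.asarray(cue_nc).any():
        return RecallReport(overlaps={}, best_event_index=None,
                            success=False, flagged_empty_cue=True)
    phg, ec = model.forward_to_ec(cue_nc)
    # recall mode: the mossy pathway is not used (and ablating it
    # therefore changes nothing); pp delivers the cue
    k_ca3 = math.ceil(model.a_ca3 * n_ca3)
    if ablation.pp_off_at_recall:
        h_pp = np.zeros(n_ca3)
    else:
        h_pp = model.pp.drive(ec, learned=True, fixed=False)
    # inhibitory floor calibrated to the stored events' own pp drive:
    # an unfamiliar cue produces only weak, interference-level drive
    # and leaves CA3 silent instead of completing to a stored attractor
    theta = novelty_threshold * float(np.mean(model.pp_drive_calibration))
    h_pp = np.where(h_pp >= theta, h_pp, 0.0)
    # ignition requirement: completion proceeds only when the cue
    # excites a substantial part of some stored pattern; a handful of
    # above-floor units (as an unfamiliar cue produces) cannot ignite
    # the recurrent dynamics
    if int((h_pp > 0).sum()) < k_ca3 // 2:
        h_pp = np.zeros(n_ca3)
    ca3_init = _topk(h_pp, k_ca3, tie_key=31) if h_pp.any() else np.zeros(n_ca3)
    cfg = AttractorConfig(a=model.a_ca3, recall_steps=recall_steps)
    stored_ca3 = PatternSet(
        np.vstack([s["states"]["ca3"] for s in model.stored_states]),
        labels=[str(i) for i in range(len(model.stored_states))])
    res = recall(model.rc_weights, ca3_init, cfg, stored=stored_ca3)
    ca3 = res.final
    ca1 = _ca1_state(model, ca3) if ca3.any() else np.zeros(model.sizes.n_ca1)
    k_ec = math.ceil(model.a * model.sizes.n_ec)
    ec_back = _topk(model.bp_ca1_ec.drive(ca1, learned=True, fixed=False),
                    k_ec, tie_key=41)
    k_phg = math.ceil(model.a * model.sizes.n_phg)
    phg_back = _topk(model.bp_ec_phg.drive(ec_back, learned=True, fixed=False),
                     k_phg, tie_key=42)
    h_nc = model.bp_phg_nc.drive(phg_back, learned=True, fixed=False)
    n_obj = model.sizes.n_nc_object
    k_obj = math.ceil(model.a * n_obj)
    k_sp = math.ceil(model.a * model.sizes.n_nc_space)
    nc_back = np.concatenate([_topk(h_nc[:n_obj], k_obj, tie_key=43),
                              _topk(h_nc[n_obj:], k_sp, tie_key=44)])
    if target_index is None:
        target_index = int(res.best_label) if res.best_label is not None else 0
    tgt = model.stored_states[target_index]["states"]

    def ov(x, y):
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return pattern_overlap(x, y)

    overlaps = {
        "ca3": ov(ca3, tgt["ca3"]),
        "ca1": ov(ca1, tgt["ca1"]),
        "ec": ov(ec_back, tgt["ec"]),
        "phg": ov(phg_back, tgt["phg"]),
        "nc_object": ov(nc_back[:n_obj], tgt["nc"][:n_obj]),
        "nc_space": ov(nc_back[n_obj:], tgt["nc"][n_obj:]),
    }
    success = overlaps["nc_object"] >= 0.9 and overlaps["nc_space"] >= 0.9
    return RecallReport(overlaps=overlaps, best_event_index=target_index,
                        success=success)


def object_cue(model: HippocampalModel, event: EpisodicEvent) -> np.ndarray:
    """Neocortical cue containing only the object part of an event."""
    return np.concatenate([model.encode_object(event.object_id),
                           np.zeros(model.sizes.n_nc_space)])


def place_cue(model: HippocampalModel, event: EpisodicEvent) -> np.ndarray:
    """Neocortical cue containing only the spatial part of an event."""
    return np.concatenate([np.zeros(model.sizes.n_nc_object),
                           model.encode_place(event)])


def ablation_experiment(events: list[EpisodicEvent],
                        conditions: list[AblationSpec] | None = None,
                        seeds: list[int] | None = None,
                        cue_kind: str = "object",
                        **model_kwargs) -> list[dict]:
    """Store-and-recall under matched seeds for each ablation condition.

    For every (seed, condition) pair a fresh model is built with the
    same seed, the same events are stored under the condition's storage
    ablations, and every event is recalled from its partial cue under
    the condition's recall ablations.  Returns one row per pair with
    the mean neocortical reinstatement overlap (the mean of the object-
    and space-bank overlaps).
    """
    conditions = conditions or [
        AblationSpec(),
        AblationSpec(mossy_off_at_recall=True),
        AblationSpec(mossy_off_at_storage=True),
        AblationSpec(pp_off_at_recall=True),
    ]
    seeds = seeds if seeds is not None else [0]
    rows = []
    for seed in seeds:
        for cond in conditions:
            model = build_model(seed=seed, **model_kwargs)
            for ev in events:
                store_event(model, ev, ablation=cond)
            model.mode = "recall"
            mean_ov = []
            for i, ev in enumerate(events):
                cue = (object_cue(model, ev) if cue_kind == "object"
                       else place_cue(model, ev))
                rep = recall_event(model, cue, ablation=cond, target_index=i)
                mean_ov.append(0.5 * (rep.overlaps["nc_object"]
                                      + rep.overlaps["nc_space"]))
            rows.append({"seed": seed, "condition": cond.label(),
                         "mean_nc_overlap": float(np.mean(mean_ov)),
                         "n_events": len(events)})
    return rows
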