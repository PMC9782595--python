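"""Damage protocols: sequential targeted attack / random failure on
aggregated cultures, and the diametral-cut + recovery timeline on
homogeneous cultures.

Protocol I mirrors the chained-deletion experiment: record spontaneous
activity, infer the effective network, pick a target (highest betweenness
centrality, highest degree, or uniformly at random), disconnect it,
record again, and let the culture recover homeostatically before the next
step.  Global efficiency is always computed with the step's deleted node
excluded from both the pre- and post-damage networks so the two are
size-matched.

Protocol II cuts the homogeneous disc in half with a band-shaped wound,
partitions ROIs into the two disc halves A and B, the disc-rim contour C
and the off-disc surroundings S, and follows per-region burst counts and
inter-region effective-connection counts through a staged recovery
schedule (before, after, 2 h, 6 h, 24 h, 3 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bursts as bursts_mod
from . import metrics as metrics_mod
from .calcium import binarize_traces
from .connectivity import EffectiveNetwork, infer_effective_network
from .culture import (
    CultureModel,
    apply_cut,
    apply_node_removal,
    homeostatic_recovery,
    render_fluorescence,
    simulate_activity,
)

__all__ = [
    "DamageStep",
    "DamageRecord",
    "RegionPartition",
    "RegionInteraction",
    "select_target",
    "geff_excluding_deleted",
    "run_damage_sequence",
    "partition_regions",
    "region_interaction_matrix",
    "recovery_timeline",
]

SCHEMES = ("bc_attack", "degree_attack", "random")
REGIONS = ("A", "B", "C", "S")
DEFAULT_STAGES = ("before", "after", "2h", "6h", "24h", "3d")
#: incremental homeostatic strength applied between consecutive post-cut
#: stages (cumulative restoration grows stage by stage)
DEFAULT_STAGE_STRENGTHS = {"2h": 0.3, "6h": 0.3, "24h": 0.3, "3d": 0.3}


def _child_seeds(seed: int, n: int) -> list[int]:
    """Split one seed into n independent sub-seeds (each < 2**31)."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s >> 1) for s in state]


@dataclass
class DamageStep:
    index: int
    scheme: str
    target: int
    phi: float
    a_pre: float
    a_post: float
    geff_pre: float
    geff_post: float
    q_pre: float
    q_post: float
    n_bursts_pre: int
    n_bursts_post: int
    flagged: bool = False  # activity extinct (no measurable bursts)


@dataclass
class DamageRecord:
    scheme: str
    seed: int
    steps: list[DamageStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


@dataclass
class RegionPartition:
    """ROI labels over {A, B, C, S, wound} plus label fractions."""

    labels: np.ndarray

    @property
    def fractions(self) -> dict[str, float]:
        n = self.labels.size
        return {
            lab: float((self.labels == lab).sum()) / n
            for lab in np.unique(self.labels)
        }

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def region_map(self, include_wound: bool = False) -> dict[str, np.ndarray]:
        labs = REGIONS + (("wound",) if include_wound else ())
        return {
            lab: self.indices(lab) for lab in labs if (self.labels == lab).any()
        }


@dataclass
class RegionInteraction:
    """Counts of effective connections between regions at one stage."""

    counts: pd.DataFrame  # symmetric (direction-folded), diagonal = within
    directed: pd.DataFrame
    stage: str

    def between(self, r: str, s: str) -> int:
        return int(self.counts.loc[r, s])


# ---------------------------------------------------------------------------
# protocol I: targeted attack vs failure on aggregated cultures


def select_target(
    network: EffectiveNetwork,
    scheme: str,
    seed: int = 0,
    live: np.ndarray | None = None,
) -> int:
    """Pick the next node to delete under a damage scheme.

    ``bc_attack`` takes the live node with maximal betweenness
    centrality, ``degree_attack`` the maximal total degree, ``random`` a
    uniform draw over live nodes; ties resolve to the lowest node id.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    adj = network.adjacency
    n = adj.shape[0]
    live_mask = np.ones(n, dtype=bool) if live is None else np.asarray(live)
    candidates = np.flatnonzero(live_mask)
    if candidates.size == 0:
        raise ValueError("no live nodes to target")
    if scheme == "random":
        rng = np.random.default_rng(seed)
        pick = candidates[rng.integers(candidates.size)]
        return int(network.node_ids[pick])
    if scheme == "bc_attack":
        score = metrics_mod.betweenness(adj)
    else:
        _, _, score = metrics_mod.degrees(adj)
    score = score.astype(float)
    score[~live_mask] = -np.inf
    pick = int(np.argmax(score))  # argmax returns the lowest index on ties
    return int(network.node_ids[pick])


def geff_excluding_deleted(
    network: EffectiveNetwork, deleted: set[int]
) -> float:
    """Global efficiency on the subgraph without the deleted nodes.

    Excluding the step's deleted node from the pre-damage network keeps
    the pre and post computations on identically sized node sets.
    """
    id_to_idx = {int(i): k for k, i in enumerate(network.node_ids)}
    exclude = {id_to_idx[int(d)] for d in deleted}
    return metrics_mod.global_efficiency(network.adjacency, exclude=exclude)


def _subgraph_q(adj: np.ndarray, keep: np.ndarray, seed: int) -> float:
    """Louvain modularity of the node-induced live subgraph."""
    sub = adj[np.ix_(keep, keep)]
    if sub.sum() == 0:
        return float("nan")
    part = metrics_mod.louvain_communities(sub, seed=seed)
    return metrics_mod.modularity(sub, part)


def _record_and_infer(
    model, recording_s, seed, te_kwargs, burst_kwargs, excitability=None
):
    spikes = simulate_activity(
        model, recording_s, excitability=excitability, seed=seed
    )
    traces = render_fluorescence(spikes, roi_meta=model.nodes, seed=seed + 1)
    raster = binarize_traces(traces)
    live = model.live
    seq = bursts_mod.detect_network_bursts(raster, live=live, **burst_kwargs)
    net = infer_effective_network(raster, live=live, **te_kwargs)
    return seq, net, live


def run_damage_sequence(
    model: CultureModel,
    scheme: str,
    steps: int = 8,
    recording_s: float = 1200.0,
    recovery_strength: float = 0.5,
    seed: int = 0,
    z_min: float = 1.0,
    excitability=None,
    paired_recordings: bool = False,
) -> DamageRecord:
    """Chained damage protocol on an aggregated culture.

    Each step: record + infer the pre-damage effective network, choose
    and disconnect the target, record + infer again, log the activity
    ratio Phi, size-matched Geff pre/post and Louvain Q pre/post, then
    apply one homeostatic recovery (modeling the 24 h between steps).
    Fully reproducible from (model, scheme, seed).  Steps where bursting
    goes extinct are flagged and the sequence continues.

    ``paired_recordings`` drives the pre- and post-damage simulations of
    each step with the same random stream (common random numbers), so
    that pre/post differences isolate the effect of the deletion from
    recording-to-recording variability; use it for simulation studies of
    damage effects.  The default (independent recordings) mirrors the
    bench protocol.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    mode = "aggregated" if model.kind == "aggregated" else "homogeneous"
    burst_kwargs = {"mode": mode}
    te_kwargs = {"z_min": z_min}
    record = DamageRecord(scheme=scheme, seed=seed)
    model = model.copy()
    sub = _child_seeds(seed, 5 * steps)
    for step in range(1, steps + 1):
        s_pre, s_sel, s_post, s_rec, s_q = sub[5 * (step - 1) : 5 * step]
        seq_pre, net_pre, live_pre = _record_and_infer(
            model, recording_s, s_pre, te_kwargs, burst_kwargs, excitability
        )
        target = select_target(net_pre, scheme, seed=s_sel, live=live_pre)
        dead = set(np.flatnonzero(~live_pre)) | {target}
        geff_pre = geff_excluding_deleted(net_pre, dead)
        q_pre = _subgraph_q(net_pre.adjacency, np.flatnonzero(live_pre), s_q)

        model = apply_node_removal(model, target)
        if paired_recordings:
            s_post = s_pre
        seq_post, net_post, live_post = _record_and_infer(
            model, recording_s, s_post, te_kwargs, burst_kwargs, excitability
        )
        geff_post = geff_excluding_deleted(net_post, dead)
        q_post = _subgraph_q(net_post.adjacency, np.flatnonzero(live_post), s_q)

        a_pre = bursts_mod.activity_summary(seq_pre).a
        a_post = bursts_mod.activity_summary(seq_post).a
        extinct = not (np.isfinite(a_pre) and np.isfinite(a_post))
        phi = (
            bursts_mod.activity_ratio(a_post, a_pre)
            if not extinct and a_pre > 0
            else float("nan")
        )
        record.steps.append(
            DamageStep(
                index=step,
                scheme=scheme,
                target=int(target),
                phi=phi,
                a_pre=a_pre,
                a_post=a_post,
                geff_pre=geff_pre,
                geff_post=geff_post,
                q_pre=q_pre,
                q_post=q_post,
                n_bursts_pre=len(seq_pre),
                n_bursts_post=len(seq_post),
                flagged=extinct,
            )
        )
        model = homeostatic_recovery(model, recovery_strength, seed=s_rec)
    return record


# ---------------------------------------------------------------------------
# protocol II: diametral cut on homogeneous cultures


def partition_regions(
    model: CultureModel, angle: float = 0.0, width_um: float = 500.0
) -> RegionPartition:
    """Label every ROI of a homogeneous culture as A/B/C/S/wound.

    Disc ROIs on the positive side of the cut line are 'A', on the
    negative side 'B', inside the wound band 'wound'; disc-rim contour
    ROIs are 'C' and off-disc ROIs 'S'.
    """
    if model.kind != "homogeneous":
        raise ValueError("region partition applies to homogeneous cultures")
    x = model.nodes["x"].to_numpy()
    y = model.nodes["y"].to_numpy()
    region = model.nodes["region"].to_numpy()
    s = -x * np.sin(angle) + y * np.cos(angle)
    half = width_um * 1e-3 / 2.0
    labels = np.empty(len(x), dtype=object)
    labels[region == "surroundings"] = "S"
    labels[region == "contour"] = "C"
    disc = region == "disc"
    labels[disc & (s > half)] = "A"
    labels[disc & (s < -half)] = "B"
    labels[disc & (np.abs(s) <= half)] = "wound"
    return RegionPartition(labels=labels.astype(str))


def region_interaction_matrix(
    network: EffectiveNetwork,
    partition: RegionPartition,
    stage: str = "",
) -> RegionInteraction:
    """Count effective connections between every pair of regions.

    Directed counts are folded into a symmetric matrix (r<->s = both
    directions pooled; the diagonal holds within-region counts).  Wound
    ROIs never contribute (they are removed, hence edgeless).
    """
    adj = network.adjacency
    labels = partition.labels
    if labels.size != adj.shape[0]:
        raise ValueError("partition does not match the network's node count")
    regs = list(REGIONS)
    directed = pd.DataFrame(0, index=regs, columns=regs, dtype=int)
    src, dst = np.nonzero(adj)
    for i, j in zip(src, dst):
        li, lj = labels[i], labels[j]
        if li in regs and lj in regs:
            directed.loc[li, lj] += 1
    folded = directed + directed.T
    np.fill_diagonal(folded.values, np.diag(directed.values))
    return RegionInteraction(counts=folded, directed=directed, stage=stage)


def recovery_timeline(
    model: CultureModel,
    angle: float = 0.0,
    width_um: float = 500.0,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    stage_strengths: dict[str, float] | None = None,
    recording_s: float = 120.0,
    seed: int = 0,
    z_min: float = 1.0,
    region_min_fraction: float = 0.5,
    trauma_factor: float = 0.5,
) -> list[dict]:
    """Diametral-cut experiment: per-stage region activity + interactions.

    Simulates one recording per stage.  The cut is applied between the
    'before' and 'after' stages, acutely depressing the wounded disc's
    couplings by ``trauma_factor``; every later stage first applies one
    homeostatic-recovery increment (cumulative restoration grows along
    the timeline), then records.  Returns one dict per stage with the
    stage label, per-region burst counts and the RegionInteraction.
    """
    if model.kind != "homogeneous":
        raise ValueError("the cut protocol applies to homogeneous cultures")
    strengths = (
        DEFAULT_STAGE_STRENGTHS if stage_strengths is None else stage_strengths
    )
    partition = partition_regions(model, angle=angle, width_um=width_um)
    regions = partition.region_map()
    sub = _child_seeds(seed, 2 * len(stages))
    model = model.copy()
    out: list[dict] = []
    for k, stage in enumerate(stages):
        if stage == "after":
            model = apply_cut(
                model,
                angle=angle,
                width_um=width_um,
                trauma_factor=trauma_factor,
            )
        elif stage != "before":
            # the wound gap persists: sever anything sprouted across it
            model = apply_cut(model, angle=angle, width_um=width_um)
            model = homeostatic_recovery(
                model, strengths.get(stage, 0.0), seed=sub[2 * k]
            )
        spikes = simulate_activity(model, recording_s, seed=sub[2 * k + 1])
        traces = render_fluorescence(
            spikes, roi_meta=model.nodes, seed=sub[2 * k + 1] + 1
        )
        raster = binarize_traces(traces)
        live = model.live
        counts = bursts_mod.region_burst_counts(
            raster, regions, min_fraction=region_min_fraction, live=live
        )
        net = infer_effective_network(raster, z_min=z_min, live=live)
        interaction = region_interaction_matrix(net, partition, stage=stage)
        out.append(
            {"stage": stage, "burst_counts": counts, "interaction": interaction}
        )
    return out
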