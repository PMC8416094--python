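"""Fractional blood supply from the solved network.

Two routes: a deterministic junction-mixing transport closure on cycle-mean
flows (complete mixing at every junction), and a stochastic particle-routing
analog of Lagrangian particle tracking on the time-resolved periodic solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .asl import FBSTable, TerritoryArteryMap, NECK_ARTERY_ORDER, TERRITORY_NAMES
from .errors import StructuralError
from .network import NetworkModel, SimResult


@dataclass
class SourceLabeling:
    """Labeled source segments (the four neck arteries) and particle budgets."""

    sources: Dict[str, str]  # artery name -> segment id
    budgets: Optional[Dict[str, int]] = None  # particles-per-cycle per artery

    @classmethod
    def from_network(cls, network: NetworkModel) -> "SourceLabeling":
        return cls(sources=dict(network.neck_arteries))


@dataclass
class ParticleLedger:
    """Per-outlet, per-source particle counts and cycle-phase histograms."""

    counts: pd.DataFrame  # outlets x sources
    phase_histograms: Dict[str, np.ndarray]  # outlet -> (sources, bins)
    phase_bins: np.ndarray
    cycles_tracked: int
    seeded: Dict[str, int]
    retired_stagnant: int = 0

    def to_dict(self) -> dict:
        return {
            "counts": {o: self.counts.loc[o].to_dict() for o in self.counts.index},
            "phase_histograms": {
                o: h.tolist() for o, h in self.phase_histograms.items()
            },
            "phase_bins": self.phase_bins.tolist(),
            "cycles_tracked": self.cycles_tracked,
            "seeded": dict(self.seeded),
            "retired_stagnant": self.retired_stagnant,
        }


def _mean_flows(result_or_flows, network: NetworkModel) -> Dict[str, float]:
    if isinstance(result_or_flows, SimResult):
        return {s.id: result_or_flows.mean_flow(s.id) for s in network.segments}
    return dict(result_or_flows)


def _outlet_segment_map(network: NetworkModel, flows: Dict[str, float]) -> Dict[str, str]:
    """Outlet name -> id of the segment delivering flow to its terminal node."""
    out = {}
    for outlet, node in network.outlets.items():
        best, best_q = None, 0.0
        for s in network.segments:
            q = flows.get(s.id, 0.0)
            if (s.to_node == node and q >= 0) or (s.from_node == node and q < 0):
                if best is None or abs(q) > best_q:
                    best, best_q = s.id, abs(q)
        if best is None:
            raise StructuralError(f"no segment feeds outlet {outlet}")
        out[outlet] = best
    return out


def segment_compositions(
    network: NetworkModel,
    flows: Dict[str, float],
    sources: Dict[str, str],
    source_order: Tuple[str, ...] = NECK_ARTERY_ORDER,
) -> Dict[str, np.ndarray]:
    """Solve the steady complete-mixing composition system on mean flows.

    Each labeled source segment carries the unit composition of its artery;
    every other segment carries the flow-weighted mixture of the compositions
    entering its upstream node.  Returns segment id -> composition vector over
    ``source_order`` (plus an implicit unlabeled remainder).
    """
    seg_ids = [s.id for s in network.segments]
    idx = {sid: i for i, sid in enumerate(seg_ids)}
    n = len(seg_ids)
    n_src = len(source_order)
    src_of_seg = {}
    for k, artery in enumerate(source_order):
        sid = sources.get(artery)
        if sid is not None:
            src_of_seg[sid] = k

    # upstream node of each segment given the signed mean flow
    up_node = {}
    for s in network.segments:
        q = flows.get(s.id, 0.0)
        up_node[s.id] = s.from_node if q >= 0 else s.to_node

    # inflows arriving at each node
    node_in: Dict[str, List[str]] = {}
    for s in network.segments:
        q = flows.get(s.id, 0.0)
        dn = s.to_node if q >= 0 else s.from_node
        node_in.setdefault(dn, []).append(s.id)

    A = np.eye(n)
    B = np.zeros((n, n_src))
    for s in network.segments:
        i = idx[s.id]
        if s.id in src_of_seg:
            B[i, src_of_seg[s.id]] = 1.0
            continue
        feeders = node_in.get(up_node[s.id], [])
        total = sum(abs(flows.get(f, 0.0)) for f in feeders)
        if total <= 0:
            continue  # stagnant: composition stays all-zero
        for f in feeders:
            A[i, idx[f]] -= abs(flows.get(f, 0.0)) / total
    try:
        X = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:
        raise StructuralError(f"singular mixing system: {exc}") from exc
    return {sid: X[idx[sid]] for sid in seg_ids}


def transport_fractions(
    result_or_flows,
    network: NetworkModel,
    sources: Optional[SourceLabeling] = None,
    territory_map: Optional[TerritoryArteryMap] = None,
) -> FBSTable:
    """Deterministic FBS on cycle-mean flows via complete junction mixing.

    ``result_or_flows`` may be a SimResult or a mapping segment id -> mean
    flow.  Segments whose mean flow reverses relative to their orientation are
    handled with signed flow; the composition system uses flow magnitudes.
    """
    sources = sources or SourceLabeling.from_network(network)
    tmap = territory_map or TerritoryArteryMap()
    flows = _mean_flows(result_or_flows, network)
    if isinstance(result_or_flows, SimResult):
        _warn_reversing(result_or_flows, network)
    comp = segment_compositions(network, flows, sources.sources)
    outlet_seg = _outlet_segment_map(network, flows)

    med = pd.DataFrame(
        index=list(TERRITORY_NAMES), columns=list(NECK_ARTERY_ORDER), dtype=float
    )
    for terr in TERRITORY_NAMES:
        num = np.zeros(len(NECK_ARTERY_ORDER))
        den = 0.0
        for artery, _share in tmap.arteries_of(terr):
            if artery not in outlet_seg:
                continue
            sid = outlet_seg[artery]
            q = abs(flows.get(sid, 0.0))
            num += q * comp[sid]
            den += q
        med.loc[terr] = num / den if den > 0 else np.nan
    return FBSTable(median=med, mad=None, source="transport")


def _warn_reversing(result: SimResult, network: NetworkModel) -> None:
    for s in network.segments:
        q = result.last_cycle(result.seg_flows[s.id])
        if np.max(q) > 0 and np.min(q) < 0:
            depth = min(np.max(q), -np.min(q))
            if depth > 0.5 * abs(np.mean(q)):
                warnings.warn(
                    f"segment {s.id} reverses flow within the cycle; "
                    "complete-mixing transport uses its cycle-mean direction"
                )


# ---------------------------------------------------------------------------
# particle routing
# ---------------------------------------------------------------------------


def particle_fbs(
    result: SimResult,
    network: NetworkModel,
    sources: Optional[SourceLabeling] = None,
    n_total: int = 100_000,
    seed: int = 0,
    territory_map: Optional[TerritoryArteryMap] = None,
    min_cycles: int = 4,
    max_cycles: int = 40,
    arrival_tol: float = 0.05,
    phase_bins: int = 20,
) -> Tuple[FBSTable, ParticleLedger]:
    """Stochastic particle-routing FBS on the time-resolved periodic solution.

    Particles are injected at the base of each labeled neck segment at a rate
    proportional to its instantaneous flow (re-injected every cycle), advected
    with transit governed by segment volume and instantaneous flow, and routed
    at junctions with probabilities proportional to instantaneous outflows.
    Tracking continues until per-outlet arrival counts per cycle change by
    less than ``arrival_tol`` (after ``min_cycles``); FBS is computed from the
    final cycle's counts.
    """
    if n_total < 1000:
        raise ValueError("n_total must be at least 10^3")
    sources = sources or SourceLabeling.from_network(network)
    tmap = territory_map or TerritoryArteryMap()
    rng = np.random.default_rng(seed)

    n_steps = result.steps_per_cycle
    dt = result.dt
    seg_ids = [s.id for s in network.segments]
    idx = {sid: i for i, sid in enumerate(seg_ids)}
    seg_from = [s.from_node for s in network.segments]
    seg_to = [s.to_node for s in network.segments]
    volumes = np.array([s.volume for s in network.segments])
    q_cycle = np.stack(
        [result.last_cycle(result.seg_flows[sid]) for sid in seg_ids], axis=1
    )  # (n_steps, n_segs)

    node_names = network.nodes
    node_idx = {nm: i for i, nm in enumerate(node_names)}
    outlet_of_node = {network.outlets[o]: o for o in network.outlets}

    # node -> candidate exit segments (either orientation; sign decides at runtime)
    node_segs: Dict[int, List[int]] = {i: [] for i in range(len(node_names))}
    for i, s in enumerate(network.segments):
        node_segs[node_idx[s.from_node]].append(i)
        node_segs[node_idx[s.to_node]].append(i)

    mean_flows = {sid: float(np.mean(q_cycle[:, idx[sid]])) for sid in seg_ids}

    # seeding schedule per artery: counts proportional to mean source flow,
    # in-cycle times sampled from the instantaneous-flow density
    src_arteries = [a for a in NECK_ARTERY_ORDER if a in sources.sources]
    src_flow = np.array(
        [max(mean_flows[sources.sources[a]], 0.0) for a in src_arteries]
    )
    if src_flow.sum() <= 0:
        raise StructuralError("no positive source flow; cannot seed particles")
    if sources.budgets:
        per_cycle = np.array([sources.budgets[a] for a in src_arteries], dtype=int)
    else:
        per_cycle = np.maximum(
            np.round(n_total / min_cycles * src_flow / src_flow.sum()).astype(int), 0
        )

    schedules = {}
    for a, n_seed in zip(src_arteries, per_cycle):
        sid = sources.sources[a]
        q = np.maximum(q_cycle[:, idx[sid]], 0.0)
        cdf = np.cumsum(q)
        if cdf[-1] <= 0:
            schedules[a] = np.array([], dtype=int)
            continue
        cdf = cdf / cdf[-1]
        u = rng.random(n_seed)
        schedules[a] = np.searchsorted(cdf, u)  # step index within the cycle

    n_src = len(src_arteries)
    outlet_names = list(network.outlets)
    counts = np.zeros((len(outlet_names), n_src), dtype=np.int64)
    out_idx = {o: i for i, o in enumerate(outlet_names)}
    hist = {o: np.zeros((n_src, phase_bins), dtype=np.int64) for o in outlet_names}
    outlet_at_node = np.full(len(node_names), -1, dtype=int)
    for node, o in outlet_of_node.items():
        outlet_at_node[node_idx[node]] = out_idx[o]
    outlet_list = list(outlet_names)

    # per-cycle seed layout, grouped by step (identical schedule every cycle)
    seed_steps: List[np.ndarray] = []
    seed_segs: List[np.ndarray] = []
    seed_srcs: List[np.ndarray] = []
    for k, a in enumerate(src_arteries):
        st = schedules[a]
        seed_steps.append(st)
        seed_segs.append(np.full(st.size, idx[sources.sources[a]], dtype=int))
        seed_srcs.append(np.full(st.size, k, dtype=int))
    seed_steps_all = np.concatenate(seed_steps) if seed_steps else np.array([], int)
    order = np.argsort(seed_steps_all, kind="stable")
    seed_steps_all = seed_steps_all[order]
    seed_segs_all = np.concatenate(seed_segs)[order] if seed_steps else np.array([], int)
    seed_srcs_all = np.concatenate(seed_srcs)[order] if seed_steps else np.array([], int)
    seeds_at_step = [
        (seed_segs_all[seed_steps_all == s], seed_srcs_all[seed_steps_all == s])
        for s in range(n_steps)
    ]

    # live particle state (flat arrays with slack capacity)
    cap = max(int(seed_steps_all.size * (max_cycles + 1)), 1024)
    p_seg = np.zeros(cap, dtype=int)
    p_pos = np.zeros(cap)
    p_src = np.zeros(cap, dtype=int)
    p_moved = np.zeros(cap, dtype=bool)
    alive = np.zeros(cap, dtype=bool)
    n_live_hint = 0  # upper bound on used slots

    per_cycle_arrivals: List[np.ndarray] = []
    seeded_total = {a: 0 for a in src_arteries}
    retired = 0
    cycles = 0
    rand = rng.random

    while cycles < max_cycles:
        # counts and histograms are per cycle; the final cycle (after arrival
        # periodicity) is what the FBS is computed from
        counts[:] = 0
        for h in hist.values():
            h[:] = 0
        cycle_counts = np.zeros(len(outlet_names), dtype=np.int64)
        for a in src_arteries:
            seeded_total[a] += len(schedules[a])
        for step in range(n_steps):
            new_segs, new_srcs = seeds_at_step[step]
            if new_segs.size:
                free = np.flatnonzero(~alive[: n_live_hint + new_segs.size + 8])
                slots = free[: new_segs.size]
                if slots.size < new_segs.size:  # grow capacity
                    extra = max(cap, new_segs.size)
                    for arr_name in ("p_seg", "p_src"):
                        pass
                    p_seg = np.concatenate([p_seg, np.zeros(extra, dtype=int)])
                    p_pos = np.concatenate([p_pos, np.zeros(extra)])
                    p_src = np.concatenate([p_src, np.zeros(extra, dtype=int)])
                    p_moved = np.concatenate([p_moved, np.zeros(extra, dtype=bool)])
                    alive = np.concatenate([alive, np.zeros(extra, dtype=bool)])
                    cap += extra
                    free = np.flatnonzero(~alive)
                    slots = free[: new_segs.size]
                p_seg[slots] = new_segs
                p_pos[slots] = 0.0
                p_src[slots] = new_srcs
                p_moved[slots] = True
                alive[slots] = True
                n_live_hint = max(n_live_hint, int(slots.max()) + 1)
            live_idx = np.flatnonzero(alive[:n_live_hint])
            if live_idx.size == 0:
                continue
            qs = q_cycle[step]
            segs_l = p_seg[live_idx]
            dq = qs[segs_l] * dt
            p_pos[live_idx] += dq
            p_moved[live_idx] |= dq != 0
            pos_l = p_pos[live_idx]
            crossed = live_idx[(pos_l < 0.0) | (pos_l > volumes[segs_l])]
            if crossed.size == 0:
                continue
            phase = int(step / n_steps * phase_bins) % phase_bins
            for j in crossed:
                pos = p_pos[j]
                si = p_seg[j]
                guard = 0
                while pos < 0.0 or pos > volumes[si]:
                    guard += 1
                    if guard > 50:
                        break
                    if pos > volumes[si]:
                        node = node_idx[seg_to[si]]
                        carry = pos - volumes[si]
                        forward = True
                    else:
                        node = node_idx[seg_from[si]]
                        carry = -pos
                        forward = False
                    oi = outlet_at_node[node]
                    if oi >= 0:
                        counts[oi, p_src[j]] += 1
                        cycle_counts[oi] += 1
                        hist[outlet_list[oi]][p_src[j], phase] += 1
                        alive[j] = False
                        break
                    node_name = node_names[node]
                    cands = []
                    dirs = []
                    weights = []
                    wsum = 0.0
                    for c in node_segs[node]:
                        if c == si:
                            continue
                        q = qs[c]
                        if seg_from[c] == node_name and q > 0:
                            cands.append(c)
                            dirs.append(1)
                            weights.append(q)
                            wsum += q
                        elif seg_to[c] == node_name and q < 0:
                            cands.append(c)
                            dirs.append(-1)
                            weights.append(-q)
                            wsum -= q
                    if not cands:
                        pos = volumes[si] if forward else 0.0
                        break
                    u = rand() * wsum
                    acc = 0.0
                    choice = len(cands) - 1
                    for ci, w in enumerate(weights):
                        acc += w
                        if u < acc:
                            choice = ci
                            break
                    si = cands[choice]
                    pos = carry if dirs[choice] > 0 else volumes[si] - carry
                if alive[j]:
                    p_seg[j] = si
                    p_pos[j] = min(max(pos, 0.0), volumes[si])
        # retire particles that did not move during an entire cycle
        stagnant = np.flatnonzero(alive[:n_live_hint] & ~p_moved[:n_live_hint])
        if stagnant.size:
            alive[stagnant] = False
            retired += int(stagnant.size)
        p_moved[:n_live_hint] = False
        per_cycle_arrivals.append(cycle_counts)
        cycles += 1
        if cycles >= max(min_cycles, 2):
            prev, cur = per_cycle_arrivals[-2], per_cycle_arrivals[-1]
            denom = np.maximum(cur, 1)
            if np.max(np.abs(cur - prev) / denom) < arrival_tol:
                break

    if retired:
        warnings.warn(f"{retired} stagnant particles retired")

    counts_df = pd.DataFrame(counts, index=outlet_names, columns=src_arteries)
    ledger = ParticleLedger(
        counts=counts_df,
        phase_histograms=hist,
        phase_bins=np.linspace(0.0, 1.0, phase_bins + 1),
        cycles_tracked=cycles,
        seeded=seeded_total,
        retired_stagnant=retired,
    )

    med = pd.DataFrame(
        index=list(TERRITORY_NAMES), columns=list(NECK_ARTERY_ORDER), dtype=float
    )
    for terr in TERRITORY_NAMES:
        num = np.zeros(len(NECK_ARTERY_ORDER))
        for artery, _share in tmap.arteries_of(terr):
            if artery not in out_idx:
                continue
            row = counts_df.loc[artery]
            for k, a in enumerate(src_arteries):
                num[NECK_ARTERY_ORDER.index(a)] += row[a]
        total = num.sum()
        med.loc[terr] = num / total if total > 0 else np.nan
    table = FBSTable(median=med, mad=None, source="particles")
    return table, ledger


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


@dataclass
class FBSComparison:
    pearson_r: float
    n_cells: int
    n_excluded: int
    differences: pd.DataFrame  # model - asl per cell
    dominant_agreement: Dict[str, bool]

    @property
    def dominant_agreement_rate(self) -> float:
        vals = list(self.dominant_agreement.values())
        return float(np.mean(vals)) if vals else np.nan

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "n_cells": self.n_cells,
            "n_excluded": self.n_excluded,
            "mean_abs_difference": float(np.nanmean(np.abs(self.differences.values))),
            "dominant_agreement": dict(self.dominant_agreement),
            "dominant_agreement_rate": self.dominant_agreement_rate,
        }


def fbs_compare(model: FBSTable, asl: FBSTable) -> FBSComparison:
    """Pearson correlation over all (territory, artery) cells, per-cell
    differences, and per-territory dominant-source agreement."""
    terrs = [t for t in model.territories if t in asl.territories]
    arts = [a for a in model.arteries if a in asl.arteries]
    m = model.median.loc[terrs, arts].astype(float)
    a = asl.median.loc[terrs, arts].astype(float)
    mask = np.isfinite(m.values) & np.isfinite(a.values)
    n_excluded = int((~mask).sum())
    mv, av = m.values[mask], a.values[mask]
    if mv.size >= 2 and np.std(mv) > 0 and np.std(av) > 0:
        r = float(np.corrcoef(mv, av)[0, 1])
    else:
        r = np.nan
    diffs = m - a
    dominant = {}
    for terr in terrs:
        if np.isfinite(m.loc[terr].values).any() and np.isfinite(a.loc[terr].values).any():
            dominant[terr] = m.loc[terr].idxmax() == a.loc[terr].idxmax()
    return FBSComparison(
        pearson_r=r,
        n_cells=int(mask.sum()),
        n_excluded=n_excluded,
        differences=diffs,
        dominant_agreement=dominant,
    )
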