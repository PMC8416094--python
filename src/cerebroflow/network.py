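"""Vascular network data model and pulsatile lumped-parameter solver.

The network is a directed graph of resistive-inertial vessel segments with
optional nonlinear stenosis elements.  Flow enters at a single inlet node as a
prescribed periodic waveform; every terminal node carries a three-element
Windkessel boundary condition (proximal resistance, distal resistance,
capacitance, venous reference pressure fixed at 0).

The transient solver integrates the network DAE with implicit Euler: segment
flows follow ``L dq/dt = P_up - P_dn - R q - dP_stenosis(q)``, Windkessel
capacitor pressures follow ``C dPc/dt = (P - Pc)/Rp - Pc/Rd``, and node
pressures are recovered each step from exact mass conservation (nodal
conductance solve).  Whole cardiac cycles are iterated until cycle-to-cycle
periodicity is reached.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    ConvergenceError,
    InvalidGeometryError,
    StructuralError,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BloodProperties:
    """Newtonian blood: dynamic viscosity [kg m^-1 s^-1] and density [kg m^-3]."""

    viscosity: float = 0.004
    density: float = 1060.0

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise InvalidGeometryError("blood viscosity and density must be positive")


@dataclass(frozen=True)
class StenosisElement:
    """Nonlinear pressure-loss element: dP = k_linear*q + k_turb*q*|q|.

    ``k_linear`` [Pa s m^-3] is the viscous coefficient on the minimal lumen,
    ``k_turb`` [Pa s^2 m^-6] the momentum (expansion) loss coefficient.
    """

    k_linear: float
    k_turb: float
    min_diameter: float
    reference_diameter: float

    def __post_init__(self):
        if self.k_linear < 0 or self.k_turb < 0:
            raise InvalidGeometryError("stenosis coefficients must be nonnegative")
        if not self.min_diameter < self.reference_diameter:
            raise InvalidGeometryError("min_diameter must be < reference_diameter")


def segment_resistance(length: float, radius: float, blood: BloodProperties) -> float:
    """Poiseuille resistance 8*mu*L/(pi*r^4) [Pa s m^-3]."""
    if length < 0 or radius <= 0:
        raise InvalidGeometryError(
            f"invalid geometry: length={length}, radius={radius}"
        )
    return 8.0 * blood.viscosity * length / (math.pi * radius**4)


def segment_inertance(length: float, radius: float, blood: BloodProperties) -> float:
    """Blood inertance rho*L/(pi*r^2) [Pa s^2 m^-3]."""
    if length < 0 or radius <= 0:
        raise InvalidGeometryError(
            f"invalid geometry: length={length}, radius={radius}"
        )
    return blood.density * length / (math.pi * radius**2)


def stenosis_pressure_drop(q: float, element: StenosisElement) -> float:
    """Signed pressure drop across a stenosis element (odd in q)."""
    return element.k_linear * q + element.k_turb * q * abs(q)


def make_stenosis(
    reference_radius: float,
    min_diameter_fraction: float,
    length: float = 0.02,
    blood: BloodProperties = BloodProperties(),
    expansion_coefficient: float = 1.52,
) -> StenosisElement:
    """Build a stenosis element from a diameter-reduction fraction.

    k_linear is the Poiseuille excess of the minimal lumen over ``length``;
    k_turb follows an expansion-loss closure on the area ratio.
    """
    if not 0 < min_diameter_fraction < 1:
        raise InvalidGeometryError("min_diameter_fraction must lie in (0, 1)")
    r_min = reference_radius * min_diameter_fraction
    a_min = math.pi * r_min**2
    a_ref = math.pi * reference_radius**2
    k_lin = 8.0 * blood.viscosity * length / (math.pi * r_min**4)
    k_turb = (
        expansion_coefficient
        * blood.density
        / (2.0 * a_ref**2)
        * (a_ref / a_min - 1.0) ** 2
    )
    return StenosisElement(
        k_linear=k_lin,
        k_turb=k_turb,
        min_diameter=2.0 * r_min,
        reference_diameter=2.0 * reference_radius,
    )


@dataclass
class VesselSegment:
    """One lumped vessel segment between two named nodes."""

    id: str
    name: str
    from_node: str
    to_node: str
    length: float
    radius: float
    poiseuille_resistance: float = None  # type: ignore[assignment]
    inertance: float = None  # type: ignore[assignment]
    stenosis: Optional[StenosisElement] = None
    blood: BloodProperties = field(default_factory=BloodProperties)

    def __post_init__(self):
        if self.length <= 0 or self.radius <= 0:
            raise InvalidGeometryError(
                f"segment {self.id}: length and radius must be positive"
            )
        if self.poiseuille_resistance is None:
            self.poiseuille_resistance = segment_resistance(
                self.length, self.radius, self.blood
            )
        if self.inertance is None:
            self.inertance = segment_inertance(self.length, self.radius, self.blood)

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class WindkesselBC:
    """Three-element Windkessel outlet boundary condition (venous reference 0)."""

    outlet_id: str
    r_prox: float
    r_dist: float
    capacitance: float

    def __post_init__(self):
        if min(self.r_prox, self.r_dist, self.capacitance) < 0:
            raise InvalidGeometryError("Windkessel parameters must be nonnegative")

    @property
    def total(self) -> float:
        return self.r_prox + self.r_dist


INTRACRANIAL_OUTLETS = (
    "RACA", "LACA", "RMCA", "LMCA", "RPCA", "LPCA", "RSCA", "LSCA",
)
NECK_ARTERIES = ("RICA", "LICA", "RVA", "LVA")


@dataclass
class NetworkModel:
    """Directed vessel-segment graph with one inlet and named outlet nodes.

    Outlet nodes are terminal nodes coupled to Windkessel models; neck arteries
    are the four labeled source segments used by supply tracking.
    """

    segments: List[VesselSegment]
    inlet: str
    outlets: Dict[str, str]  # outlet name -> terminal node
    neck_arteries: Dict[str, str]  # artery name -> segment id

    def __post_init__(self):
        self._by_id = {s.id: s for s in self.segments}
        if len(self._by_id) != len(self.segments):
            raise StructuralError("duplicate segment ids")
        self.validate()

    # -- lookups ----------------------------------------------------------
    def segment(self, seg_id: str) -> VesselSegment:
        return self._by_id[seg_id]

    @property
    def nodes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.from_node)
            seen.setdefault(s.to_node)
        return list(seen)

    @property
    def outlet_nodes(self) -> Dict[str, str]:
        return dict(self.outlets)

    def segments_at(self, node: str) -> List[VesselSegment]:
        return [s for s in self.segments if node in (s.from_node, s.to_node)]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        import networkx as nx

        g = nx.Graph()
        for s in self.segments:
            g.add_edge(s.from_node, s.to_node, id=s.id)
        if self.inlet not in g:
            raise StructuralError(f"inlet node {self.inlet!r} not in graph")
        for name, node in self.outlets.items():
            if node not in g:
                raise StructuralError(f"outlet {name} node {node!r} not in graph")
            if not nx.has_path(g, self.inlet, node):
                raise StructuralError(f"outlet {name} unreachable from inlet")
        for name, seg_id in self.neck_arteries.items():
            if seg_id not in self._by_id:
                raise StructuralError(f"neck artery {name} segment {seg_id!r} missing")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        segs = []
        for s in self.segments:
            d = {
                "id": s.id,
                "name": s.name,
                "from": s.from_node,
                "to": s.to_node,
                "length_m": s.length,
                "radius_m": s.radius,
            }
            if s.stenosis is not None:
                d["stenosis"] = {
                    "k_linear": s.stenosis.k_linear,
                    "k_turb": s.stenosis.k_turb,
                    "min_diameter_m": s.stenosis.min_diameter,
                    "reference_diameter_m": s.stenosis.reference_diameter,
                }
            segs.append(d)
        return {
            "segments": segs,
            "inlet": self.inlet,
            "outlets": dict(self.outlets),
            "neck_arteries": dict(self.neck_arteries),
        }

    @classmethod
    def from_dict(cls, d: dict, blood: BloodProperties = BloodProperties()) -> "NetworkModel":
        segments = []
        for sd in d["segments"]:
            sten = None
            if sd.get("stenosis"):
                sb = sd["stenosis"]
                sten = StenosisElement(
                    k_linear=sb["k_linear"],
                    k_turb=sb["k_turb"],
                    min_diameter=sb["min_diameter_m"],
                    reference_diameter=sb["reference_diameter_m"],
                )
            segments.append(
                VesselSegment(
                    id=sd["id"],
                    name=sd["name"],
                    from_node=sd["from"],
                    to_node=sd["to"],
                    length=sd["length_m"],
                    radius=sd["radius_m"],
                    stenosis=sten,
                    blood=blood,
                )
            )
        return cls(
            segments=segments,
            inlet=d["inlet"],
            outlets=dict(d["outlets"]),
            neck_arteries=dict(d["neck_arteries"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "NetworkModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled periodic signal over one period.

    ``times`` cover [0, period) — the sample at t=period is the sample at 0.
    """

    times: np.ndarray
    values: np.ndarray
    period: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform values must be finite")

    def __call__(self, t) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        tt = np.mod(t, self.period)
        tp = np.concatenate([self.times, [self.times[0] + self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        return np.interp(tt, tp, vp)

    @property
    def mean(self) -> float:
        tp = np.concatenate([self.times, [self.times[0] + self.period]])
        vp = np.concatenate([self.values, [self.values[0]]])
        return float(np.trapezoid(vp, tp) / self.period)


@dataclass(frozen=True)
class SolverOptions:
    dt: float = 1e-3
    periodicity_tol: float = 1e-3
    max_cycles: int = 20
    min_cycles: int = 2
    stenosis_iterations: int = 8
    stenosis_tol: float = 1e-10
    r_prox_floor: float = 1.0  # Pa s m^-3; avoids a singular nodal matrix


@dataclass
class SimResult:
    """Periodic network solution: full multi-cycle series plus bookkeeping."""

    times: np.ndarray  # full series, t[0]=dt
    seg_flows: Dict[str, np.ndarray]  # segment id -> flow series [m^3/s]
    node_pressures: Dict[str, np.ndarray]  # node -> pressure series [Pa]
    period: float
    dt: float
    cycles_run: int
    periodicity_error: float
    final_state: dict = field(default_factory=dict, repr=False)

    @property
    def steps_per_cycle(self) -> int:
        return int(round(self.period / self.dt))

    def last_cycle(self, series: np.ndarray) -> np.ndarray:
        return series[-self.steps_per_cycle:]

    def mean_flow(self, seg_id: str) -> float:
        return float(np.mean(self.last_cycle(self.seg_flows[seg_id])))

    def mean_pressure(self, node: str) -> float:
        return float(np.mean(self.last_cycle(self.node_pressures[node])))

    def flow_waveform(self, seg_id: str) -> Waveform:
        q = self.last_cycle(self.seg_flows[seg_id])
        t = np.arange(q.size) * self.dt
        return Waveform(times=t, values=q, period=self.period)


def check_periodicity(result: SimResult, tol: float) -> bool:
    """True iff the last two cycles of every monitored series differ by < tol
    in relative L2 norm."""
    if result.cycles_run < 2:
        raise ConvergenceError("need at least 2 full cycles to check periodicity")
    return _cycle_error(result) < tol


def _cycle_error(result: SimResult) -> float:
    n = result.steps_per_cycle
    err = 0.0
    for series in list(result.seg_flows.values()) + list(result.node_pressures.values()):
        a, b = series[-n:], series[-2 * n : -n]
        denom = float(np.linalg.norm(a))
        scale = max(denom, 1e-30)
        err = max(err, float(np.linalg.norm(a - b)) / scale)
    return err


def first_periodic_cycle(result: SimResult, tol: float) -> Optional[int]:
    """Index (1-based) of the first cycle whose change from its predecessor is
    below tol, scanning the stored series; None if never."""
    n = result.steps_per_cycle
    series = list(result.seg_flows.values()) + list(result.node_pressures.values())
    for c in range(1, result.cycles_run):
        err = 0.0
        for s in series:
            a = s[(c) * n : (c + 1) * n]
            b = s[(c - 1) * n : c * n]
            err = max(err, float(np.linalg.norm(a - b)) / max(np.linalg.norm(a), 1e-30))
        if err < tol:
            return c + 1
    return None


# ---------------------------------------------------------------------------
# transient solver
# ---------------------------------------------------------------------------


class _Assembled:
    """Index arrays and constant matrices for one (network, wk, dt) triple."""

    def __init__(self, network: NetworkModel, wk: Dict[str, WindkesselBC], opts: SolverOptions):
        self.network = network
        self.opts = opts
        nodes = network.nodes
        self.node_index = {n: i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        segs = network.segments
        self.segs = segs
        self.n_segs = len(segs)
        self.iu = np.array([self.node_index[s.from_node] for s in segs])
        self.iv = np.array([self.node_index[s.to_node] for s in segs])
        self.R = np.array([
            s.poiseuille_resistance + (s.stenosis.k_linear if s.stenosis else 0.0)
            for s in segs
        ])
        self.L = np.array([s.inertance for s in segs])
        self.kt = np.array([s.stenosis.k_turb if s.stenosis else 0.0 for s in segs])
        self.has_sten = bool(np.any(self.kt > 0))
        self.inlet_idx = self.node_index[network.inlet]

        missing = [o for o in network.outlets if o not in wk]
        if missing:
            raise StructuralError(f"Windkessel set missing outlets: {missing}")
        self.outlet_names = list(network.outlets)
        self.outlet_node_idx = np.array(
            [self.node_index[network.outlets[o]] for o in self.outlet_names]
        )
        self.rp = np.maximum(
            np.array([wk[o].r_prox for o in self.outlet_names]), opts.r_prox_floor
        )
        self.rd = np.array([wk[o].r_dist for o in self.outlet_names])
        self.C = np.array([wk[o].capacitance for o in self.outlet_names])


def solve_transient(
    network: NetworkModel,
    wk: Dict[str, WindkesselBC],
    inflow: Waveform,
    opts: SolverOptions = SolverOptions(),
    initial_state: Optional[dict] = None,
) -> SimResult:
    """Integrate the network to cycle-to-cycle periodicity.

    ``wk`` maps outlet name to its WindkesselBC.  ``initial_state`` (from a
    previous SimResult.final_state) warm-starts the integration.
    """
    asm = _Assembled(network, wk, opts)
    dt = opts.dt
    n_steps = int(round(inflow.period / dt))
    if n_steps < 2:
        raise ValueError("time step too large for the period")
    period = n_steps * dt

    q = np.zeros(asm.n_segs)
    pc = np.zeros(len(asm.outlet_names))
    if initial_state:
        for i, s in enumerate(asm.segs):
            q[i] = initial_state.get("seg_flows", {}).get(s.id, 0.0)
        for i, o in enumerate(asm.outlet_names):
            pc[i] = initial_state.get("wk_pressures", {}).get(o, 0.0)
    else:
        # charge capacitors to the mean-flow operating point estimate
        q_mean = inflow.mean
        r_par = 1.0 / np.sum(1.0 / (asm.rp + asm.rd))
        pc[:] = q_mean * r_par * asm.rd / (asm.rp + asm.rd)

    t_grid = (np.arange(n_steps) + 1) * dt
    qin_cycle = inflow(t_grid)

    alpha = asm.L / dt
    # Windkessel implicit-Euler coefficients:  q_wk = gwk*P - hwk_coeff*pc
    D = asm.C / dt + 1.0 / asm.rp + 1.0 / asm.rd
    gwk = (1.0 - 1.0 / (asm.rp * D)) / asm.rp
    hcoef = (asm.C / dt) / (asm.rp * D)

    n_nodes = asm.n_nodes
    iu, iv = asm.iu, asm.iv

    flows_hist: List[np.ndarray] = []
    press_hist: List[np.ndarray] = []

    def build_G(g):
        G = np.zeros((n_nodes, n_nodes))
        np.add.at(G, (iu, iu), g)
        np.add.at(G, (iv, iv), g)
        np.add.at(G, (iu, iv), -g)
        np.add.at(G, (iv, iu), -g)
        G[asm.outlet_node_idx, asm.outlet_node_idx] += gwk
        return G

    lu = None
    if not asm.has_sten:
        beta0 = alpha + asm.R
        g0 = 1.0 / beta0
        from scipy.linalg import lu_factor, lu_solve

        lu = lu_factor(build_G(g0))

    err = np.inf
    cycles = 0
    q_cycle = np.empty((n_steps, asm.n_segs))
    p_cycle = np.empty((n_steps, n_nodes))

    while cycles < opts.max_cycles:
        for k in range(n_steps):
            qin = qin_cycle[k]
            q_star = q.copy()
            for _ in range(opts.stenosis_iterations if asm.has_sten else 1):
                beta = alpha + asm.R + asm.kt * np.abs(q_star)
                g = 1.0 / beta
                b = alpha * q / beta
                rhs = np.zeros(n_nodes)
                np.add.at(rhs, iu, -b)
                np.add.at(rhs, iv, b)
                rhs[asm.inlet_idx] += qin
                rhs[asm.outlet_node_idx] += hcoef * pc
                if lu is not None:
                    from scipy.linalg import lu_solve

                    P = lu_solve(lu, rhs)
                else:
                    P = np.linalg.solve(build_G(g), rhs)
                q_new = g * (P[iu] - P[iv]) + b
                if not asm.has_sten:
                    q_star = q_new
                    break
                if np.max(np.abs(q_new - q_star)) <= opts.stenosis_tol * (
                    1.0 + np.max(np.abs(q_new))
                ):
                    q_star = q_new
                    break
                q_star = q_new
            q = q_star
            p_out = P[asm.outlet_node_idx]
            pc = (asm.C / dt * pc + p_out / asm.rp) / D
            q_cycle[k] = q
            p_cycle[k] = P
        flows_hist.append(q_cycle.copy())
        press_hist.append(p_cycle.copy())
        cycles += 1
        if cycles >= 2:
            a_q, b_q = flows_hist[-1], flows_hist[-2]
            a_p, b_p = press_hist[-1], press_hist[-2]
            err = 0.0
            for a, b in ((a_q, b_q), (a_p, b_p)):
                num = np.linalg.norm(a - b, axis=0)
                den = np.maximum(np.linalg.norm(a, axis=0), 1e-30)
                err = max(err, float(np.max(num / den)))
            if err < opts.periodicity_tol and cycles >= opts.min_cycles:
                break

    if err >= opts.periodicity_tol:
        raise ConvergenceError(
            f"no periodicity after {cycles} cycles (error {err:.3e} >= "
            f"{opts.periodicity_tol:.3e})",
            trace={"cycles": cycles, "periodicity_error": err},
        )

    all_q = np.concatenate(flows_hist, axis=0)
    all_p = np.concatenate(press_hist, axis=0)
    times = (np.arange(all_q.shape[0]) + 1) * dt
    seg_flows = {s.id: all_q[:, i] for i, s in enumerate(asm.segs)}
    node_pressures = {n: all_p[:, asm.node_index[n]] for n in asm.node_index}
    final_state = {
        "seg_flows": {s.id: float(q[i]) for i, s in enumerate(asm.segs)},
        "wk_pressures": {o: float(pc[i]) for i, o in enumerate(asm.outlet_names)},
    }
    return SimResult(
        times=times,
        seg_flows=seg_flows,
        node_pressures=node_pressures,
        period=period,
        dt=dt,
        cycles_run=cycles,
        periodicity_error=err,
        final_state=final_state,
    )


def steady_state_flows(
    network: NetworkModel, wk: Dict[str, WindkesselBC], q_in: float
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Pure-resistive steady solve (capacitors open, inertance irrelevant).

    Returns (segment flows, node pressures).  Stenosis elements are linearized
    iteratively on |q|.  Used for initialization and as an independent check of
    the transient solver's steady-state limit.
    """
    asm = _Assembled(network, wk, SolverOptions())
    n = asm.n_nodes
    q_abs = np.zeros(asm.n_segs)
    for _ in range(60):
        g = 1.0 / (asm.R + asm.kt * q_abs)
        G = np.zeros((n, n))
        np.add.at(G, (asm.iu, asm.iu), g)
        np.add.at(G, (asm.iv, asm.iv), g)
        np.add.at(G, (asm.iu, asm.iv), -g)
        np.add.at(G, (asm.iv, asm.iu), -g)
        G[asm.outlet_node_idx, asm.outlet_node_idx] += 1.0 / (asm.rp + asm.rd)
        rhs = np.zeros(n)
        rhs[asm.inlet_idx] = q_in
        P = np.linalg.solve(G, rhs)
        q = g * (P[asm.iu] - P[asm.iv])
        if np.max(np.abs(np.abs(q) - q_abs)) < 1e-14 * (1.0 + np.max(np.abs(q))):
            q_abs = np.abs(q)
            break
        q_abs = np.abs(q)
    flows = {s.id: float(q[i]) for i, s in enumerate(asm.segs)}
    press = {node: float(P[i]) for node, i in asm.node_index.items()}
    return flows, press
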