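"""Three-stage patient-specific calibration of Windkessel outlet parameters.

Stage 1 tunes each outlet's distal resistance with a proportional controller
until every outlet's cycle-mean flow matches its target within tolerance.
Stage 2 tunes a shared proximal/distal resistance ratio of the cerebral and
cerebellar outlets by bisection until simulated neck-artery pulsatility
matches the measured PC-MRI waveforms, holding each outlet's total resistance
fixed.  Stage 3 rescales total resistance and compliance multiplicatively
(preserving per-outlet splits) until systolic/diastolic pressure at the
brachial-surrogate node matches the cuff measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import units
from .errors import ConvergenceError
from .network import (
    NetworkModel,
    SimResult,
    SolverOptions,
    Waveform,
    solve_transient,
)
from .targets import (
    FlowTargets,
    InflowSummary,
    WindkesselSet,
    INTRACRANIAL_OUTLETS,
)

#: node whose pressure stands in for the brachial cuff (downstream subclavian)
BRACHIAL_OUTLET = "R_subclavian"


@dataclass
class CalibrationConfig:
    stage1_gain: float = 0.5
    stage1_tol: float = 0.01
    stage1_max_iterations: int = 60
    stage2_pulsatility_tol: float = 0.05
    stage2_max_iterations: int = 12
    stage2_ratio_bracket: tuple = (0.01, 0.9)
    stage3_pressure_tol_mmhg: float = 0.5
    stage3_max_iterations: int = 40
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if self.stage1_gain <= 0:
            raise ValueError("stage1_gain must be positive")
        for tol in (self.stage1_tol, self.stage2_pulsatility_tol, self.stage3_pressure_tol_mmhg):
            if tol <= 0:
                raise ValueError("tolerances must be positive")


@dataclass
class StageTrace:
    name: str
    iterations: List[dict] = field(default_factory=list)
    converged: bool = False


@dataclass
class CalibrationReport:
    stages: Dict[str, StageTrace] = field(default_factory=dict)
    final_wk: Optional[WindkesselSet] = None

    def to_dict(self) -> dict:
        return {
            "stages": {
                k: {"converged": v.converged, "iterations": v.iterations}
                for k, v in self.stages.items()
            },
            "windkessel": self.final_wk.to_dict() if self.final_wk else None,
        }


def _outlet_terminal_segment(network: NetworkModel, outlet: str) -> str:
    """Segment id whose to_node is the outlet's terminal node."""
    node = network.outlets[outlet]
    for s in network.segments:
        if s.to_node == node:
            return s.id
    raise KeyError(f"no segment terminates at outlet {outlet}")


def outlet_mean_flows(result: SimResult, network: NetworkModel) -> Dict[str, float]:
    return {
        o: result.mean_flow(_outlet_terminal_segment(network, o))
        for o in network.outlets
    }


def pulsatility_index(values: np.ndarray) -> float:
    """(Q_max - Q_min) / Q_mean of one cycle of a flow waveform."""
    mean = float(np.mean(values))
    if mean == 0.0:
        return np.nan
    return float((np.max(values) - np.min(values)) / mean)


# ---------------------------------------------------------------------------
# stage 1: mean-flow matching via distal resistance
# ---------------------------------------------------------------------------


def stage1_flow_match(
    network: NetworkModel,
    wk: WindkesselSet,
    targets: FlowTargets,
    inflow: Waveform,
    cfg: CalibrationConfig = CalibrationConfig(),
    trace: Optional[StageTrace] = None,
    state: Optional[dict] = None,
) -> tuple:
    """Proportional control of R_d per outlet toward the target mean flows.

    Returns (WindkesselSet, SimResult, StageTrace).  Updates are applied once
    per cardiac cycle on the cycle-mean flow.
    """
    wk = wk.copy()
    trace = trace if trace is not None else StageTrace(name="stage1")
    result = None
    for it in range(cfg.stage1_max_iterations):
        result = solve_transient(network, wk.bcs, inflow, cfg.solver, initial_state=state)
        state = result.final_state
        flows = outlet_mean_flows(result, network)
        errs = {
            o: (flows[o] - targets.targets[o]) / targets.targets[o]
            for o in network.outlets
        }
        max_err = max(abs(e) for e in errs.values())
        trace.iterations.append(
            {"iteration": it, "max_rel_flow_error": max_err, "errors": errs}
        )
        if max_err < cfg.stage1_tol:
            trace.converged = True
            return wk, result, trace, state
        for o in network.outlets:
            bc = wk.bcs[o]
            new_rd = max(bc.r_dist * (1.0 + cfg.stage1_gain * errs[o]), 0.0)
            wk.replace(o, r_dist=new_rd)
    raise ConvergenceError(
        f"stage 1 did not reach {cfg.stage1_tol:.1%} flow error in "
        f"{cfg.stage1_max_iterations} iterations (last max error {max_err:.3%})",
        trace=trace,
    )


# ---------------------------------------------------------------------------
# stage 2: pulsatility matching via the R_p/R_d split
# ---------------------------------------------------------------------------


def _apply_ratio(wk: WindkesselSet, ratio: float) -> WindkesselSet:
    """Set r_prox = ratio * R_i on every cerebral/cerebellar outlet, holding
    each outlet's total resistance exactly."""
    out = wk.copy()
    for o in INTRACRANIAL_OUTLETS:
        if o not in out.bcs:
            continue
        total = out.bcs[o].total
        out.replace(o, r_prox=ratio * total, r_dist=(1.0 - ratio) * total)
    return out


def _neck_pi_error(
    network: NetworkModel,
    wk: WindkesselSet,
    inflow: Waveform,
    measured_neck: Dict[str, Waveform],
    solver: SolverOptions,
    state: Optional[dict],
) -> tuple:
    result = solve_transient(network, wk.bcs, inflow, solver, initial_state=state)
    signed, absolute, n = 0.0, 0.0, 0
    for artery, wf in measured_neck.items():
        seg_id = network.neck_arteries[artery]
        sim = result.last_cycle(result.seg_flows[seg_id])
        pi_sim = pulsatility_index(sim)
        pi_meas = pulsatility_index(wf.values)
        if not (np.isfinite(pi_sim) and np.isfinite(pi_meas)):
            continue
        signed += pi_sim - pi_meas
        absolute += abs(pi_sim - pi_meas)
        n += 1
    if n == 0:
        raise ConvergenceError("no usable neck waveforms for stage 2")
    return signed / n, absolute / n, result


def stage2_pulsatility(
    network: NetworkModel,
    wk: WindkesselSet,
    measured_neck: Dict[str, Waveform],
    inflow: Waveform,
    cfg: CalibrationConfig = CalibrationConfig(),
    state: Optional[dict] = None,
) -> tuple:
    """Bisection on the shared intracranial R_p/R_i ratio.

    Per-outlet total resistance is restored exactly after every trial.  If no
    ratio in the bracket brackets a sign change, the best sampled ratio is
    returned with the trace flagged.
    """
    trace = StageTrace(name="stage2")
    totals_before = {o: wk.bcs[o].total for o in wk.bcs}

    cache = {}

    def ev(ratio):
        if ratio not in cache:
            trial = _apply_ratio(wk, ratio)
            cache[ratio] = _neck_pi_error(
                network, trial, inflow, measured_neck, cfg.solver, state
            )
        return cache[ratio]

    # current operating point first: unchanged if already within tolerance
    present = [o for o in INTRACRANIAL_OUTLETS if o in wk.bcs]
    if not present:
        raise ConvergenceError("no cerebral/cerebellar outlets to adjust in stage 2")
    ref = wk.bcs[present[0]]
    ratio0 = ref.r_prox / ref.total
    signed0, abs0, result0 = ev(ratio0)
    trace.iterations.append({"ratio": ratio0, "mean_abs_pi_error": abs0})
    if abs0 < cfg.stage2_pulsatility_tol:
        trace.converged = True
        out = _apply_ratio(wk, ratio0)
        _assert_totals(out, totals_before)
        return out, result0, trace

    lo, hi = cfg.stage2_ratio_bracket
    s_lo, a_lo, _ = ev(lo)
    s_hi, a_hi, _ = ev(hi)
    best_ratio, best_abs = min(
        [(ratio0, abs0), (lo, a_lo), (hi, a_hi)], key=lambda t: t[1]
    )
    if s_lo * s_hi > 0:
        trace.iterations.append({"flag": "no sign change in bracket"})
        out = _apply_ratio(wk, best_ratio)
        _assert_totals(out, totals_before)
        signed, absolute, result = ev(best_ratio)
        return out, result, trace

    for _ in range(cfg.stage2_max_iterations):
        mid = 0.5 * (lo + hi)
        s_mid, a_mid, result = ev(mid)
        trace.iterations.append({"ratio": mid, "mean_abs_pi_error": a_mid})
        if a_mid < best_abs:
            best_ratio, best_abs = mid, a_mid
        if a_mid < cfg.stage2_pulsatility_tol:
            trace.converged = True
            best_ratio = mid
            break
        if s_lo * s_mid <= 0:
            hi, s_hi = mid, s_mid
        else:
            lo, s_lo = mid, s_mid

    out = _apply_ratio(wk, best_ratio)
    _assert_totals(out, totals_before)
    signed, absolute, result = ev(best_ratio)
    return out, result, trace


def _assert_totals(wk: WindkesselSet, totals: Dict[str, float]) -> None:
    for o, t in totals.items():
        assert wk.bcs[o].total == t or abs(wk.bcs[o].total - t) <= 4 * np.finfo(float).eps * t


# ---------------------------------------------------------------------------
# stage 3: brachial pressure matching via global R/C rescaling
# ---------------------------------------------------------------------------


def _rescale(wk: WindkesselSet, r_factor: float, c_factor: float) -> WindkesselSet:
    out = wk.copy()
    for o in list(out.bcs):
        bc = out.bcs[o]
        out.replace(
            o,
            r_prox=bc.r_prox * r_factor,
            r_dist=bc.r_dist * r_factor,
            capacitance=bc.capacitance * c_factor,
        )
    out.r_total *= r_factor
    out.c_total *= c_factor
    return out


def stage3_pressure_match(
    network: NetworkModel,
    wk: WindkesselSet,
    p_sys_meas: float,
    p_dia_meas: float,
    inflow: Waveform,
    cfg: CalibrationConfig = CalibrationConfig(),
    state: Optional[dict] = None,
    brachial_outlet: str = BRACHIAL_OUTLET,
) -> tuple:
    """Iterate R_T <- R_T * (Pmean_meas/Pmean_sim), C_T <- C_T * (pulse_sim/
    pulse_meas) until systolic and diastolic errors at the brachial node are
    below tolerance; changes are applied multiplicatively to every outlet."""
    trace = StageTrace(name="stage3")
    wk = wk.copy()
    node = network.outlets[brachial_outlet]
    tol = cfg.stage3_pressure_tol_mmhg * units.MMHG_TO_PA
    p_mean_meas = p_sys_meas / 3.0 + 2.0 * p_dia_meas / 3.0
    pulse_meas = p_sys_meas - p_dia_meas
    prev_err = np.inf
    increases = 0
    damping = 1.0
    result = None
    for it in range(cfg.stage3_max_iterations):
        result = solve_transient(network, wk.bcs, inflow, cfg.solver, initial_state=state)
        state = result.final_state
        p = result.last_cycle(result.node_pressures[node])
        p_sys_sim, p_dia_sim = float(np.max(p)), float(np.min(p))
        err_sys = p_sys_sim - p_sys_meas
        err_dia = p_dia_sim - p_dia_meas
        err = max(abs(err_sys), abs(err_dia))
        trace.iterations.append(
            {
                "iteration": it,
                "p_sys_mmhg": p_sys_sim * units.PA_TO_MMHG,
                "p_dia_mmhg": p_dia_sim * units.PA_TO_MMHG,
                "max_abs_error_mmhg": err * units.PA_TO_MMHG,
            }
        )
        if err < tol:
            trace.converged = True
            return wk, result, trace, state
        if err > prev_err:
            increases += 1
            if increases >= 3:
                if damping > 0.3:
                    damping = 0.25  # damped retry
                    increases = 0
                else:
                    raise ConvergenceError(
                        "stage 3 oscillating: pressure error increased on three "
                        "consecutive iterations despite damping",
                        trace=trace,
                    )
        else:
            increases = 0
        prev_err = err
        p_mean_sim = p_sys_sim / 3.0 + 2.0 * p_dia_sim / 3.0
        pulse_sim = p_sys_sim - p_dia_sim
        r_factor = (p_mean_meas / p_mean_sim) ** damping
        c_factor = (pulse_sim / pulse_meas) ** damping
        wk = _rescale(wk, r_factor, c_factor)
    raise ConvergenceError(
        f"stage 3 did not match brachial pressures within "
        f"{cfg.stage3_pressure_tol_mmhg} mmHg in {cfg.stage3_max_iterations} "
        "iterations",
        trace=trace,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class CalibratedModel:
    network: NetworkModel
    windkessel: WindkesselSet
    inflow: Waveform
    result: SimResult
    targets: FlowTargets
    summary: InflowSummary


def calibrate(
    network: NetworkModel,
    wk0: WindkesselSet,
    targets: FlowTargets,
    inflow: Waveform,
    measured_neck: Dict[str, Waveform],
    summary: InflowSummary,
    cfg: CalibrationConfig = CalibrationConfig(),
) -> tuple:
    """Run stages 1-3 in order, then re-check stage-1 flow errors once.

    Returns (CalibratedModel, CalibrationReport).
    """
    report = CalibrationReport()
    wk, result, tr1, state = stage1_flow_match(network, wk0, targets, inflow, cfg)
    report.stages["stage1"] = tr1

    wk, result, tr2 = stage2_pulsatility(network, wk, measured_neck, inflow, cfg, state)
    report.stages["stage2"] = tr2
    state = result.final_state

    wk, result, tr3, state = stage3_pressure_match(
        network, wk, summary.p_systolic, summary.p_diastolic, inflow, cfg, state
    )
    report.stages["stage3"] = tr3

    # stage 3 rescaled R_T; verify stage-1 flow splits survived
    flows = outlet_mean_flows(result, network)
    max_err = max(
        abs(flows[o] - targets.targets[o]) / targets.targets[o] for o in network.outlets
    )
    if max_err >= cfg.stage1_tol:
        wk, result, tr1b, state = stage1_flow_match(
            network, wk, targets, inflow, cfg, state=state
        )
        report.stages["stage1_recheck"] = tr1b

    report.final_wk = wk
    model = CalibratedModel(
        network=network,
        windkessel=wk,
        inflow=inflow,
        result=result,
        targets=targets,
        summary=summary,
    )
    return model, report
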