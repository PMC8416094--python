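"""Hemodynamic assessment metrics: trans-stenotic pressure drop, fractional
flow, and distal-vasculature outlet resistances, reported in clinical units."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import units
from .calibration import CalibratedModel, outlet_mean_flows
from .errors import CerebroflowError
from .network import NetworkModel, SimResult
from .tracking import FBSComparison

#: fractional-flow significance threshold, reported as an annotation only
FF_THRESHOLD = 0.8


@dataclass(frozen=True)
class StenosisAssessment:
    vessel_id: str
    p_prox_mean_mmhg: float
    p_dist_mean_mmhg: float
    q_mean_mlps: float

    @property
    def dp_mean_mmhg(self) -> float:
        return self.p_prox_mean_mmhg - self.p_dist_mean_mmhg

    @property
    def ff(self) -> float:
        return self.p_dist_mean_mmhg / self.p_prox_mean_mmhg

    @property
    def below_threshold(self) -> bool:
        return self.ff < FF_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "vessel": self.vessel_id,
            "p_prox_mean_mmhg": self.p_prox_mean_mmhg,
            "p_dist_mean_mmhg": self.p_dist_mean_mmhg,
            "q_mean_mlps": self.q_mean_mlps,
            "dp_mean_mmhg": self.dp_mean_mmhg,
            "ff": self.ff,
            "ff_threshold": FF_THRESHOLD,
            "ff_below_threshold": self.below_threshold,
        }


@dataclass(frozen=True)
class OutletSummary:
    outlet: str
    p_mean_mmhg: float
    q_mean_mlps: float

    @property
    def r_total(self) -> float:
        return outlet_resistance(self.p_mean_mmhg, self.q_mean_mlps)

    def to_dict(self) -> dict:
        return {
            "outlet": self.outlet,
            "p_mean_mmhg": self.p_mean_mmhg,
            "q_mean_mlps": self.q_mean_mlps,
            "r_total_pa_s_m3": self.r_total,
        }


def pressure_drop(
    result: SimResult,
    network: NetworkModel,
    vessel_id: str,
    prox_node: Optional[str] = None,
    dist_node: Optional[str] = None,
) -> StenosisAssessment:
    """Cycle-mean pressures at the nodes bracketing a vessel and the derived
    dP/FF assessment.  Defaults to the vessel's own end nodes."""
    seg = network.segment(vessel_id)
    prox = prox_node or seg.from_node
    dist = dist_node or seg.to_node
    for node in (prox, dist):
        if node not in result.node_pressures:
            raise CerebroflowError(f"node {node!r} absent from the simulation result")
    p_prox = result.mean_pressure(prox)
    p_dist = result.mean_pressure(dist)
    if p_prox <= 0:
        raise CerebroflowError(
            f"nonpositive proximal mean pressure at {prox}; FF undefined"
        )
    return StenosisAssessment(
        vessel_id=vessel_id,
        p_prox_mean_mmhg=p_prox * units.PA_TO_MMHG,
        p_dist_mean_mmhg=p_dist * units.PA_TO_MMHG,
        q_mean_mlps=result.mean_flow(vessel_id) * units.M3PS_TO_MLPS,
    )


def outlet_resistance(p_mean_mmhg: float, q_mean_mlps: float) -> float:
    """Outlet resistance P_mean/Q_mean [Pa s m^-3], venous reference 0."""
    if q_mean_mlps <= 0:
        raise CerebroflowError("outlet resistance requires positive mean flow")
    return (p_mean_mmhg * units.MMHG_TO_PA) / (q_mean_mlps * units.MLPS_TO_M3PS)


def hemodynamic_report(
    model: CalibratedModel,
    fbs_tables: Optional[Dict[str, object]] = None,
    comparison: Optional[FBSComparison] = None,
) -> dict:
    """Aggregate all assessment metrics into one JSON-serializable report."""
    network, result = model.network, model.result
    stenoses = [
        pressure_drop(result, network, s.id)
        for s in network.segments
        if s.stenosis is not None
    ]
    flows = outlet_mean_flows(result, network)
    outlets = []
    for o, node in model.network.outlets.items():
        outlets.append(
            OutletSummary(
                outlet=o,
                p_mean_mmhg=result.mean_pressure(node) * units.PA_TO_MMHG,
                q_mean_mlps=flows[o] * units.M3PS_TO_MLPS,
            )
        )
    report = {
        "stenoses": [s.to_dict() for s in stenoses],
        "outlets": [o.to_dict() for o in outlets],
        "cycles_run": result.cycles_run,
        "periodicity_error": result.periodicity_error,
    }
    if fbs_tables:
        report["fbs"] = {
            name: table.to_long().to_dict(orient="records")
            for name, table in fbs_tables.items()
        }
    if comparison is not None:
        report["fbs_comparison"] = comparison.to_dict()
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


def plot_report(model: CalibratedModel, out_dir) -> list:
    """Waveform plots for the neck arteries and stenosis pressures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    result, network = model.result, model.network
    n = result.steps_per_cycle
    t = np.arange(n) * result.dt

    fig, ax = plt.subplots(figsize=(7, 4))
    for artery, sid in network.neck_arteries.items():
        ax.plot(t, result.last_cycle(result.seg_flows[sid]) * units.M3PS_TO_MLPS,
                label=artery)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("flow [ml/s]")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "neck_flows.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)
    return written
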