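"""Per-outlet target mean flows and initial Windkessel parameters.

Combines ASL perfusion splits, PC-MRI waveforms, and brachial pressure into a
full 13-outlet target-flow vector, then distributes total resistance and
compliance across the outlets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .asl import PerfusionSplit, TerritoryArteryMap, TERRITORY_NAMES
from .errors import (
    DegenerateSignalError,
    InconsistentMeasurementsError,
    CerebroflowError,
)
from .network import Waveform, WindkesselBC

INTRACRANIAL_OUTLETS = ("RACA", "LACA", "RMCA", "LMCA", "RPCA", "LPCA", "RSCA", "LSCA")
EXTRACRANIAL_OUTLETS = ("RECA", "LECA", "R_subclavian", "L_subclavian", "desc_aorta")
ALL_OUTLETS = INTRACRANIAL_OUTLETS + EXTRACRANIAL_OUTLETS

#: mean subclavian flow as a fraction of cardiac output, applied per subclavian
SUBCLAVIAN_FRACTION = 0.056

#: initial proximal share of each outlet's total resistance
R_PROX_FRACTION = 0.06


@dataclass(frozen=True)
class InflowSummary:
    """Aortic-inflow and brachial-pressure summary (all SI)."""

    q_mean: float
    q_max: float
    q_min: float
    dt_max_to_min: float
    p_systolic: float
    p_diastolic: float
    period: float

    def __post_init__(self):
        if self.q_max < self.q_min:
            raise DegenerateSignalError("q_max < q_min")
        if self.p_systolic <= self.p_diastolic:
            raise DegenerateSignalError("systolic pressure must exceed diastolic")
        if not (0.0 < self.dt_max_to_min < self.period):
            raise DegenerateSignalError("dt_max_to_min must lie in (0, period)")

    @property
    def p_mean(self) -> float:
        """Mean arterial pressure: P_sys/3 + 2 P_dia/3."""
        return self.p_systolic / 3.0 + 2.0 * self.p_diastolic / 3.0


@dataclass
class FlowTargets:
    """Target mean flow per outlet [m^3/s] for all 13 outlets."""

    targets: Dict[str, float]
    q_cow: float

    def __post_init__(self):
        missing = [o for o in ALL_OUTLETS if o not in self.targets]
        if missing:
            raise CerebroflowError(f"flow targets missing outlets: {missing}")

    @property
    def total(self) -> float:
        return sum(self.targets.values())

    @property
    def intracranial_total(self) -> float:
        return sum(self.targets[o] for o in INTRACRANIAL_OUTLETS)


@dataclass
class WindkesselSet:
    """Per-outlet three-element Windkessel parameters plus the totals."""

    bcs: Dict[str, WindkesselBC]
    r_total: float
    c_total: float

    def parallel_resistance(self) -> float:
        return 1.0 / sum(1.0 / bc.total for bc in self.bcs.values())

    def total_capacitance(self) -> float:
        return sum(bc.capacitance for bc in self.bcs.values())

    def replace(self, outlet: str, **kw) -> None:
        bc = self.bcs[outlet]
        self.bcs[outlet] = WindkesselBC(
            outlet_id=outlet,
            r_prox=kw.get("r_prox", bc.r_prox),
            r_dist=kw.get("r_dist", bc.r_dist),
            capacitance=kw.get("capacitance", bc.capacitance),
        )

    def copy(self) -> "WindkesselSet":
        return WindkesselSet(bcs=dict(self.bcs), r_total=self.r_total, c_total=self.c_total)

    def to_dict(self) -> dict:
        return {
            "r_total": self.r_total,
            "c_total": self.c_total,
            "outlets": {
                o: {
                    "r_prox": bc.r_prox,
                    "r_dist": bc.r_dist,
                    "capacitance": bc.capacitance,
                }
                for o, bc in self.bcs.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WindkesselSet":
        bcs = {
            o: WindkesselBC(
                outlet_id=o,
                r_prox=v["r_prox"],
                r_dist=v["r_dist"],
                capacitance=v["capacitance"],
            )
            for o, v in d["outlets"].items()
        }
        return cls(bcs=bcs, r_total=d["r_total"], c_total=d["c_total"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def summarize_inflow(aortic: Waveform, p_sys: float, p_dia: float) -> InflowSummary:
    """Extract Q_T, extrema, and the max-to-min time lapse from the inflow.

    The lapse wraps across the period end so it is always positive.
    """
    v = aortic.values
    if float(np.max(v)) == float(np.min(v)):
        raise DegenerateSignalError("flat aortic waveform")
    i_max = int(np.argmax(v))
    i_min = int(np.argmin(v))
    t_max = float(aortic.times[i_max])
    t_min = float(aortic.times[i_min])
    dt = (t_min - t_max) % aortic.period
    return InflowSummary(
        q_mean=aortic.mean,
        q_max=float(v[i_max]),
        q_min=float(v[i_min]),
        dt_max_to_min=dt,
        p_systolic=p_sys,
        p_diastolic=p_dia,
        period=aortic.period,
    )


def total_resistance(summary: InflowSummary) -> float:
    """R_T = P_mean / Q_T with P_mean = P_sys/3 + 2 P_dia/3."""
    if summary.q_mean <= 0:
        raise InconsistentMeasurementsError("cardiac output must be positive")
    return summary.p_mean / summary.q_mean


def total_compliance(summary: InflowSummary) -> float:
    """C_T = (Q_max - Q_min)/(P_sys - P_dia) * dt(max->min)."""
    pulse = summary.p_systolic - summary.p_diastolic
    if pulse <= 0:
        raise InconsistentMeasurementsError("zero pulse pressure")
    return (summary.q_max - summary.q_min) / pulse * summary.dt_max_to_min


def intracranial_targets(
    ps: PerfusionSplit,
    q_cow: float,
    territory_map: Optional[TerritoryArteryMap] = None,
    available_arteries: Optional[set] = None,
) -> Dict[str, float]:
    """Per intracranial artery target: q_cow * ps_j * artery share.

    If ``available_arteries`` is given, arteries absent from the network whose
    territory share is positive are reported via CerebroflowError so the map
    can be amended, never silently dropped.
    """
    if q_cow <= 0:
        raise InconsistentMeasurementsError("total CoW inflow must be positive")
    tmap = territory_map or TerritoryArteryMap()
    out: Dict[str, float] = {}
    missing = []
    for terr in TERRITORY_NAMES:
        for artery, share in tmap.arteries_of(terr):
            if available_arteries is not None and artery not in available_arteries:
                if share > 0:
                    missing.append((terr, artery, share))
                continue
            out[artery] = out.get(artery, 0.0) + q_cow * ps.ps[terr] * share
    if missing:
        raise CerebroflowError(
            f"territory shares assigned to arteries absent from the network: {missing}"
        )
    return out


def cow_inflow(
    ica_r: Optional[Waveform],
    ica_l: Optional[Waveform],
    va_r: Optional[Waveform],
    va_l: Optional[Waveform],
) -> float:
    """Total mean inflow to the CoW: sum of ICA and VA mean flows.

    A missing (hypoplastic) vessel contributes zero with a warning.
    """
    total = 0.0
    any_present = False
    for name, wf in (("RICA", ica_r), ("LICA", ica_l), ("RVA", va_r), ("LVA", va_l)):
        if wf is None:
            warnings.warn(f"neck artery {name} waveform missing; assuming zero flow")
            continue
        total += wf.mean
        any_present = True
    if not any_present or total == 0.0:
        warnings.warn("total CoW inflow is zero")
    return total


def extracranial_targets(
    eca_r: Waveform,
    eca_l: Waveform,
    summary: InflowSummary,
    intracranial_total: float,
    subclavian_fraction: float = SUBCLAVIAN_FRACTION,
) -> Dict[str, float]:
    """ECA targets from PC-MRI; each subclavian at a fixed fraction of cardiac
    output; descending aorta takes the remainder."""
    q_t = summary.q_mean
    q_reca, q_leca = eca_r.mean, eca_l.mean
    q_sub = subclavian_fraction * q_t
    q_desc = q_t - (intracranial_total + q_reca + q_leca + 2.0 * q_sub)
    if q_desc < 0:
        raise InconsistentMeasurementsError(
            f"assigned branch flows exceed cardiac output by {-q_desc:.3e} m^3/s"
        )
    return {
        "RECA": q_reca,
        "LECA": q_leca,
        "R_subclavian": q_sub,
        "L_subclavian": q_sub,
        "desc_aorta": q_desc,
    }


def assemble_targets(
    intracranial: Dict[str, float], extracranial: Dict[str, float], q_cow: float
) -> FlowTargets:
    targets = dict(intracranial)
    targets.update(extracranial)
    return FlowTargets(targets=targets, q_cow=q_cow)


def init_windkessel(
    targets: FlowTargets,
    summary: InflowSummary,
    r_prox_fraction: float = R_PROX_FRACTION,
) -> WindkesselSet:
    """Distribute R_T and C_T over outlets from the flow targets.

    R_i = P_mean / Q_target_i (so parallel(R_i) = R_T and each outlet draws its
    target at mean pressure); C_i = C_T * R_T / R_i (compliance proportional to
    flow share); R_i split into r_prox/r_dist by ``r_prox_fraction``.
    """
    r_t = total_resistance(summary)
    c_t = total_compliance(summary)
    p_mean = summary.p_mean
    bcs = {}
    for outlet, q in targets.targets.items():
        if q <= 0:
            raise InconsistentMeasurementsError(
                f"target flow for outlet {outlet} must be positive, got {q}"
            )
        r_i = p_mean / q
        c_i = c_t * r_t / r_i
        bcs[outlet] = WindkesselBC(
            outlet_id=outlet,
            r_prox=r_prox_fraction * r_i,
            r_dist=(1.0 - r_prox_fraction) * r_i,
            capacitance=c_i,
        )
    return WindkesselSet(bcs=bcs, r_total=r_t, c_total=c_t)
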