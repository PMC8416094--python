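"""Synthetic-cohort generator: networks, ground-truth Windkessel sets, and
noisy synthetic measurements (ASL volumes, PC-MRI-like waveforms, brachial
pressures) so that every pipeline stage can be tested against a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import units
from .asl import (
    FBSTable,
    PerfusionVolume,
    TerritoryAtlas,
    TerritoryArteryMap,
    NECK_ARTERY_ORDER,
    TERRITORY_NAMES,
    perfusion_splits,
    subtract_and_average,
)
from .errors import CerebroflowError
from .network import (
    BloodProperties,
    NetworkModel,
    SimResult,
    SolverOptions,
    VesselSegment,
    Waveform,
    make_stenosis,
    solve_transient,
)
from .targets import (
    FlowTargets,
    InflowSummary,
    WindkesselSet,
    init_windkessel,
    summarize_inflow,
    INTRACRANIAL_OUTLETS,
)
from .tracking import transport_fractions

ANATOMY_VARIANTS = ("complete", "pcom_hypoplasia_bilateral", "p1_and_va_hypoplasia")

GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class AnatomyVariant:
    """CoW anatomy variant plus optional stenoses (vessel, min-diameter frac)."""

    name: str = "complete"
    stenoses: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.name not in ANATOMY_VARIANTS:
            raise CerebroflowError(
                f"unknown variant {self.name!r}; choose from {ANATOMY_VARIANTS}"
            )


@dataclass
class AcquisitionSpec:
    """Parameters of the emulated acquisition."""

    grid_shape: Tuple[int, int, int] = (64, 64, 24)
    voxel_size_mm: Tuple[float, float, float] = (3.0, 3.0, 6.0)
    asl_noise_sd: float = 0.0  # fraction of mean territory signal
    n_pairs: int = 8
    labeling_efficiencies: Dict[str, float] = field(
        default_factory=lambda: {a: 0.85 for a in NECK_ARTERY_ORDER}
    )
    waveform_noise_sd: float = 0.0  # fraction of mean absolute flow
    seed: int = 0

    def __post_init__(self):
        if self.asl_noise_sd < 0 or self.waveform_noise_sd < 0:
            raise CerebroflowError("noise standard deviations must be nonnegative")
        for a, e in self.labeling_efficiencies.items():
            if not (0.0 < e <= 1.0):
                raise CerebroflowError(f"labeling efficiency for {a} not in (0, 1]")


# ---------------------------------------------------------------------------
# network templates
# ---------------------------------------------------------------------------

# (id, name, from, to, length m, radius m)
_SEGMENT_TABLE = [
    ("aorta_asc", "ascending aorta", "inlet", "arch", 0.060, 0.0145),
    ("aorta_desc", "descending aorta", "arch", "desc_aorta_out", 0.200, 0.0110),
    ("brachioceph", "brachiocephalic trunk", "arch", "bct", 0.035, 0.0060),
    ("r_subclavian_prox", "R subclavian", "bct", "rsub", 0.040, 0.0040),
    ("r_subclavian_dist", "R subclavian distal", "rsub", "rsub_out", 0.050, 0.0035),
    ("l_subclavian_prox", "L subclavian", "arch", "lsub", 0.045, 0.0040),
    ("l_subclavian_dist", "L subclavian distal", "lsub", "lsub_out", 0.050, 0.0035),
    ("r_cca", "R common carotid", "bct", "rcb", 0.120, 0.0035),
    ("l_cca", "L common carotid", "arch", "lcb", 0.130, 0.0035),
    ("reca", "RECA", "rcb", "reca_out", 0.040, 0.0020),
    ("leca", "LECA", "lcb", "leca_out", 0.040, 0.0020),
    ("rica", "RICA", "rcb", "rica_end", 0.150, 0.0025),
    ("lica", "LICA", "lcb", "lica_end", 0.150, 0.0025),
    ("rva", "RVA", "rsub", "rva_mid", 0.100, 0.0017),
    ("rva_distal", "RVA distal", "rva_mid", "vb_junction", 0.100, 0.0017),
    ("lva", "LVA", "lsub", "lva_mid", 0.100, 0.0017),
    ("lva_distal", "LVA distal", "lva_mid", "vb_junction", 0.100, 0.0017),
    ("basilar", "basilar", "vb_junction", "bas_top", 0.030, 0.0016),
    ("rsca", "RSCA", "bas_top", "rsca_out", 0.020, 0.0008),
    ("lsca", "LSCA", "bas_top", "lsca_out", 0.020, 0.0008),
    ("r_p1", "R P1", "bas_top", "rpca_n", 0.010, 0.0011),
    ("l_p1", "L P1", "bas_top", "lpca_n", 0.010, 0.0011),
    ("rpca", "RPCA", "rpca_n", "rpca_out", 0.040, 0.0011),
    ("lpca", "LPCA", "lpca_n", "lpca_out", 0.040, 0.0011),
    ("r_pcom", "R PComA", "rica_end", "rpca_n", 0.015, 0.0007),
    ("l_pcom", "L PComA", "lica_end", "lpca_n", 0.015, 0.0007),
    ("rmca", "RMCA", "rica_end", "rmca_out", 0.050, 0.0014),
    ("lmca", "LMCA", "lica_end", "lmca_out", 0.050, 0.0014),
    ("r_a1", "R A1", "rica_end", "raca_n", 0.013, 0.0011),
    ("l_a1", "L A1", "lica_end", "laca_n", 0.013, 0.0011),
    ("acom", "AComA", "raca_n", "laca_n", 0.003, 0.00074),
    ("raca", "RACA", "raca_n", "raca_out", 0.040, 0.0011),
    ("laca", "LACA", "laca_n", "laca_out", 0.040, 0.0011),
]

_OUTLET_NODES = {
    "desc_aorta": "desc_aorta_out",
    "R_subclavian": "rsub_out",
    "L_subclavian": "lsub_out",
    "RECA": "reca_out",
    "LECA": "leca_out",
    "RACA": "raca_out",
    "LACA": "laca_out",
    "RMCA": "rmca_out",
    "LMCA": "lmca_out",
    "RPCA": "rpca_out",
    "LPCA": "lpca_out",
    "RSCA": "rsca_out",
    "LSCA": "lsca_out",
}

_NECK_SEGMENTS = {"RICA": "rica", "LICA": "lica", "RVA": "rva", "LVA": "lva"}

_VARIANT_REMOVALS = {
    "complete": (),
    "pcom_hypoplasia_bilateral": ("r_pcom", "l_pcom"),
    "p1_and_va_hypoplasia": ("r_p1", "rva_distal"),
}


def make_network(
    variant: AnatomyVariant = AnatomyVariant(),
    seed: int = 0,
    blood: BloodProperties = BloodProperties(),
) -> NetworkModel:
    """Deterministic network for a given (variant, seed).

    Hypoplasia is encoded by removing segments; stenoses attach nonlinear
    loss elements to named segments.  ``seed`` is reserved for future
    geometric jitter; current templates are seed-independent.
    """
    removed = set(_VARIANT_REMOVALS[variant.name])
    sten_by_seg = {}
    for seg_name, frac in variant.stenoses:
        key = seg_name.lower()
        if key in removed:
            raise CerebroflowError(
                f"stenosis requested on removed segment {seg_name!r}"
            )
        sten_by_seg[key] = frac
    known_ids = {row[0] for row in _SEGMENT_TABLE}
    for key in sten_by_seg:
        if key not in known_ids:
            raise CerebroflowError(f"stenosis on unknown segment {key!r}")

    segments = []
    for sid, name, frm, to, length, radius in _SEGMENT_TABLE:
        if sid in removed:
            continue
        sten = None
        if sid in sten_by_seg:
            sten = make_stenosis(radius, sten_by_seg[sid], blood=blood)
        segments.append(
            VesselSegment(
                id=sid, name=name, from_node=frm, to_node=to,
                length=length, radius=radius, stenosis=sten, blood=blood,
            )
        )
    return NetworkModel(
        segments=segments,
        inlet="inlet",
        outlets=dict(_OUTLET_NODES),
        neck_arteries=dict(_NECK_SEGMENTS),
    )


# ---------------------------------------------------------------------------
# physiological defaults for the synthetic subject
# ---------------------------------------------------------------------------

#: nominal territory perfusion splits for the synthetic truth
DEFAULT_SPLITS = {
    "RACA": 0.105,
    "LACA": 0.105,
    "RMCA": 0.27,
    "LMCA": 0.27,
    "RPCA": 0.08,
    "LPCA": 0.08,
    "Cerebellum": 0.09,
}

DEFAULT_CARDIAC_OUTPUT_MLPS = 83.0
DEFAULT_COW_INFLOW_MLPS = 12.0
DEFAULT_ECA_FLOW_MLPS = 2.0
DEFAULT_P_SYS_MMHG = 120.0
DEFAULT_P_DIA_MMHG = 80.0
DEFAULT_PERIOD_S = 1.0


def aortic_inflow_waveform(
    cardiac_output_mlps: float = DEFAULT_CARDIAC_OUTPUT_MLPS,
    period: float = DEFAULT_PERIOD_S,
    n_samples: int = 200,
    systole_fraction: float = 0.33,
) -> Waveform:
    """Half-sine-squared systolic ejection with a small post-systolic dip."""
    t = np.arange(n_samples) / n_samples * period
    ts = systole_fraction * period
    shape = np.where(t < ts, np.sin(np.pi * t / ts) ** 2, 0.0)
    dip = -0.05 * np.exp(-(((t - ts - 0.04 * period) / (0.03 * period)) ** 2))
    shape = shape + dip
    mean_shape = float(np.mean(shape))
    amp = cardiac_output_mlps * units.MLPS_TO_M3PS / mean_shape
    return Waveform(times=t, values=amp * shape, period=period)


def default_ground_truth_targets(
    cardiac_output_mlps: float = DEFAULT_CARDIAC_OUTPUT_MLPS,
    cow_inflow_mlps: float = DEFAULT_COW_INFLOW_MLPS,
    eca_flow_mlps: float = DEFAULT_ECA_FLOW_MLPS,
    splits: Optional[Dict[str, float]] = None,
    subclavian_fraction: float = 0.056,
) -> FlowTargets:
    """Nominal 13-outlet targets consistent with the extracranial rule."""
    splits = splits or DEFAULT_SPLITS
    q_t = cardiac_output_mlps * units.MLPS_TO_M3PS
    q_cow = cow_inflow_mlps * units.MLPS_TO_M3PS
    tmap = TerritoryArteryMap()
    targets: Dict[str, float] = {}
    for terr in TERRITORY_NAMES:
        for artery, share in tmap.arteries_of(terr):
            targets[artery] = targets.get(artery, 0.0) + q_cow * splits[terr] * share
    q_eca = eca_flow_mlps * units.MLPS_TO_M3PS
    q_sub = subclavian_fraction * q_t
    targets["RECA"] = q_eca
    targets["LECA"] = q_eca
    targets["R_subclavian"] = q_sub
    targets["L_subclavian"] = q_sub
    targets["desc_aorta"] = q_t - (q_cow + 2 * q_eca + 2 * q_sub)
    return FlowTargets(targets=targets, q_cow=q_cow)


def default_true_windkessel(
    targets: Optional[FlowTargets] = None,
    inflow: Optional[Waveform] = None,
    p_sys_mmhg: float = DEFAULT_P_SYS_MMHG,
    p_dia_mmhg: float = DEFAULT_P_DIA_MMHG,
) -> WindkesselSet:
    targets = targets or default_ground_truth_targets()
    inflow = inflow if inflow is not None else aortic_inflow_waveform()
    summary = summarize_inflow(
        inflow, p_sys_mmhg * units.MMHG_TO_PA, p_dia_mmhg * units.MMHG_TO_PA
    )
    return init_windkessel(targets, summary)


# ---------------------------------------------------------------------------
# atlas + study synthesis
# ---------------------------------------------------------------------------


def make_atlas(spec: AcquisitionSpec) -> TerritoryAtlas:
    """Block-partition atlas: 7 slabs along x inside a 2-voxel background rim."""
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    margin = 2
    x0, x1 = margin, nx - margin
    edges = np.linspace(x0, x1, 8).astype(int)
    for j in range(7):
        labels[edges[j]:edges[j + 1], margin:ny - margin, margin:nz - margin] = j + 1
    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    return TerritoryAtlas(labels=labels, affine=affine)


@dataclass
class GroundTruth:
    windkessel: WindkesselSet
    outlet_flows: Dict[str, float]  # simulated mean flows of the true model
    splits: Dict[str, float]  # simulated intracranial splits
    fbs: FBSTable  # transport fractions on the true model
    result: SimResult
    brachial_p_sys: float
    brachial_p_dia: float


@dataclass
class SyntheticStudy:
    network: NetworkModel
    atlas: TerritoryAtlas
    ns_asl_labels: List[np.ndarray]
    ns_asl_controls: List[np.ndarray]
    vs_asl: Dict[str, PerfusionVolume]
    efficiencies: Dict[str, float]
    waveforms: Dict[str, Waveform]  # aorta + neck + ECA flows, with noise
    p_sys: float
    p_dia: float
    spec: AcquisitionSpec
    seed: int

    def ns_perfusion(self) -> PerfusionVolume:
        return subtract_and_average(
            self.ns_asl_labels, self.ns_asl_controls, affine=self.atlas.affine
        )


def _territory_flows(
    outlet_flows: Dict[str, float], tmap: TerritoryArteryMap
) -> Dict[str, float]:
    out = {}
    for terr in TERRITORY_NAMES:
        out[terr] = sum(
            outlet_flows.get(artery, 0.0) for artery, _ in tmap.arteries_of(terr)
        )
    return out


def forward_study(
    network: NetworkModel,
    true_wk: WindkesselSet,
    spec: AcquisitionSpec,
    inflow: Optional[Waveform] = None,
    solver: SolverOptions = SolverOptions(),
    true_result: Optional[SimResult] = None,
) -> Tuple[SyntheticStudy, GroundTruth]:
    """Simulate the true model and emit noisy synthetic measurements.

    NS-ASL territory signal is proportional to each territory's simulated
    blood flow; VS-ASL signal per neck artery is the NS signal times the true
    transport FBS, scaled down by labeling efficiency; waveforms and brachial
    pressures come from the simulation with additive measurement noise.
    """
    rng = np.random.default_rng(spec.seed)
    inflow = inflow if inflow is not None else aortic_inflow_waveform()
    result = true_result or solve_transient(network, true_wk.bcs, inflow, solver)
    tmap = TerritoryArteryMap()

    from .calibration import outlet_mean_flows

    outlet_flows = outlet_mean_flows(result, network)
    terr_flows = _territory_flows(outlet_flows, tmap)
    total_cow = sum(terr_flows.values())
    splits = {t: terr_flows[t] / total_cow for t in TERRITORY_NAMES}
    fbs_true = transport_fractions(result, network, territory_map=tmap)

    atlas = make_atlas(spec)

    # territory-constant NS signal whose territory integral tracks flow
    signal = np.zeros(spec.grid_shape)
    terr_signal_values = {}
    for lab, terr in atlas.territory_names.items():
        mask = atlas.mask(lab)
        val = terr_flows[terr] * units.M3PS_TO_MLPS / int(mask.sum())
        terr_signal_values[terr] = val
        signal[mask] = val
    mean_sig = float(np.mean([v for v in terr_signal_values.values()]))
    noise_sd = spec.asl_noise_sd * mean_sig

    baseline = 100.0 * mean_sig  # static tissue signal common to label/control
    labels_imgs, controls_imgs = [], []
    for _ in range(spec.n_pairs):
        ctl = baseline + (rng.normal(0.0, noise_sd, spec.grid_shape) if noise_sd else 0.0)
        lab = baseline - signal + (
            rng.normal(0.0, noise_sd, spec.grid_shape) if noise_sd else 0.0
        )
        controls_imgs.append(np.asarray(ctl) + np.zeros(spec.grid_shape))
        labels_imgs.append(np.asarray(lab) + np.zeros(spec.grid_shape))

    # vessel-selective volumes: NS signal x true FBS x efficiency (+ noise)
    vs = {}
    for artery in NECK_ARTERY_ORDER:
        eff = spec.labeling_efficiencies[artery]
        vol = np.zeros(spec.grid_shape)
        for lab, terr in atlas.territory_names.items():
            frac = float(fbs_true.median.loc[terr, artery])
            vol[atlas.mask(lab)] = terr_signal_values[terr] * frac * eff
        if noise_sd:
            vol = vol + rng.normal(0.0, noise_sd, spec.grid_shape)
        vs[artery] = PerfusionVolume(voxels=vol, affine=atlas.affine)

    # waveform exports with measurement noise
    def noisy(wf: Waveform) -> Waveform:
        if spec.waveform_noise_sd == 0:
            return wf
        sd = spec.waveform_noise_sd * float(np.mean(np.abs(wf.values)))
        return Waveform(
            times=wf.times,
            values=wf.values + rng.normal(0.0, sd, wf.values.shape),
            period=wf.period,
        )

    waveforms = {"aorta": noisy(inflow)}
    for artery, sid in network.neck_arteries.items():
        waveforms[artery] = noisy(result.flow_waveform(sid))
    for eca, sid in (("RECA", "reca"), ("LECA", "leca")):
        if sid in result.seg_flows:
            waveforms[eca] = noisy(result.flow_waveform(sid))

    from .calibration import BRACHIAL_OUTLET

    node = network.outlets[BRACHIAL_OUTLET]
    p = result.last_cycle(result.node_pressures[node])
    p_sys, p_dia = float(np.max(p)), float(np.min(p))

    study = SyntheticStudy(
        network=network,
        atlas=atlas,
        ns_asl_labels=labels_imgs,
        ns_asl_controls=controls_imgs,
        vs_asl=vs,
        efficiencies=dict(spec.labeling_efficiencies),
        waveforms=waveforms,
        p_sys=p_sys,
        p_dia=p_dia,
        spec=spec,
        seed=spec.seed,
    )
    truth = GroundTruth(
        windkessel=true_wk,
        outlet_flows=outlet_flows,
        splits=splits,
        fbs=fbs_true,
        result=result,
        brachial_p_sys=p_sys,
        brachial_p_dia=p_dia,
    )
    return study, truth


# ---------------------------------------------------------------------------
# end-to-end harness
# ---------------------------------------------------------------------------


def calibrate_study(study: SyntheticStudy, cfg=None):
    """Run the full measurement-to-model pipeline on a synthetic study."""
    from .asl import VSASLStudy, asl_fbs_table
    from .calibration import CalibrationConfig, calibrate
    from .targets import (
        assemble_targets,
        cow_inflow,
        extracranial_targets,
        intracranial_targets,
    )

    cfg = cfg or CalibrationConfig()
    perf = study.ns_perfusion()
    ps = perfusion_splits(perf, study.atlas)
    wf = study.waveforms
    q_cow = cow_inflow(wf.get("RICA"), wf.get("LICA"), wf.get("RVA"), wf.get("LVA"))
    summary = summarize_inflow(wf["aorta"], study.p_sys, study.p_dia)
    intr = intracranial_targets(ps, q_cow)
    extr = extracranial_targets(wf["RECA"], wf["LECA"], summary, sum(intr.values()))
    targets = assemble_targets(intr, extr, q_cow)
    wk0 = init_windkessel(targets, summary)
    measured_neck = {a: wf[a] for a in NECK_ARTERY_ORDER if a in wf}
    model, report = calibrate(
        study.network, wk0, targets, wf["aorta"], measured_neck, summary, cfg
    )
    return model, report, targets, ps


def end_to_end_recovery(
    variant: AnatomyVariant = AnatomyVariant(),
    spec: AcquisitionSpec = AcquisitionSpec(),
    cfg=None,
) -> dict:
    """forward_study -> calibrate -> supply tracking -> recovery error table."""
    from .calibration import outlet_mean_flows
    from .tracking import fbs_compare

    network = make_network(variant, seed=spec.seed)
    targets_true = default_ground_truth_targets()
    inflow = aortic_inflow_waveform()
    true_wk = default_true_windkessel(targets_true, inflow)
    study, truth = forward_study(network, true_wk, spec, inflow)
    model, report, targets, ps = calibrate_study(study, cfg)

    rec_flows = outlet_mean_flows(model.result, network)
    flow_err = {
        o: (rec_flows[o] - truth.outlet_flows[o]) / truth.outlet_flows[o]
        for o in network.outlets
    }
    r_err = {
        o: (
            model.windkessel.bcs[o].total - truth.windkessel.bcs[o].total
        ) / truth.windkessel.bcs[o].total
        for o in network.outlets
    }
    fbs_model = transport_fractions(model.result, network)
    comp = fbs_compare(fbs_model, truth.fbs)
    neck_err = {}
    for artery, sid in network.neck_arteries.items():
        meas = study.waveforms[artery].mean
        sim = model.result.mean_flow(sid)
        neck_err[artery] = (sim - meas) / meas if meas != 0 else np.nan
    return {
        "flow_errors": flow_err,
        "resistance_errors": r_err,
        "neck_flow_errors": neck_err,
        "fbs_pearson_r": comp.pearson_r,
        "model": model,
        "truth": truth,
        "study": study,
        "report": report,
    }
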