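"""File-format readers/writers shared by the pipeline: NIfTI-1 volumes,
waveform CSVs, network/Windkessel JSON, and whole study directories."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from . import units
from .asl import (
    FBSTable,
    PerfusionVolume,
    TerritoryAtlas,
    NECK_ARTERY_ORDER,
    TERRITORY_LABELS,
)
from .errors import FormatError
from .network import NetworkModel, Waveform
from .synth import AcquisitionSpec, SyntheticStudy, GENERATOR_VERSION

_FLOW_UNITS = {"flow_m3s": 1.0, "flow_mls": units.MLPS_TO_M3PS}


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def write_nifti(path, voxels: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(voxels), np.asarray(affine))
    nib.save(img, str(path))


def read_nifti_volume(path, kind: str = "perfusion"):
    """Read a NIfTI-1 file as a PerfusionVolume or TerritoryAtlas.

    ``kind='atlas'`` requires an integer-typed image with labels in 0..7.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    affine = img.affine
    if kind == "atlas":
        if not np.issubdtype(data.dtype, np.integer):
            raise FormatError(
                f"atlas {path} must be integer-typed, got {data.dtype}"
            )
        return TerritoryAtlas(labels=data, affine=affine)
    if kind != "perfusion":
        raise ValueError(f"unknown kind {kind!r}")
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))
    return PerfusionVolume(
        voxels=data.astype(float), affine=affine, voxel_volume_mm3=voxel_volume
    )


# ---------------------------------------------------------------------------
# waveform CSV
# ---------------------------------------------------------------------------


def write_waveform_csv(path, wf: Waveform, unit: str = "flow_mls") -> None:
    if unit not in _FLOW_UNITS:
        raise FormatError(f"unknown flow unit column {unit!r}")
    values = wf.values / _FLOW_UNITS[unit]
    df = pd.DataFrame({"time_s": wf.times, unit: values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_waveform_csv(path, period: Optional[float] = None) -> Waveform:
    """2-column CSV (time_s, flow_mls|flow_m3s) -> SI Waveform.

    Period defaults to the implied sample spacing past the last sample.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing 'time_s' column")
    unit_cols = [c for c in df.columns if c in _FLOW_UNITS]
    if len(unit_cols) != 1:
        raise FormatError(
            f"{path}: need exactly one flow column from {sorted(_FLOW_UNITS)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    v = df[unit_cols[0]].to_numpy(dtype=float) * _FLOW_UNITS[unit_cols[0]]
    if t.size < 2 or not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    if period is None:
        period = float(t[-1] - t[0] + np.median(np.diff(t)))
    return Waveform(times=t - t[0], values=v, period=period)


# ---------------------------------------------------------------------------
# FBS tables
# ---------------------------------------------------------------------------


def write_fbs_csv(path, table: FBSTable) -> None:
    table.to_long().to_csv(path, index=False, float_format="%.10g")


def read_fbs_csv(path) -> FBSTable:
    return FBSTable.from_long(pd.read_csv(path))


# ---------------------------------------------------------------------------
# study directories
# ---------------------------------------------------------------------------


@dataclass
class StudyInputs:
    """Resolved paths making up one study directory."""

    root: Path
    network: Path
    atlas: Path
    ns_labels: list
    ns_controls: list
    vs_asl: Dict[str, Path]
    waveforms: Dict[str, Path]
    meta: Path

    @classmethod
    def locate(cls, root) -> "StudyInputs":
        root = Path(root)
        meta = root / "study.json"
        if not meta.exists():
            raise FormatError(f"missing study manifest: {meta}")
        manifest = json.loads(meta.read_text())
        def p(rel):
            path = root / rel
            if not path.exists():
                raise FormatError(f"study file missing: {path}")
            return path
        return cls(
            root=root,
            network=p(manifest["network"]),
            atlas=p(manifest["atlas"]),
            ns_labels=[p(f) for f in manifest["ns_asl_labels"]],
            ns_controls=[p(f) for f in manifest["ns_asl_controls"]],
            vs_asl={a: p(f) for a, f in manifest["vs_asl"].items()},
            waveforms={n: p(f) for n, f in manifest["waveforms"].items()},
            meta=meta,
        )


def write_study(study: SyntheticStudy, out_dir) -> Path:
    """Serialize a synthetic study to a directory (NIfTI + CSV + JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = study.atlas.affine

    study.network.to_json(out / "network.json")
    write_nifti(out / "atlas.nii", study.atlas.labels.astype(np.int16), affine)
    (out / "atlas_labels.json").write_text(
        json.dumps({str(k): v for k, v in TERRITORY_LABELS.items()}, indent=2)
    )

    manifest = {
        "generator_version": GENERATOR_VERSION,
        "seed": study.seed,
        "network": "network.json",
        "atlas": "atlas.nii",
        "ns_asl_labels": [],
        "ns_asl_controls": [],
        "vs_asl": {},
        "waveforms": {},
        "labeling_efficiencies": dict(study.efficiencies),
        "brachial_p_sys_mmhg": study.p_sys * units.PA_TO_MMHG,
        "brachial_p_dia_mmhg": study.p_dia * units.PA_TO_MMHG,
    }
    for i, (lab, ctl) in enumerate(zip(study.ns_asl_labels, study.ns_asl_controls)):
        ln, cn = f"ns_asl_label_{i:02d}.nii", f"ns_asl_control_{i:02d}.nii"
        write_nifti(out / ln, lab, affine)
        write_nifti(out / cn, ctl, affine)
        manifest["ns_asl_labels"].append(ln)
        manifest["ns_asl_controls"].append(cn)
    for artery, vol in study.vs_asl.items():
        fn = f"vs_asl_{artery}.nii"
        write_nifti(out / fn, vol.voxels, affine)
        manifest["vs_asl"][artery] = fn
    for name, wf in study.waveforms.items():
        fn = f"waveform_{name}.csv"
        write_waveform_csv(out / fn, wf)
        manifest["waveforms"][name] = fn
    (out / "study.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_config(path) -> dict:
    """Pipeline configuration from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def run_pipeline(config) -> dict:
    """Execute calibrate -> solve -> track -> report for one study.

    ``config`` is a dict or a path to a JSON/YAML file with keys:
    study_dir, out_dir, optional tracking {mode, n_particles, seed} and
    calibration overrides.  Returns a manifest of written artifacts; on stage
    failure the partial manifest is written alongside the error.
    """
    import time

    from .asl import VSASLStudy, asl_fbs_table
    from .calibration import CalibrationConfig
    from .metrics import hemodynamic_report, write_report
    from .synth import calibrate_study
    from .tracking import fbs_compare, particle_fbs, transport_fractions

    if not isinstance(config, dict):
        config = read_config(config)
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": {}, "artifacts": []}
    t_start = time.perf_counter()

    def _done(stage):
        manifest["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t_start, 3)
        }

    try:
        study = load_study(config["study_dir"])
        _done("load")
        cfg = CalibrationConfig(**config.get("calibration", {}))
        model, report, targets, ps = calibrate_study(study, cfg)
        (out / "calibrated_windkessel.json").write_text(
            json.dumps(model.windkessel.to_dict(), indent=2, sort_keys=True)
        )
        (out / "calibration_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True, default=float)
        )
        manifest["artifacts"] += ["calibrated_windkessel.json", "calibration_report.json"]
        manifest["stages"]["calibrate"] = {
            "converged": {k: tr.converged for k, tr in report.stages.items()},
            "elapsed_s": round(time.perf_counter() - t_start, 3),
        }

        track_cfg = config.get("tracking", {})
        mode = track_cfg.get("mode", "transport")
        fbs_tables = {}
        fbs_model = transport_fractions(model.result, study.network)
        write_fbs_csv(out / "fbs_transport.csv", fbs_model)
        manifest["artifacts"].append("fbs_transport.csv")
        fbs_tables["transport"] = fbs_model
        if mode in ("particles", "both"):
            table, ledger = particle_fbs(
                model.result,
                study.network,
                n_total=int(track_cfg.get("n_particles", 20000)),
                seed=int(track_cfg.get("seed", 0)),
            )
            write_fbs_csv(out / "fbs_particles.csv", table)
            (out / "particle_ledger.json").write_text(
                json.dumps(ledger.to_dict(), indent=2, sort_keys=True)
            )
            manifest["artifacts"] += ["fbs_particles.csv", "particle_ledger.json"]
            fbs_tables["particles"] = table
        _done("track")

        fbs_asl = asl_fbs_table(
            VSASLStudy(volumes=study.vs_asl, efficiencies=study.efficiencies),
            study.atlas,
        )
        write_fbs_csv(out / "fbs_asl.csv", fbs_asl)
        manifest["artifacts"].append("fbs_asl.csv")
        fbs_tables["asl"] = fbs_asl
        comp = fbs_compare(fbs_model, fbs_asl)
        doc = hemodynamic_report(model, fbs_tables=fbs_tables, comparison=comp)
        write_report(doc, out / "report.json")
        manifest["artifacts"].append("report.json")
        _done("report")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_study(root) -> SyntheticStudy:
    """Read a study directory back into memory."""
    inputs = StudyInputs.locate(root)
    manifest = json.loads(inputs.meta.read_text())
    network = NetworkModel.from_json(inputs.network)
    atlas = read_nifti_volume(inputs.atlas, kind="atlas")
    labels = [np.asarray(read_nifti_volume(f).voxels) for f in inputs.ns_labels]
    controls = [np.asarray(read_nifti_volume(f).voxels) for f in inputs.ns_controls]
    vs = {a: read_nifti_volume(f) for a, f in inputs.vs_asl.items()}
    missing = [a for a in NECK_ARTERY_ORDER if a not in vs]
    if missing:
        raise FormatError(f"study missing VS-ASL volumes for {missing}")
    waveforms = {n: read_waveform_csv(f) for n, f in inputs.waveforms.items()}
    spec = AcquisitionSpec(
        grid_shape=tuple(atlas.shape),
        n_pairs=len(labels),
        labeling_efficiencies=dict(manifest["labeling_efficiencies"]),
        seed=manifest.get("seed", 0),
    )
    return SyntheticStudy(
        network=network,
        atlas=atlas,
        ns_asl_labels=labels,
        ns_asl_controls=controls,
        vs_asl=vs,
        efficiencies=dict(manifest["labeling_efficiencies"]),
        waveforms=waveforms,
        p_sys=manifest["brachial_p_sys_mmhg"] * units.MMHG_TO_PA,
        p_dia=manifest["brachial_p_dia_mmhg"] * units.MMHG_TO_PA,
        spec=spec,
        seed=manifest.get("seed", 0),
    )
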