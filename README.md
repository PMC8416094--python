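# cerebroflow

Reduced-order quantification of patient-specific cerebral hemodynamics.

`cerebroflow` calibrates three-element Windkessel outflow boundary conditions
of a pulsatile lumped-parameter (0D) arterial network — aorta, neck arteries,
and Circle of Willis — from ASL-derived perfusion splits, PC-MRI-like flow
waveforms, and a brachial pressure pair.  The calibrated model is then
exploited for:

- **fractional blood supply (FBS)** of each vascular territory from each neck
  artery, via deterministic junction-mixing transport and stochastic particle
  routing, compared against vessel-selective ASL;
- **stenosis severity metrics**: mean trans-stenotic pressure drop, fractional
  flow (FF), and distal-vasculature outlet resistances.

A synthetic-cohort generator produces complete studies (NIfTI ASL volumes,
waveform CSVs, network JSON, brachial pressures) from a known ground truth, so
the entire pipeline is testable offline.

## Layout

| module | contents |
| --- | --- |
| `cerebroflow.network` | vessel-segment graph, stenosis elements, pulsatile 0D solver with Windkessel outlets |
| `cerebroflow.asl` | NS-ASL subtraction/averaging, perfusion splits, VS-ASL FBS maps and median/MAD statistics |
| `cerebroflow.targets` | inflow summary, total resistance/compliance, per-outlet target flows, Windkessel initialization |
| `cerebroflow.calibration` | three-stage calibration (flow match, pulsatility match, pressure match) |
| `cerebroflow.tracking` | transport and particle FBS, model-vs-ASL comparison |
| `cerebroflow.metrics` | pressure drop, FF, outlet resistance, report document |
| `cerebroflow.synth` | anatomy variants, ground-truth Windkessel sets, noisy synthetic measurements |
| `cerebroflow.io` / `cerebroflow.cli` | NIfTI/CSV/JSON readers and writers, study directories, pipeline runner, CLI |

## CLI

```sh
# generate a synthetic study with a severe right-ICA stenosis and 5% noise
cerebroflow synth --variant complete --stenosis rica:0.3 --noise 0.05 \
    --seed 1 --out study/

# calibrate Windkessel parameters for it
cerebroflow calibrate study/ --out calib/

# fractional blood supply (transport + particles)
cerebroflow track study/ --calibration calib/ --mode both --out fbs/

# hemodynamic assessment report (JSON + plots)
cerebroflow report study/ --calibration calib/ --out report/

# one-shot pipeline from a config file
cerebroflow run pipeline.json

# end-to-end recovery harness against the generator's ground truth
cerebroflow recover --noise 0.05 --seed 1 --out recovery.json
```

`pipeline.json` (or YAML):

```json
{
  "study_dir": "study/",
  "out_dir": "out/",
  "tracking": {"mode": "both", "n_particles": 20000, "seed": 0}
}
```

## Units

All internal computation is SI (Pa, m³/s, s, m³/Pa).  Configuration and
reports use clinical units: mmHg (1 mmHg = 133.322 Pa) and ml/s.
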