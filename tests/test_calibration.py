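"""Three-stage calibration: controllers, conservation identities, recovery."""

import numpy as np
import pytest
from scipy.optimize import brentq, fsolve

from cerebroflow import units
from cerebroflow.calibration import (
    CalibrationConfig,
    outlet_mean_flows,
    pulsatility_index,
    stage1_flow_match,
    stage2_pulsatility,
    stage3_pressure_match,
)
from cerebroflow.errors import ConvergenceError
from cerebroflow.network import (
    NetworkModel,
    SolverOptions,
    Waveform,
    solve_transient,
)
from cerebroflow.targets import ALL_OUTLETS, FlowTargets, WindkesselSet

from conftest import constant_waveform, make_wk, seg


def wkset(bcs, r_total=None, c_total=None):
    rt = r_total or 1.0 / sum(1.0 / bc.total for bc in bcs.values())
    ct = c_total or sum(bc.capacitance for bc in bcs.values())
    return WindkesselSet(bcs=dict(bcs), r_total=rt, c_total=ct)


def fast_cfg(**kw):
    kw.setdefault("solver", SolverOptions(dt=1e-3, periodicity_tol=1e-4, max_cycles=30))
    return CalibrationConfig(**kw)


def mini_targets(d):
    """FlowTargets without the 13-outlet completeness check."""
    t = FlowTargets.__new__(FlowTargets)
    t.targets = dict(d)
    t.q_cow = sum(d.values())
    return t


class TestPulsatilityIndex:
    def test_closed_form(self):
        t = np.arange(200) / 200
        q = 5 + 2 * np.sin(2 * np.pi * t)
        assert pulsatility_index(q) == pytest.approx(4 / 5, rel=1e-3)

    def test_zero_mean_nan(self):
        assert np.isnan(pulsatility_index(np.array([-1.0, 1.0])))


class TestStage1:
    def test_already_converged_is_identity(self, y_network):
        wk = wkset(make_wk(O1=(1e8, 1.5e9, 1e-10), O2=(1e8, 1.5e9, 1e-10)))
        q_in = 8e-6
        res = solve_transient(y_network, wk.bcs, constant_waveform(q_in))
        flows = outlet_mean_flows(res, y_network)
        targets = mini_targets(flows)
        out, result, trace, _ = stage1_flow_match(
            y_network, wk, targets, constant_waveform(q_in), fast_cfg()
        )
        assert trace.converged and len(trace.iterations) == 1
        assert out.bcs["O1"].r_dist == wk.bcs["O1"].r_dist

    def test_single_outlet_resistance_identity(self, single_outlet_network):
        """Converged R_d satisfies R_seg + R_p + R_d = P_inlet/Q, matching a
        brute-force scalar root find on the steady model."""
        q = 5e-6
        wk = wkset(make_wk(O=(1e8, 2.0e9, 1e-10)))
        targets = mini_targets({"O": q})
        out, result, trace, _ = stage1_flow_match(
            single_outlet_network, wk, targets, constant_waveform(q), fast_cfg()
        )
        r_seg = single_outlet_network.segment("s0").poiseuille_resistance
        p_in = result.mean_pressure("inlet")
        lhs = r_seg + out.bcs["O"].r_prox + out.bcs["O"].r_dist
        assert lhs == pytest.approx(p_in / q, rel=1e-6)
        # independent scalar root find: f(rd) = q_steady(rd) - q == 0 is
        # degenerate for a single outlet (flow always q), so verify instead
        # that the achieved pressure solves the same steady relation
        rd_root = brentq(
            lambda rd: (r_seg + out.bcs["O"].r_prox + rd) * q - p_in,
            1e6, 1e12,
        )
        assert out.bcs["O"].r_dist == pytest.approx(rd_root, rel=1e-6)

    def test_asymmetric_y_matches_linear_inverse(self, y_network):
        """Converged flows hit asymmetric targets; independent resistive-
        divider solve with the returned R_d reproduces them."""
        q_in = 9e-6
        targets = mini_targets({"O1": 6e-6, "O2": 3e-6})
        wk = wkset(make_wk(O1=(1e8, 1.5e9, 1e-10), O2=(1e8, 1.5e9, 1e-10)))
        out, result, trace, _ = stage1_flow_match(
            y_network, wk, targets, constant_waveform(q_in), fast_cfg()
        )
        flows = outlet_mean_flows(result, y_network)
        assert flows["O1"] == pytest.approx(6e-6, rel=0.01)
        assert flows["O2"] == pytest.approx(3e-6, rel=0.01)
        # independent two-path divider oracle
        r1 = y_network.segment("s1").poiseuille_resistance + out.bcs["O1"].total
        r2 = y_network.segment("s2").poiseuille_resistance + out.bcs["O2"].total
        pj = q_in / (1 / r1 + 1 / r2)
        assert pj / r1 == pytest.approx(6e-6, rel=0.01)
        assert pj / r2 == pytest.approx(3e-6, rel=0.01)

    def test_rp_and_c_untouched(self, y_network):
        wk = wkset(make_wk(O1=(1e8, 1.5e9, 1e-10), O2=(2e8, 1.5e9, 2e-10)))
        targets = mini_targets({"O1": 6e-6, "O2": 3e-6})
        out, *_ = stage1_flow_match(
            y_network, wk, targets, constant_waveform(9e-6), fast_cfg()
        )
        for o in ("O1", "O2"):
            assert out.bcs[o].r_prox == wk.bcs[o].r_prox
            assert out.bcs[o].capacitance == wk.bcs[o].capacitance

    def test_max_iterations_raises_with_trace(self, y_network):
        wk = wkset(make_wk(O1=(1e8, 1.5e9, 1e-10), O2=(1e8, 1.5e9, 1e-10)))
        targets = mini_targets({"O1": 6e-6, "O2": 3e-6})
        with pytest.raises(ConvergenceError) as exc:
            stage1_flow_match(
                y_network, wk, targets, constant_waveform(9e-6),
                fast_cfg(stage1_max_iterations=1),
            )
        assert len(exc.value.trace.iterations) == 1


def carotid_network():
    """Mini cerebral fixture: two neck arteries feeding RMCA/LMCA outlets,
    plus a competing extracranial branch so the cerebral Rp/Rd split shifts
    pulsatile flow between the ICA and ECA paths."""
    return NetworkModel(
        segments=[
            seg("a0", "inlet", "c", length=0.06, radius=6e-3),
            seg("rica", "c", "m1", length=0.15, radius=2.5e-3),
            seg("lica", "c", "m2", length=0.15, radius=2.5e-3),
            seg("eca", "c", "e1", length=0.05, radius=2.5e-3),
        ],
        inlet="inlet",
        outlets={"RMCA": "m1", "LMCA": "m2", "RECA": "e1"},
        neck_arteries={"RICA": "rica", "LICA": "lica"},
    )


def pulsatile_inflow(q_mean=8e-6, rel_amp=0.8, period=1.0, n=200):
    t = np.arange(n) / n * period
    return Waveform(
        times=t, values=q_mean * (1 + rel_amp * np.sin(2 * np.pi * t)), period=period
    )


class TestStage2:
    def setup_method(self):
        self.net = carotid_network()
        self.inflow = pulsatile_inflow()

    def _wk(self, ratio=0.06):
        r_i = 2.5e9
        return wkset(
            make_wk(
                RMCA=(ratio * r_i, (1 - ratio) * r_i, 2e-10),
                LMCA=(ratio * r_i, (1 - ratio) * r_i, 2e-10),
                RECA=(2e8, 2.8e9, 1.5e-10),  # fixed non-cerebral outlet
            )
        )

    def _measured(self, ratio):
        res = solve_transient(self.net, self._wk(ratio).bcs, self.inflow)
        return {a: res.flow_waveform(sid) for a, sid in self.net.neck_arteries.items()}

    def test_measured_equals_simulated_unchanged(self):
        wk = self._wk(0.06)
        measured = self._measured(0.06)
        out, result, trace = stage2_pulsatility(
            self.net, wk, measured, self.inflow, fast_cfg()
        )
        assert trace.converged and len(trace.iterations) == 1
        assert out.bcs["RMCA"].r_prox == pytest.approx(wk.bcs["RMCA"].r_prox)

    def test_total_resistance_preserved_to_machine_precision(self):
        wk = self._wk(0.06)
        measured = self._measured(0.25)
        out, result, trace = stage2_pulsatility(
            self.net, wk, measured, self.inflow, fast_cfg()
        )
        for o in ("RMCA", "LMCA"):
            assert out.bcs[o].total == pytest.approx(
                wk.bcs[o].total, rel=4 * np.finfo(float).eps
            )

    def test_pi_monotone_and_bisection_recovers_ratio(self):
        """Neck PI is strictly monotone in the cerebral Rp share on this
        fixture (verified by sweep); bisection then matches a synthetic PI
        generated at a known ratio."""
        ratios = [0.02, 0.1, 0.2, 0.35, 0.5]
        pis = []
        for f in ratios:
            res = solve_transient(self.net, self._wk(f).bcs, self.inflow)
            pis.append(
                pulsatility_index(res.last_cycle(res.seg_flows["rica"]))
            )
        assert all(b < a for a, b in zip(pis, pis[1:]))  # sweep oracle
        measured = self._measured(0.3)
        cfg = fast_cfg(stage2_pulsatility_tol=0.01)
        out, result, trace = stage2_pulsatility(
            self.net, self._wk(0.06), measured, self.inflow, cfg
        )
        sim_pi = pulsatility_index(result.last_cycle(result.seg_flows["rica"]))
        meas_pi = pulsatility_index(measured["RICA"].values)
        assert abs(sim_pi - meas_pi) < 0.01


class TestStage3:
    def setup_method(self):
        self.net = carotid_network()
        self.net = NetworkModel(
            segments=[seg("s0", "inlet", "n_out", length=0.05, radius=4e-3)],
            inlet="inlet",
            outlets={"R_subclavian": "n_out"},
            neck_arteries={},
        )
        self.inflow = pulsatile_inflow(q_mean=10e-6, rel_amp=0.9)

    def _forward(self, r, c, ratio=0.1):
        wk = wkset(make_wk(R_subclavian=(ratio * r, (1 - ratio) * r, c)))
        res = solve_transient(
            self.net, wk.bcs, self.inflow,
            SolverOptions(periodicity_tol=1e-5, max_cycles=40),
        )
        p = res.last_cycle(res.node_pressures["n_out"])
        return float(np.max(p)), float(np.min(p))

    def test_measured_equals_simulated_identity(self):
        r_true, c_true = 1.2e9, 1.5e-10
        p_sys, p_dia = self._forward(r_true, c_true)
        wk = wkset(make_wk(R_subclavian=(0.1 * r_true, 0.9 * r_true, c_true)))
        out, result, trace, _ = stage3_pressure_match(
            self.net, wk, p_sys, p_dia, self.inflow, fast_cfg()
        )
        assert trace.converged and len(trace.iterations) == 1
        assert out.bcs["R_subclavian"].total == pytest.approx(r_true)

    def test_proportional_rescaling_identity(self):
        """After stage 3, every outlet's total changed by one common factor
        and its R_p:R_d split is exactly preserved."""
        r0, c0 = 1.2e9, 1.5e-10
        p_sys, p_dia = self._forward(r0 * 1.3, c0 * 0.8)
        wk = wkset(make_wk(R_subclavian=(0.1 * r0, 0.9 * r0, c0)))
        out, result, trace, _ = stage3_pressure_match(
            self.net, wk, p_sys, p_dia, self.inflow, fast_cfg()
        )
        bc0, bc1 = wk.bcs["R_subclavian"], out.bcs["R_subclavian"]
        assert bc1.r_prox / bc1.r_dist == pytest.approx(
            bc0.r_prox / bc0.r_dist, rel=1e-12
        )

    def test_recovers_rc_vs_grid_refine_oracle(self):
        """Stage 3 recovers the (R_T, C_T) that produce the target pressures,
        cross-checked by an independent grid + root-refined inverse."""
        r_true, c_true = 1.5e9, 1.2e-10
        p_sys, p_dia = self._forward(r_true, c_true)
        wk = wkset(make_wk(R_subclavian=(0.1 * 1e9, 0.9 * 1e9, 2.2e-10)))
        out, result, trace, _ = stage3_pressure_match(
            self.net, wk, p_sys, p_dia, self.inflow,
            fast_cfg(stage3_pressure_tol_mmhg=0.1),
        )
        # coarse grid search + fsolve refine, independent of the controller
        grid_r = np.linspace(0.8e9, 2.2e9, 6)
        grid_c = np.linspace(0.6e-10, 2.4e-10, 6)
        best = min(
            ((r, c) for r in grid_r for c in grid_c),
            key=lambda rc: max(
                abs(self._forward(rc[0], rc[1])[0] - p_sys),
                abs(self._forward(rc[0], rc[1])[1] - p_dia),
            ),
        )
        def residual(x):
            ps, pd = self._forward(x[0] * 1e9, x[1] * 1e-10)
            return [ps - p_sys, pd - p_dia]
        sol = fsolve(residual, [best[0] / 1e9, best[1] / 1e-10], xtol=1e-10)
        r_oracle, c_oracle = sol[0] * 1e9, sol[1] * 1e-10
        assert out.bcs["R_subclavian"].total == pytest.approx(r_oracle, rel=0.01)
        assert out.bcs["R_subclavian"].capacitance == pytest.approx(c_oracle, rel=0.05)
        # and the oracle itself should sit at the generating parameters
        assert r_oracle == pytest.approx(r_true, rel=0.01)


class TestFullCalibration:
    def test_zero_noise_recovery(self, clean_recovery):
        """Noise-free synthetic subject: outlet resistances within 2%,
        flows within stage-1 tolerance of the generating truth."""
        assert max(abs(v) for v in clean_recovery["resistance_errors"].values()) < 0.02
        assert max(abs(v) for v in clean_recovery["flow_errors"].values()) < 0.01 + 0.005

    def test_stage1_reaches_one_percent(self, clean_recovery):
        tr = clean_recovery["report"].stages["stage1"]
        assert tr.converged
        assert tr.iterations[-1]["max_rel_flow_error"] < 0.01

    def test_neck_flows_within_ten_percent(self, clean_recovery):
        assert max(abs(v) for v in clean_recovery["neck_flow_errors"].values()) < 0.10

    def test_noisy_splits_deviate_less_than_noise(self, true_setup):
        """5% multiplicative ASL noise: recovered intracranial splits deviate
        from truth by less than the injected noise (median over territories)."""
        from cerebroflow.asl import perfusion_splits
        from cerebroflow.synth import AcquisitionSpec, forward_study

        study, truth = forward_study(
            true_setup["network"], true_setup["wk"],
            AcquisitionSpec(asl_noise_sd=0.05, seed=7),
            inflow=true_setup["inflow"], true_result=true_setup["result"],
        )
        ps = perfusion_splits(study.ns_perfusion(), study.atlas)
        devs = [
            abs(ps.ps[t] - truth.splits[t]) / truth.splits[t]
            for t in truth.splits
        ]
        assert np.median(devs) < 0.05
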