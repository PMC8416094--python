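import warnings

import numpy as np
import pytest

from cerebroflow.network import (
    BloodProperties,
    NetworkModel,
    SimResult,
    VesselSegment,
    Waveform,
    WindkesselBC,
    solve_transient,
)
from cerebroflow.synth import (
    AcquisitionSpec,
    AnatomyVariant,
    aortic_inflow_waveform,
    default_ground_truth_targets,
    default_true_windkessel,
    end_to_end_recovery,
    forward_study,
    make_network,
)

warnings.filterwarnings("ignore", message=".*reverses flow.*")


def constant_waveform(q, period=1.0, n=100):
    t = np.arange(n) / n * period
    return Waveform(times=t, values=np.full(n, float(q)), period=period)


def seg(sid, frm, to, length=0.05, radius=2e-3, **kw):
    return VesselSegment(
        id=sid, name=sid, from_node=frm, to_node=to, length=length, radius=radius, **kw
    )


@pytest.fixture
def blood():
    return BloodProperties()


@pytest.fixture
def single_outlet_network():
    """inlet --seg--> out node with one Windkessel outlet 'O'."""
    return NetworkModel(
        segments=[seg("s0", "inlet", "n_out")],
        inlet="inlet",
        outlets={"O": "n_out"},
        neck_arteries={},
    )


@pytest.fixture
def y_network():
    """inlet --s0--> j --s1/s2--> two outlets O1, O2 (identical branches)."""
    return NetworkModel(
        segments=[
            seg("s0", "inlet", "j", length=0.06, radius=4e-3),
            seg("s1", "j", "n1"),
            seg("s2", "j", "n2"),
        ],
        inlet="inlet",
        outlets={"O1": "n1", "O2": "n2"},
        neck_arteries={},
    )


def make_wk(**outlets):
    """outlets: name=(r_prox, r_dist, capacitance)."""
    return {
        name: WindkesselBC(outlet_id=name, r_prox=rp, r_dist=rd, capacitance=c)
        for name, (rp, rd, c) in outlets.items()
    }


# ---------------------------------------------------------------------------
# diamond fixture: two labeled sources, collateral cross-flow
# ---------------------------------------------------------------------------


@pytest.fixture
def diamond_network():
    """RICA->a, LICA->b, AComA b->a carrying 1 ml/s, RACA out of a at 3 ml/s,
    LACA out of b at 3 ml/s.  Hand mass balance: FBS_RACA = (2/3, 1/3)."""
    return NetworkModel(
        segments=[
            seg("feed_r", "inlet", "src_r", radius=4e-3),
            seg("feed_l", "inlet", "src_l", radius=4e-3),
            seg("rica", "src_r", "a", length=0.10, radius=2.5e-3),
            seg("lica", "src_l", "b", length=0.10, radius=2.5e-3),
            seg("acom", "b", "a", length=0.01, radius=1e-3),
            seg("raca", "a", "out_r", length=0.04, radius=1.5e-3),
            seg("laca", "b", "out_l", length=0.04, radius=1.5e-3),
        ],
        inlet="inlet",
        outlets={"RACA": "out_r", "LACA": "out_l"},
        neck_arteries={"RICA": "rica", "LICA": "lica"},
    )


@pytest.fixture
def diamond_flows():
    """Hand-balanced mean flows [m^3/s] for the diamond (acom carries 1 ml/s
    from the LICA side into the RICA side)."""
    return {
        "feed_r": 2e-6,
        "feed_l": 4e-6,
        "rica": 2e-6,
        "lica": 4e-6,
        "acom": 1e-6,
        "raca": 3e-6,
        "laca": 3e-6,
    }


@pytest.fixture
def diamond_result(diamond_network, diamond_flows):
    """Steady SimResult on the diamond with the hand-balanced flows."""
    n, dt = 100, 0.01
    times = (np.arange(2 * n) + 1) * dt
    seg_flows = {
        sid: np.full(2 * n, q) for sid, q in diamond_flows.items()
    }
    node_pressures = {
        nd: np.zeros(2 * n) for nd in diamond_network.nodes
    }
    return SimResult(
        times=times,
        seg_flows=seg_flows,
        node_pressures=node_pressures,
        period=n * dt,
        dt=dt,
        cycles_run=2,
        periodicity_error=0.0,
    )


# ---------------------------------------------------------------------------
# session-scoped expensive fixtures (shared with the acceptance tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def true_setup():
    """Complete-variant network, nominal targets, inflow, ground-truth WK set,
    and the solved true model."""
    network = make_network()
    targets = default_ground_truth_targets()
    inflow = aortic_inflow_waveform()
    wk = default_true_windkessel(targets, inflow)
    result = solve_transient(network, wk.bcs, inflow)
    return {
        "network": network,
        "targets": targets,
        "inflow": inflow,
        "wk": wk,
        "result": result,
    }


@pytest.fixture(scope="session")
def clean_recovery():
    """Zero-noise end-to-end recovery on the complete variant (seed 1)."""
    return end_to_end_recovery(
        AnatomyVariant(), AcquisitionSpec(asl_noise_sd=0.0, waveform_noise_sd=0.0, seed=1)
    )


@pytest.fixture(scope="session")
def noisy_stenosed_recovery():
    """5% measurement noise, severe RICA stenosis, seed 1 (the t6 scenario)."""
    return end_to_end_recovery(
        AnatomyVariant(name="complete", stenoses=(("rica", 0.3),)),
        AcquisitionSpec(asl_noise_sd=0.05, waveform_noise_sd=0.05, seed=1),
    )


@pytest.fixture(scope="session")
def clean_study(true_setup):
    """Zero-noise synthetic study generated from the solved true model."""
    study, truth = forward_study(
        true_setup["network"],
        true_setup["wk"],
        AcquisitionSpec(asl_noise_sd=0.0, waveform_noise_sd=0.0, seed=1),
        inflow=true_setup["inflow"],
        true_result=true_setup["result"],
    )
    return study, truth
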