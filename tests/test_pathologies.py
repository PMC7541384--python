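"""Disease schedules: scheduled coefficients at t = 0 (continuity with the
normal model) and at the 700 s endpoint, plus per-cycle application rules."""

import math

import numpy as np
import pytest

from pulmosim import load_config
from pulmosim.pathologies import make_schedule
from pulmosim.topology import build_model, LAW_LOG


@pytest.fixture()
def setup():
    params, _ = load_config()

    def make(scenario):
        model = build_model(params, scenario)
        return model, make_schedule(scenario, params, model)

    return params, make


def stats_for(model, mean=12.0, spap=20.0, dpap=10.0):
    nn = model.n_nodes
    s = {"mean": np.full(nn, mean), "min": np.full(nn, dpap), "max": np.full(nn, spap)}
    return s


def test_normal_schedule_is_identity(setup):
    _, make = setup
    model, sched = make("normal")
    before = (model.nodep.copy(), model.erp.copy(), model.actA.copy())
    for cyc, t in enumerate(np.arange(0, 5) * 0.7845):
        snap = sched(model, float(t), cyc, stats_for(model) if cyc else None)
        assert snap == {}
    assert np.array_equal(model.nodep, before[0])
    assert np.array_equal(model.erp, before[1])
    assert np.array_equal(model.actA, before[2])


class TestDpas:
    def test_initial_cycle_matches_normal_state(self, setup):
        params, make = setup
        model, sched = make("dpas")
        snap = sched(model, 0.0, 0, None)
        assert snap["E_es_rv"] == pytest.approx(0.8)
        assert model.nodep[model.node_index["rv"], 0] == pytest.approx(1.5 * 0.8)
        assert snap["R_rpad"] == pytest.approx(0.06)
        assert snap["C_rpad"] == pytest.approx(9.0)
        # proximal arteries switched to the saturating log law
        i = model.node_index["rpap"]
        assert model.law[i] == LAW_LOG
        assert model.nodep[i, 0] == 20.0 and model.nodep[i, 1] == 100.0

    def test_rv_elastance_ramp_before_breakpoint(self, setup):
        _, make = setup
        model, sched = make("dpas")
        sched(model, 0.0, 0, None)
        snap = sched(model, 100.0, 127, stats_for(model, spap=30, dpap=20))
        assert snap["E_es_rv"] == pytest.approx(0.8 + 0.0013 * 100.0)
        assert snap["t_c"] is None

    def test_resistance_multiplier_at_endpoint(self, setup):
        _, make = setup
        model, sched = make("dpas")
        sched(model, 0.0, 0, None)
        snap = sched(model, 700.0, 892, stats_for(model, spap=40, dpap=30))
        assert snap["R_rpad"] / 0.06 == pytest.approx(1 + 0.018 * 700, rel=1e-12)
        e = model.edge_index["rpap->rpad"]
        assert model.erp[e, 0] == pytest.approx(0.816)

    def test_breakpoint_freezes_and_elastance_is_continuous(self, setup):
        _, make = setup
        model, sched = make("dpas")
        sched(model, 0.0, 0, None)
        # mPAP from stats: (60 + 2*48)/3 = 52 >= 50 -> t_c set at this boundary
        snap = sched(model, 300.0, 382, stats_for(model, spap=60.0, dpap=48.0))
        assert sched.state.t_c == 300.0
        assert snap["E_es_rv"] == pytest.approx(0.8 + 0.0013 * 300.0)  # both branches agree
        snap2 = sched(model, 700.0, 892, stats_for(model, spap=70.0, dpap=60.0))
        assert sched.state.t_c == 300.0  # immutable once set
        assert snap2["E_es_rv"] == pytest.approx(0.8 + 0.0013 * 300.0 + 0.0008 * 400.0)

    def test_scheduled_resistance_strictly_increasing(self, dpas_run):
        R = [s["R_rpad"] for s in dpas_run.snapshots]
        assert all(b > a for a, b in zip(R, R[1:]))

    def test_one_snapshot_per_cycle(self, dpas_run):
        assert len(dpas_run.snapshots) == math.floor(700.0 / 0.7845) == 892


class TestLvdd:
    def test_endpoint_values(self, setup):
        _, make = setup
        model, sched = make("lvdd")
        sched(model, 0.0, 0, None)
        snap = sched(model, 700.0, 892, stats_for(model, mean=12.0))
        assert snap["M_lv"] == pytest.approx(1.7 + 0.004 * 700)       # 4.5
        assert snap["lambda_lv"] == pytest.approx(0.015 + 1e-5 * 700)  # 0.022
        assert snap["K_rpap"] == pytest.approx(44.5)
        assert 19.0 < snap["K_rpap"] < 56.0
        assert snap["K_rpv"] == pytest.approx(5.0 + 0.02 * 700)       # 19 < 37
        assert snap["a_3"] == pytest.approx(0.9 - 0.000655 * 700)     # 0.4415
        assert snap["E_es_la"] == pytest.approx(0.3 + 0.0004 * 700)
        assert snap["E_es_rv"] == pytest.approx(0.8 + 0.0012 * 700)

    def test_pressure_coupled_resistance_uses_last_cycle_mean(self, setup):
        _, make = setup
        model, sched = make("lvdd")
        sched(model, 0.0, 0, None)
        t, P_m = 100.0, 15.0
        snap = sched(model, t, 127, stats_for(model, mean=P_m))
        tau = 0.54 * math.exp(-0.0004 * t)
        want = tau / (14.0 * math.exp(-0.031 * P_m))
        assert snap["R_rpad"] == pytest.approx(want, rel=1e-12)

    def test_resistances_unchanged_until_first_cycle_completes(self, setup):
        _, make = setup
        model, sched = make("lvdd")
        e = model.edge_index["rv->rpap"]
        before = model.erp[e, 0]
        snap = sched(model, 0.0, 0, None)
        assert model.erp[e, 0] == before
        assert "R_rpap" not in snap

    def test_ten_gaussian_atrial_activation_installed(self, setup):
        _, make = setup
        model, sched = make("lvdd")
        sched(model, 0.0, 0, None)
        ila = model.node_index["la"]
        assert model.actn[ila] == 10
        sl = model.act_slice("la")
        assert model.actA[sl][2] == pytest.approx(0.9)  # a_3,0; all others zero
        assert model.actA[sl].sum() == pytest.approx(0.9)
        # negative extrapolation of a_3 clamps at zero far beyond the run
        sched(model, 2000.0, 2549, stats_for(model))
        assert model.actA[sl].min() >= 0.0

    def test_k_stays_inside_printed_intervals_during_run(self, lvdd_run):
        for s in lvdd_run.snapshots:
            if "K_rpap" not in s:
                continue
            assert 19.0 < s["K_rpap"] < 56.0
            assert 14.0 < s["K_rpad"] < 49.0
            assert 4.0 < s["K_rpv"] < 37.0


class TestVsd:
    def test_shunt_resistance_collapse(self, setup):
        _, make = setup
        model, sched = make("vsd")
        snap = sched(model, 0.0, 0, None)
        assert snap["R_ltor"] == pytest.approx(100.0)
        snap = sched(model, 700.0, 892, stats_for(model))
        assert snap["R_ltor"] == pytest.approx(100.0 / (1 + 0.0408 * 700) ** 2, rel=1e-12)
        e = model.edge_index["shunt"]
        assert model.erp[e, 0] == pytest.approx(0.1144434, abs=1e-6)

    def test_normal_topology_has_no_shunt(self, setup):
        _, make = setup
        model, _ = make("normal")
        assert "shunt" not in model.edge_index

    def test_atrial_second_peak_growth(self, setup):
        _, make = setup
        model, sched = make("vsd")
        sched(model, 0.0, 0, None)
        snap = sched(model, 700.0, 892, stats_for(model))
        assert snap["alpha_2"] == pytest.approx(0.000056 * 700)  # 0.0392
        assert snap["alpha_3"] == pytest.approx(0.0392)
        sl = model.act_slice("la")
        assert model.actA[sl][0] == pytest.approx(0.9)  # first peak constant


class TestMs:
    def test_mitral_resistance_ramp(self, setup):
        _, make = setup
        model, sched = make("ms")
        snap = sched(model, 0.0, 0, None)
        assert snap["R_m"] == pytest.approx(0.02)
        snap = sched(model, 700.0, 892, stats_for(model))
        assert snap["R_m"] == pytest.approx(0.23)
        assert model.erp[model.edge_index["la->lv"], 0] == pytest.approx(0.23)

    def test_atrial_activation_endpoint(self, setup):
        _, make = setup
        model, sched = make("ms")
        sched(model, 0.0, 0, None)
        snap = sched(model, 700.0, 892, stats_for(model))
        assert snap["X_1"] == pytest.approx(0.9 - 0.000336 * 700)  # 0.6648
        assert snap["X_2"] == pytest.approx(0.000168 * 700)
        assert snap["baseline"] == pytest.approx(0.000336 * 700)
        ila = model.node_index["la"]
        assert model.nodep[ila, 7] == pytest.approx(0.2352)

    def test_la_compensation_ramps(self, setup):
        _, make = setup
        model, sched = make("ms")
        sched(model, 0.0, 0, None)
        snap = sched(model, 700.0, 892, stats_for(model))
        assert snap["E_es_la"] == pytest.approx(0.3 + 0.0003 * 700)
        assert snap["M_la"] == pytest.approx(0.5 + 0.001 * 700)
        assert snap["lambda_la"] == pytest.approx(0.025 + 0.0000056 * 700)


def test_all_scenarios_mpap_nondecreasing_after_cycle_50(dpas_run, lvdd_run, vsd_run, ms_run):
    """Disease monotonicity: per-cycle mPAP rises once the startup transient
    has settled, in every etiology."""
    from pulmosim.parameters import mean_pap

    for traj in (dpas_run, lvdd_run, vsd_run, ms_run):
        il, ir = traj.node("lpap"), traj.node("rpap")
        spap = 0.5 * (traj.cycle_max_P[:, il] + traj.cycle_max_P[:, ir])
        dpap = 0.5 * (traj.cycle_min_P[:, il] + traj.cycle_min_P[:, ir])
        mpap = np.array([mean_pap(s, d) for s, d in zip(spap, dpap)])
        assert np.all(np.diff(mpap[50:]) > -1e-9)
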