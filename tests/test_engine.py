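"""Engine behaviour: scheme correctness, conservation, superposition."""

import numpy as np
import pandas as pd
import pytest

from spraymix.engine import (
    Scenario,
    ScenarioError,
    SimulationResult,
    mass_audit,
    run,
    time_weighted_average,
)
from spraymix.fixtures import toy_single_pulse, worked_example_h2o2
from spraymix.physchem import R_GAS

pytestmark = pytest.mark.filterwarnings("ignore:Stokes settling")


def series_result(t, y, name="y"):
    frame = pd.DataFrame({"t": t, name: y})
    return SimulationResult(frame=frame, scenario=None, metadata={})


class TestTimeWeightedAverage:
    def test_constant_series(self):
        res = series_result(np.linspace(0, 10, 11), np.full(11, 3.5))
        assert time_weighted_average(res, "y", (0, 10)) == pytest.approx(3.5)

    def test_linear_ramp(self):
        t = np.linspace(0, 10, 101)
        res = series_result(t, 0.4 * t)
        assert time_weighted_average(res, "y", (0, 10)) == pytest.approx(2.0)

    def test_two_level_step_series(self):
        # 2 for the first 4 s, 6 afterwards -> average over (0, 10) is 4.4
        t = np.array([0.0, 4.0, 4.0 + 1e-9, 10.0])
        res = series_result(t, np.array([2.0, 2.0, 6.0, 6.0]))
        assert time_weighted_average(res, "y", (0, 10)) == pytest.approx(4.4, abs=1e-6)

    def test_window_validation(self):
        res = series_result(np.linspace(0, 10, 11), np.ones(11))
        with pytest.raises(ValueError):
            time_weighted_average(res, "y", (5, 5))
        with pytest.raises(ValueError):
            time_weighted_average(res, "y", (0, 50))


class TestScenarioValidation:
    def test_worked_example_validates(self):
        worked_example_h2o2().validate()

    def test_bad_mass_fractions(self):
        with pytest.raises(ScenarioError):
            worked_example_h2o2(w_pr=(0.9, 0.2)).validate()

    def test_wall_mode_needs_jet(self):
        with pytest.raises(ScenarioError):
            worked_example_h2o2(jet=None).validate()

    def test_dt_post_not_smaller_than_dt(self):
        with pytest.raises(ScenarioError):
            worked_example_h2o2(dt=0.2, dt_post=0.1).validate()

    def test_pulse_schedule_spacing_and_mass(self):
        sc = worked_example_h2o2()
        sched = sc.pulse_schedule()
        assert len(sched) == 75                      # 300 s / (20 * 0.2 s)
        times = np.array([t for t, _ in sched])
        np.testing.assert_allclose(np.diff(times), 4.0)
        assert sum(m for _, m in sched) == pytest.approx(8e-3 * 300.0)


class TestEngineBasics:
    def test_zero_release_is_inert(self):
        sc = toy_single_pulse(rate=0.0, t_expo=100.0, C_init=(1e-3, 0.0),
                              psat1=0.0, psat2=0.0)
        res = run(sc)
        assert res.frame["A_total"].max() == 0.0
        np.testing.assert_allclose(res.frame["C_comp1"], 1e-3, rtol=1e-12)

    def test_ventilation_only_exponential_decay(self):
        # nonvolatile aerosol, no gravity: A(t) = A0 exp(-Q t / V)
        sc = toy_single_pulse(
            psat1=0.0, psat2=0.0, g=1e-12, Q_vent=0.75, V_room=150.0,
            dt=0.2, dt_post=0.2, t_expo=600.0,
        )
        res = run(sc)
        f = res.frame
        t = f["t"].to_numpy()
        A = f["A_total"].to_numpy()
        i0 = np.argmax(A)
        lam = sc.Q_vent / sc.V_room
        expected = A[i0] * np.exp(-lam * (t[i0:] - t[i0]))
        np.testing.assert_allclose(A[i0:], expected, rtol=5e-3)

    def test_superposition_of_two_pulse_groups(self):
        # with evaporation disabled the model is linear per pulse: two
        # application blocks simulated jointly equal the sum of the blocks
        common = dict(psat1=0.0, psat2=0.0, dt=0.2, dt_post=0.2, t_expo=120.0,
                      IM=20, d_m=80e-6, Q_vent=0.3)
        sc_a = toy_single_pulse(**common, application=((0.0, 4.0, 1e-3),))
        sc_b = toy_single_pulse(**common, application=((8.0, 12.0, 1e-3),))
        sc_ab = toy_single_pulse(**common,
                                 application=((0.0, 4.0, 1e-3), (8.0, 12.0, 1e-3)))
        A_a = run(sc_a).frame["A_total"].to_numpy()
        A_b = run(sc_b).frame["A_total"].to_numpy()
        A_ab = run(sc_ab).frame["A_total"].to_numpy()
        np.testing.assert_allclose(A_ab, A_a + A_b, rtol=1e-9, atol=1e-15)

    def test_droplet_lifetime_matches_d2_law(self):
        # a single pure-volatile pulse in a huge room (no backpressure)
        # disappears after the closed-form d^2-law lifetime
        tau = (50e-6) ** 2 * R_GAS * 293.0 / (8 * 2308.0 * 1.8e-5 * 2.4e-5)
        sc = toy_single_pulse(
            psat1=2308.0, psat2=0.0, w_pr=(1.0, 0.0), d_m=50e-6,
            V_room=1e6, F=1e4, rate=1e-6, duration=0.02, dt=1e-3, dt_post=1e-3,
            IM=20, t_expo=2.0, g=1e-12,
        )
        res = run(sc)
        f = res.frame
        alive = f["A_total"].to_numpy() > 0
        t_death = f["t"].to_numpy()[np.nonzero(alive)[0][-1] + 1]
        assert t_death == pytest.approx(tau, rel=0.01)

    def test_nonnegative_states_throughout(self):
        # concentrations, film masses and one-way rates stay physical;
        # droplet evaporation rates are signed (condensation is allowed)
        sc = worked_example_h2o2(t_expo=1200.0)
        f = run(sc).frame
        for col in f.columns:
            if col != "t" and not col.startswith("rate_evap_"):
                assert (f[col] >= 0).all(), col
        assert (np.diff(f["t"].to_numpy()) > 0).all()


class TestMassAudit:
    def test_zero_release_ledger(self):
        sc = toy_single_pulse(rate=0.0, t_expo=50.0, psat1=0.0, psat2=0.0)
        audit = mass_audit(run(sc))
        assert audit["released"] == 0.0
        assert audit["vented"] == 0.0
        assert audit["closure_error"] == 0.0

    def test_closure_and_step_refinement(self):
        # a short room-spray with settling, evaporation and films closes
        # the ledger, and refinement does not degrade the closure
        sc = toy_single_pulse(
            psat1=2308.0, psat2=0.0, w_pr=(0.99, 0.01), d_m=120e-6,
            rate=2e-3, duration=30.0, t_expo=300.0, dt=0.2, dt_post=1.0,
            Q_vent=0.1,
        )
        err = mass_audit(run(sc))["closure_error"]
        assert err < 0.01
        sc2 = toy_single_pulse(
            psat1=2308.0, psat2=0.0, w_pr=(0.99, 0.01), d_m=120e-6,
            rate=2e-3, duration=30.0, t_expo=300.0, dt=0.1, dt_post=0.5,
            IM=40, Q_vent=0.1,
        )
        err2 = mass_audit(run(sc2))["closure_error"]
        assert err2 <= max(err, 1e-9)

    def test_time_step_convergence_of_averages(self):
        # halving dt changes the exposure averages by well under 2%
        base = dict(psat1=2308.0, psat2=0.0, w_pr=(0.988, 0.012), d_m=150e-6,
                    rate=5e-3, duration=30.0, t_expo=400.0, V_room=201.6, F=50.4)
        res1 = run(toy_single_pulse(**base, dt=0.1, dt_post=1.0))
        res2 = run(toy_single_pulse(**base, dt=0.05, dt_post=0.5, IM=40))
        for col in ("C_comp1", "A_inh_comp2"):
            a = time_weighted_average(res1, col, (0, 400))
            b = time_weighted_average(res2, col, (0, 400))
            assert a == pytest.approx(b, rel=0.02)


class TestWallMode:
    def test_overspray_and_deposit_partition(self):
        sc = worked_example_h2o2(t_expo=400.0)
        res = run(sc)
        md = res.metadata
        released = md["released_airborne"] + md["released_wall"]
        assert released == pytest.approx(2.4, rel=1e-9)
        # classes 1-2 of 5 are overspray in this geometry
        assert md["released_airborne"] == pytest.approx(2.4 * 0.4, rel=1e-9)

    def test_aerosol_confined_to_spraying_phase(self):
        res = run(worked_example_h2o2(t_expo=1200.0))
        f = res.frame
        t = f["t"].to_numpy()
        A = f["A_inh"].to_numpy()
        after = A[np.argmin(np.abs(t - 900.0))]
        assert after < 0.01 * A.max()

    def test_wall_film_grows_then_depletes(self):
        res = run(worked_example_h2o2(t_expo=3600.0))
        f = res.frame
        wall_w = f["m_wall_H2O"].to_numpy()
        assert wall_w.max() > 0
        assert wall_w[-1] < 0.5 * wall_w.max()
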