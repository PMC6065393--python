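"""Equilibria, tipping points, resilience and calibration."""

import numpy as np
import pytest

from metacoop import (
    DILUTION_SHOCK,
    Protocol,
    calibrate,
    critical_dilution,
    generations_per_cycle,
    isolated,
    max_shock,
    migration_per_generation,
    phase_diagram,
    producer_fraction,
    recovery_threshold,
    simulate,
    star,
    steady_state,
    survives,
)
from metacoop.analysis import BracketError
from conftest import dense_start


class TestProducerFraction:
    def test_pure_producers_give_one(self, params, star9):
        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=5)
        traj = simulate(star9, proto, dense_start(10, fraction=1.0))
        pf = producer_fraction(traj)
        assert np.allclose(pf.overall, 1.0)
        assert np.allclose(pf.per_node, 1.0)

    def test_overall_fraction_is_density_weighted(self, params):
        # two wells (10, 90) and (30, 70): overall = 40/200
        from metacoop import Trajectory

        states = np.array([[[10.0, 90.0], [30.0, 70.0]]])
        traj = Trajectory(
            states=states,
            cycles=np.array([1]),
            topology=isolated(2),
            protocol=Protocol(D=650, m=0.0, params=params, n_cycles=1),
            initial_states=states[0],
        )
        pf = producer_fraction(traj)
        assert pf.overall[0] == pytest.approx(0.2)
        assert pf.per_node[0, 0] == pytest.approx(0.1)

    def test_empty_network_is_flagged_nan(self, params, iso1):
        proto = Protocol(D=650.0, m=0.0, params=params, n_cycles=5)
        traj = simulate(iso1, proto, np.zeros((1, 2)))
        pf = producer_fraction(traj)
        assert np.isnan(pf.overall).all()


class TestSteadyState:
    def test_isolated_converges_below_collapse(self, iso_equilibrium):
        assert iso_equilibrium.status == "converged"
        assert iso_equilibrium.period is None

    def test_huge_dilution_reports_extinction(self, params, iso1):
        proto = Protocol(D=1e5, m=0.0, params=params, n_cycles=100)
        ss = steady_state(iso1, proto, dense_start(1))
        assert ss.status == "extinct"
        assert not ss.surviving

    def test_period_two_orbit_detected_with_min_phase(self, params, iso1):
        # toy cycle map alternating between a high and a low state
        hi = np.array([[200.0, 800.0]])
        lo = np.array([[20.0, 80.0]])

        def step(dens, t):
            return lo.copy() if t % 2 == 0 else hi.copy()

        proto = Protocol(D=650.0, m=0.0, params=params, n_cycles=100)
        ss = steady_state(iso1, proto, hi, step=step)
        assert ss.status == "oscillatory"
        assert ss.period == 2
        assert ss.states.sum() == pytest.approx(lo.sum())  # minimum-density phase

    def test_frequency_dependence_converges_from_both_sides(self, params, iso1):
        """Starting from 5% or 90% producers, the same equilibrium fraction."""
        proto = Protocol(D=650.0, m=0.0, params=params, n_cycles=1000)
        fracs = []
        for f0 in (0.05, 0.9):
            ss = steady_state(iso1, proto, dense_start(1, fraction=f0))
            assert ss.status == "converged"
            fracs.append(ss.states[0, 0] / ss.states.sum())
        assert fracs[0] == pytest.approx(fracs[1], rel=0.01)


class TestSurvivalAndCriticalDilution:
    def test_survives_benign_collapses_harsh(self, params, iso1, iso_equilibrium):
        eq = iso_equilibrium.states
        benign = Protocol(D=650.0, m=0.0, params=params, n_cycles=300)
        harsh = Protocol(D=1900.0, m=0.0, params=params, n_cycles=300)
        assert survives(iso1, benign, eq)
        assert not survives(iso1, harsh, eq)

    def test_star_at_zero_migration_equals_isolated(self, params):
        kw = dict(bracket=(800.0, 2000.0), tol=5e-3, n_cycles=400)
        d_star_net = critical_dilution(star(9), 0.0, params, **kw)
        d_iso = critical_dilution(isolated(10), 0.0, params, **kw)
        assert d_star_net == d_iso

    def test_boundary_is_bracketed(self, params, iso1, iso_equilibrium):
        tol = 5e-3
        d_star = critical_dilution(
            iso1, 0.0, params, bracket=(800.0, 2000.0), tol=tol, n_cycles=400,
            initial_states=iso_equilibrium.states,
        )
        assert 800.0 < d_star < 2000.0
        lo = Protocol(D=d_star * (1 - 2 * tol), m=0.0, params=params, n_cycles=400)
        hi = Protocol(D=d_star * (1 + 2 * tol), m=0.0, params=params, n_cycles=400)
        assert survives(iso1, lo, iso_equilibrium.states)
        assert not survives(iso1, hi, iso_equilibrium.states)

    def test_bad_bracket_raises(self, params, iso1, iso_equilibrium):
        with pytest.raises(BracketError):
            critical_dilution(
                iso1, 0.0, params, bracket=(400.0, 700.0), n_cycles=200,
                initial_states=iso_equilibrium.states,
            )

    def test_equilibrium_fraction_monotone_in_dilution(self, params, iso1):
        """Below collapse, harsher dilution leaves sparser, more producer-rich wells."""
        fracs = []
        for D in (400.0, 650.0, 800.0, 1000.0, 1150.0):
            ss = steady_state(iso1, Protocol(D=D, m=0.0, params=params, n_cycles=1000))
            assert ss.surviving
            fracs.append(ss.states[0, 0] / ss.states.sum())
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


class TestPhaseDiagram:
    def test_small_grid_shape_and_monotonicity(self, params, star9):
        pd_ = phase_diagram(
            star9, D_grid=[500.0, 900.0, 1600.0], m_grid=[0.0, 0.6], params=params,
            n_cycles=300,
        )
        assert pd_.survival.shape == (2, 3)
        assert pd_.monotonicity_violations == ()
        # benign corner survives; harsh dilution with strong migration collapses
        assert pd_.survival[0, 0] and pd_.survival[1, 0]
        assert not pd_.survival[1, 2]
        df = pd_.to_dataframe()
        assert set(df.columns) == {"m", "D", "survives"}
        assert len(df) == 6

    def test_zero_migration_row_matches_isolated(self, params, star9):
        grid = [500.0, 900.0, 1600.0]
        pd_star = phase_diagram(star9, grid, [0.0], params, n_cycles=300)
        pd_iso = phase_diagram(isolated(10), grid, [0.0], params, n_cycles=300)
        assert np.array_equal(pd_star.survival, pd_iso.survival)


class TestResilience:
    def test_trivial_shock_always_recovers(self, params, iso1):
        proto = Protocol(D=750.0, m=0.0, params=params, n_cycles=1000)
        res = max_shock(iso1, proto, DILUTION_SHOCK, tol=0.05)
        assert res.max_magnitude > 1.0

    def test_unsurvivable_baseline_rejected(self, params, iso1):
        proto = Protocol(D=5000.0, m=0.0, params=params, n_cycles=1000)
        with pytest.raises(ValueError):
            max_shock(iso1, proto, DILUTION_SHOCK)

    def test_recovery_threshold_sits_below_equilibrium(self, params, iso1):
        proto = Protocol(D=750.0, m=0.0, params=params, n_cycles=1000)
        thr = recovery_threshold(iso1, proto, tol=0.05)
        assert 0.0 < thr.scaling < 1.0
        eq_mean = thr.steady_state.states.sum() / 1
        assert 0.0 < thr.density < eq_mean


class TestCalibration:
    def test_grid_search_recovers_true_cost(self, params, iso1):
        ss = steady_state(iso1, Protocol(D=650.0, m=0.0, params=params, n_cycles=1000))
        truth = ss.states[0, 0] / ss.states.sum()
        best = calibrate(
            {"equilibrium_fraction": truth},
            c_grid=(0.03, 0.07, 0.09),
            eps_ratio_grid=(params.eps / params.k_m,),
            t_grow_grid=(22.0,),
            top=3,
        )
        assert best[0].params.c == pytest.approx(params.c)
        assert best[0].score < best[-1].score

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate({"collapse_day": 3})


def test_generation_scale_arithmetic():
    assert migration_per_generation(0.6, 10.0) == pytest.approx(0.06)
    assert 9.0 < generations_per_cycle(650.0) < 10.5
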