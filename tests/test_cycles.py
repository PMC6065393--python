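"""The daily cycle map and trajectory bookkeeping."""

import numpy as np
import pytest

from metacoop import (
    DILUTION_SHOCK,
    GROWTH_SHOCK,
    Perturbation,
    Protocol,
    fully_connected,
    isolated,
    migration_matrix,
    run_cycle,
    simulate,
    standard_initial_state,
    star,
)
from conftest import dense_start


class TestRunCycle:
    def test_trivial_cycle_is_identity(self, params):
        # D=1, m=0 and a full growth-rate shock: nothing happens
        proto = Protocol(
            D=1.0, m=0.0, params=params, n_cycles=1,
            perturbation=Perturbation(cycle=0, kind=GROWTH_SHOCK, magnitude=params.r),
        )
        op = migration_matrix(isolated(3), 0.0)
        dens = dense_start(3)
        out = run_cycle(dens, op, proto, 0)
        assert np.allclose(out, dens, rtol=1e-14)

    def test_full_growth_shock_is_pure_dilution_and_migration(self, params, star9):
        proto = Protocol(
            D=650.0, m=0.6, params=params, n_cycles=1,
            perturbation=Perturbation(cycle=0, kind=GROWTH_SHOCK, magnitude=params.r),
        )
        op = migration_matrix(star9, 0.6)
        dens = dense_start(10)
        out = run_cycle(dens, op, proto, 0)
        expected = op.M @ (dens / 650.0)
        expected[expected < proto.extinction_cutoff] = 0.0
        assert np.allclose(out, expected, rtol=1e-14)

    def test_dilution_shock_applies_to_one_cycle_only(self, params, star9):
        base = Protocol(D=650.0, m=0.6, params=params, n_cycles=6)
        shocked = base.replace(
            perturbation=Perturbation(cycle=3, kind=DILUTION_SHOCK, magnitude=5.0)
        )
        init = dense_start(10)
        t0 = simulate(star9, base, init)
        t1 = simulate(star9, shocked, init)
        assert np.array_equal(t0.states[:3], t1.states[:3])
        assert not np.allclose(t0.states[3], t1.states[3])

    def test_sub_cutoff_densities_are_zeroed_exactly(self, params):
        proto = Protocol(D=650.0, m=0.0, params=params, n_cycles=1, extinction_cutoff=0.005)
        op = migration_matrix(isolated(1), 0.0)
        # rare producers regrow ~36x per cycle; 0.05/650 × 36 is still < 0.005
        out = run_cycle(np.array([[0.05, 0.05]]), op, proto, 0)
        assert (out == 0.0).all()


class TestSimulate:
    def test_determinism_is_bitwise(self, params, star9):
        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=20)
        init = dense_start(10)
        a = simulate(star9, proto, init)
        b = simulate(star9, proto, init)
        assert np.array_equal(a.states, b.states)

    def test_all_zero_start_flagged_extinct_immediately(self, params, star9):
        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=50)
        traj = simulate(star9, proto, np.zeros((10, 2)))
        assert traj.all_extinct_cycle == 1
        assert traj.extinct.all()
        assert (traj.states == 0).all()

    def test_extinction_is_absorbing(self, params, iso1):
        # dilute start below the public-good Allee threshold collapses and stays at 0
        proto = Protocol(D=650.0, m=0.0, params=params, n_cycles=300)
        traj = simulate(iso1, proto, np.array([[50.0, 950.0]]))
        assert traj.all_extinct_cycle is not None
        assert (traj.states[traj.all_extinct_cycle - 1 :] == 0).all()

    def test_nonproducers_absent_stay_absent(self, params, star9):
        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=30)
        traj = simulate(star9, proto, dense_start(10, fraction=1.0))
        assert (traj.states[:, :, 1] == 0.0).all()
        assert (traj.final_states[:, 0] > 0).all()

    def test_fully_connected_matches_isolated_from_identical_states(self, params):
        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=60)
        init = dense_start(10)
        t_fc = simulate(fully_connected(10), proto, init)
        t_iso = simulate(isolated(10), proto, init)
        assert np.allclose(t_fc.states, t_iso.states, rtol=1e-9)

    def test_zero_migration_star_is_bitwise_isolated(self, params):
        proto = Protocol(D=650.0, m=0.0, params=params, n_cycles=40)
        init = dense_start(10)
        t_star = simulate(star(9), proto, init)
        t_iso = simulate(isolated(10), proto, init)
        assert np.array_equal(t_star.states, t_iso.states)

    def test_dimension_mismatch_rejected(self, params, star9):
        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=5)
        with pytest.raises(ValueError):
            simulate(star9, proto, np.ones((4, 2)))


class TestTrajectoryExport:
    def test_tidy_dataframe_schema_and_roles(self, params, star9):
        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=5)
        traj = simulate(star9, proto, dense_start(10))
        df = traj.to_dataframe()
        assert list(df.columns) == ["cycle", "node", "role", "Np", "Nnp", "total", "fraction"]
        assert len(df) == 5 * 10
        assert set(df["role"]) == {"center", "side"}
        assert ((df["fraction"] >= 0) & (df["fraction"] <= 1)).all()
        assert np.allclose(df["total"], df["Np"] + df["Nnp"])

    def test_manifest_round_trips_through_json(self, params, star9, tmp_path):
        import json

        proto = Protocol(D=650.0, m=0.6, params=params, n_cycles=3)
        traj = simulate(star9, proto, dense_start(10))
        path = tmp_path / "run.json"
        traj.write_manifest(path)
        manifest = json.loads(path.read_text())
        assert manifest["protocol"]["D"] == 650.0
        assert manifest["protocol"]["params"]["K"] == params.K
        assert manifest["cycles_run"] == 3

    def test_csv_round_trip(self, params, iso1, tmp_path):
        import pandas as pd

        proto = Protocol(D=650.0, m=0.0, params=params, n_cycles=4)
        traj = simulate(iso1, proto, dense_start(1))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == 4
        assert back["Np"].to_numpy() == pytest.approx(traj.states[:, 0, 0])


def test_protocol_validation(params):
    with pytest.raises(ValueError):
        Protocol(D=0.5, m=0.0, params=params)
    with pytest.raises(ValueError):
        Protocol(D=650, m=1.5, params=params)
    with pytest.raises(ValueError):
        Perturbation(cycle=0, kind=DILUTION_SHOCK, magnitude=0.5)
    with pytest.raises(ValueError):
        Protocol(
            D=650, m=0.0, params=params,
            perturbation=Perturbation(cycle=0, kind=GROWTH_SHOCK, magnitude=params.r + 0.1),
        )
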