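"""Stochastic engine: transport law, movement propensities, exactness,
conservation, determinism, and checkpoint/resume."""

import numpy as np
import pytest

from svbsim import engine, geometry
from svbsim.engine import (
    StateField,
    longitudinal_move_probability,
    movement_propensities,
)
from svbsim.network import (
    BASIPETAL_ONLY,
    Reaction,
    ReactionNetwork,
    Species,
    TransportRule,
)


class TestTransportLaw:
    def test_no_carrier_baseline(self):
        assert longitudinal_move_probability(0, 1.0, 1.0) == pytest.approx(1 / 3)

    def test_half_saturation(self):
        # carrier count at Km = 6 D / alpha gives 1/3 + Vmax/2 = 2/3
        assert longitudinal_move_probability(6, 1.0, 1.0) == pytest.approx(2 / 3)

    def test_saturation_limit(self):
        assert longitudinal_move_probability(10**9, 1.0, 1.0) == \
            pytest.approx(1.0, abs=1e-6)

    def test_range(self):
        n = np.arange(0, 1000)
        p = longitudinal_move_probability(n, 0.5, 0.2)
        assert (p >= 1 / 3 - 1e-12).all() and (p < 1).all()
        assert (np.diff(p) > 0).all()  # monotone in carrier count

    def test_degenerate_diffusion(self):
        with pytest.raises(ValueError):
            longitudinal_move_probability(5, 0.0, 1.0)


class TestMovementPropensities:
    def _state(self, net, geom, counts):
        return StateField(geom, net.species_names, counts)

    def test_immobile_carrier(self):
        net = ReactionNetwork((Species("P", 0.0),), ())
        geom = geometry.build_cylinder(2, 5)
        counts = np.full((geom.n_voxels, 1), 9, dtype=np.int64)
        st = self._state(net, geom, counts)
        center = geom.voxel_index(2, 2, 2)
        rates = movement_propensities(st, net, "P", center)
        assert all(v == 0.0 for v in rates.values())

    def test_interior_passive_longitudinal_share(self):
        net = ReactionNetwork((Species("H", 1.0),), ())
        geom = geometry.build_cylinder(2, 5)
        counts = np.full((geom.n_voxels, 1), 4, dtype=np.int64)
        st = self._state(net, geom, counts)
        center = geom.voxel_index(2, 2, 2)
        rates = movement_propensities(st, net, "H", center)
        total = sum(rates.values())
        assert (rates["-z"] + rates["+z"]) / total == pytest.approx(1 / 3)

    def test_facilitated_totals_match_transport_law(self):
        # D=1, alpha=2, nP=3, ncargo=5: total = (6D + alpha nP) ncargo = 60
        net = ReactionNetwork(
            (Species("H", 1.0), Species("P", 0.0)),
            (),
            (TransportRule("P", "H", 2.0),),
        )
        geom = geometry.build_cylinder(2, 5)
        counts = np.zeros((geom.n_voxels, 2), dtype=np.int64)
        center = geom.voxel_index(2, 2, 2)
        counts[center] = (5, 3)
        st = self._state(net, geom, counts)
        rates = movement_propensities(st, net, "H", center)
        total = sum(rates.values())
        assert total == pytest.approx(60.0)
        long_share = (rates["-z"] + rates["+z"]) / total
        assert long_share == pytest.approx((2 + 6) / 12)
        assert long_share == pytest.approx(
            longitudinal_move_probability(3, 1.0, 2.0))

    def test_basipetal_only_goes_down(self):
        net = ReactionNetwork(
            (Species("A", 1.0), Species("P", 0.0)),
            (),
            (TransportRule("P", "A", 2.0, BASIPETAL_ONLY),),
        )
        geom = geometry.build_cylinder(2, 5)
        counts = np.zeros((geom.n_voxels, 2), dtype=np.int64)
        center = geom.voxel_index(2, 2, 2)
        counts[center] = (5, 3)
        st = self._state(net, geom, counts)
        rates = movement_propensities(st, net, "A", center)
        assert rates["-z"] == pytest.approx(1.0 * 5 + 2.0 * 3 * 5)
        assert rates["+z"] == pytest.approx(1.0 * 5)


class TestRunSemantics:
    def test_pure_birth_counts_events(self):
        net = ReactionNetwork((Species("H", 0.0),),
                              (Reaction("X4", {}, {"H": 1}, 2.0),))
        geom = geometry.build_disc(1)
        traj = engine.run(net, geom, {"seed": 4, "max_events": 777})
        assert traj.final.total("H") == 777
        assert traj.final.events == 777

    def test_diffusion_conserves_molecules(self, diffusion_only_network,
                                           cyl_small):
        init = np.zeros((cyl_small.n_voxels, 1), dtype=np.int64)
        init[0, 0] = 321
        traj = engine.run(diffusion_only_network, cyl_small,
                          {"seed": 9, "max_events": 50_000,
                           "initial_counts": init})
        assert traj.final.total() == 321
        assert (traj.final.counts >= 0).all()

    def test_max_events_zero_returns_initial_state(self, hb_network):
        geom = geometry.build_disc(3)
        traj = engine.run(hb_network, geom, {"seed": 1, "max_events": 0})
        assert traj.final.events == 0
        assert traj.final.time == 0.0
        assert len(traj.times) == 1
        assert traj.final.total() == 0

    def test_absorbing_state_terminates_cleanly(self):
        # all-degradation network from the zero state has zero propensity
        net = ReactionNetwork((Species("H", 0.0),),
                              (Reaction("X5", {"H": 1}, {}, 1.0),))
        geom = geometry.build_disc(1)
        traj = engine.run(net, geom, {"seed": 1, "max_events": 100})
        assert traj.absorbed
        assert traj.final.events == 0

    def test_snapshot_times_strictly_increasing(self, hb_network):
        geom = geometry.build_disc(4)
        traj = engine.run(hb_network, geom,
                          {"seed": 3, "max_time": 0.5,
                           "snapshot_every_time": 0.1})
        assert all(b > a for a, b in zip(traj.times, traj.times[1:]))
        assert traj.times[-1] == pytest.approx(0.5)

    def test_mean_field_agreement_single_voxel(self):
        """Large-count single-voxel SSA tracks the deterministic ODE."""
        from svbsim.network import make_model
        from svbsim.pde import integrate_single_voxel

        # scale copy numbers up 100x so relative fluctuations are ~1%
        params = dict(k1=1.0 / (100 * 40)**2, k2=1.3 * 100 * 40, k3=0.02,
                      k4=0.2 * 100 * 40, k5=1.0, D_H=0.0, D_B=0.0)
        net = make_model("HB", params)
        geom = geometry.build_disc(1)  # D = 0: 5 independent replicates
        traj = engine.run(net, geom, {"seed": 21, "max_time": 14.0,
                                      "snapshot_every_time": 0.5})
        sol = integrate_single_voxel(0.0, 0.0, params, 14.0)
        # compare time-averages over the post-transient window, averaged
        # additionally over the 5 independent voxels
        window = [(t, c) for t, c in zip(traj.times, traj.fields) if t >= 7.0]
        ssa_H = np.mean([c[:, 0].mean() for _, c in window])
        ssa_B = np.mean([c[:, 1].mean() for _, c in window])
        ode = np.array([sol.sol(t) for t, _ in window])
        assert ssa_H == pytest.approx(ode[:, 0].mean(), rel=0.05)
        assert ssa_B == pytest.approx(ode[:, 1].mean(), rel=0.05)


class TestDeterminismAndResume:
    def test_same_seed_bit_identical(self, hb_network):
        geom = geometry.build_disc(5)
        cfg = {"seed": 42, "max_events": 30_000}
        a = engine.run(hb_network, geom, cfg)
        b = engine.run(hb_network, geom, cfg)
        assert np.array_equal(a.final.counts, b.final.counts)
        assert a.final.time == b.final.time
        assert np.array_equal(a.rng_state, b.rng_state)

    def test_resume_event_identical(self, hb_network):
        geom = geometry.build_disc(5)
        full = engine.run(hb_network, geom, {"seed": 5, "max_events": 10_000})
        half = engine.run(hb_network, geom, {"seed": 5, "max_events": 5_000})
        cont = engine.resume(half, {"max_events": 5_000})
        assert cont.final.events == 10_000
        assert np.array_equal(full.final.counts, cont.final.counts)
        assert full.final.time == cont.final.time

    def test_resume_by_time_event_identical(self, hb_network):
        geom = geometry.build_disc(5)
        full = engine.run(hb_network, geom, {"seed": 5, "max_time": 2.0})
        half = engine.run(hb_network, geom, {"seed": 5, "max_time": 0.7})
        cont = engine.resume(half, {"max_time": 1.3})
        assert np.array_equal(full.final.counts, cont.final.counts)
        assert full.final.events == cont.final.events

    def test_resume_rejects_altered_rates(self, hb_params, hb_network):
        from svbsim.network import make_model

        geom = geometry.build_disc(5)
        half = engine.run(hb_network, geom, {"seed": 5, "max_events": 1_000})
        tampered = make_model("HB", dict(hb_params, k1=hb_params["k1"] * 2))
        with pytest.raises(engine.IncompatibleCheckpoint):
            engine.resume(half, {"max_events": 1}, network=tampered)

    def test_checkpoint_file_roundtrip(self, hb_network, tmp_path):
        geom = geometry.build_disc(5)
        full = engine.run(hb_network, geom, {"seed": 8, "max_events": 8_000})
        half = engine.run(hb_network, geom, {"seed": 8, "max_events": 4_000})
        path = tmp_path / "ck.h5"
        engine.save_checkpoint(half, path)
        loaded = engine.load_checkpoint(path)
        cont = engine.resume(loaded, {"max_events": 4_000})
        assert np.array_equal(full.final.counts, cont.final.counts)
        assert full.final.time == cont.final.time


class TestEventLog:
    def test_shell_restricted_events_stay_in_shell(self):
        """Every shell-restricted production event fires in a shell voxel."""
        from svbsim.config import _hbpm
        from svbsim.network import make_model

        net = make_model("HBPM", _hbpm())
        geom = geometry.build_disc(8)
        traj = engine.run(net, geom, {"seed": 13, "max_events": 200_000,
                                      "event_log": True,
                                      "event_log_capacity": 200_000})
        log = traj.event_log
        kern = log["kernel"]
        x9 = [i for i, r in enumerate(net.reactions) if r.label == "X9"][0]
        shell = geometry.shell_mask(geom, geom.shell_fraction)
        x9_events = log["voxel"][log["channel"] == x9]
        assert x9_events.size > 0
        assert shell[x9_events].all()
        assert kern.decode_channel(x9) == ("reaction", "X9")
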