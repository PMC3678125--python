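import numpy as np
import pytest

from brainsim import (
    ConfigurationError,
    Connectome,
    DimensionError,
    Generic2dOscillator,
    HeunDeterministic,
    HeunStochastic,
    HistoryBuffer,
    LinearCoupling,
    PulseTrain,
    RawMonitor,
    SimulationDivergenceError,
    Simulator,
    TemporalAverageMonitor,
    WhiteNoise,
    WilsonCowan,
    build_local_kernel,
    gaussian_profile,
    make_grid_mesh,
    node_coupling,
    region_stimulus,
)
from brainsim.surface import RegionSurface

from reference import naive_generic2d_heun, naive_node_coupling


def _chain_connectome(delay_steps, dt=0.25, weight=1.0):
    """Two nodes, node 1 <- node 0 with the requested integer delay."""
    length = delay_steps * dt * 4.0  # speed 4 mm/ms
    return Connectome(
        weights=np.array([[0.0, 0.0], [weight, 0.0]]),
        tract_lengths=np.array([[0.0, length], [length, 0.0]]),
        speed=4.0,
    )


class TestHistoryBuffer:
    def test_delayed_read_matches_step_bookkeeping(self):
        h = HistoryBuffer(horizon=5, n_nodes=2, n_cvar=1, n_modes=1)
        # steps -4..0 hold distinguishable values
        init = np.arange(-4, 1, dtype=float).reshape(5, 1, 1, 1) * np.ones((5, 2, 1, 1))
        h.initialize(init)
        col = np.arange(2)[None, :]
        for step in range(1, 20):
            h.write(step, np.full((2, 1, 1), float(step)))
            for d in range(5):
                delays = np.full((2, 2), d)
                got = h.read_delayed(step, delays, col)
                np.testing.assert_array_equal(got, float(step - d))

    def test_initialize_orientation_most_recent_last(self):
        h = HistoryBuffer(horizon=3, n_nodes=1, n_cvar=1, n_modes=1)
        init = np.array([10.0, 20.0, 30.0]).reshape(3, 1, 1, 1)
        h.initialize(init)
        col = np.arange(1)[None, :]
        for d, expected in [(0, 30.0), (1, 20.0), (2, 10.0)]:
            got = h.read_delayed(0, np.array([[d]]), col)
            assert got[0, 0, 0, 0] == expected


class TestNodeCoupling:
    def test_matches_triple_loop_oracle_bit_exact(self):
        rng = np.random.default_rng(0)
        n, horizon = 3, 6
        h = HistoryBuffer(horizon, n, n_cvar=2, n_modes=1)
        h.initialize(rng.normal(size=(horizon, n, 2, 1)))
        weights = rng.uniform(0, 2, size=(n, n))
        delays = rng.integers(0, horizon, size=(n, n))
        for step in range(0, 4):
            got = node_coupling(h, weights, delays, LinearCoupling(a=1.0, b=0.0), step)
            want = naive_node_coupling(h.buffer, step, weights, delays)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-13)

    def test_zero_weights_give_zero_input(self):
        h = HistoryBuffer(4, 3, 1, 1)
        h.initialize(np.random.default_rng(1).normal(size=(4, 3, 1, 1)))
        out = node_coupling(h, np.zeros((3, 3)), np.zeros((3, 3), int),
                            LinearCoupling(a=1.0), 0)
        np.testing.assert_array_equal(out, 0.0)

    def test_zero_delay_is_matrix_vector_product(self):
        rng = np.random.default_rng(2)
        h = HistoryBuffer(1, 4, 1, 1)
        current = rng.normal(size=(1, 4, 1, 1))
        h.initialize(current)
        w = rng.uniform(size=(4, 4))
        out = node_coupling(h, w, np.zeros((4, 4), int), LinearCoupling(a=1.0, b=0.0), 0)
        np.testing.assert_allclose(out[:, 0, 0], w @ current[0, :, 0, 0], atol=1e-14)

    def test_pre_summation_transform_switch(self):
        rng = np.random.default_rng(3)
        h = HistoryBuffer(2, 3, 1, 1)
        h.initialize(rng.normal(size=(2, 3, 1, 1)))
        w = rng.uniform(size=(3, 3))
        from brainsim import SigmoidalCoupling

        pre = SigmoidalCoupling(apply_before_sum=True)
        post = SigmoidalCoupling(apply_before_sum=False)
        out_pre = node_coupling(h, w, np.zeros((3, 3), int), pre, 0)
        out_post = node_coupling(h, w, np.zeros((3, 3), int), post, 0)
        assert not np.allclose(out_pre, out_post)
        # pre-sum oracle
        delayed = h.buffer[0]  # step 0, zero delays
        want = w @ post(delayed[:, 0, 0])
        np.testing.assert_allclose(out_pre[:, 0, 0], want, atol=1e-13)


class TestConfigure:
    def test_horizon_for_80mm_tract(self):
        c = Connectome(
            weights=np.ones((2, 2)),
            tract_lengths=np.array([[0.0, 80.0], [80.0, 0.0]]),
            speed=4.0,
        )
        sim = Simulator(c, Generic2dOscillator(), HeunDeterministic(dt=0.0625),
                        seed=0).configure()
        assert sim.horizon == 321  # 320 delay steps + current slot

    def test_random_history_within_state_ranges(self, small_connectome):
        model = Generic2dOscillator()
        sim = Simulator(small_connectome, model, HeunDeterministic(dt=0.25),
                        seed=7).configure()
        buf = sim.history.buffer
        lo, hi = model.state_ranges[0]
        assert buf.min() >= lo and buf.max() <= hi  # cvar = v

    def test_short_initial_conditions_padded_recent_slots_preserved(self, small_connectome):
        model = Generic2dOscillator()
        probe = Simulator(small_connectome, model, HeunDeterministic(dt=0.25),
                          seed=0).configure()
        horizon = probe.horizon
        assert horizon > 4
        supplied = np.full((horizon // 2, 4, 2, 1), 0.123)
        sim = Simulator(small_connectome, model, HeunDeterministic(dt=0.25),
                        initial_conditions=supplied, seed=0).configure()
        col = np.arange(4)[None, :]
        for k in range(horizon // 2):  # most recent horizon//2 slots = supplied
            got = sim.history.read_delayed(0, np.full((4, 4), k), col)
            np.testing.assert_array_equal(got, 0.123)
        older = sim.history.read_delayed(0, np.full((4, 4), horizon - 1), col)
        assert not np.allclose(older, 0.123)

    def test_inconsistent_initial_conditions_rejected(self, small_connectome):
        with pytest.raises(ConfigurationError, match="initial_conditions"):
            Simulator(
                small_connectome, Generic2dOscillator(), HeunDeterministic(dt=0.25),
                initial_conditions=np.zeros((10, 3, 2, 1)), seed=0,
            ).configure()

    def test_stimulus_length_mismatch_rejected(self, small_connectome):
        stim = region_stimulus(np.ones(3), PulseTrain())
        with pytest.raises(DimensionError):
            Simulator(small_connectome, Generic2dOscillator(),
                      HeunDeterministic(dt=0.25), stimulus=stim, seed=0).configure()


class TestRun:
    def test_step_count(self, small_connectome):
        sim = Simulator(small_connectome, Generic2dOscillator(),
                        HeunDeterministic(dt=0.0625), monitors=[RawMonitor()],
                        seed=1).configure()
        ts = sim.run(1000.0)[0]
        assert ts.n_samples == 16000

    def test_two_monitor_shapes(self, small_connectome):
        from brainsim import ProjectionMatrix, SensorProjectionMonitor

        gain = np.random.default_rng(0).normal(size=(6, 4))
        sim = Simulator(
            small_connectome,
            Generic2dOscillator(),
            HeunDeterministic(dt=0.25),
            monitors=[
                TemporalAverageMonitor(period=1.0),
                SensorProjectionMonitor(ProjectionMatrix(gain), period=1.0),
            ],
            seed=1,
        ).configure()
        avg, proj = sim.run(100.0)
        assert avg.data.shape == (100, 1, 4, 1)   # [time, svar, space, modes]
        assert proj.data.shape == (100, 1, 6, 1)  # [time, 1, sensors, 1]

    def test_deterministic_run_reproducible(self, small_connectome):
        def run():
            sim = Simulator(small_connectome, Generic2dOscillator(),
                            HeunDeterministic(dt=0.25), monitors=[RawMonitor()],
                            seed=5).configure()
            return sim.run(50.0)[0].data

        np.testing.assert_array_equal(run(), run())

    def test_divergence_reports_step_and_node(self, small_connectome):
        # runaway positive feedback: g > 0 large, no cubic damping
        model = Generic2dOscillator(f=0.0, g=50.0, d=10.0)
        sim = Simulator(small_connectome, model, HeunDeterministic(dt=1.0),
                        seed=0).configure()
        with pytest.raises(SimulationDivergenceError) as err:
            sim.run(2000.0)
        assert err.value.step > 0

    def test_isolated_nodes_match_single_node_runs(self):
        """Zero weights: each node's trajectory equals its own 1-node run."""
        c = Connectome(weights=np.zeros((2, 2)),
                       tract_lengths=np.array([[0.0, 10.0], [10.0, 0.0]]))
        ic = np.array([[[0.5], [0.0]], [[-0.3], [0.2]]])  # (2 nodes, 2 svar, 1)
        horizon = 11  # 10 mm / 4 mm/ms / 0.25 ms = 10 steps
        full_ic = np.tile(ic[None], (horizon, 1, 1, 1))
        sim = Simulator(c, Generic2dOscillator(), HeunDeterministic(dt=0.25),
                        monitors=[RawMonitor()], initial_conditions=full_ic,
                        seed=0).configure()
        both = sim.run(50.0)[0].data
        for node in range(2):
            c1 = Connectome(weights=np.zeros((1, 1)), tract_lengths=np.zeros((1, 1)))
            solo = Simulator(
                c1, Generic2dOscillator(), HeunDeterministic(dt=0.25),
                monitors=[RawMonitor()],
                initial_conditions=ic[node][None, None], seed=0,
            ).configure().run(50.0)[0].data
            np.testing.assert_array_equal(both[:, :, node, 0], solo[:, :, 0, 0])


class TestOracleEquivalence:
    def test_full_simulator_matches_naive_reference(self):
        """5-node deterministic Heun vs an independent loop-based
        implementation: sample-for-sample to 1e-12 over 100 ms."""
        rng = np.random.default_rng(7)
        n = 5
        weights = rng.uniform(0, 1.5, size=(n, n))
        np.fill_diagonal(weights, 0.0)
        lengths = rng.uniform(2, 10, size=(n, n))
        lengths = (lengths + lengths.T) / 2
        np.fill_diagonal(lengths, 0.0)
        c = Connectome(weights=weights, tract_lengths=lengths, speed=4.0)
        dt = 0.25
        sim = Simulator(c, Generic2dOscillator(), HeunDeterministic(dt=dt),
                        LinearCoupling(a=0.02), [RawMonitor()], seed=3).configure()
        init_history = np.array(
            [sim.history.buffer[(-k) % sim.horizon] for k in range(sim.horizon)]
        )[::-1]  # reconstruct [horizon, n, 1(cvar), 1] oldest first
        # full state history: w component is only needed at step 0
        full_init = np.zeros((sim.horizon, n, 2))
        full_init[:, :, 0] = init_history[:, :, 0, 0]
        full_init[-1, :, 1] = sim.state[:, 1, 0]
        n_steps = int(round(100.0 / dt))
        want = naive_generic2d_heun(
            weights, sim.delay_steps, Generic2dOscillator.parameter_defaults,
            full_init, dt, n_steps, coupling_a=0.02,
        )
        got = sim.run(100.0)[0].data  # [time, svar, nodes, modes]
        np.testing.assert_allclose(got[:, :, :, 0].transpose(0, 2, 1), want,
                                   rtol=0, atol=1e-12)


class TestDelayCausality:
    @pytest.mark.parametrize("delay_steps", [3, 8])
    def test_pulse_arrives_exactly_after_delay(self, delay_steps):
        """Feed-forward pair at rest: V2's state departs from zero exactly
        delay + 1 steps after V1's does (input lags by the delay, the state
        by one more explicit-update step)."""
        dt = 0.25
        c = _chain_connectome(delay_steps, dt=dt, weight=5.0)
        stim = region_stimulus([1.0, 0.0], PulseTrain(onset=0.0, width=5.0,
                                                      period=1000.0, amplitude=2.0))
        ic = np.zeros((delay_steps + 1, 2, 2, 1))  # full-horizon rest history
        sim = Simulator(c, WilsonCowan(), HeunDeterministic(dt=dt),
                        LinearCoupling(a=1.0), [RawMonitor()], stimulus=stim,
                        initial_conditions=ic, seed=0).configure()
        data = sim.run(20.0)[0].data  # [time, svar, nodes, modes], steps 1..n
        first_v1 = int(np.flatnonzero(np.abs(data[:, 0, 0, 0]) > 0)[0]) + 1
        first_v2 = int(np.flatnonzero(np.abs(data[:, 0, 1, 0]) > 0)[0]) + 1
        assert first_v1 == 1  # stimulus active from t = 0
        assert first_v2 - first_v1 == delay_steps + 1


class TestContinuation:
    def _simulator(self, connectome, stochastic=False, seed=11):
        integ = (
            HeunStochastic(dt=0.25, noise=WhiteNoise(nsig=1e-4))
            if stochastic
            else HeunDeterministic(dt=0.25)
        )
        return Simulator(connectome, Generic2dOscillator(), integ,
                         LinearCoupling(a=0.02), [RawMonitor()], seed=seed).configure()

    @pytest.mark.parametrize("stochastic", [False, True])
    def test_split_run_equals_uninterrupted(self, small_connectome, stochastic):
        one = self._simulator(small_connectome, stochastic).run(200.0)[0].data
        sim = self._simulator(small_connectome, stochastic)
        a = sim.run(100.0)[0].data
        b = sim.continue_run(100.0)[0].data
        np.testing.assert_array_equal(np.concatenate([a, b]), one)

    def test_parameter_change_affects_only_later_samples(self, small_connectome):
        sim = self._simulator(small_connectome)
        a1 = sim.run(100.0)[0].data
        b1 = sim.continue_run(100.0, modified={"model.I_ext": 1.5})[0].data
        sim2 = self._simulator(small_connectome)
        a2 = sim2.run(100.0)[0].data
        b2 = sim2.continue_run(100.0)[0].data
        np.testing.assert_array_equal(a1, a2)
        assert not np.array_equal(b1, b2)

    def test_coupling_and_stimulus_modifiable(self, small_connectome):
        sim = self._simulator(small_connectome)
        sim.run(10.0)
        stim = region_stimulus(np.ones(4), PulseTrain())
        out = sim.continue_run(10.0, modified={"coupling.a": 0.05, "stimulus": stim})
        assert out[0].n_samples == 40

    def test_forbidden_modifications_rejected(self, small_connectome):
        sim = self._simulator(small_connectome)
        sim.run(10.0)
        for key in ("integrator.dt", "connectome.speed", "surface"):
            with pytest.raises(ConfigurationError):
                sim.continue_run(10.0, modified={key: 1.0})


class TestSurfaceMode:
    def _surface_sim(self, local=True):
        mesh = make_grid_mesh(3, 3, spacing=2.0)  # 9 vertices
        # 3 regions: vertices map to regions 0/1, region 2 is non-cortical
        mapping = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1])
        c = Connectome(
            weights=np.array([[0.0, 1.0, 0.5], [2.0, 0.0, 0.0], [1.0, 1.0, 0.0]]),
            tract_lengths=np.array([[0.0, 20.0, 30.0], [20.0, 0.0, 10.0],
                                    [30.0, 10.0, 0.0]]),
            region_labels=["A", "B", "thalamus"],
            speed=4.0,
        )
        kernel = (
            build_local_kernel(mesh, gaussian_profile(sigma=2.0, cutoff=3.0), cutoff=3.0)
            if local else None
        )
        surf = RegionSurface(mesh=mesh, region_mapping=mapping)
        return Simulator(
            c, Generic2dOscillator(), HeunDeterministic(dt=0.25),
            LinearCoupling(a=0.01), [RawMonitor()], surface=surf,
            local_kernel=kernel, seed=4,
        ).configure()

    def test_node_count_is_vertices_plus_non_cortical(self):
        sim = self._surface_sim()
        assert sim.n_nodes == 9 + 1
        assert sim.node_labels[-1] == "thalamus"

    def test_surface_run_produces_vertex_timeseries(self):
        ts = self._surface_sim().run(20.0)[0]
        assert ts.data.shape == (80, 2, 10, 1)
        assert np.all(np.isfinite(ts.data))

    def test_local_kernel_changes_dynamics(self):
        with_k = self._surface_sim(local=True).run(20.0)[0].data
        without = self._surface_sim(local=False).run(20.0)[0].data
        assert not np.allclose(with_k, without)


class TestLocalKernel:
    def test_matches_dense_distance_oracle(self):
        mesh = make_grid_mesh(4, 3, spacing=1.5)
        eq = gaussian_profile(amplitude=1.0, sigma=2.0, cutoff=4.0)
        k = build_local_kernel(mesh, eq, cutoff=4.0).toarray()
        v = mesh.vertices
        for i in range(v.shape[0]):
            for j in range(v.shape[0]):
                d = float(np.sqrt(((v[i] - v[j]) ** 2).sum()))
                want = np.exp(-d**2 / (2 * 2.0**2)) if d <= 4.0 else 0.0
                assert k[i, j] == pytest.approx(want, abs=1e-12)

    def test_symmetric_for_symmetric_equation(self):
        mesh = make_grid_mesh(4, 4)
        k = build_local_kernel(mesh, gaussian_profile(cutoff=5.0), cutoff=5.0).toarray()
        np.testing.assert_allclose(k, k.T)

    def test_tiny_cutoff_keeps_only_diagonal(self):
        mesh = make_grid_mesh(3, 3, spacing=2.0)
        k = build_local_kernel(mesh, gaussian_profile(cutoff=1.0), cutoff=1.0).toarray()
        np.testing.assert_allclose(k, np.eye(9))
        k2 = build_local_kernel(mesh, gaussian_profile(cutoff=1.0), cutoff=1.0,
                                include_self=False).toarray()
        np.testing.assert_array_equal(k2, 0.0)

    def test_non_positive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            build_local_kernel(make_grid_mesh(2, 2), gaussian_profile(), cutoff=0.0)
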