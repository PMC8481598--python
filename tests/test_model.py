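"""Unit and property tests for the network model: gating kinetics, ionic
currents, synapses, the Izhikevich cortex, parkinsonism scaling, and the
integrator itself (kernel-vs-reference equality, determinism, convergence,
decoupling)."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from dbsloop.model import (
    ConfigError,
    GatingSpec,
    NetworkConfig,
    SynapseSpec,
    alpha_kernel,
    apply_parkinsonism,
    default_network,
    gate_derivative,
    ionic_currents,
    izhikevich_equilibrium,
    izhikevich_step,
    neuron_model,
    reference_rhs,
    simulate,
    steady_state_gate,
    synapse_drive,
    _Packed,
    _rhs,
    SYN_TAU,
)

# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------


class TestGating:
    def test_sigmoid_midpoint(self):
        spec = GatingSpec("instantaneous", half_voltage=40.0, slope=8.0)
        assert steady_state_gate(-40.0, spec) == pytest.approx(0.5)

    @pytest.mark.parametrize("slope,lo,hi", [(8.0, 0.0, 1.0), (-6.4, 1.0, 0.0)])
    def test_sigmoid_limits(self, slope, lo, hi):
        spec = GatingSpec("instantaneous", half_voltage=0.0, slope=slope)
        assert steady_state_gate(-1e4, spec) == pytest.approx(lo, abs=1e-12)
        assert steady_state_gate(1e4, spec) == pytest.approx(hi, abs=1e-12)

    def test_stn_m_gate_half_activation(self):
        # STN fast activation: half voltage 40 mV, slope 8 mV
        m = neuron_model("STN").gates["m"]
        assert steady_state_gate(-40.0, m) == pytest.approx(0.5)

    def test_monotone_in_v(self):
        m = neuron_model("STN").gates["m"]
        v = np.linspace(-100, 60, 200)
        vals = [steady_state_gate(x, m) for x in v]
        assert np.all(np.diff(vals) > 0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ConfigError):
            GatingSpec("instantaneous", half_voltage=0.0, slope=0.0)

    def test_fixed_point_has_zero_derivative(self):
        h = neuron_model("STN").gates["h"]
        for v in (-80.0, -60.0, -40.0):
            x = steady_state_gate(v, h)
            assert gate_derivative(x, v, h) == pytest.approx(0.0, abs=1e-14)

    def test_alpha_beta_balance_point(self):
        spec = GatingSpec("alpha_beta", alpha_fn=lambda v: 0.3,
                          beta_fn=lambda v: 0.3)
        assert gate_derivative(0.5, -60.0, spec) == pytest.approx(0.0)

    def test_stn_r_gate_relaxation_rate(self):
        # r has unit rate scale and a fixed 2 ms time constant
        r = neuron_model("STN").gates["r"]
        for v in (-70.0, -20.0, 10.0):
            rinf = steady_state_gate(v, r)
            assert gate_derivative(0.3, v, r) == pytest.approx((rinf - 0.3) / 2.0)

    def test_striatal_gates_use_rate_form(self):
        p = neuron_model("dSTR").gates["p"]
        a, b = p.alpha_fn(-50.0), p.beta_fn(-50.0)
        x = 0.4
        assert gate_derivative(x, -50.0, p) == pytest.approx(a * (1 - x) - b * x)

    def test_striatal_rate_singularities_are_removable(self):
        m = neuron_model("dSTR").gates["m"]
        # α_m has a removable singularity at v = −54 mV
        near = m.alpha_fn(-54.0 + 1e-9)
        assert m.alpha_fn(-54.0) == pytest.approx(near, rel=1e-6)
        assert m.alpha_fn(-54.0) == pytest.approx(0.32 * 4.0)


# ---------------------------------------------------------------------------
# Ionic currents
# ---------------------------------------------------------------------------


class TestIonicCurrents:
    def test_zero_driving_force(self):
        model = neuron_model("STN")
        cur = ionic_currents(60.0, {g: 0.5 for g in model.gates}, model)
        assert cur["Na"] == pytest.approx(0.0)  # E_Na = 60 mV

    def test_stn_sodium_arithmetic(self):
        model = neuron_model("STN")
        gates = {g: 0.0 for g in model.gates}
        gates["m"] = 1.0
        gates["h"] = 1.0
        cur = ionic_currents(0.0, gates, model)
        assert cur["Na"] == pytest.approx(49.0 * (0.0 - 60.0))  # −2940 μA/cm²

    def test_pallidal_ahp_calcium_saturation(self):
        model = neuron_model("GPe")
        gates = {"h": 0.5, "n": 0.5, "r": 0.5}
        v = -40.0
        full = ionic_currents(v, gates, model, ca=1e9)["AHP"]
        half = ionic_currents(v, gates, model, ca=10.0)["AHP"]
        assert full == pytest.approx(10.0 * (v + 80.0), rel=1e-6)
        assert half == pytest.approx(full / 2.0, rel=1e-6)

    def test_missing_gate_raises(self):
        model = neuron_model("STN")
        with pytest.raises(ConfigError):
            ionic_currents(-60.0, {"m": 0.5}, model)


# ---------------------------------------------------------------------------
# Alpha synapse
# ---------------------------------------------------------------------------


def _spec(delay=2.0, tau=SYN_TAU):
    return SynapseSpec("STN", "GPe", 1.0, "excitatory", delay, tau=tau)


class TestAlphaSynapse:
    def test_causality(self):
        spec = _spec(delay=2.0)
        assert synapse_drive([10.0], 11.9, spec) == 0.0

    def test_kernel_peak_is_inverse_e(self):
        # dS/dt = 0 at t − t_s − t_d = τ, where S = e⁻¹
        spec = _spec(delay=2.0)
        t_peak = 10.0 + 2.0 + SYN_TAU
        assert synapse_drive([10.0], t_peak, spec) == pytest.approx(math.exp(-1))

    def test_two_spike_superposition(self):
        # spikes τ apart, evaluated τ after the second: e⁻¹ + 2e⁻²
        spec = _spec(delay=0.0)
        t = 2.0 * SYN_TAU
        expected = math.exp(-1) + 2.0 * math.exp(-2)
        assert synapse_drive([0.0, SYN_TAU], t, spec) == pytest.approx(expected)

    def test_kernel_integral_equals_tau(self):
        val, _ = quad(lambda t: alpha_kernel(t, SYN_TAU), 0, 50 * SYN_TAU)
        assert val == pytest.approx(SYN_TAU, rel=1e-6)

    def test_state_space_form_matches_spike_sum(self):
        """The simulator's (s, z) linear system reproduces the explicit
        spike-sum kernel evaluation (independent solve_ivp oracle)."""
        spikes = [3.0, 7.5, 8.0, 20.0]
        spec = _spec(delay=1.5)

        def rhs(t, y):
            return [(y[1] - y[0]) / SYN_TAU, -y[1] / SYN_TAU]

        y = [0.0, 0.0]
        t_now = 0.0
        arrivals = sorted(s + spec.delay for s in spikes)
        for ta in arrivals:
            sol = solve_ivp(rhs, (t_now, ta), y, rtol=1e-10, atol=1e-12)
            y = sol.y[:, -1]
            y[1] += 1.0
            t_now = ta
        t_end = 30.0
        sol = solve_ivp(rhs, (t_now, t_end), y, rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(
            synapse_drive(spikes, t_end, spec), abs=1e-7)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            SynapseSpec("STN", "GPe", -1.0, "excitatory", 1.0)
        with pytest.raises(ConfigError):
            SynapseSpec("STN", "GPe", 1.0, "excitatory", -1.0)
        with pytest.raises(ConfigError):
            SynapseSpec("STN", "GPe", 1.0, "excitatory", 1.0, tau=0.0)


# ---------------------------------------------------------------------------
# Cortical (Izhikevich) neurons
# ---------------------------------------------------------------------------


class TestCortex:
    def test_excitatory_reset_increment(self):
        params = neuron_model("eCTX").izhikevich_params
        v, u, spiked = izhikevich_step(29.9, 0.0, -50.0, 0.1, params)
        assert spiked and v == -65.0
        assert u == pytest.approx(0.0 + 8.0, abs=0.2)

    def test_inhibitory_reset_increment(self):
        params = neuron_model("iCTX").izhikevich_params
        v, u, spiked = izhikevich_step(29.9, 1.0, -50.0, 0.1, params)
        assert spiked and v == -65.0
        assert u == pytest.approx(1.0 + 2.0, abs=0.2)

    def test_input_free_equilibrium(self):
        # 0.04v² + 4.8v + 140 = 0 → v = −70, u = 0.2v = −14
        v, u = izhikevich_equilibrium()
        assert v == pytest.approx(-70.0)
        assert u == pytest.approx(-14.0)
        dv = 0.04 * v * v + 5 * v + 140 - u
        assert dv == pytest.approx(0.0, abs=1e-9)

    def test_quiescent_below_threshold(self):
        params = neuron_model("eCTX").izhikevich_params
        v, u = izhikevich_equilibrium()
        for _ in range(100):
            v, u, spiked = izhikevich_step(v, u, 0.0, 0.5, params)
            assert not spiked
        assert v == pytest.approx(izhikevich_equilibrium()[0], abs=1e-6)


# ---------------------------------------------------------------------------
# Parkinsonism scaling
# ---------------------------------------------------------------------------


class TestParkinsonism:
    def test_healthy_limit(self):
        cfg = apply_parkinsonism(default_network(pd=1.0), 0.0)
        assert cfg.synapse("eCTX", "dSTR").g == pytest.approx(0.07)
        assert cfg.synapse("GPe", "GPe").g == pytest.approx(0.0125)
        from dbsloop.model import striatal_m_conductance
        assert striatal_m_conductance(0.0) == pytest.approx(2.6)

    @pytest.mark.parametrize("pd,gm,gcs,ggg", [
        (1.0, 1.7, 0.026, 0.05),
        (0.5, 2.15, 0.048, 0.03125),
    ])
    def test_linear_interpolation(self, pd, gm, gcs, ggg):
        from dbsloop.model import striatal_m_conductance
        cfg = apply_parkinsonism(default_network(), pd)
        assert striatal_m_conductance(pd) == pytest.approx(gm)
        assert cfg.synapse("eCTX", "dSTR").g == pytest.approx(gcs)
        assert cfg.synapse("GPe", "GPe").g == pytest.approx(ggg)

    def test_idempotent(self):
        cfg = default_network(pd=0.3)
        twice = apply_parkinsonism(apply_parkinsonism(cfg, 0.7), 0.7)
        once = apply_parkinsonism(cfg, 0.7)
        assert twice.synapse("eCTX", "dSTR").g == once.synapse("eCTX", "dSTR").g
        assert twice.pd == 0.7

    @pytest.mark.parametrize("bad", [-0.1, 1.5, 2.0])
    def test_range_validation(self, bad):
        with pytest.raises(ConfigError):
            apply_parkinsonism(default_network(), bad)
        with pytest.raises(ConfigError):
            NetworkConfig(pd=bad)

    def test_other_conductances_untouched(self):
        cfg = default_network(pd=0.0)
        g_before = cfg.synapse("GPe", "GPi").g
        assert apply_parkinsonism(cfg, 1.0).synapse("GPe", "GPi").g == g_before


# ---------------------------------------------------------------------------
# The integrator
# ---------------------------------------------------------------------------


class TestSimulate:
    def test_duration_validation_and_single_step(self):
        cfg = default_network(seed=0)
        with pytest.raises(ConfigError):
            simulate(cfg, 0.0)
        res = simulate(cfg, cfg.dt)
        assert res.time.shape == (2,)
        assert res.v_traces["STN"].shape == (cfg.n, 2)

    def test_kernel_matches_generic_reference(self):
        """The compiled kernel and the spec-table reference evaluate the
        same right-hand side to machine precision on an evolved state."""
        cfg = default_network(pd=0.4, seed=5)
        cfg.noise_sigma = {}
        res = simulate(cfg, 80.0)
        y = res.final_state.y
        dy_ref = reference_rhs(y, cfg, istim=1.7)
        pk = _Packed(cfg)
        dy = np.zeros_like(y)
        isyn = np.empty(8 * cfg.n)
        noise = np.zeros(8 * cfg.n)
        _rhs(y, dy, isyn, cfg.n, pk.off, pk.osyn, pk.npairs, pk.pair_post,
             pk.pair_g, pk.pair_E, SYN_TAU, pk.gm_str, pk.iapp, 1.7, noise)
        np.testing.assert_allclose(dy, dy_ref, rtol=1e-10, atol=1e-10)

    def test_bit_identical_given_seed(self):
        cfg = default_network(pd=1.0, seed=7)
        r1 = simulate(cfg, 300.0)
        r2 = simulate(default_network(pd=1.0, seed=7), 300.0)
        for nm in r1.v_traces:
            np.testing.assert_array_equal(r1.v_traces[nm], r2.v_traces[nm])
        for nm in r1.spike_times:
            for a, b in zip(r1.spike_times[nm], r2.spike_times[nm]):
                np.testing.assert_array_equal(a, b)

    def test_gates_bounded(self, short_pd_run):
        from dbsloop.model import _layout, _VARS, NUCLEI
        y = short_pd_run.final_state.y
        cfg = short_pd_run.config_echo
        off, _, _ = _layout(cfg.n)
        for k, name in enumerate(NUCLEI):
            names = _VARS[name]
            for gi, gname in enumerate(names):
                if gname in ("v", "u", "CA"):
                    continue
                block = y[off[k] + gi * cfg.n: off[k] + (gi + 1) * cfg.n]
                assert np.all(block >= 0.0) and np.all(block <= 1.0)

    def test_dt_halving_consistency(self):
        """Integrator-order check: halving dt shifts no spike by more than
        0.5 ms over a 200 ms noise-free coupled run (spiking networks are
        timing-sensitive, so pointwise voltage comparison is not a valid
        convergence metric)."""
        def run(dt, rec_every):
            cfg = default_network(pd=1.0, seed=0, dt=dt)
            cfg.noise_sigma = {}
            return simulate(cfg, 200.0, rec_every=rec_every)

        ra, rb = run(0.025, 1), run(0.0125, 2)
        for nm in ("STN", "GPe", "GPi", "dSTR", "idSTR"):
            for a, b in zip(ra.spike_times[nm], rb.spike_times[nm]):
                assert abs(len(a) - len(b)) <= 1
                m = min(len(a), len(b))
                if m:
                    assert np.abs(a[:m] - b[:m]).max() < 0.5

    def test_zero_conductance_decouples(self):
        """With all synaptic conductances zero, each population's trajectory
        is unchanged by arbitrary modification of other populations."""
        def base(seed):
            cfg = default_network(pd=1.0, seed=seed)
            for s in cfg.synapses:
                s.g = 0.0
            return cfg

        c1 = base(3)
        c2 = base(3)
        c2.bias_currents["GPe"] = 40.0  # perturb another population hard
        r1, r2 = simulate(c1, 200.0), simulate(c2, 200.0)
        np.testing.assert_array_equal(r1.v_traces["STN"], r2.v_traces["STN"])
        np.testing.assert_array_equal(r1.v_traces["dSTR"], r2.v_traces["dSTR"])
        assert np.abs(r1.v_traces["GPe"] - r2.v_traces["GPe"]).max() > 1.0

    def test_stimulus_reaches_only_gpi(self):
        cfg = default_network(pd=1.0, seed=2)
        for s in cfg.synapses:
            s.g = 0.0
        steps = int(round(100.0 / cfg.dt))
        stim = np.full(steps, 50.0)
        r0 = simulate(default_network(pd=1.0, seed=2), 100.0)  # rebuild: same seed
        cfg0 = default_network(pd=1.0, seed=2)
        for s in cfg0.synapses:
            s.g = 0.0
        r0 = simulate(cfg0, 100.0)
        r1 = simulate(cfg, 100.0, stimulus=stim)
        assert np.abs(r1.v_traces["GPi"] - r0.v_traces["GPi"]).max() > 1.0
        np.testing.assert_array_equal(r1.v_traces["STN"], r0.v_traces["STN"])

    def test_short_stimulus_rejected(self):
        cfg = default_network(seed=0)
        with pytest.raises(ConfigError):
            simulate(cfg, 10.0, stimulus=np.zeros(3))

    def test_wiring_index_validation(self):
        with pytest.raises(ConfigError):
            NetworkConfig(synapses=[SynapseSpec(
                "STN", "GPe", 0.1, "excitatory", 1.0, pairs=((0, 99),))])

    def test_config_round_trip(self):
        cfg = default_network(pd=0.6, seed=9)
        clone = NetworkConfig.from_dict(cfg.to_dict())
        assert clone.pd == cfg.pd
        assert clone.synapse("GPe", "GPe").g == cfg.synapse("GPe", "GPe").g
        assert len(clone.synapses) == len(cfg.synapses)
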