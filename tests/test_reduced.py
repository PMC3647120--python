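import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shuntnet.compartmental import (
    NeuronParams,
    PathConfig,
    SynapticDrive,
    steady_state_three_compartment,
)
from shuntnet.reduced import (
    GEOMETRIES,
    DendriticConfig,
    decompose_multiplicative,
    point_neuron_steady_state,
    shunting_strength,
    simulate_reduced_neuron,
    somatic_response_excitatory,
    somatic_response_inhibitory,
    steady_state_soma,
    tau_soma,
)

ON = DendriticConfig("on_path")
OUT = DendriticConfig("out_of_path")
GLOBAL200 = DendriticConfig("global_shunting", 200)


class TestDendriticConfig:
    def test_two_site_forces_single_branch(self):
        with pytest.raises(ValueError):
            DendriticConfig("on_path", N=2)

    def test_zero_branches_rejected(self):
        with pytest.raises(ValueError):
            DendriticConfig("global_shunting", N=0)

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ValueError):
            DendriticConfig("ring", N=1)


class TestPointNeuron:
    def test_rest(self, params):
        assert point_neuron_steady_state(0.0, 0.0, params) == -70.0

    def test_excitatory_clamp(self, params):
        assert point_neuron_steady_state(1e9, 0.0, params) == pytest.approx(10.0, abs=1e-4)

    def test_direct_evaluation(self, params):
        # g_E = g = 30 nS splits the E driving force in half
        assert point_neuron_steady_state(30.0, 0.0, params, g_leak=30.0) == pytest.approx(-30.0)


class TestResponseFunctions:
    @pytest.mark.parametrize("geometry,N", [(g, 200 if g not in ("on_path", "out_of_path") else 1) for g in GEOMETRIES])
    def test_zero_input_gives_zero(self, params, geometry, N):
        cfg = DendriticConfig(geometry, N)
        assert somatic_response_excitatory(0.0, params, cfg) == 0.0
        assert somatic_response_inhibitory(0.0, params, cfg) == 0.0

    @pytest.mark.parametrize("geometry,N", [(g, 200 if g not in ("on_path", "out_of_path") else 1) for g in GEOMETRIES])
    def test_monotone_and_bounded(self, params, geometry, N):
        cfg = DendriticConfig(geometry, N)
        g = np.linspace(0, 1e4, 400)
        fe = somatic_response_excitatory(g, params, cfg)
        fi = somatic_response_inhibitory(g, params, cfg)
        assert np.all(np.diff(fe) > 0)
        assert np.all(np.diff(fi) < 0)
        assert fe[-1] < params.E_E - params.E_L
        assert fi[-1] > params.E_I - params.E_L

    def test_small_input_approximately_linear(self, params):
        g = np.array([0.01, 0.02])
        fe = somatic_response_excitatory(g, params, ON)
        fi = somatic_response_inhibitory(g, params, ON)
        assert fe[1] == pytest.approx(2 * fe[0], rel=1e-3)
        assert fi[1] == pytest.approx(2 * fi[0], rel=1e-3)

    def test_on_path_excitatory_saturation_limit(self, params):
        p = params
        num = p.g_IS * p.g_EI * (p.E_E - p.E_L)
        den = (
            p.g_S * p.g_D + p.g_S * p.g_SI + p.g_S * p.g_EI
            + p.g_D * p.g_IS + p.g_EI * p.g_IS
        )
        assert somatic_response_excitatory(1e6, params, ON) == pytest.approx(
            num / den, rel=1e-3
        )

    def test_on_path_inhibitory_saturation_limit(self, params):
        p = params
        limit = p.g_IS * (p.E_I - p.E_L) / (p.g_S + p.g_IS)
        assert somatic_response_inhibitory(1e6, params, ON) == pytest.approx(limit, rel=1e-3)

    def test_global_inhibitory_plug_in(self, params):
        # N=200 branches, g_I = 10 nS
        expect = 10 * (params.E_I - params.E_L) / (params.g_S + 10 + 200 * params.g_ES)
        assert somatic_response_inhibitory(10.0, params, GLOBAL200) == pytest.approx(expect)

    def test_negative_conductance_rejected(self, params):
        with pytest.raises(ValueError):
            somatic_response_excitatory(-1.0, params, ON)


class TestShuntingStrength:
    def test_on_path_table_value(self, params):
        assert shunting_strength(params, ON) == pytest.approx((30 + 25) / (25 * 10))

    def test_out_of_path_table_value(self, params):
        assert shunting_strength(params, OUT) == pytest.approx((30 + 50) / (50 * -80))

    def test_global_table_value(self, params):
        assert shunting_strength(params, GLOBAL200) == pytest.approx(0.1)

    def test_out_much_smaller_than_on(self, params):
        k_on = shunting_strength(params, ON)
        k_out = shunting_strength(params, OUT)
        assert abs(k_out) / k_on < 0.1

    def test_paired_scales_with_branches(self, params):
        k1 = shunting_strength(params, DendriticConfig("paired_on_path", 1))
        k10 = shunting_strength(params, DendriticConfig("paired_on_path", 10))
        assert k10 > k1

    def test_degenerate_parameters_named(self):
        p = NeuronParams(g_SI=0.0)
        with pytest.raises(ZeroDivisionError, match="g_IS"):
            shunting_strength(p, ON)


class TestSteadyStateSoma:
    def test_rest(self, params):
        dec = steady_state_soma(0.0, 0.0, params, ON)
        assert dec.v_steady == pytest.approx(params.E_L)
        assert dec.f_exc == dec.f_inh == 0.0

    def test_additive_reduction_all_geometries(self, params):
        for geometry in GEOMETRIES:
            N = 1 if geometry in ("on_path", "out_of_path") else 5
            cfg = DendriticConfig(geometry, N)
            if geometry == "single_per_branch":
                gE, gI = np.full(3, 2.0), np.zeros(2)
            elif geometry in ("on_path", "out_of_path"):
                gE, gI = 2.0, 0.0
            else:
                gE, gI = np.full(N, 2.0), np.zeros(N) if geometry == "paired_on_path" else 0.0
            dec = steady_state_soma(gE, gI, params, cfg)
            assert dec.cross == 0.0, geometry
            assert dec.v_steady - params.E_L == pytest.approx(dec.f_exc), geometry

    def test_on_path_matches_full_model_within_1mV(self, params):
        for gE in np.linspace(0, 10, 6):
            for gI in np.linspace(0, 10, 6):
                full = steady_state_three_compartment(params, SynapticDrive(gE, gI)).v_S
                red = steady_state_soma(gE, gI, params, ON).v_steady
                assert abs(full - red) < 1.0

    def test_decomposition_identity(self, params):
        dec = steady_state_soma(3.0, 4.0, params, ON)
        assert dec.v_steady == pytest.approx(
            params.E_L + dec.f_exc + dec.f_inh + dec.kappa * dec.f_exc * dec.f_inh
        )

    def test_paired_branch_additivity(self, params):
        # N branches driven together equal the sum of per-branch contributions
        N = 4
        cfg = DendriticConfig("paired_on_path", N)
        gE = np.array([1.0, 2.0, 3.0, 4.0])
        gI = np.array([0.5, 1.0, 1.5, 2.0])
        dec = steady_state_soma(gE, gI, params, cfg)
        kappa = shunting_strength(params, cfg)
        total = 0.0
        for i in range(N):
            one = steady_state_soma(
                np.r_[gE[i], np.zeros(N - 1)], np.r_[gI[i], np.zeros(N - 1)], params, cfg
            )
            total += one.v_steady - params.E_L
        assert dec.v_steady - params.E_L == pytest.approx(total)
        assert dec.cross == pytest.approx(
            kappa
            * np.sum(
                [
                    steady_state_soma(np.r_[gE[i], np.zeros(N - 1)], np.zeros(N), params, cfg).f_exc
                    * steady_state_soma(np.zeros(N), np.r_[gI[i], np.zeros(N - 1)], params, cfg).f_inh
                    for i in range(N)
                ]
            )
        )

    def test_global_shunting_sums_inhibition(self, params):
        cfg = DendriticConfig("global_shunting", 3)
        gE = np.array([1.0, 2.0, 3.0])
        a = steady_state_soma(gE, np.array([2.0, 3.0]), params, cfg)
        b = steady_state_soma(gE, 5.0, params, cfg)
        assert a.v_steady == pytest.approx(b.v_steady)

    def test_length_mismatch_rejected(self, params):
        cfg = DendriticConfig("paired_on_path", 3)
        with pytest.raises(ValueError, match="length"):
            steady_state_soma(np.ones(2), np.ones(3), params, cfg)


class TestSimulateReducedNeuron:
    def test_constant_drive_converges_to_steady_state(self, params):
        t, v, spikes = simulate_reduced_neuron(params, ON, 2.0, 5.0, 200.0, 0.05)
        assert v[-1] == pytest.approx(steady_state_soma(2.0, 5.0, params, ON).v_steady, abs=1e-6)
        assert spikes.size == 0

    def test_step_response_half_rise(self, params):
        tau = tau_soma(params, ON)
        t, v, _ = simulate_reduced_neuron(params, ON, 2.0, 0.0, 100.0, 0.01)
        target = steady_state_soma(2.0, 0.0, params, ON).v_steady
        half = params.E_L + 0.5 * (target - params.E_L)
        t_half = t[np.argmax(v >= half)]
        assert t_half == pytest.approx(tau * np.log(2), abs=0.05)

    def test_paired_pulse_sublinear(self, params):
        # simultaneous E+I pulses deflect less than the sum of individual peaks
        n = 4000
        gE = np.zeros(n)
        gI = np.zeros(n)
        gE[1000:1500] = 5.0
        gI[1000:1500] = 10.0
        _, v_both, _ = simulate_reduced_neuron(params, ON, gE, gI, 200.0, 0.05)
        _, v_e, _ = simulate_reduced_neuron(params, ON, gE, np.zeros(n), 200.0, 0.05)
        _, v_i, _ = simulate_reduced_neuron(params, ON, np.zeros(n), gI, 200.0, 0.05)
        EL = params.E_L
        peak_both = np.max(np.abs(v_both - EL))
        assert peak_both < np.max(v_e - EL) + np.max(np.abs(v_i - EL))

    def test_threshold_and_reset(self, params):
        # strong constant excitation with a threshold produces periodic spikes
        t, v, spikes = simulate_reduced_neuron(
            params, ON, 50.0, 0.0, 300.0, 0.05,
            threshold=params.E_L + 3.0, reset=params.E_L,
        )
        assert spikes.size > 3
        assert np.max(v) <= params.E_L + 3.0 + 1e-9

    def test_bad_dt(self, params):
        with pytest.raises(ValueError):
            simulate_reduced_neuron(params, ON, 0.0, 0.0, 10.0, -0.1)


class TestTauSoma:
    def test_geometry_rules(self, params):
        p = params
        assert tau_soma(p, ON) == pytest.approx(p.C_S / (p.g_S + p.g_IS))
        assert tau_soma(p, DendriticConfig("paired_on_path", 10)) == pytest.approx(
            p.C_S / (p.g_S + 10 * p.g_IS)
        )
        assert tau_soma(p, GLOBAL200) == pytest.approx(p.C_S / p.g_S)


class TestDecomposition:
    def test_pure_excitation(self):
        f1, f2, rec = decompose_multiplicative(10.0, -10.0, 50.0, 0.0)
        assert f1 == 0.0
        assert rec == pytest.approx(10.0 / 50.0)

    def test_pure_inhibition(self):
        f1, f2, rec = decompose_multiplicative(0.0, -10.0, 50.0, 5.0)
        assert f2 == 0.0
        assert rec == pytest.approx(-10.0 * 5.0 / 55.0)

    def test_beta_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            decompose_multiplicative(1.0, 0.0, 50.0, 5.0)

    @given(
        h=st.floats(-1e3, 1e3),
        beta=st.floats(-100.0, 100.0).filter(lambda b: abs(b) > 1e-3),
        gamma=st.floats(0.1, 1e3),
        g_I=st.floats(0.0, 1e3),
    )
    @settings(max_examples=200, deadline=None)
    def test_identity_exact(self, h, beta, gamma, g_I):
        f1, f2, rec = decompose_multiplicative(h, beta, gamma, g_I)
        direct = (h + beta * g_I) / (gamma + g_I)
        assert abs(rec - direct) <= 1e-12 * max(1.0, abs(direct), abs(f1), abs(f2))
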