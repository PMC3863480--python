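"""Path-selection probability, gating sampling, propagation, decoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from columnhough import (
    AmbiguousDecodeError,
    GatingSample,
    NetworkConfig,
    StimulusPattern,
    build_network,
    decode,
    fixture_fig5,
    p_direct,
    propagate,
    sample_gating,
    set_binary_config,
    spiking_outputs,
)

SECTION6_BITS = np.array([[1, 1], [1, 0]], dtype=np.uint8)  # leading column delayed


def _net22(bits=None):
    net = build_network(2, 2)
    return net if bits is None else set_binary_config(net, bits)


class TestPDirect:
    def test_symmetric_weights_give_half_at_any_temperature(self):
        for T in (0.01, 0.5, 1.0, 10.0):
            assert p_direct(0.5, 0.5, T) == pytest.approx(0.5)

    def test_annealed_limit_saturates(self):
        assert p_direct(1.0, 0.0, 0.05) >= 1 - 1e-6
        assert p_direct(0.0, 1.0, 0.05) <= 1e-6

    def test_hand_evaluated_boltzmann_value(self):
        # independent evaluation of e^{w_d/T} / (e^{w_d/T} + e^{w_del/T})
        expected = math.exp(0.8 / 0.5) / (math.exp(0.8 / 0.5) + math.exp(0.2 / 0.5))
        assert p_direct(0.8, 0.2, 0.5) == pytest.approx(expected, abs=1e-12)
        assert p_direct(0.8, 0.2, 0.5) == pytest.approx(0.7685, abs=5e-5)

    @given(
        w=st.floats(0, 1),
        T=st.floats(0.01, 10),
    )
    @settings(derandomize=True, max_examples=80)
    def test_normalization_is_exact(self, w, T):
        p = p_direct(w, 1 - w, T)
        q = p_direct(1 - w, w, T)
        assert 0 <= p <= 1
        assert p + q == pytest.approx(1.0, abs=1e-12)

    @given(T=st.floats(0.02, 5), data=st.data())
    @settings(derandomize=True, max_examples=60)
    def test_strictly_increasing_in_direct_weight(self, T, data):
        a = data.draw(st.floats(0, 0.999))
        b = data.draw(st.floats(a + 1e-3, 1.0))
        assert p_direct(b, 1 - b, T) > p_direct(a, 1 - a, T)

    def test_step_limit_at_zero_temperature(self):
        # as T -> 0 the probability approaches the indicator of the larger weight
        assert p_direct(0.6, 0.4, 1e-4) == pytest.approx(1.0, abs=1e-12)
        assert p_direct(0.4, 0.6, 1e-4) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            p_direct(0.5, 0.5, 0.0)


class TestSampling:
    def test_fresh_net_samples_near_half_direct(self):
        net = build_network(4, 4)
        rng = np.random.default_rng(0)
        draws = 10_000
        frac = np.mean(
            [sample_gating(net, rng).choices[:, 1:].mean() for _ in range(draws)]
        )
        sigma = 0.5 / math.sqrt(draws * 12)
        assert abs(frac - 0.5) < 3 * sigma

    def test_binarized_net_samples_its_own_configuration(self):
        net = _net22(SECTION6_BITS)
        net.temperatures[:] = net.config.T_min
        rng = np.random.default_rng(1)
        mismatches = sum(
            not np.array_equal(sample_gating(net, rng).choices, SECTION6_BITS)
            for _ in range(10_000)
        )
        # P(flip) per trainable gate is expit(-1/0.05) ~ 2e-9
        assert mismatches == 0

    def test_same_seed_gives_identical_samples(self):
        a = sample_gating(build_network(5, 5), np.random.default_rng(42))
        b = sample_gating(build_network(5, 5), np.random.default_rng(42))
        assert np.array_equal(a.choices, b.choices)

    def test_input_layer_always_direct(self):
        net = build_network(6, 3)
        for _ in range(50):
            assert np.all(sample_gating(net).choices[:, 0] == 1)


class TestPropagation:
    def test_minimal_circuit_vertical_pattern_fires_output_zero(self, fig5):
        net = _net22(SECTION6_BITS)
        trace = propagate(net, GatingSample(SECTION6_BITS), fig5[0])
        assert {k for k, _ in trace.output_spikes} == {0}

    def test_minimal_circuit_diagonal_pattern_fires_output_one(self, fig5):
        net = _net22(SECTION6_BITS)
        trace = propagate(net, GatingSample(SECTION6_BITS), fig5[1])
        assert {k for k, _ in trace.output_spikes} == {1}
        assert decode(trace) == (1, 2)  # planar front two steps after first pulse

    def test_empty_pattern_is_silent(self):
        net = _net22(SECTION6_BITS)
        empty = StimulusPattern(width=2, duration=2, events=(), label=0.0)
        trace = propagate(net, GatingSample(SECTION6_BITS), empty)
        assert trace.output_spikes == ()
        assert trace.occupancy == {}
        assert decode(trace) is None

    def test_delay_path_adds_exactly_one_clock_step(self):
        # single column, two layers, threshold 0: the output-1 spike time
        # shifts by one step when the segment routes via the delay neuron
        net = build_network(1, 2)
        pattern = StimulusPattern(width=1, duration=1, events=((0, 0),), label=0.0)
        direct = propagate(
            net, GatingSample(np.array([[1, 1]], dtype=np.uint8)), pattern
        )
        delayed = propagate(
            net, GatingSample(np.array([[1, 0]], dtype=np.uint8)), pattern
        )
        t_direct = dict(direct.output_spikes)[1]
        t_delay = dict(delayed.output_spikes)[1]
        assert t_delay - t_direct == 1

    def test_width_mismatch_rejected(self, fig3):
        net = _net22(SECTION6_BITS)
        with pytest.raises(ValueError, match="width"):
            propagate(net, GatingSample(SECTION6_BITS), fig3[0])

    def test_propagation_deterministic_and_signals_bounded(self, fig3, analytic_net9):
        from columnhough import get_binary_matrix

        gating = GatingSample(get_binary_matrix(analytic_net9))
        t1 = propagate(analytic_net9, gating, fig3[4])
        t2 = propagate(analytic_net9, gating, fig3[4])
        assert t1.occupancy == t2.occupancy and t1.output_spikes == t2.output_spikes
        for cells in t1.occupancy.values():
            assert len({c for c, _ in cells}) <= 9

    def test_fast_path_agrees_with_full_trace(self, fig3, analytic_net9):
        from columnhough import get_binary_matrix

        gating = GatingSample(get_binary_matrix(analytic_net9))
        for pattern in fig3:
            fast = spiking_outputs(analytic_net9, gating, pattern)
            full = propagate(analytic_net9, gating, pattern).output_spikes
            assert tuple(fast) == full

    def test_wavefront_dissolves_off_target(self, fig3, analytic_net9):
        # under the analytic configuration no non-target output ever reaches
        # coincidence: exactly one spike per training pattern
        from columnhough import get_binary_matrix

        gating = GatingSample(get_binary_matrix(analytic_net9))
        for k, pattern in enumerate(fig3):
            spikes = propagate(analytic_net9, gating, pattern).output_spikes
            assert [s for s, _ in spikes] == [k]


class TestDecode:
    def test_place_and_relative_time(self):
        from columnhough.dynamics import PropagationTrace

        trace = PropagationTrace(
            occupancy={}, output_spikes=((3, 7),), first_input_time=2
        )
        assert decode(trace) == (3, 5)

    def test_multiple_outputs_is_ambiguous_not_resolved(self):
        from columnhough.dynamics import PropagationTrace

        trace = PropagationTrace(
            occupancy={}, output_spikes=((0, 1), (1, 2)), first_input_time=0
        )
        with pytest.raises(AmbiguousDecodeError):
            decode(trace)

    def test_analytic_nine_by_nine_decodes_every_class(self, fig3, analytic_net9):
        from columnhough import get_binary_matrix

        gating = GatingSample(get_binary_matrix(analytic_net9))
        for k, pattern in enumerate(fig3):
            place, rel = decode(propagate(analytic_net9, gating, pattern))
            assert place == k
            assert rel >= 0
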