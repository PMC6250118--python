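"""Plasticity rules: hand-evaluated updates, lazy decay, bound preservation."""

import math

import numpy as np
import pytest

from famsnn.dynamics import LayerParams, NeuronLayerState
from famsnn.plasticity import (ConnectionGroup, ConnectionKind, clamp,
                               lazy_decay, update_bcm, update_feedforward,
                               update_hidden_lateral, update_output_inhibition,
                               update_reciprocal)


def state_with(n, a, theta):
    params = LayerParams(N=n)
    s = NeuronLayerState.zeros(params)
    s.a[:] = a
    s.theta[:] = theta
    return s


def group(W, kind, lr=0.1, tau=10_000.0):
    return ConnectionGroup(W=np.asarray(W, dtype=float), kind=kind,
                           learning_rate=lr, tau_decay=tau)


class TestLazyDecay:
    def test_zero_elapsed_is_identity(self):
        g = group([[0.5]], ConnectionKind.FEEDFORWARD)
        lazy_decay(g, 0.0)
        assert g.W[0, 0] == 0.5

    def test_one_time_constant_divides_by_e(self):
        g = group([[0.8]], ConnectionKind.FEEDFORWARD)
        lazy_decay(g, 10_000.0)
        assert g.W[0, 0] == pytest.approx(0.8 / math.e)

    def test_decays_negative_weights_toward_zero(self):
        g = group([[0.0, -1.0], [-0.5, 0.0]], ConnectionKind.LATERAL_HIDDEN)
        lazy_decay(g, 10_000.0)
        assert g.W[0, 1] == pytest.approx(-1.0 / math.e)
        assert g.W[1, 0] == pytest.approx(-0.5 / math.e)

    def test_matches_dense_per_step_decay_on_random_schedule(self):
        """Event-driven decay tracks a dense per-ms decay within 0.1%."""
        rng = np.random.default_rng(11)
        tau = 10_000.0
        lazy = group(rng.uniform(0, 1, (6, 4)), ConnectionKind.FEEDFORWARD,
                     tau=tau)
        dense_W = lazy.W.copy()
        spike_steps = np.sort(rng.choice(np.arange(1, 5001), 60, replace=False))
        cols = rng.integers(0, 4, size=60)
        t_prev = {}
        for t in range(1, 5001):
            dense_W *= 1.0 - 1.0 / tau
            hits = spike_steps == t
            for c in cols[hits]:
                lazy_decay(lazy, float(t), cols=np.array([c]))
        lazy_decay(lazy, 5000.0)
        np.testing.assert_allclose(lazy.W, dense_W, rtol=1e-3)

    def test_clock_must_be_monotone(self):
        g = group([[0.5]], ConnectionKind.FEEDFORWARD)
        lazy_decay(g, 100.0)
        with pytest.raises(ValueError, match="monotone"):
            lazy_decay(g, 50.0)

    def test_infinite_tau_disables_decay(self):
        g = group([[0.5]], ConnectionKind.FEEDFORWARD, tau=np.inf)
        lazy_decay(g, 1e7)
        assert g.W[0, 0] == 0.5


class TestFeedforwardRule:
    def test_hand_evaluated_increment(self):
        # w=0.20, a-theta=0.5, alpha=0.1, one post spike, no elapsed time
        g = group([[0.20]], ConnectionKind.FEEDFORWARD)
        pre = state_with(1, a=0.6, theta=0.1)
        update_feedforward(g, pre, np.array([1.0]), alpha=0.1, t_now=0.0)
        assert g.W[0, 0] == pytest.approx(0.25)

    def test_balanced_traces_change_nothing_but_decay(self):
        g = group([[0.3, 0.7]], ConnectionKind.FEEDFORWARD)
        pre = state_with(1, a=0.4, theta=0.4)
        update_feedforward(g, pre, np.array([1.0, 1.0]), 0.1, t_now=1000.0)
        np.testing.assert_allclose(g.W, np.array([[0.3, 0.7]]) * np.exp(-0.1))

    def test_only_spiking_columns_touched(self):
        g = group([[0.5, 0.5]], ConnectionKind.FEEDFORWARD)
        pre = state_with(1, a=1.0, theta=0.0)
        update_feedforward(g, pre, np.array([0.0, 1.0]), 0.1, t_now=0.0)
        assert g.W[0, 0] == 0.5 and g.W[0, 1] == pytest.approx(0.6)

    def test_no_spikes_is_a_no_op_even_for_decay(self):
        g = group([[0.5]], ConnectionKind.FEEDFORWARD)
        update_feedforward(g, state_with(1, 1.0, 0.0), np.array([0.0]),
                           0.1, t_now=5000.0)
        assert g.W[0, 0] == 0.5  # event-driven: decay waits for a post spike

    def test_wrong_kind_raises(self):
        g = group([[0.0, -1.0], [-1.0, 0.0]], ConnectionKind.LATERAL_HIDDEN)
        with pytest.raises(ValueError, match="feedforward"):
            update_feedforward(g, state_with(2, 0, 0), np.array([1.0, 0.0]),
                               0.1, 0.0)


class TestReciprocalRule:
    def test_hand_evaluated_increment(self):
        # w_kj=0, a_j-theta_j=0.4, w_jk=0.5, beta=0.3 -> 0.06
        rec = group(np.zeros((1, 1)), ConnectionKind.RECIPROCAL)
        fwd = group([[0.5]], ConnectionKind.FEEDFORWARD)
        hid = state_with(1, a=0.5, theta=0.1)
        update_reciprocal(rec, fwd, hid, np.array([1.0]), beta=0.3, t_now=0.0)
        assert rec.W[0, 0] == pytest.approx(0.06)

    def test_zero_forward_weight_blocks_growth(self):
        rec = group(np.zeros((1, 2)), ConnectionKind.RECIPROCAL)
        fwd = group([[0.0], [0.9]], ConnectionKind.FEEDFORWARD)
        hid = state_with(2, a=0.9, theta=0.0)
        update_reciprocal(rec, fwd, hid, np.array([1.0]), 0.3, 0.0)
        assert rec.W[0, 0] == 0.0 and rec.W[0, 1] > 0.0

    def test_shape_mismatch_raises(self):
        rec = group(np.zeros((2, 3)), ConnectionKind.RECIPROCAL)
        fwd = group(np.zeros((2, 3)), ConnectionKind.FEEDFORWARD)
        with pytest.raises(ValueError, match="shape"):
            update_reciprocal(rec, fwd, state_with(3, 0, 0),
                              np.array([1.0, 0.0]), 0.3, 0.0)


class TestOutputInhibitionRule:
    def test_hand_evaluated_increment(self):
        # w=-0.5, a_k-theta_k=0.3, gamma=0.1, spike of k' -> -0.53
        g = group([[0.0, -0.5], [-0.5, 0.0]], ConnectionKind.LATERAL_OUTPUT)
        out = state_with(2, a=[0.4, 0.0], theta=[0.1, 0.0])
        update_output_inhibition(g, out, np.array([0.0, 1.0]), gamma=0.1,
                                 t_now=0.0)
        assert g.W[0, 1] == pytest.approx(-0.53)
        assert g.W[1, 0] == -0.5  # column of the non-spiker untouched

    def test_diagonal_stays_zero(self):
        g = group([[0.0, -0.5], [-0.5, 0.0]], ConnectionKind.LATERAL_OUTPUT)
        out = state_with(2, a=[0.4, 0.4], theta=[0.0, 0.0])
        update_output_inhibition(g, out, np.array([1.0, 1.0]), 0.1, 0.0)
        assert g.W[0, 0] == 0.0 and g.W[1, 1] == 0.0

    def test_nonzero_diagonal_rejected_at_construction(self):
        with pytest.raises(ValueError, match="diagonal"):
            group([[-0.1, -0.5], [-0.5, 0.0]], ConnectionKind.LATERAL_OUTPUT)


class TestHiddenLateralRule:
    def test_hand_evaluated_cooperation(self):
        # w=-1.0, diffs 0.4 and 0.5, eta=0.15, spike of j -> -0.97
        g = group([[0.0, -1.0], [-1.0, 0.0]], ConnectionKind.LATERAL_HIDDEN)
        hid = state_with(2, a=[0.5, 0.6], theta=[0.1, 0.1])
        update_hidden_lateral(g, hid, np.array([1.0, 0.0]), eta=0.15, t_now=0.0)
        assert g.W[0, 1] == pytest.approx(-0.97)
        assert g.W[1, 0] == -1.0  # j' did not spike; its row untouched

    def test_discordant_pair_deepens_inhibition(self):
        g = group([[0.0, -0.5], [-0.5, 0.0]], ConnectionKind.LATERAL_HIDDEN)
        hid = state_with(2, a=[0.6, 0.0], theta=[0.1, 0.3])
        update_hidden_lateral(g, hid, np.array([1.0, 0.0]), 0.15, 0.0)
        assert g.W[0, 1] < -0.5

    def test_concordant_pairs_never_deepen(self):
        """Identical positive drives can only relax inhibition toward 0."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            W = np.zeros((3, 3))
            W[~np.eye(3, dtype=bool)] = rng.uniform(-1, 0, 6)
            g = group(W, ConnectionKind.LATERAL_HIDDEN)
            before = g.W.copy()
            diff = rng.uniform(0.01, 0.5)
            hid = state_with(3, a=diff + 0.2, theta=0.2)
            update_hidden_lateral(g, hid, np.array([1.0, 1.0, 1.0]),
                                  0.15, 0.0)
            assert np.all(g.W >= before - 1e-12)


class TestBCMRule:
    def test_hand_evaluated_increment(self):
        # w=0.1, a_i=0.2, a_j-theta_j=0.5, rate=0.1 -> 0.11
        g = group([[0.1]], ConnectionKind.FEEDFORWARD)
        pre = state_with(1, a=0.2, theta=0.0)
        post = state_with(1, a=0.6, theta=0.1)
        update_bcm(g, pre, post, np.array([1.0]), rate=0.1, t_now=0.0)
        assert g.W[0, 0] == pytest.approx(0.11)

    @pytest.mark.parametrize("a_i,post_a,post_th", [(0.0, 0.6, 0.1),
                                                    (0.2, 0.4, 0.4)])
    def test_silent_pre_or_balanced_post_changes_nothing(self, a_i, post_a,
                                                         post_th):
        g = group([[0.1]], ConnectionKind.FEEDFORWARD)
        update_bcm(g, state_with(1, a_i, 0.0), state_with(1, post_a, post_th),
                   np.array([1.0]), 0.1, 0.0)
        assert g.W[0, 0] == pytest.approx(0.1)


class TestClamping:
    def test_upper_and_lower_clamps(self):
        g = group([[0.9]], ConnectionKind.FEEDFORWARD)
        pre = state_with(1, a=2.0, theta=0.0)
        update_feedforward(g, pre, np.array([1.0]), 0.1, 0.0)
        assert g.W[0, 0] == 1.0
        gl = group([[0.0, -0.9], [-0.9, 0.0]], ConnectionKind.LATERAL_OUTPUT)
        out = state_with(2, a=[5.0, 0.0], theta=[0.0, 0.0])
        update_output_inhibition(gl, out, np.array([0.0, 1.0]), 1.0, 0.0)
        assert gl.W[0, 1] == -1.0

    def test_lateral_cooperation_saturates_at_zero(self):
        """Cooperation cannot turn inhibition into net excitation."""
        g = group([[0.0, -0.01], [-0.01, 0.0]], ConnectionKind.LATERAL_HIDDEN)
        hid = state_with(2, a=1.0, theta=0.0)
        update_hidden_lateral(g, hid, np.array([1.0, 1.0]), 5.0, 0.0)
        assert np.all(g.W <= 0.0)
        assert g.W[0, 1] == 0.0

    def test_clamp_function_projects_everything(self):
        g = group([[0.5]], ConnectionKind.FEEDFORWARD)
        g.W[0, 0] = 1.7
        clamp(g)
        assert g.W[0, 0] == 1.0


class TestBoundPreservationFuzz:
    def test_random_rule_applications_stay_in_bounds(self):
        """Fuzz all four rules with random traces/spikes; bounds must hold."""
        rng = np.random.default_rng(99)
        n_hid, n_out = 12, 4
        ff = group(rng.uniform(0, 1, (n_hid, n_out)),
                   ConnectionKind.FEEDFORWARD)
        rec = group(np.zeros((n_out, n_hid)), ConnectionKind.RECIPROCAL)
        lo = -np.ones((n_out, n_out))
        np.fill_diagonal(lo, 0)
        lat_out = group(lo, ConnectionKind.LATERAL_OUTPUT)
        lh = -np.ones((n_hid, n_hid))
        np.fill_diagonal(lh, 0)
        lat_hid = group(lh, ConnectionKind.LATERAL_HIDDEN)
        t = 0.0
        for _ in range(400):
            t += rng.uniform(0.5, 30.0)
            hid = state_with(n_hid, rng.uniform(0, 0.5, n_hid),
                             rng.uniform(0, 0.5, n_hid))
            out = state_with(n_out, rng.uniform(0, 0.5, n_out),
                             rng.uniform(0, 0.5, n_out))
            hs = (rng.random(n_hid) < 0.4).astype(float)
            os_ = (rng.random(n_out) < 0.4).astype(float)
            update_feedforward(ff, hid, os_, rng.uniform(0, 2), t)
            update_reciprocal(rec, ff, hid, os_, rng.uniform(0, 2), t)
            update_output_inhibition(lat_out, out, os_, rng.uniform(0, 2), t)
            update_hidden_lateral(lat_hid, hid, hs, rng.uniform(0, 5), t)
            for g, (low, high) in ((ff, (0, 1)), (rec, (0, 1)),
                                   (lat_out, (-1, 0)), (lat_hid, (-1, 0))):
                assert g.W.min() >= low and g.W.max() <= high

    def test_zero_learning_and_infinite_tau_freeze_weights(self):
        rng = np.random.default_rng(5)
        ff = group(rng.uniform(0, 1, (5, 3)), ConnectionKind.FEEDFORWARD,
                   tau=np.inf)
        before = ff.W.copy()
        t = 0.0
        for _ in range(100):
            t += 7.0
            pre = state_with(5, rng.uniform(0, 1, 5), rng.uniform(0, 1, 5))
            update_feedforward(ff, pre, (rng.random(3) < 0.5).astype(float),
                               alpha=0.0, t_now=t)
        np.testing.assert_array_equal(ff.W, before)


class TestRuleProperties:
    """Randomized invariants of the rule family (derandomized hypothesis)."""

    from hypothesis import given, settings, strategies as st

    @given(w0=st.floats(0.01, 1.0), elapsed=st.floats(0.0, 1e5),
           tau=st.floats(1.0, 1e6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_decay_is_contractive_and_sign_preserving(self, w0, elapsed, tau):
        g = group([[w0]], ConnectionKind.FEEDFORWARD, tau=tau)
        lazy_decay(g, elapsed)
        assert 0.0 <= g.W[0, 0] <= w0

    @given(a=st.floats(0, 1), theta=st.floats(0, 1), alpha=st.floats(0, 2),
           w0=st.floats(0, 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_feedforward_moves_with_sign_of_activity_difference(
            self, a, theta, alpha, w0):
        g = group([[w0]], ConnectionKind.FEEDFORWARD, tau=np.inf)
        update_feedforward(g, state_with(1, a, theta), np.array([1.0]),
                           alpha, t_now=0.0)
        w1 = g.W[0, 0]
        assert 0.0 <= w1 <= 1.0
        if a > theta:
            assert w1 >= w0
        elif a < theta:
            assert w1 <= w0
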