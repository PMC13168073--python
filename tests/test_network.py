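"""Architecture enumeration, connection tables, and the delayed update rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiasm.network import (
    C_L,
    C_R,
    M_L,
    M_R,
    S_L,
    S_R,
    ArchitectureSpec,
    Connection,
    ModelParams,
    NetworkState,
    build_connection_table,
    delay_cost_coefficients,
    enumerate_architectures,
    split_weight_matrices,
    step_states,
)

TANH1 = math.tanh(1.0)


class TestEnumeration:
    def test_eight_distinct_architectures(self):
        archs = enumerate_architectures()
        assert len(archs) == 8
        assert len(set(archs)) == 8
        assert len({a.code for a in archs}) == 8

    def test_factor_balance(self):
        archs = enumerate_architectures()
        assert sum(a.is_contralateral for a in archs) == 4
        assert sum(a.commissural_excitation for a in archs) == 4
        assert sum(a.local_feedback for a in archs) == 4

    def test_canonical_order_ipsilateral_first(self):
        archs = enumerate_architectures()
        assert archs[0] == ArchitectureSpec("ipsilateral", False, False)
        # all ipsilateral variants precede all contralateral ones
        assert [a.is_contralateral for a in archs] == [False] * 4 + [True] * 4

    def test_invalid_routing_rejected(self):
        with pytest.raises(ValueError, match="sensory_routing"):
            ArchitectureSpec("bilateral", False, False)


class TestConnectionTable:
    def test_bare_ipsilateral_has_four_links(self):
        arch = ArchitectureSpec("ipsilateral", False, False)
        table = build_connection_table(arch, ModelParams(i_inhib=0.0))
        assert len(table) == 4
        assert {(c.source, c.target) for c in table} == {
            (S_L, C_L), (S_R, C_R), (C_L, M_L), (C_R, M_R)
        }

    def test_full_contralateral_has_ten_links(self):
        arch = ArchitectureSpec("contralateral", True, True)
        mp = ModelParams(i_inhib=0.5, d_long=7)
        table = build_connection_table(arch, mp)
        assert len(table) == 12  # 2 S->C + 4 feedback + 2 commissural + 2 inhib + 2 C->M
        long_links = [c for c in table if c.delay == mp.d_long]
        assert {(c.source, c.target) for c in long_links} == {(C_L, C_R), (C_R, C_L)}
        assert all(c.weight == mp.w_cc for c in long_links)
        assert all(c.delay == mp.d_short for c in table if c not in long_links)
        # without inhibition the same architecture has 10 links
        table0 = build_connection_table(arch, mp.with_(i_inhib=0.0))
        assert len(table0) == 10
        # crossed sensory routing
        assert {(c.source, c.target) for c in table0[:2]} == {(S_L, C_R), (S_R, C_L)}

    def test_inhibitory_weight_product(self):
        arch = ArchitectureSpec("ipsilateral", False, False)
        mp = ModelParams(i_inhib=1.8, w_inhib_scale=1.0)
        inhib = [c for c in build_connection_table(arch, mp) if c.weight < 0]
        assert len(inhib) == 2
        assert all(c.weight == -1.8 for c in inhib)
        assert all(c.delay == mp.d_short for c in inhib)

    def test_rejects_invalid_delays(self):
        with pytest.raises(ValueError, match="d_long"):
            ModelParams(d_long=0)
        with pytest.raises(ValueError, match="delay"):
            Connection(S_L, C_L, 1.0, 0)
        with pytest.raises(ValueError, match="self-connection"):
            Connection(C_L, C_L, 1.0, 1)

    def test_split_matrices_match_table(self):
        arch = ArchitectureSpec("contralateral", True, True)
        mp = ModelParams(i_inhib=0.8, d_long=9)
        table = build_connection_table(arch, mp)
        w_short, w_long = split_weight_matrices(table, mp.d_short, mp.d_long)
        assert w_long[C_R, C_L] == mp.w_cc and w_long[C_L, C_R] == mp.w_cc
        assert np.count_nonzero(w_long) == 2
        # inhibition and commissural excitation both target C<-C but at
        # different delays, so they do not merge
        assert w_short[C_L, C_R] == mp.w_inh

    def test_delay_cost_coefficients(self):
        table = [Connection(0, 2, 1.0, 1), Connection(1, 2, -0.5, 2)]
        c = delay_cost_coefficients(table)
        assert c[0] == 1.0 and c[1] == 1.0 and np.all(c[2:] == 0)


class TestStepStates:
    def test_empty_table_zero_input_stays_zero(self):
        state = NetworkState(depth=3)
        step_states(state, [], np.zeros(6), np.zeros(6))
        assert np.all(state.current == 0.0)

    def test_single_link_closed_form(self):
        state = NetworkState(depth=3)
        ext = np.zeros(6)
        ext[S_L] = 0.5
        step_states(state, [], ext, np.zeros(6))
        assert state.current[S_L] == pytest.approx(math.tanh(0.5), abs=1e-15)
        # the downstream link reads the 0.5-activation one step later
        table = [Connection(S_L, C_L, 1.0, 1)]
        step_states(state, table, np.zeros(6), np.zeros(6))
        assert state.current[C_L] == pytest.approx(
            math.tanh(math.tanh(0.5)), abs=1e-15
        )

    def test_external_input_restricted_to_sensory_nodes(self):
        state = NetworkState(depth=3)
        bad = np.zeros(6)
        bad[M_L] = 1.0
        with pytest.raises(ValueError, match="sensory"):
            step_states(state, [], bad, np.zeros(6))

    @pytest.mark.parametrize("d", [1, 5, 20])
    def test_impulse_first_arrives_after_its_delay(self, d):
        state = NetworkState(depth=25)
        table = [Connection(S_L, C_L, 1.0, d)]
        ext = np.zeros(6)
        ext[S_L] = 1.0
        step_states(state, table, ext, np.zeros(6))  # impulse at t=0
        for t in range(1, d + 2):
            step_states(state, table, np.zeros(6), np.zeros(6))
            if t < d:
                assert state.current[C_L] == 0.0, f"leaked at t={t}"
        # the C_L activation written at step t=d reflects the t=0 impulse
        hist_at_d = state.history[d % state.depth]
        assert hist_at_d[C_L] == pytest.approx(math.tanh(TANH1), abs=1e-15)

    def test_three_step_hand_unrolled_recursion(self):
        """Constant drive on S_R propagates as tanh(1) -> tanh(tanh(1)) ->
        tanh(tanh(tanh(1))) with one-step lags through the bare chain."""
        arch = ArchitectureSpec("ipsilateral", False, False)
        mp = ModelParams(i_inhib=0.0)
        table = build_connection_table(arch, mp)
        state = NetworkState(depth=3)
        ext = np.zeros(6)
        ext[S_R] = 1.0
        seen = []
        for _ in range(3):
            step_states(state, table, ext, np.zeros(6), g=mp.g)
            seen.append(state.current.copy())
        t1, t2, t3 = TANH1, math.tanh(TANH1), math.tanh(math.tanh(TANH1))
        assert [s[S_R] for s in seen] == pytest.approx([t1, t1, t1], abs=1e-15)
        assert [s[C_R] for s in seen] == pytest.approx([0.0, t2, t2], abs=1e-15)
        assert [s[M_R] for s in seen] == pytest.approx([0.0, 0.0, t3], abs=1e-15)
        # nothing reaches the left pathway
        assert all(s[S_L] == s[C_L] == s[M_L] == 0.0 for s in seen)


class TestDynamicsProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_activities_stay_bounded_by_one(self, data):
        """tanh keeps every activity in [-1, 1] for arbitrary weights/inputs
        (strictly inside except where float tanh saturates)."""
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        n_links = int(rng.integers(1, 12))
        table = []
        for _ in range(n_links):
            s, t = rng.choice(6, size=2, replace=False)
            table.append(Connection(int(s), int(t),
                                    float(rng.normal(scale=5.0)),
                                    int(rng.integers(1, 6))))
        state = NetworkState(depth=8)
        for _ in range(10):
            ext = np.zeros(6)
            ext[:2] = rng.normal(scale=10.0, size=2)
            step_states(state, table, ext, rng.normal(scale=10.0, size=6))
            assert np.all(np.abs(state.current) <= 1.0)

    def test_zero_state_is_fixed_point_for_every_architecture(self):
        mp = ModelParams(i_inhib=1.2, d_long=4)
        for arch in enumerate_architectures():
            state = NetworkState(depth=6)
            table = build_connection_table(arch, mp)
            for _ in range(5):
                step_states(state, table, np.zeros(6), np.zeros(6))
            assert np.all(state.history == 0.0)
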