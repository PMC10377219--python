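"""Model core: cells, encoder, attention, decoder, head, counting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import stresslstm as sl
from stresslstm.model import CellState, _encode_batch

from conftest import perturbed_params, zeroed_params


class TestInit:
    def test_seeded_reproducibility(self):
        a = sl.init_params(T=9, n=4, m=1, seed=5)
        b = sl.init_params(T=9, n=4, m=1, seed=5)
        for (na, aa), (_, ab) in zip(a.named_arrays(), b.named_arrays()):
            np.testing.assert_array_equal(aa, ab, err_msg=na)

    def test_bias_initialization(self):
        p = sl.init_params(T=9, n=4, m=1, seed=5)
        for cell in (p.encoder.forward, p.encoder.backward, p.decoder):
            np.testing.assert_array_equal(cell.b_i, 0.0)
            np.testing.assert_array_equal(cell.b_o, 0.0)
            np.testing.assert_array_equal(cell.b_c, 0.0)
            np.testing.assert_array_equal(cell.b_f, 1.0)

    def test_shapes_consistent(self):
        p = sl.init_params(T=9, n=4, m=1, seed=0)
        assert p.encoder.forward.W_i.shape == (4, 9)  # n x (2n + m)
        assert p.encoder.forward.W_c.shape == (4, 5)  # n x (n + m)
        assert p.decoder.W_i.shape == (4, 12)  # input width = n
        assert p.encoder.V.shape == (4, 8)
        assert p.head_w.shape == (4,)

    @pytest.mark.parametrize("T,n,m", [(0, 3, 1), (4, 0, 1), (4, 3, 0)])
    def test_nonpositive_dimensions_raise(self, T, n, m):
        with pytest.raises(ValueError):
            sl.init_params(T=T, n=n, m=m, seed=0)


class TestCellStep:
    def test_zero_everything_is_a_fixed_point(self):
        p = zeroed_params(T=4, n=3)
        st0 = CellState(c=np.zeros(3), h=np.zeros(3))
        out = sl.cell_step([0.7], st0, p.encoder.forward)
        np.testing.assert_array_equal(out.c, 0.0)
        np.testing.assert_array_equal(out.h, 0.0)

    def test_hand_evaluated_zero_weight_step(self):
        """Zero weights, c_prev = 1: all gates 0.5, candidate 0, so
        c = 0.5 and h = 0.5 * tanh(0.5)."""
        p = zeroed_params(T=4, n=1)
        out = sl.cell_step([123.0], CellState(c=np.ones(1), h=np.zeros(1)), p.encoder.forward)
        assert out.c[0] == pytest.approx(0.5)
        assert out.h[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-10)

    @given(seed=st.integers(0, 500))
    def test_gates_bounded_hidden_in_open_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = perturbed_params(T=4, n=3, seed=seed).encoder.forward
        state = CellState(c=rng.normal(size=3), h=np.tanh(rng.normal(size=3)))
        out = sl.cell_step(rng.normal(size=1), state, p)
        assert np.all(np.abs(out.h) < 1.0)
        assert np.all(np.isfinite(out.c))

    def test_shape_mismatch_raises(self):
        p = perturbed_params(T=4, n=3).encoder.forward
        with pytest.raises(ValueError):
            sl.cell_step([0.1, 0.2], CellState(c=np.zeros(3), h=np.zeros(3)), p)
        with pytest.raises(ValueError):
            sl.cell_step([0.1], CellState(c=np.zeros(2), h=np.zeros(2)), p)

    def test_peephole_with_zero_cell_columns_reduces_to_standard_cell(self):
        """Zeroing the memory-cell columns of every gate matrix must give
        the plain (non-peephole) cell, step for step."""
        n, m, T = 3, 1, 6
        peep = perturbed_params(T=T, n=n, seed=3).encoder.forward
        reduced = dataclasses.replace(
            peep,
            W_i=np.concatenate([np.zeros((n, n)), peep.W_i[:, n:]], axis=1),
            W_f=np.concatenate([np.zeros((n, n)), peep.W_f[:, n:]], axis=1),
            W_o=np.concatenate([np.zeros((n, n)), peep.W_o[:, n:]], axis=1),
        )
        plain = dataclasses.replace(
            peep,
            W_i=peep.W_i[:, n:].copy(),
            W_f=peep.W_f[:, n:].copy(),
            W_o=peep.W_o[:, n:].copy(),
            peephole=False,
        )
        rng = np.random.default_rng(0)
        xs = rng.normal(size=(T, m))
        sa = sb = CellState(c=np.zeros(n), h=np.zeros(n))
        for t in range(T):
            sa = sl.cell_step(xs[t], sa, reduced)
            sb = sl.cell_step(xs[t], sb, plain)
            np.testing.assert_allclose(sa.c, sb.c, atol=1e-12, rtol=0)
            np.testing.assert_allclose(sa.h, sb.h, atol=1e-12, rtol=0)


class TestEncode:
    def test_zero_weights_give_zero_states(self):
        p = zeroed_params(T=5, n=2)
        H, cbar = sl.encode(np.linspace(-1, 1, 5), p.encoder)
        np.testing.assert_array_equal(H, 0.0)
        np.testing.assert_array_equal(cbar, 0.0)

    def test_direction_symmetry(self):
        """With identical directional cells, the backward trajectory on a
        sequence equals the forward trajectory on the reversed sequence,
        step-reversed."""
        enc = perturbed_params(T=6, n=3, seed=9).encoder
        enc_sym = dataclasses.replace(enc, backward=enc.forward)
        rng = np.random.default_rng(2)
        seq = rng.normal(size=(6, 1))
        _, _, cache_fwdseq = _encode_batch(enc_sym, seq[None, :, :])
        _, _, cache_revseq = _encode_batch(enc_sym, seq[::-1][None, :, :])
        # hidden state after processing step j is cache entry j's h output
        hf_rev = np.stack([c[7] * c[8] for c in cache_revseq[0]])  # o * tanh(c)
        hb_seq = np.stack([c[7] * c[8] for c in cache_fwdseq[1]])
        np.testing.assert_allclose(hf_rev, hb_seq, atol=1e-12, rtol=0)

    def test_deterministic_across_calls(self):
        enc = perturbed_params(T=4, n=3, seed=1).encoder
        seq = np.arange(4.0)
        H1, c1 = sl.encode(seq, enc)
        H2, c2 = sl.encode(seq, enc)
        np.testing.assert_array_equal(H1, H2)
        np.testing.assert_array_equal(c1, c2)

    def test_length_mismatch_raises(self):
        p = perturbed_params(T=4, n=3)
        with pytest.raises(ValueError):
            sl.forward(np.zeros(5), p)


class TestAttend:
    def test_zero_memory_gives_uniform_weights(self):
        H = np.random.default_rng(0).normal(size=(7, 3))
        res = sl.attend(np.zeros(3), H)
        np.testing.assert_allclose(res.weights, np.full(7, 1 / 7), atol=1e-12)

    def test_identical_states_give_uniform_weights_and_state_context(self):
        h = np.array([0.3, -0.2])
        H = np.tile(h, (5, 1))
        res = sl.attend(np.array([1.0, 2.0]), H)
        np.testing.assert_allclose(res.weights, 0.2, atol=1e-12)
        np.testing.assert_allclose(res.context, h, atol=1e-12)

    def test_two_state_softmax_arithmetic(self):
        res = sl.attend(np.array([1.0]), np.array([[1.0], [2.0]]))
        np.testing.assert_allclose(res.scores, [1.0, 2.0])
        np.testing.assert_allclose(res.weights, [0.26894142, 0.73105858], atol=1e-8)
        assert res.context[0] == pytest.approx(1.73105858, abs=1e-8)

    @given(seed=st.integers(0, 1000), scale=st.sampled_from([1.0, 50.0, 1000.0]))
    def test_weights_normalized_and_nonnegative(self, seed, scale):
        rng = np.random.default_rng(seed)
        T, n = rng.integers(1, 12), rng.integers(1, 8)
        c = rng.normal(size=n) * np.sqrt(scale)
        H = rng.normal(size=(T, n)) * np.sqrt(scale)
        res = sl.attend(c, H)
        assert np.all(res.weights >= 0.0)
        assert abs(res.weights.sum() - 1.0) <= 1e-12
        assert np.all(np.isfinite(res.weights))
        np.testing.assert_allclose(res.context, res.weights @ H, atol=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            sl.attend(np.zeros(3), np.zeros((4, 2)))


class TestDecode:
    def test_zero_weights_give_zero_output(self):
        p = zeroed_params(T=4, n=2)
        H = np.random.default_rng(1).normal(size=(4, 2))
        np.testing.assert_array_equal(sl.decode(H, p.decoder), 0.0)

    def test_first_step_context_is_uniform_average(self):
        """Zero initial memory means uniform attention at step one."""
        dec = perturbed_params(T=4, n=3, seed=6).decoder
        H = np.random.default_rng(3).normal(size=(4, 3))
        ctx = sl.attend(np.zeros(3), H).context
        np.testing.assert_allclose(ctx, H.mean(axis=0), atol=1e-12)
        manual = sl.cell_step(ctx, CellState(c=np.zeros(3), h=np.zeros(3)), dec)
        np.testing.assert_allclose(sl.decode(H, dec, steps=1), manual.h, atol=1e-12)

    def test_two_steps_match_manual_composition(self):
        dec = perturbed_params(T=5, n=3, seed=8).decoder
        H = np.random.default_rng(4).normal(size=(5, 3))
        state = CellState(c=np.zeros(3), h=np.zeros(3))
        for _ in range(2):
            ctx = sl.attend(state.c, H).context
            state = sl.cell_step(ctx, state, dec)
        np.testing.assert_allclose(sl.decode(H, dec, steps=2), state.h, atol=1e-12)

    def test_nonpositive_steps_raise(self):
        dec = perturbed_params(T=4, n=3).decoder
        with pytest.raises(ValueError):
            sl.decode(np.zeros((4, 3)), dec, steps=0)


class TestForward:
    def test_zero_head_weights_give_half(self):
        p = perturbed_params(T=5, n=3, seed=2)
        p = p.replace_arrays({"head.w": np.zeros(3), "head.b": np.zeros(())})
        assert sl.forward(np.arange(5.0), p) == pytest.approx(0.5)

    def test_deterministic_and_pure(self):
        p = perturbed_params(T=5, n=3, seed=2)
        seq = np.linspace(-2, 2, 5)
        before = {name: np.array(a, copy=True) for name, a in p.named_arrays()}
        v1 = sl.forward(seq, p)
        v2 = sl.forward(seq, p)
        assert v1 == v2
        for name, a in p.named_arrays():
            np.testing.assert_array_equal(a, before[name], err_msg=name)

    @given(seed=st.integers(0, 200))
    def test_probability_in_open_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        p = perturbed_params(T=6, n=4, seed=seed, scale=1.0)
        prob = sl.forward(rng.normal(size=6) * 3.0, p)
        assert 0.0 < prob < 1.0


class TestCountParameters:
    def test_exact_count_minimal_model(self):
        p = sl.init_params(T=9, n=1, m=1, seed=0)
        count = sl.count_parameters(p)
        # encoder 2*15 + combiner 3, decoder 15, head 2
        assert count.exact == 50
        assert count.nominal == 21  # 7 * (1 + 1 + 1)

    def test_quadratic_growth_in_hidden_size(self):
        small = sl.count_parameters(sl.init_params(T=9, n=4, m=1, seed=0)).exact
        big = sl.count_parameters(sl.init_params(T=9, n=8, m=1, seed=0)).exact
        assert big > 3 * small


class TestCheckpoint:
    def test_roundtrip_preserves_forward_bitwise(self, tmp_path):
        p = perturbed_params(T=5, n=3, seed=13)
        scaler = sl.FeatureScaler(
            mean=np.arange(5.0), sd=np.ones(5) * 2.0,
            feature_names=("a", "b", "c", "d", "e"),
        )
        path = tmp_path / "model.ckpt"
        sl.save_checkpoint(path, p, scaler, meta={"seed": 13})
        p2, scaler2, meta = sl.load_checkpoint(path)
        seq = np.linspace(-1, 1, 5)
        assert sl.forward(seq, p) == sl.forward(seq, p2)
        np.testing.assert_array_equal(scaler.mean, scaler2.mean)
        assert scaler2.feature_names == scaler.feature_names
        assert meta == {"seed": 13}
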