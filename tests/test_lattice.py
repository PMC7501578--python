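"""Lattice encoder: hand oracles, degeneracy, normalization, gradients."""

import numpy as np
import pytest

from lattice_ner.autodiff import Tensor, no_grad
from lattice_ner.crf import crf_nll, make_transitions
from lattice_ner.lattice import (LatticeParams, build_input_representation,
                                 char_step, encode, encode_bidirectional,
                                 word_cell)
from lattice_ner.lexicon import LatticeMatch, build_lexicon


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def reference_lstm(xs, params):
    """Plain LSTM with the same char parameters (NumPy, tape-free)."""
    H = params.hidden_dim
    h, c = np.zeros(H), np.zeros(H)
    out = []
    for x in xs:
        a = params.W_char.data @ np.concatenate([h, x]) + params.b_char.data
        f, o, i, g = (sigmoid(a[:H]), sigmoid(a[H:2 * H]),
                      sigmoid(a[2 * H:3 * H]), np.tanh(a[3 * H:]))
        c = f * c + i * g
        h = o * np.tanh(c)
        out.append(h)
    return out


@pytest.fixture
def toy_params():
    return LatticeParams(input_dim=3, hidden_dim=2, word_dim=3, seed=11)


class TestWordCell:
    def test_zero_params_closed_form(self, toy_params):
        """With all-zero parameters the gates are sigmoid(0)=0.5 and the
        candidate tanh(0)=0, so c_w = 0.5 * c_b."""
        p = LatticeParams(3, 2, 3, seed=0)
        p.W_word.data[:] = 0.0
        p.b_word.data[:] = 0.0
        c_b = Tensor(np.array([0.4, -0.8]))
        with no_grad():
            cw = word_cell(Tensor(np.zeros(3)), Tensor(np.zeros(2)), c_b, p)
        np.testing.assert_allclose(cw.data, 0.5 * c_b.data, atol=1e-12)

    def test_matches_hand_evaluation(self):
        """1-dim instance with printed weights vs. hand arithmetic."""
        p = LatticeParams(1, 1, 1, seed=0)
        p.W_word.data[:] = np.array([[1.0, 0.5], [-1.0, 2.0], [0.5, 0.5]])
        p.b_word.data[:] = np.array([0.1, -0.1, 0.2])
        x_w, h_b, c_b = 0.3, -0.2, 0.7
        f = sigmoid(1.0 * x_w + 0.5 * h_b + 0.1)
        i = sigmoid(-1.0 * x_w + 2.0 * h_b - 0.1)
        g = np.tanh(0.5 * x_w + 0.5 * h_b + 0.2)
        expect = f * c_b + i * g
        with no_grad():
            cw = word_cell(Tensor(np.array([x_w])), Tensor(np.array([h_b])),
                           Tensor(np.array([c_b])), p)
        assert cw.data[0] == pytest.approx(expect, abs=1e-12)

    def test_zero_memory_zero_candidate(self, toy_params):
        p = LatticeParams(3, 2, 3, seed=5)
        p.W_word.data[2 * 2:, :] = 0.0  # candidate rows
        p.b_word.data[2 * 2:] = 0.0
        with no_grad():
            cw = word_cell(Tensor(np.ones(3)), Tensor(np.ones(2)),
                           Tensor(np.zeros(2)), p)
        np.testing.assert_allclose(cw.data, 0.0, atol=1e-12)


class TestCharStep:
    def test_no_incoming_equals_standard_lstm(self, toy_params, rng):
        xs = [rng.normal(size=3) for _ in range(4)]
        with no_grad():
            hs = encode([Tensor(x) for x in xs], [], [], toy_params)
        ref = reference_lstm(xs, toy_params)
        for h, r in zip(hs, ref):
            np.testing.assert_allclose(h.data, r, atol=1e-12)

    def test_equal_logits_give_half_half(self, rng):
        """One word cell whose combine logit equals the char input-gate
        logit elementwise -> alpha = 0.5/0.5 and c = (c_w + candidate)/2."""
        p = LatticeParams(2, 2, 2, seed=3)
        x = Tensor(rng.normal(size=2))
        h0, c0 = Tensor(np.zeros(2)), Tensor(np.zeros(2))
        H = 2
        with no_grad():
            a = (p.W_char.data @ np.concatenate([h0.data, x.data])
                 + p.b_char.data)
            i_logit = a[2 * H:3 * H]
            cand = np.tanh(a[3 * H:])
            cw_val = rng.normal(size=2)
            # force the combine gate to produce exactly i_logit
            p.W_comb.data[:] = 0.0
            p.b_comb.data[:] = i_logit
            h, c, alphas = char_step(x, h0, c0, [Tensor(cw_val)], p)
        np.testing.assert_allclose(alphas, 0.5, atol=1e-12)
        np.testing.assert_allclose(c.data, 0.5 * cw_val + 0.5 * cand,
                                   atol=1e-12)

    def test_matches_hand_evaluation_1dim(self):
        """Full merge arithmetic on a 1-dim instance, by hand."""
        p = LatticeParams(1, 1, 1, seed=0)
        p.W_char.data[:] = np.array([[0.5, 1.0], [1.0, -0.5],
                                     [2.0, 0.5], [-1.0, 1.0]])
        p.b_char.data[:] = np.array([0.1, 0.2, 0.3, 0.4])
        p.W_comb.data[:] = np.array([[1.5, -2.0]])
        p.b_comb.data[:] = np.array([0.25])
        x, h_prev, c_prev, cw = 0.6, 0.2, -0.3, 0.5
        z = np.array([h_prev, x])
        o = sigmoid(1.0 * h_prev - 0.5 * x + 0.2)
        i_logit = 2.0 * h_prev + 0.5 * x + 0.3
        cand = np.tanh(-1.0 * h_prev + 1.0 * x + 0.4)
        comb_logit = 1.5 * x - 2.0 * cw + 0.25
        e = np.exp([comb_logit, i_logit])
        a_w, a_c = e[0] / e.sum(), e[1] / e.sum()
        c_expect = a_w * cw + a_c * cand
        h_expect = o * np.tanh(c_expect)
        with no_grad():
            h, c, alphas = char_step(Tensor(np.array([x])),
                                     Tensor(np.array([h_prev])),
                                     Tensor(np.array([c_prev])),
                                     [Tensor(np.array([cw]))], p)
        assert c.data[0] == pytest.approx(c_expect, abs=1e-12)
        assert h.data[0] == pytest.approx(h_expect, abs=1e-12)
        np.testing.assert_allclose(alphas[:, 0], [a_w, a_c], atol=1e-12)

    def test_alphas_normalized(self, rng):
        """alpha weights sum to 1 at every merge across random steps."""
        p = LatticeParams(3, 4, 3, seed=7)
        for _ in range(200):
            m = int(rng.integers(1, 4))
            with no_grad():
                _, _, alphas = char_step(
                    Tensor(rng.normal(size=3)), Tensor(rng.normal(size=4)),
                    Tensor(rng.normal(size=4)),
                    [Tensor(rng.normal(size=4)) for _ in range(m)], p)
            np.testing.assert_allclose(alphas.sum(axis=0), 1.0, atol=1e-6)


class TestEncode:
    def test_worked_example_merge_positions(self, mini_lexicon, rng):
        """On the gastric-mucosa sentence the final position merges the
        char candidate with the word cells of both terms ending there."""
        matches = mini_lexicon.match(list("胃体粘膜"))
        p = LatticeParams(3, 2, 3, seed=1)
        alphas = []
        with no_grad():
            encode([Tensor(rng.normal(size=3)) for _ in range(4)], matches,
                   [Tensor(rng.normal(size=3)) for _ in matches], p,
                   collect_alphas=alphas)
        # merges at position 2 (胃体) and position 4 (粘膜 + 胃体粘膜)
        assert [a.shape[0] for a in alphas] == [2, 3]

    def test_match_order_invariance(self, rng):
        """Hidden states are invariant to the listing order of matches
        sharing an endpoint."""
        lex = build_lexicon(["ab", "cb", "aacb"])
        chars = list("aacb")
        matches = lex.match(chars)
        p = LatticeParams(2, 3, 2, seed=2)
        xs = [Tensor(rng.normal(size=2)) for _ in chars]
        wv = {i: Tensor(rng.normal(size=2)) for i in range(len(matches))}
        with no_grad():
            hs1 = encode(xs, matches, [wv[i] for i in range(len(matches))], p)
            perm = list(reversed(range(len(matches))))
            hs2 = encode(xs, [matches[i] for i in perm],
                         [wv[i] for i in perm], p)
        for a, b in zip(hs1, hs2):
            np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_bidirectional_shape_and_single_char(self, rng):
        pf, pb = LatticeParams(2, 3, 2, seed=4), LatticeParams(2, 3, 2, seed=5)
        for n in (1, 2, 6):
            xs = [Tensor(rng.normal(size=2)) for _ in range(n)]
            with no_grad():
                hs = encode_bidirectional(xs, [], [], pf, pb)
            assert len(hs) == n and all(h.shape == (6,) for h in hs)

    def test_empty_lexicon_bidirectional_degeneracy(self, rng):
        """No matches -> both directions are plain LSTMs."""
        pf = LatticeParams(3, 4, 3, seed=8)
        pb = LatticeParams(3, 4, 3, seed=9)
        xs = [rng.normal(size=3) for _ in range(5)]
        with no_grad():
            hs = encode_bidirectional([Tensor(x) for x in xs], [], [], pf, pb)
        ref_f = reference_lstm(xs, pf)
        ref_b = reference_lstm(xs[::-1], pb)[::-1]
        for t in range(5):
            np.testing.assert_allclose(hs[t].data[:4], ref_f[t], atol=1e-12)
            np.testing.assert_allclose(hs[t].data[4:], ref_b[t], atol=1e-12)


class TestInputRepresentation:
    def test_dims_with_and_without_contextual(self, small_fixture, rng):
        table = small_fixture["char_table"]
        chars = small_fixture["corpus"][0].chars
        x = build_input_representation(chars, table)
        assert x.shape == (len(chars), table.dim)
        elmo = rng.normal(size=(len(chars), 6))
        x2 = build_input_representation(chars, table, elmo)
        assert x2.shape == (len(chars), table.dim + 6)

    def test_elmo_length_mismatch(self, small_fixture, rng):
        with pytest.raises(ValueError):
            build_input_representation(["a", "b"], small_fixture["char_table"],
                                       rng.normal(size=(3, 4)))

    def test_eval_deterministic_dropout_only_in_training(self, small_fixture,
                                                         rng):
        table = small_fixture["char_table"]
        chars = small_fixture["corpus"][0].chars
        a = build_input_representation(chars, table, dropout_rate=0.5)
        b = build_input_representation(chars, table, dropout_rate=0.5)
        np.testing.assert_array_equal(a, b)
        c = build_input_representation(chars, table, dropout_rate=0.5,
                                       rng=np.random.default_rng(0),
                                       training=True)
        assert (c == 0).any()  # dropout actually applied


class TestGradients:
    def test_full_loss_finite_difference(self):
        """Analytic gradients of the complete loss (lattice + combine gates
        + CRF) on a 2-char, 1-match toy instance, vs central differences."""
        p = LatticeParams(input_dim=2, hidden_dim=3, word_dim=2, seed=21)
        A = make_transitions(2, np.random.default_rng(1))
        W_emit = Tensor(np.random.default_rng(2).normal(size=(2, 3)),
                        requires_grad=True)
        rng = np.random.default_rng(3)
        xs_data = rng.normal(size=(2, 2))
        wv_data = rng.normal(size=2)
        match = LatticeMatch(0, 2, 0)
        A_t = Tensor(A, requires_grad=True)
        xs_t = Tensor(xs_data, requires_grad=True)
        wv_t = Tensor(wv_data, requires_grad=True)

        def loss():
            inputs = [xs_t[0], xs_t[1]]
            hs = encode(inputs, [match], [wv_t], p)
            from lattice_ner.autodiff import stack
            em = stack(hs, axis=0) @ Tensor(W_emit.data.T)
            return crf_nll(em, A_t, [0, 1])

        params = p.params() + [xs_t, wv_t, A_t]
        for q in params:
            q.grad = None
        loss().backward()
        eps = 1e-5  # near-optimal for float64 central differences
        for q in params:
            num = np.zeros_like(q.data)
            for i in np.ndindex(q.data.shape):
                old = q.data[i]
                q.data[i] = old + eps
                f1 = loss().item()
                q.data[i] = old - eps
                f2 = loss().item()
                q.data[i] = old
                num[i] = (f1 - f2) / (2 * eps)
            denom = np.maximum(
                np.maximum(np.abs(num), np.abs(q.grad)), 1e-6)
            rel = np.abs(num - q.grad) / denom
            assert rel.max() < 1e-4
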