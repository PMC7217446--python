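"""Context mechanisms: GRU recurrence, self-attention, concatenation.

The GRU is checked against an independent scalar recurrence written from the
gate equations; attention against a brute-force softmax(QK^T/scale)V oracle;
and all causal variants against the invariance that future reports cannot
influence earlier outputs.
"""

import numpy as np
import pytest

from caseseq.context import (
    GruContext,
    SelfAttentionContext,
    concat_case,
    run_gru,
    run_self_attention,
)


def scalar_gru_oracle(xs, wz, wr, wc, bz, br, bc):
    """Hand-rolled scalar gate recurrence: weights act on [h_prev, x_t]."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    h = 0.0
    out = []
    for x in xs:
        z = sig(wz[0] * h + wz[1] * x + bz)
        r = sig(wr[0] * h + wr[1] * x + br)
        c = np.tanh(wc[0] * (r * h) + wc[1] * x + bc)
        h = (1 - z) * h + z * c
        out.append(h)
    return np.array(out)


class TestGru:
    def test_all_zero_parameters_give_zero_outputs(self):
        gru = GruContext(input_dim=3, hidden_dim=4, seed=0)
        for d in gru.directions:
            for p in d.values():
                p.data[...] = 0.0
        out = run_gru(np.ones((5, 3)), gru)
        # z = 0.5 and c = tanh(0) = 0 at every step, so h stays 0
        assert np.allclose(out, 0.0)

    def test_matches_independent_scalar_recurrence(self):
        rng = np.random.default_rng(3)
        gru = GruContext(input_dim=1, hidden_dim=1, seed=0)
        params = gru.directions[0]
        wz, wr, wc = (rng.normal(size=2) for _ in range(3))
        bz, br, bc = rng.normal(size=3)
        params["W_z"].data = wz.reshape(2, 1)
        params["W_r"].data = wr.reshape(2, 1)
        params["W_c"].data = wc.reshape(2, 1)
        params["b_z"].data = np.array([bz])
        params["b_r"].data = np.array([br])
        params["b_c"].data = np.array([bc])
        xs = rng.normal(size=4)
        expected = scalar_gru_oracle(xs, wz, wr, wc, bz, br, bc)
        got = run_gru(xs.reshape(-1, 1), gru)[:, 0]
        assert np.allclose(got, expected, atol=1e-12)

    def test_unidirectional_ignores_future_reports(self):
        rng = np.random.default_rng(5)
        gru = GruContext(input_dim=6, hidden_dim=8, seed=1)
        e = rng.normal(size=(5, 6))
        base = run_gru(e, gru)
        perturbed = e.copy()
        perturbed[3:] = rng.normal(size=(2, 6))
        out = run_gru(perturbed, gru)
        assert np.array_equal(base[:3], out[:3])  # bitwise
        assert not np.allclose(base[3:], out[3:])

    def test_bidirectional_doubles_dim_and_sees_future(self):
        rng = np.random.default_rng(6)
        gru = GruContext(input_dim=4, hidden_dim=5, bidirectional=True, seed=2)
        e = rng.normal(size=(3, 4))
        out = run_gru(e, gru)
        assert out.shape == (3, 10)
        perturbed = e.copy()
        perturbed[2] += 1.0
        assert not np.allclose(run_gru(perturbed, gru)[0], out[0])


def attention_oracle(x, p, wq, wk, wv, bq, bk, bv, scale, causal):
    """Brute-force single-head attention from the printed operations."""

    def elu(v):
        return np.where(v > 0, v, np.exp(v) - 1)

    xp = x + p
    q, k, v = elu(xp @ wq + bq), elu(xp @ wk + bk), elu(xp @ wv + bv)
    scores = q @ k.T / scale
    n = x.shape[0]
    if causal:
        scores = np.where(np.tril(np.ones((n, n))) > 0, scores, -np.inf)
    w = np.exp(scores - scores.max(axis=1, keepdims=True))
    w = w / w.sum(axis=1, keepdims=True)
    return w @ v, w


class TestSelfAttention:
    def test_single_entry_weight_is_exactly_one(self):
        attn = SelfAttentionContext(dim=4, heads=2, seed=0)
        w = attn.attention_weights(np.random.default_rng(0).normal(size=(1, 4)))
        assert w.shape == (2, 1, 1)
        assert np.all(w == 1.0)

    @pytest.mark.parametrize("causal", [False, True])
    def test_matches_brute_force_oracle(self, causal):
        rng = np.random.default_rng(8)
        d, n = 2, 3
        attn = SelfAttentionContext(dim=d, heads=1, causal=causal, seed=0)
        x = rng.normal(size=(n, d))
        expected, expected_w = attention_oracle(
            x,
            attn.positional.data[:n],
            attn.W_q.data, attn.W_k.data, attn.W_v.data,
            attn.b_q.data, attn.b_k.data, attn.b_v.data,
            scale=np.sqrt(d / 1),
            causal=causal,
        )
        got = run_self_attention(x, attn)
        got_w = attn.attention_weights(x)
        assert np.allclose(got, expected, atol=1e-10)
        assert np.allclose(got_w[0], expected_w, atol=1e-10)

    def test_rows_are_stochastic(self):
        rng = np.random.default_rng(9)
        attn = SelfAttentionContext(dim=6, heads=3, causal=True, seed=1)
        w = attn.attention_weights(rng.normal(size=(5, 6)))
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        # masked upper triangle is exactly zero
        assert np.all(w[:, np.triu_indices(5, 1)[0], np.triu_indices(5, 1)[1]] == 0.0)

    def test_causal_mask_blocks_future_bitwise(self):
        rng = np.random.default_rng(10)
        attn = SelfAttentionContext(dim=8, heads=2, causal=True, seed=3)
        e = rng.normal(size=(6, 8))
        base = run_self_attention(e, attn)
        perturbed = e.copy()
        perturbed[4:] = rng.normal(size=(2, 8))
        out = run_self_attention(perturbed, attn)
        assert np.array_equal(base[:4], out[:4])
        assert not np.allclose(base[4:], out[4:])

    def test_unmasked_attention_sees_future(self):
        rng = np.random.default_rng(11)
        attn = SelfAttentionContext(dim=8, heads=2, causal=False, seed=3)
        e = rng.normal(size=(4, 8))
        perturbed = e.copy()
        perturbed[3] += 1.0
        assert not np.allclose(
            run_self_attention(e, attn)[0], run_self_attention(perturbed, attn)[0]
        )

    def test_permutation_equivariant_with_zero_positional(self):
        rng = np.random.default_rng(12)
        attn = SelfAttentionContext(dim=6, heads=2, causal=False, seed=4)
        attn.positional.data[...] = 0.0
        e = rng.normal(size=(5, 6))
        perm = rng.permutation(5)
        assert np.allclose(
            run_self_attention(e, attn)[perm], run_self_attention(e[perm], attn), atol=1e-10
        )

    def test_sequence_longer_than_positional_table_rejected(self):
        attn = SelfAttentionContext(dim=4, heads=1, max_seq_len=3, seed=0)
        with pytest.raises(ValueError, match="positional"):
            run_self_attention(np.zeros((4, 4)), attn)

    def test_scale_switch_changes_weights(self):
        rng = np.random.default_rng(13)
        e = rng.normal(size=(3, 4))
        a = SelfAttentionContext(dim=4, heads=1, attn_scale="sqrt_d", seed=5)
        b = SelfAttentionContext(dim=4, heads=1, attn_scale="d", seed=5)
        assert not np.allclose(a.attention_weights(e), b.attention_weights(e))


class TestConcatCase:
    DOCS = [list(range(10)), list(range(20)), list(range(30))]

    def test_all_mode_joins_everything_with_separators(self):
        out = concat_case(self.DOCS, target_index=0, mode="all", separator_id=99)
        assert len(out) == 60 + 2
        assert list(out).count(99) == 2

    def test_previous_mode_includes_target(self):
        out = concat_case(self.DOCS, target_index=1, mode="previous", separator_id=99)
        assert len(out) == 30 + 1

    def test_first_report_previous_mode_is_doc_alone(self):
        out = concat_case(self.DOCS, target_index=0, mode="previous", separator_id=99)
        assert list(out) == self.DOCS[0]

    def test_differing_labels_rejected(self):
        with pytest.raises(ValueError, match="labels differ"):
            concat_case(self.DOCS, 0, "all", labels=[1, 1, 2])

    def test_line_structured_merge_shifts_ranges(self):
        from caseseq.context import concat_case_docs
        from caseseq.preprocess import TokenizedDoc

        a = TokenizedDoc(np.array([1, 2, 3]), [(0, 2), (2, 3)])
        b = TokenizedDoc(np.array([4, 5]), [(0, 2)])
        merged = concat_case_docs([a, b], 0, "all", separator_id=9)
        assert list(merged.token_ids) == [1, 2, 3, 9, 4, 5]
        assert merged.line_ranges == [(0, 2), (2, 3), (3, 4), (4, 6)]
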