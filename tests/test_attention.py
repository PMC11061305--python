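"""Attention operators vs independent brute-force loop oracles.

The oracles below evaluate the attention formulas position by position with
explicit Python loops and plain numpy, sharing no code with the vectorized
implementations they check.
"""

import numpy as np
import pytest

import wmtseg.attention as wa
from wmtseg.attention import (
    AttentionProjections,
    AxialAttention2D,
    GateVector,
    RelativePositionTables,
    axial_attention_1d,
    axial_attention_2d,
    full_self_attention,
    weighted_axial_attention_1d,
)
from conftest import numeric_grad


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def _softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def brute_full(x, wq, wk, wv):
    """Double loop over all (h, w) keys for every (i, j) query."""
    _, H, W = x.shape
    q = np.einsum("oc,chw->ohw", wq, x)
    k = np.einsum("oc,chw->ohw", wk, x)
    v = np.einsum("oc,chw->ohw", wv, x)
    y = np.zeros_like(q)
    for i in range(H):
        for j in range(W):
            logits = np.array([q[:, i, j] @ k[:, h, w]
                               for h in range(H) for w in range(W)])
            a = _softmax(logits)
            y[:, i, j] = sum(
                a[h * W + w] * v[:, h, w] for h in range(H) for w in range(W))
    return y


def brute_axial_width(x, wq, wk, wv, rq, rk, rv, gates=(1.0, 1.0, 1.0, 1.0)):
    """Row loop: each (i, j) attends over w in its own row i.

    rq/rk/rv are pairwise (W, W, C) tables indexed (query pos, key pos).
    """
    cq, ck, cv1, cv2 = gates
    _, H, W = x.shape
    q = np.einsum("oc,chw->ohw", wq, x)
    k = np.einsum("oc,chw->ohw", wk, x)
    v = np.einsum("oc,chw->ohw", wv, x)
    y = np.zeros_like(q)
    for i in range(H):
        for j in range(W):
            logits = np.array([
                q[:, i, j] @ k[:, i, w]
                + cq * (q[:, i, j] @ rq[j, w])
                + ck * (k[:, i, w] @ rk[j, w])
                for w in range(W)
            ])
            a = _softmax(logits)
            y[:, i, j] = sum(a[w] * (cv1 * v[:, i, w] + cv2 * rv[j, w])
                             for w in range(W))
    return y


def brute_axial_height(x, wq, wk, wv, rq, rk, rv, gates=(1.0, 1.0, 1.0, 1.0)):
    xt = np.swapaxes(x, 1, 2)
    return np.swapaxes(brute_axial_width(xt, wq, wk, wv, rq, rk, rv, gates), 1, 2)


def _random_setup(rng, c_in, c_out, H, W):
    x = rng.normal(size=(c_in, H, W))
    proj = AttentionProjections(*(rng.normal(size=(c_out, c_in)) * 0.5
                                  for _ in range(3)))
    return x, proj


def _random_tables(rng, L, c_out):
    return RelativePositionTables(
        *(rng.normal(size=(L, L, c_out)) * 0.5 for _ in range(3)),
        relative=False)


# ---------------------------------------------------------------------------
# full self-attention
# ---------------------------------------------------------------------------


def test_full_attention_single_position_returns_value(rng):
    x, proj = _random_setup(rng, 3, 2, 1, 1)
    out = full_self_attention(x, proj).data
    v = proj.w_v.data @ x[:, 0, 0]
    assert np.allclose(out[:, 0, 0], v)


def test_full_attention_zero_query_is_uniform_mean(rng):
    x, proj = _random_setup(rng, 2, 3, 4, 5)
    proj.w_q.data[:] = 0.0
    out = full_self_attention(x, proj).data
    v = np.einsum("oc,chw->ohw", proj.w_v.data, x)
    mean_v = v.mean(axis=(1, 2))
    assert np.allclose(out, mean_v[:, None, None])


@pytest.mark.parametrize("seed", range(20))
def test_full_attention_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    c_in = int(rng.integers(1, 5))
    c_out = int(rng.integers(1, 5))
    H, W = int(rng.integers(1, 9)), int(rng.integers(1, 9))
    x, proj = _random_setup(rng, c_in, c_out, H, W)
    out = full_self_attention(x, proj).data
    expected = brute_full(x, proj.w_q.data, proj.w_k.data, proj.w_v.data)
    assert np.abs(out - expected).max() < 1e-5


def test_full_attention_shape_mismatch_names_both_shapes(rng):
    x, _ = _random_setup(rng, 3, 2, 2, 2)
    proj = AttentionProjections(*(np.zeros((2, 5)) for _ in range(3)))
    with pytest.raises(ValueError, match=r"(?s)3.*5"):
        full_self_attention(x, proj)


# ---------------------------------------------------------------------------
# axial attention (ungated)
# ---------------------------------------------------------------------------


def test_axial_single_key_returns_value_plus_positional(rng):
    x, proj = _random_setup(rng, 2, 3, 4, 1)
    pos = _random_tables(rng, 1, 3)
    out = axial_attention_1d(x, proj, pos, axis="width").data
    v = np.einsum("oc,chw->ohw", proj.w_v.data, x)
    assert np.allclose(out, v + pos.r_v.data[0, 0][:, None, None])


def test_axial_zero_tables_reduces_to_rowwise_full_attention(rng):
    x, proj = _random_setup(rng, 2, 3, 3, 4)
    pos = RelativePositionTables(*(np.zeros((4, 4, 3)) for _ in range(3)),
                                 relative=False)
    out = axial_attention_1d(x, proj, pos, axis="width").data
    for i in range(3):
        row = x[:, i:i + 1, :]
        expected = brute_full(row, proj.w_q.data, proj.w_k.data, proj.w_v.data)
        assert np.abs(out[:, i:i + 1, :] - expected).max() < 1e-5


@pytest.mark.parametrize("seed", range(20))
@pytest.mark.parametrize("axis", ["width", "height"])
def test_axial_matches_brute_force(seed, axis):
    rng = np.random.default_rng(100 + seed)
    c_in, c_out = int(rng.integers(1, 5)), int(rng.integers(1, 5))
    H, W = int(rng.integers(1, 9)), int(rng.integers(1, 9))
    L = W if axis == "width" else H
    x, proj = _random_setup(rng, c_in, c_out, H, W)
    pos = _random_tables(rng, L, c_out)
    out = axial_attention_1d(x, proj, pos, axis=axis).data
    oracle = brute_axial_width if axis == "width" else brute_axial_height
    expected = oracle(x, proj.w_q.data, proj.w_k.data, proj.w_v.data,
                      pos.r_q.data, pos.r_k.data, pos.r_v.data)
    assert np.abs(out - expected).max() < 1e-5


def test_axial_relative_tables_match_explicit_pairwise_expansion(rng):
    x, proj = _random_setup(rng, 2, 3, 4, 4)
    rel = RelativePositionTables.init(4, 3, rng, relative=True)
    out = axial_attention_1d(x, proj, rel, axis="width").data
    j = np.arange(4)
    idx = (j[None, :] - j[:, None]) + 3
    expected = brute_axial_width(
        x, proj.w_q.data, proj.w_k.data, proj.w_v.data,
        rel.r_q.data[idx], rel.r_k.data[idx], rel.r_v.data[idx])
    assert np.abs(out - expected).max() < 1e-5


def test_axial_length_mismatch_raises(rng):
    x, proj = _random_setup(rng, 2, 3, 4, 5)
    pos = _random_tables(rng, 4, 3)   # sized for the height axis, not width
    with pytest.raises(ValueError, match="axis length"):
        axial_attention_1d(x, proj, pos, axis="width")


# ---------------------------------------------------------------------------
# weighted (gated) axial attention
# ---------------------------------------------------------------------------


def test_unit_gates_recover_ungated_operator_exactly(rng):
    x, proj = _random_setup(rng, 3, 2, 4, 5)
    pos = _random_tables(rng, 5, 2)
    gated = weighted_axial_attention_1d(x, proj, pos, GateVector(), "width")
    ungated = axial_attention_1d(x, proj, pos, "width")
    assert np.array_equal(gated.data, ungated.data)


def test_zero_gates_strip_positional_terms(rng):
    x, proj = _random_setup(rng, 3, 2, 4, 5)
    pos = _random_tables(rng, 5, 2)
    zeros = RelativePositionTables(*(np.zeros((5, 5, 2)) for _ in range(3)),
                                   relative=False)
    out = weighted_axial_attention_1d(x, proj, pos, GateVector(0, 0, 1, 0),
                                      "width").data
    expected = axial_attention_1d(x, proj, zeros, "width").data
    assert np.abs(out - expected).max() < 1e-12


@pytest.mark.parametrize("seed", range(20))
def test_weighted_axial_matches_brute_force(seed):
    rng = np.random.default_rng(300 + seed)
    c_in, c_out = int(rng.integers(1, 5)), int(rng.integers(1, 5))
    H, W = int(rng.integers(1, 9)), int(rng.integers(1, 9))
    x, proj = _random_setup(rng, c_in, c_out, H, W)
    pos = _random_tables(rng, W, c_out)
    gates = (0.5, 2.0, 1.0, 0.25)
    out = weighted_axial_attention_1d(x, proj, pos, GateVector(*gates),
                                      "width").data
    expected = brute_axial_width(x, proj.w_q.data, proj.w_k.data,
                                 proj.w_v.data, pos.r_q.data, pos.r_k.data,
                                 pos.r_v.data, gates)
    assert np.abs(out - expected).max() < 1e-5


def test_all_four_gates_receive_gradient(rng):
    x, proj = _random_setup(rng, 2, 3, 4, 4)
    pos = _random_tables(rng, 4, 3)
    gates = GateVector(1.0, 1.0, 1.0, 1.0)
    out = weighted_axial_attention_1d(x, proj, pos, gates, "width")
    (out * out).sum().backward()
    for g in (gates.c_q, gates.c_k, gates.c_v1, gates.c_v2):
        assert g.grad is not None and abs(float(g.grad)) > 0


# ---------------------------------------------------------------------------
# 2-D composition
# ---------------------------------------------------------------------------


def _params_for(rng, c_in, c_out, L, zero_pos=False, unit_gates=True):
    proj = AttentionProjections(*(rng.normal(size=(c_out, c_in)) * 0.5
                                  for _ in range(3)))
    if zero_pos:
        pos = RelativePositionTables(*(np.zeros((L, L, c_out)) for _ in range(3)),
                                     relative=False)
    else:
        pos = _random_tables(rng, L, c_out)
    return proj, pos, GateVector() if unit_gates else None


def test_axial_2d_composes_height_then_width(rng):
    c_in, c_out, H, W = 2, 3, 4, 5
    x = rng.normal(size=(c_in, H, W))
    ph = _params_for(rng, c_in, c_out, H)
    pw = _params_for(rng, c_out, c_out, W)
    out = axial_attention_2d(x, ph, pw, gated=True).data
    mid = brute_axial_height(x, ph[0].w_q.data, ph[0].w_k.data, ph[0].w_v.data,
                             ph[1].r_q.data, ph[1].r_k.data, ph[1].r_v.data)
    expected = brute_axial_width(mid, pw[0].w_q.data, pw[0].w_k.data,
                                 pw[0].w_v.data, pw[1].r_q.data,
                                 pw[1].r_k.data, pw[1].r_v.data)
    assert np.abs(out - expected).max() < 1e-5


def test_axial_2d_zero_pos_equals_sequential_row_column_attention(rng):
    c = 3
    x = rng.normal(size=(2, 4, 4))
    ph = _params_for(rng, 2, c, 4, zero_pos=True)
    pw = _params_for(rng, c, c, 4, zero_pos=True)
    out = axial_attention_2d(x, ph, pw, gated=True).data
    # column-restricted full attention, then row-restricted full attention
    mid = np.zeros((c, 4, 4))
    for j in range(4):
        col = x[:, :, j:j + 1]
        mid[:, :, j:j + 1] = brute_full(col, ph[0].w_q.data, ph[0].w_k.data,
                                        ph[0].w_v.data)
    expected = np.zeros((c, 4, 4))
    for i in range(4):
        row = mid[:, i:i + 1, :]
        expected[:, i:i + 1, :] = brute_full(row, pw[0].w_q.data,
                                             pw[0].w_k.data, pw[0].w_v.data)
    assert np.abs(out - expected).max() < 1e-5


def test_axial_2d_attends_height_plus_width_keys(rng, monkeypatch):
    """On an 8x8 input the two passes see 8 + 8 = 16 keys per position."""
    x = rng.normal(size=(2, 8, 8))
    ph = _params_for(rng, 2, 3, 8)
    pw = _params_for(rng, 3, 3, 8)
    key_counts = []
    orig = wa.softmax

    def recording_softmax(t, axis=-1):
        key_counts.append(t.shape[axis])
        return orig(t, axis=axis)

    monkeypatch.setattr(wa, "softmax", recording_softmax)
    axial_attention_2d(x, ph, pw, gated=True)
    assert sum(key_counts) == 16


def test_width_attention_equivariant_under_row_permutation(rng):
    x, proj = _random_setup(rng, 2, 3, 5, 4)
    pos = _random_tables(rng, 4, 3)
    perm = np.random.default_rng(7).permutation(5)
    out = axial_attention_1d(x, proj, pos, "width").data
    out_perm = axial_attention_1d(x[:, perm, :], proj, pos, "width").data
    assert np.allclose(out_perm, out[:, perm, :])


def test_attention_softmax_weights_sum_to_one(rng, monkeypatch):
    x, proj = _random_setup(rng, 2, 3, 5, 6)
    pos = _random_tables(rng, 6, 3)
    sums = []
    orig = wa.softmax

    def recording_softmax(t, axis=-1):
        out = orig(t, axis=axis)
        sums.append(out.data.sum(axis=axis))
        return out

    monkeypatch.setattr(wa, "softmax", recording_softmax)
    weighted_axial_attention_1d(x, proj, pos, GateVector(0.3, 1.7, 1.0, 0.5),
                                "width")
    full_self_attention(x, proj)
    for s in sums:
        assert np.abs(s - 1.0).max() < 1e-6


def test_operators_pass_finite_difference_gradient_check(rng):
    c_in, c_out, H, W = 2, 2, 3, 3
    x = rng.normal(size=(c_in, H, W)) * 0.5
    proj = AttentionProjections(*(rng.normal(size=(c_out, c_in)) * 0.5
                                  for _ in range(3)))
    pos = _random_tables(rng, W, c_out)
    gates = GateVector(0.8, 1.2, 0.9, 1.1)

    def loss_of(xa):
        from wmtseg._tensor import Tensor
        out = weighted_axial_attention_1d(Tensor(xa), proj, pos, gates, "width")
        return float((out * out).sum().data)

    from wmtseg._tensor import Tensor
    t = Tensor(x, requires_grad=True)
    out = weighted_axial_attention_1d(t, proj, pos, gates, "width")
    (out * out).sum().backward()
    num = numeric_grad(loss_of, x, eps=1e-5)
    assert np.abs(t.grad - num).max() < 1e-3

    # and through a projection parameter
    wq = proj.w_q.data.copy()

    def loss_of_wq(w):
        proj2 = AttentionProjections(w, proj.w_k.data, proj.w_v.data)
        out = weighted_axial_attention_1d(x, proj2, pos, gates, "width")
        return float((out * out).sum().data)

    proj.w_q.grad = None
    out = weighted_axial_attention_1d(x, proj, pos, gates, "width")
    (out * out).sum().backward()
    assert np.abs(proj.w_q.grad - numeric_grad(loss_of_wq, wq, eps=1e-5)).max() < 1e-3


def test_layer_batch_and_heads_consistency(rng):
    layer = AxialAttention2D(2, 4, 6, 6, rng=np.random.default_rng(5),
                             gated=True, heads=1)
    x = rng.normal(size=(3, 2, 6, 6))
    batched = layer(x).data
    singles = np.stack([layer(x[i]).data for i in range(3)])
    assert np.allclose(batched, singles, atol=1e-12)

    two_head = AxialAttention2D(2, 4, 6, 6, rng=np.random.default_rng(6),
                                gated=True, heads=2)
    out = two_head(x)
    assert out.shape == (3, 4, 6, 6)
    assert len([n for n, _ in two_head.named_parameters() if "c_q" in n]) == 4
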