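"""Attention mechanisms against independent straight-line references.

The reference implementations below use explicit Python loops and plain
NumPy only — no code shared with the layer implementations — and serve as
the oracle for randomized equivalence checks.
"""

import math

import numpy as np
import pytest

from nucleiguide.attention import (
    FusionState,
    flatten_to_tokens,
    nga_forward,
    ngf_forward,
    ngf_layer,
    scaled_dot_attention,
    spatial_softmax,
    unflatten_tokens,
)
from nucleiguide.autodiff import Tensor

from _references import ref_nga, ref_ngf, ref_sdpa


# ---------------------------------------------------------------------------
# randomized equivalence (the oracle tests)


@pytest.mark.parametrize("trial", range(100))
def test_nga_matches_reference_on_random_instances(trial):
    rng = np.random.default_rng(trial)
    c = int(rng.integers(1, 5))
    h, w = int(rng.integers(1, 5)), int(rng.integers(1, 5))
    main = rng.standard_normal((c, h, w))
    guide = rng.standard_normal((c, h, w))
    w1 = rng.standard_normal((c, c))
    b1 = rng.standard_normal(c)
    out = nga_forward(main, guide, w1, b1).data
    assert np.allclose(out, ref_nga(main, guide, w1, b1), atol=1e-6)


@pytest.mark.parametrize("trial", range(100))
def test_scaled_dot_attention_matches_bruteforce(trial):
    rng = np.random.default_rng(1000 + trial)
    n, d, dv = (int(rng.integers(1, 5)) for _ in range(3))
    q = rng.standard_normal((n, d))
    k = rng.standard_normal((n, d))
    v = rng.standard_normal((n, dv))
    assert np.allclose(
        scaled_dot_attention(q, k, v).data, ref_sdpa(q, k, v), atol=1e-6
    )


@pytest.mark.parametrize("trial", range(100))
def test_ngf_layer_and_stack_match_reference(trial):
    rng = np.random.default_rng(2000 + trial)
    n, d = int(rng.integers(1, 5)), int(rng.integers(1, 5))
    L = int(rng.integers(1, 4))
    main = rng.standard_normal((n, d))
    guide = rng.standard_normal((n, d))
    wqs = [rng.standard_normal((d, d)) for _ in range(L)]
    wks = [rng.standard_normal((d, d)) for _ in range(L)]
    # single layer
    state = FusionState(v=Tensor(main), q_source=Tensor(guide), w_q=wqs, w_k=wks)
    stepped = ngf_layer(state)
    assert stepped.layer_index == 1
    assert np.allclose(
        stepped.v.data, ref_ngf(main, guide, wqs[:1], wks[:1]), atol=1e-6
    )
    # full stack
    out = ngf_forward(main, guide, wqs, wks).data
    assert np.allclose(out, ref_ngf(main, guide, wqs, wks), atol=1e-6)


# ---------------------------------------------------------------------------
# analytic identities


def test_uniform_attention_for_constant_features():
    att = spatial_softmax(np.full((3, 2, 2), 1.7), np.eye(3), np.zeros(3)).data
    assert np.allclose(att, 0.25)


def test_attention_normalises_per_channel(rng):
    feats = rng.standard_normal((4, 3, 5))
    att = spatial_softmax(feats, rng.standard_normal((4, 4))).data
    assert ((att > 0) & (att < 1)).all()
    assert np.allclose(att.sum(axis=(1, 2)), 1.0, atol=1e-6)


def test_hand_softmax_two_positions():
    # post-conv logits [0, ln 3] -> softmax [0.25, 0.75]
    feats = np.array([[[0.0, math.log(3.0)]]])
    att = spatial_softmax(feats, np.eye(1), np.zeros(1)).data
    assert np.allclose(att, [[[0.25, 0.75]]], atol=1e-9)


def test_attention_stable_at_extreme_logits():
    feats = np.array([[[50.0, -50.0], [0.0, 25.0]]])
    att = spatial_softmax(feats, np.eye(1)).data
    assert np.isfinite(att).all()
    assert np.allclose(att.sum(), 1.0)


def test_nga_zero_main_annihilates(rng):
    guide = rng.standard_normal((2, 3, 3))
    out = nga_forward(np.zeros((2, 3, 3)), guide, rng.standard_normal((2, 2)))
    assert np.allclose(out.data, 0.0)


def test_nga_constant_guide_scales_main(rng):
    h, w = 3, 4
    main = rng.standard_normal((2, h, w))
    out = nga_forward(main, np.full((2, h, w), 2.2), rng.standard_normal((2, 2)))
    assert np.allclose(out.data, main * (1.0 + 1.0 / (h * w)), atol=1e-9)


def test_singleton_attention_returns_value(rng):
    q = rng.standard_normal((1, 3))
    k = rng.standard_normal((1, 3))
    v = rng.standard_normal((1, 2))
    assert np.allclose(scaled_dot_attention(q, k, v).data, v)


def test_orthogonal_query_yields_column_mean(rng):
    k = rng.standard_normal((4, 2))
    v = rng.standard_normal((4, 3))
    q = np.zeros((1, 2))  # all logits 0 -> uniform weights
    assert np.allclose(
        scaled_dot_attention(q, k, v).data, v.mean(axis=0), atol=1e-9
    )


def test_single_token_fusion_doubles_per_layer(rng):
    t = rng.standard_normal((1, 3))
    g = rng.standard_normal((1, 3))
    wqs = [rng.standard_normal((3, 3)) for _ in range(3)]
    wks = [rng.standard_normal((3, 3)) for _ in range(3)]
    assert np.allclose(ngf_forward(t, g, wqs, wks).data, 8.0 * t, atol=1e-9)


def test_zero_projections_add_token_mean(rng):
    n, d = 4, 3
    v = rng.standard_normal((n, d))
    g = rng.standard_normal((n, d))
    out = ngf_forward(v, g, [np.zeros((d, d))], [np.zeros((d, d))]).data
    assert np.allclose(out, v + v.mean(axis=0), atol=1e-9)


# ---------------------------------------------------------------------------
# token plumbing and contracts


def test_flatten_is_row_major_and_invertible(rng):
    f = rng.standard_normal((3, 2, 2))
    toks = flatten_to_tokens(f).data
    assert toks.shape == (4, 3)
    assert np.allclose(toks[0], f[:, 0, 0])
    assert np.allclose(toks[1], f[:, 0, 1])
    assert np.allclose(toks[2], f[:, 1, 0])
    assert np.allclose(toks[3], f[:, 1, 1])
    assert np.allclose(unflatten_tokens(toks, 2, 2).data, f)


def test_single_position_token_is_channel_vector(rng):
    f = rng.standard_normal((3, 1, 1))
    toks = flatten_to_tokens(f).data
    assert toks.shape == (1, 3)
    assert np.allclose(toks[0], f[:, 0, 0])


def test_fusion_output_shape_matches_main(rng):
    main = rng.standard_normal((6, 4))
    guide = rng.standard_normal((6, 4))
    wq = [rng.standard_normal((4, 4))]
    wk = [rng.standard_normal((4, 4))]
    assert ngf_forward(main, guide, wq, wk).shape == main.shape


def test_token_permutation_equivariance(rng):
    # no positional encoding: permuting both sequences permutes the output
    n, d = 5, 3
    main = rng.standard_normal((n, d))
    guide = rng.standard_normal((n, d))
    wq = [rng.standard_normal((d, d)) for _ in range(2)]
    wk = [rng.standard_normal((d, d)) for _ in range(2)]
    perm = rng.permutation(n)
    out = ngf_forward(main, guide, wq, wk).data
    out_p = ngf_forward(main[perm], guide[perm], wq, wk).data
    assert np.allclose(out_p, out[perm], atol=1e-9)


def test_dimension_mismatches_signal():
    with pytest.raises(ValueError, match="d_k mismatch"):
        scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 4)))
    with pytest.raises(ValueError, match="shape mismatch"):
        nga_forward(np.zeros((2, 3, 3)), np.zeros((2, 4, 4)), np.eye(2))
    with pytest.raises(ValueError, match="preserve channels"):
        spatial_softmax(np.zeros((2, 3, 3)), np.zeros((2, 3)))
    with pytest.raises(ValueError, match="invalid fusion depth"):
        ngf_forward(np.zeros((2, 2)), np.zeros((2, 2)), [], [])


def test_gradient_reaches_projections(rng):
    main = rng.standard_normal((3, 2))
    guide = rng.standard_normal((3, 2))
    wq = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
    wk = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
    ngf_forward(main, guide, [wq], [wk]).sum().backward()
    assert wq.grad is not None and np.abs(wq.grad).sum() > 0
    assert wk.grad is not None and np.abs(wk.grad).sum() > 0
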