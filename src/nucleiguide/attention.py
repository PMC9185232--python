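"""Nuclei-guided attention primitives.

Two mechanisms let a nuclei-only guide branch steer the main image branch
of the grading network:

* **Nuclei-guided attention (NGA)** — at each backbone stage, guide-branch
  features pass through a channel-preserving 1x1 convolution and a softmax
  over spatial positions (independently per channel), producing an
  attention map ``A`` in (0,1) whose per-channel spatial mass sums to 1.
  The main-branch features are reweighted elementwise and added back:
  ``F_fuse = F_main + F_main * A``.

* **Nuclei-guided fusion (NGF)** — at the deepest stage both feature maps
  are flattened to token sequences (one token per spatial position).
  A stack of ``L`` cross-attention layers uses queries projected from the
  fixed guide tokens and keys projected from the running main sequence;
  values are the running main sequence itself, with a residual connection:
  ``V <- V + Att(Q_nuclei, K_main, V_main)``.

All softmaxes are computed with max-subtraction and are stable for
arbitrarily extreme logits.  Functions accept either batched ``(N,C,H,W)``
arrays/tensors or unbatched ``(C,H,W)`` ones.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .autodiff import Tensor, conv2d_1x1

__all__ = [
    "spatial_softmax",
    "nga_forward",
    "flatten_to_tokens",
    "unflatten_tokens",
    "scaled_dot_attention",
    "FusionState",
    "ngf_layer",
    "ngf_forward",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _batched(x: Tensor) -> tuple[Tensor, bool]:
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    if x.ndim != 4:
        raise ValueError(f"expected (C,H,W) or (N,C,H,W), got shape {x.shape}")
    return x, False


def spatial_softmax(
    features, weight, bias=None, axis: str = "spatial"
) -> Tensor:
    """1x1 convolution followed by a softmax -> attention map in (0,1).

    ``weight`` is (C, C) — the 1x1 convolution preserves the channel
    count.  With ``axis="spatial"`` (default) the softmax runs over the
    flattened H*W positions independently per channel, so each channel's
    attention mass sums to 1; ``axis="channel"`` normalises across
    channels per position instead.
    """
    features, squeeze = _batched(_as_tensor(features))
    weight = _as_tensor(weight)
    if weight.shape[0] != weight.shape[1]:
        raise ValueError(f"1x1 conv must preserve channels, got {weight.shape}")
    z = conv2d_1x1(features, weight, None if bias is None else _as_tensor(bias))
    n, c, h, w = z.shape
    if axis == "spatial":
        att = z.reshape(n, c, h * w).softmax(axis=-1).reshape(n, c, h, w)
    elif axis == "channel":
        att = z.softmax(axis=1)
    else:
        raise ValueError(f"unknown softmax axis {axis!r}")
    return att.reshape(c, h, w) if squeeze else att


def nga_forward(main, guide, weight, bias=None, axis: str = "spatial") -> Tensor:
    """One nuclei-guided attention gate.

    ``A = softmax(conv1x1(guide))``; ``F_guide = main * A``;
    returns ``main + F_guide`` with the input shape preserved.
    """
    main = _as_tensor(main)
    guide = _as_tensor(guide)
    if main.shape != guide.shape:
        raise ValueError(
            f"shape mismatch: main {main.shape} vs guide {guide.shape}"
        )
    main_b, squeeze = _batched(main)
    guide_b, _ = _batched(guide)
    att = spatial_softmax(guide_b, weight, bias, axis=axis)
    fused = main_b + main_b * att
    return fused.reshape(*main.shape) if squeeze else fused


def flatten_to_tokens(features) -> Tensor:
    """Flatten a feature map to a token sequence, one token per position.

    ``(N, C, H, W) -> (N, H*W, C)`` (or unbatched ``(C,H,W) -> (H*W, C)``)
    in row-major spatial order: token i is the channel vector at position
    ``(i // W, i % W)``.  Inverse: :func:`unflatten_tokens`.
    """
    x, squeeze = _batched(_as_tensor(features))
    n, c, h, w = x.shape
    tokens = x.transpose(0, 2, 3, 1).reshape(n, h * w, c)
    return tokens.reshape(h * w, c) if squeeze else tokens


def unflatten_tokens(tokens, height: int, width: int) -> Tensor:
    """Inverse of :func:`flatten_to_tokens`."""
    t = _as_tensor(tokens)
    if t.ndim == 2:
        return t.reshape(height, width, t.shape[-1]).transpose(2, 0, 1)
    n = t.shape[0]
    return t.reshape(n, height, width, t.shape[-1]).transpose(0, 3, 1, 2)


def scaled_dot_attention(q, k, v) -> Tensor:
    """Scaled dot-product attention ``softmax(Q K^T / sqrt(d_k)) V``.

    Shapes (optionally with a leading batch axis): ``q``: (Tq, d_k),
    ``k``: (Tk, d_k), ``v``: (Tk, d_v).  Each attention row sums to 1.
    """
    q, k, v = map(_as_tensor, (q, k, v))
    if q.shape[-1] != k.shape[-1]:
        raise ValueError(
            f"d_k mismatch: query dim {q.shape[-1]} != key dim {k.shape[-1]}"
        )
    if k.shape[-2] != v.shape[-2]:
        raise ValueError(
            f"key/value token counts differ: {k.shape[-2]} vs {v.shape[-2]}"
        )
    d_k = q.shape[-1]
    kt = k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)
    logits = (q @ kt) * (1.0 / math.sqrt(d_k))
    return logits.softmax(axis=-1) @ v


@dataclasses.dataclass
class FusionState:
    """Running state of the nuclei-guided fusion stack.

    ``v`` is the evolving main-branch value sequence; ``q_source`` holds
    the fixed guide tokens re-projected at every layer; ``w_q``/``w_k``
    are per-layer square (dim x dim) projections.
    """

    v: Tensor
    q_source: Tensor
    w_q: list[Tensor]
    w_k: list[Tensor]
    layer_index: int = 0

    def __post_init__(self):
        self.v = _as_tensor(self.v)
        self.q_source = _as_tensor(self.q_source)
        if self.v.shape != self.q_source.shape:
            raise ValueError(
                f"token sequences differ: main {self.v.shape} vs "
                f"guide {self.q_source.shape}"
            )


def ngf_layer(state: FusionState) -> FusionState:
    """One fusion layer: ``V <- V + Att(Q_guide W_q, V W_k, V)``."""
    l = state.layer_index
    if l >= len(state.w_q):
        raise ValueError(f"layer_index {l} exceeds fusion depth {len(state.w_q)}")
    w_q, w_k = _as_tensor(state.w_q[l]), _as_tensor(state.w_k[l])
    dim = state.v.shape[-1]
    for name, w in (("W_Q", w_q), ("W_K", w_k)):
        if w.shape != (dim, dim):
            raise ValueError(
                f"{name} projection shape {w.shape} incompatible with token dim {dim}"
            )
    q = state.q_source @ w_q
    k = state.v @ w_k
    new_v = state.v + scaled_dot_attention(q, k, state.v)
    return dataclasses.replace(state, v=new_v, layer_index=l + 1)


def ngf_forward(main_tokens, guide_tokens, w_q: list, w_k: list) -> Tensor:
    """Apply the full fusion stack; returns the fused sequence ``P``.

    Depth ``L = len(w_q)`` must be >= 1.
    """
    if len(w_q) < 1 or len(w_q) != len(w_k):
        raise ValueError(f"invalid fusion depth: {len(w_q)} W_Q vs {len(w_k)} W_K")
    state = FusionState(
        v=_as_tensor(main_tokens), q_source=_as_tensor(guide_tokens),
        w_q=list(w_q), w_k=list(w_k),
    )
    for _ in range(len(w_q)):
        state = ngf_layer(state)
    return state.v
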