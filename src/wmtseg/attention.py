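"""Self-attention, axial attention, and gated (weighted) axial attention.

Three operators on single-channel-stack feature maps, in increasing order of
structure:

* ``full_self_attention`` — every position attends to every other position:
  ``y_ij = sum_hw softmax(q_ij^T k_hw) v_hw``.
* ``axial_attention_1d`` — attention restricted to one row (or one column),
  with additive relative positional encodings ``r^Q, r^K, r^V``:
  ``y_ij = sum_w softmax(q_ij^T k_iw + q_ij^T r_iw^Q + k_iw^T r_iw^K)(v_iw + r_iw^V)``.
* ``weighted_axial_attention_1d`` — the same, with four learnable scalar
  gates ``C_Q, C_K, C_V1, C_V2`` multiplying the positional and value terms,
  so a network trained on a small dataset can down-weight positional
  encodings it has not learned reliably:
  ``y_ij = sum_w softmax(q_ij^T k_iw + C_Q q_ij^T r_iw^Q + C_K k_iw^T r_iw^K)
  (C_V1 v_iw + C_V2 r_iw^V)``.

``axial_attention_2d`` composes a height-axis pass followed by a width-axis
pass, reducing the per-position attended-key count from H*W to H+W.

The positional tables are per-pair *vectors* of the same channel dimension
as q/k/v (the logit terms are inner products); by default they are
parameterized by relative displacement (2L-1 learnable vectors expanded to
the L x L pairwise table), which makes the encodings translation-shared.

All operators accept an optional leading batch axis and are differentiable
through the package's autodiff core.
"""

from __future__ import annotations

import numpy as np

from ._tensor import (
    Module,
    Parameter,
    Tensor,
    astensor,
    softmax,
    take,
)

__all__ = [
    "AttentionProjections",
    "RelativePositionTables",
    "GateVector",
    "full_self_attention",
    "axial_attention_1d",
    "weighted_axial_attention_1d",
    "axial_attention_2d",
    "AxialAttention2D",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


class AttentionProjections(Module):
    """Learnable projections W_Q, W_K, W_V, each of shape (C_out, C_in)."""

    def __init__(self, w_q, w_k, w_v):
        self.w_q = w_q if isinstance(w_q, Parameter) else Parameter(w_q)
        self.w_k = w_k if isinstance(w_k, Parameter) else Parameter(w_k)
        self.w_v = w_v if isinstance(w_v, Parameter) else Parameter(w_v)
        shapes = {self.w_q.shape, self.w_k.shape, self.w_v.shape}
        if len(shapes) != 1 or self.w_q.ndim != 2:
            raise ValueError(
                f"W_Q/W_K/W_V must share one (C_out, C_in) shape, got "
                f"{self.w_q.shape}, {self.w_k.shape}, {self.w_v.shape}"
            )

    @property
    def c_in(self) -> int:
        return self.w_q.shape[1]

    @property
    def c_out(self) -> int:
        return self.w_q.shape[0]

    @classmethod
    def init(cls, c_in: int, c_out: int, rng: np.random.Generator) -> "AttentionProjections":
        sd = (2.0 / (c_in + c_out)) ** 0.5
        return cls(*(rng.normal(0.0, sd, size=(c_out, c_in)) for _ in range(3)))


class RelativePositionTables(Module):
    """Relative positional encodings r^Q, r^K, r^V for one axis of length L.

    ``relative=True`` stores one vector per displacement w-j (2L-1 rows,
    translation-shared); ``relative=False`` stores a free L x L table.
    ``pairwise()`` returns the expanded (L, L, C) tables in either case.
    """

    def __init__(self, r_q, r_k, r_v, relative: bool | None = None):
        self.r_q = r_q if isinstance(r_q, Parameter) else Parameter(r_q)
        self.r_k = r_k if isinstance(r_k, Parameter) else Parameter(r_k)
        self.r_v = r_v if isinstance(r_v, Parameter) else Parameter(r_v)
        shapes = {self.r_q.shape, self.r_k.shape, self.r_v.shape}
        if len(shapes) != 1:
            raise ValueError("r^Q/r^K/r^V must share one shape")
        if relative is None:
            relative = self.r_q.ndim == 2
        self.relative = relative
        if relative:
            if self.r_q.ndim != 2 or self.r_q.shape[0] % 2 == 0:
                raise ValueError(
                    f"relative tables need shape (2L-1, C), got {self.r_q.shape}"
                )
            self._L = (self.r_q.shape[0] + 1) // 2
        else:
            if self.r_q.ndim != 3 or self.r_q.shape[0] != self.r_q.shape[1]:
                raise ValueError(f"free tables need shape (L, L, C), got {self.r_q.shape}")
            self._L = self.r_q.shape[0]

    @property
    def axis_length(self) -> int:
        return self._L

    @property
    def channels(self) -> int:
        return self.r_q.shape[-1]

    def _expand(self, t: Tensor) -> Tensor:
        if not self.relative:
            return t
        L = self._L
        j = np.arange(L)
        idx = (j[None, :] - j[:, None]) + (L - 1)   # displacement w-j -> row
        return take(t, idx)

    def pairwise(self) -> tuple[Tensor, Tensor, Tensor]:
        return self._expand(self.r_q), self._expand(self.r_k), self._expand(self.r_v)

    @classmethod
    def init(cls, length: int, channels: int, rng: np.random.Generator,
             relative: bool = True) -> "RelativePositionTables":
        shape = (2 * length - 1, channels) if relative else (length, length, channels)
        sd = length ** -0.5
        return cls(*(rng.normal(0.0, sd, size=shape) for _ in range(3)),
                   relative=relative)


class GateVector(Module):
    """The four learnable scalar gates C_Q, C_K, C_V1, C_V2 (initialized to 1
    so training starts at ungated axial-attention behaviour)."""

    def __init__(self, c_q=1.0, c_k=1.0, c_v1=1.0, c_v2=1.0):
        self.c_q = c_q if isinstance(c_q, Parameter) else Parameter(float(c_q))
        self.c_k = c_k if isinstance(c_k, Parameter) else Parameter(float(c_k))
        self.c_v1 = c_v1 if isinstance(c_v1, Parameter) else Parameter(float(c_v1))
        self.c_v2 = c_v2 if isinstance(c_v2, Parameter) else Parameter(float(c_v2))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (float(self.c_q.data), float(self.c_k.data),
                float(self.c_v1.data), float(self.c_v2.data))


# ---------------------------------------------------------------------------
# functional operators
# ---------------------------------------------------------------------------


def _with_batch(x) -> tuple[Tensor, bool]:
    x = astensor(x)
    if x.ndim == 3:
        return x.reshape(1, *x.shape), True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"feature map must be (C,H,W) or (B,C,H,W), got shape {x.shape}")


def _check_channels(x: Tensor, proj: AttentionProjections) -> None:
    if x.shape[1] != proj.c_in:
        raise ValueError(
            f"channel mismatch: feature map has {x.shape[1]} channels "
            f"(shape {x.shape}) but projections expect C_in={proj.c_in} "
            f"(shape {proj.w_q.shape})"
        )


def _project(x: Tensor, w: Parameter) -> Tensor:
    """(B,C_in,H,W) x (C_out,C_in) -> (B,C_out,H,W)."""
    B, C, H, W = x.shape
    return (w @ x.reshape(B, C, H * W)).reshape(B, w.shape[0], H, W)


def full_self_attention(x, proj: AttentionProjections,
                        scale_logits: bool = False) -> Tensor:
    """Global self-attention over all H*W positions.

    Every output position is a convex combination (softmax weights) of the
    value vectors at all positions.  Logits are plain inner products
    ``q_ij^T k_hw``; no 1/sqrt(d) scaling unless ``scale_logits`` is set.
    """
    x, squeeze = _with_batch(x)
    _check_channels(x, proj)
    B, _, H, W = x.shape
    C = proj.c_out
    q = _project(x, proj.w_q).reshape(B, C, H * W)
    k = _project(x, proj.w_k).reshape(B, C, H * W)
    v = _project(x, proj.w_v).reshape(B, C, H * W)
    logits = q.swapaxes(1, 2) @ k                      # (B, N, N)
    if scale_logits:
        logits = logits * (C ** -0.5)
    attn = softmax(logits, axis=-1)
    out = (attn @ v.swapaxes(1, 2)).swapaxes(1, 2)     # (B, C, N)
    out = out.reshape(B, C, H, W)
    return out.reshape(C, H, W) if squeeze else out


def _axial_width(x: Tensor, proj: AttentionProjections,
                 pos: RelativePositionTables,
                 gates: GateVector | None,
                 scale_logits: bool) -> Tensor:
    """Width-axis attention on (B,C,H,W); each position attends along its row."""
    B, _, H, W = x.shape
    C = proj.c_out
    if pos.axis_length != W:
        raise ValueError(
            f"positional tables sized for axis length {pos.axis_length} "
            f"but the attended axis has length {W}"
        )
    if pos.channels != C:
        raise ValueError(
            f"positional tables have {pos.channels} channels but projections "
            f"produce C_out={C}"
        )
    q = _project(x, proj.w_q).moveaxis(1, 3)            # (B,H,W,C)
    k = _project(x, proj.w_k).moveaxis(1, 3)
    v = _project(x, proj.w_v).moveaxis(1, 3)
    rq, rk, rv = pos.pairwise()                         # (Wq,Wk,C) each

    # content term q_ij^T k_iw : (B,H,Wq,Wk)
    content = q @ k.swapaxes(-1, -2)
    # positional-query term q_ij^T r_jw^Q
    pos_q = (q.reshape(B, H, W, 1, C) @ rq.swapaxes(-1, -2)).reshape(B, H, W, W)
    # positional-key term k_iw^T r_jw^K  (broadcast over the query index j)
    pos_k = (k.reshape(B, H, 1, W, C) * rk).sum(axis=-1)

    if gates is None:
        logits = content + pos_q + pos_k
    else:
        logits = content + gates.c_q * pos_q + gates.c_k * pos_k
    if scale_logits:
        logits = logits * (C ** -0.5)
    attn = softmax(logits, axis=-1)                     # (B,H,Wq,Wk)

    if gates is None:
        payload_v, payload_r = v, rv
    else:
        payload_v, payload_r = gates.c_v1 * v, gates.c_v2 * rv
    out = attn @ payload_v                              # (B,H,Wq,C)
    out = out + (attn.reshape(B, H, W, 1, W) @ payload_r).reshape(B, H, W, C)
    return out.moveaxis(3, 1)                           # (B,C,H,W)


def axial_attention_1d(x, proj: AttentionProjections,
                       pos: RelativePositionTables, axis: str,
                       scale_logits: bool = False) -> Tensor:
    """Axial attention with relative positional encodings along one axis.

    ``axis='width'`` attends within rows; ``axis='height'`` is the exact
    transpose-symmetric analog (attends within columns).
    """
    return weighted_axial_attention_1d(x, proj, pos, None, axis,
                                       scale_logits=scale_logits)


def weighted_axial_attention_1d(x, proj: AttentionProjections,
                                pos: RelativePositionTables,
                                gates: GateVector | None, axis: str,
                                scale_logits: bool = False) -> Tensor:
    """Gated axial attention; ``gates=None`` or all-unit gates reduce it to
    the ungated operator."""
    if axis not in ("height", "width"):
        raise ValueError(f"axis must be 'height' or 'width', got {axis!r}")
    x, squeeze = _with_batch(x)
    _check_channels(x, proj)
    if axis == "height":
        out = _axial_width(x.swapaxes(2, 3), proj, pos, gates, scale_logits)
        out = out.swapaxes(2, 3)
    else:
        out = _axial_width(x, proj, pos, gates, scale_logits)
    return out.reshape(out.shape[1:]) if squeeze else out


def axial_attention_2d(x, params_h, params_w, gated: bool = True,
                       scale_logits: bool = False) -> Tensor:
    """Height-axis attention followed by width-axis attention.

    ``params_h``/``params_w`` are (proj, pos, gates) triples (gates ignored
    when ``gated=False``).  Per output position, the two passes attend to
    H + W keys in total rather than H*W.
    """
    proj_h, pos_h, gates_h = params_h
    proj_w, pos_w, gates_w = params_w
    y = weighted_axial_attention_1d(x, proj_h, pos_h,
                                    gates_h if gated else None, "height",
                                    scale_logits=scale_logits)
    return weighted_axial_attention_1d(y, proj_w, pos_w,
                                       gates_w if gated else None, "width",
                                       scale_logits=scale_logits)


# ---------------------------------------------------------------------------
# layer module
# ---------------------------------------------------------------------------


class AxialAttention2D(Module):
    """One 2-D axial attention layer: height pass then width pass.

    Each pass owns its projections and positional tables (per-layer, not
    shared between the passes).  ``heads > 1`` splits C_out evenly into
    independent heads whose positional tables live in the per-head channel
    dimension; head outputs are re-concatenated.
    """

    def __init__(self, c_in: int, c_out: int, height: int, width: int,
                 rng: np.random.Generator, gated: bool = True,
                 heads: int = 1, relative: bool = True,
                 scale_logits: bool = False):
        if c_out % heads:
            raise ValueError(f"C_out={c_out} not divisible by heads={heads}")
        self.c_in, self.c_out = c_in, c_out
        self.heads = heads
        self.gated = gated
        self.scale_logits = scale_logits
        ch = c_out // heads
        self.head_params: list[Module] = []
        for _ in range(heads):
            # height pass maps c_in -> ch; width pass then maps ch -> ch
            for length, cin_pass in ((height, c_in), (width, ch)):
                self.head_params.append(AttentionProjections.init(cin_pass, ch, rng))
                self.head_params.append(
                    RelativePositionTables.init(length, ch, rng, relative=relative))
                if gated:
                    self.head_params.append(GateVector())

    def _triples(self):
        step = 3 if self.gated else 2
        per_head = 2 * step
        for h in range(self.heads):
            base = h * per_head
            items = self.head_params[base:base + per_head]
            proj_h, pos_h = items[0], items[1]
            gates_h = items[2] if self.gated else None
            proj_w, pos_w = items[step], items[step + 1]
            gates_w = items[step + 2] if self.gated else None
            yield (proj_h, pos_h, gates_h), (proj_w, pos_w, gates_w)

    def forward(self, x) -> Tensor:
        outs = [
            axial_attention_2d(x, ph, pw, gated=self.gated,
                               scale_logits=self.scale_logits)
            for ph, pw in self._triples()
        ]
        from ._tensor import concat
        axis = 0 if astensor(x).ndim == 3 else 1
        return outs[0] if len(outs) == 1 else concat(outs, axis=axis)
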