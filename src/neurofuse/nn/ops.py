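"""Network building blocks for the hierarchical 3D branch.

All functions accept NumPy arrays or :class:`~neurofuse.nn.autodiff.Tensor`
and return Tensors, so the same code path serves numeric unit tests and
gradient-based training.  Feature maps are laid out (N, C, D, H, W).
"""

from __future__ import annotations

import warnings

import numpy as np

from .autodiff import Tensor, as_tensor, concat, stack

__all__ = [
    "conv3d",
    "dilated_conv3d",
    "spectral_normalize",
    "stat_normalize",
    "residual_fuse",
    "channel_attention",
    "spatial_attention",
    "graph_propagate",
    "global_avg_pool",
    "entropy_penalty",
    "softmax",
    "log_softmax",
]


def _ensure_batched(x: Tensor) -> tuple[Tensor, bool]:
    if x.ndim == 4:  # (C, D, H, W) -> add batch axis
        return x.reshape((1,) + x.shape), True
    if x.ndim != 5:
        raise ValueError("expected (C, D, H, W) or (N, C, D, H, W)")
    return x, False


def conv3d(
    x,
    w,
    b=None,
    stride: int = 1,
    dilation: int = 1,
    padding: int | str = "same",
) -> Tensor:
    """3D cross-correlation with zero padding.

    ``x`` is (N, Cin, D, H, W) (or unbatched (Cin, D, H, W)); ``w`` is
    (Cout, Cin, k, k, k).  ``padding='same'`` preserves spatial dims at
    stride 1.  Implemented as a gather (im2col) followed by a matmul, so
    gradients flow through the autodiff core.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    x, unbatch = _ensure_batched(x)
    N, Cin, D, H, W = x.shape
    Cout, Cin_w, k, k2, k3 = w.shape
    if not (k == k2 == k3):
        raise ValueError("kernel must be cubic")
    if Cin_w != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    eff_k = (k - 1) * dilation + 1
    pad = dilation * (k - 1) // 2 if padding == "same" else int(padding)
    if eff_k > min(D, H, W) + 2 * pad:
        raise ValueError("effective kernel larger than padded input")
    xp = x.pad(((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Dp, Hp, Wp = D + 2 * pad, H + 2 * pad, W + 2 * pad
    Do = (Dp - eff_k) // stride + 1
    Ho = (Hp - eff_k) // stride + 1
    Wo = (Wp - eff_k) // stride + 1

    taps = np.arange(k) * dilation
    od = np.arange(Do) * stride
    oh = np.arange(Ho) * stride
    ow = np.arange(Wo) * stride
    ci = np.arange(Cin).reshape(Cin, 1, 1, 1, 1, 1, 1)
    dpos = taps.reshape(1, k, 1, 1, 1, 1, 1) + od.reshape(1, 1, 1, 1, Do, 1, 1)
    hpos = taps.reshape(1, 1, k, 1, 1, 1, 1) + oh.reshape(1, 1, 1, 1, 1, Ho, 1)
    wpos = taps.reshape(1, 1, 1, k, 1, 1, 1) + ow.reshape(1, 1, 1, 1, 1, 1, Wo)
    idx = ((ci * Dp + dpos) * Hp + hpos) * Wp + wpos  # (Cin,k,k,k,Do,Ho,Wo)
    ck = Cin * k**3
    L = Do * Ho * Wo
    idx = idx.reshape(ck, L)
    offs = (np.arange(N) * Cin * Dp * Hp * Wp).reshape(N, 1, 1)
    cols = xp.take_flat(offs + idx[None])  # (N, CK, L)

    w2 = w.reshape(Cout, ck)
    out = w2 @ cols  # (N, Cout, L)
    if b is not None:
        out = out + as_tensor(b).reshape(1, Cout, 1)
    out = out.reshape(N, Cout, Do, Ho, Wo)
    return out.reshape(out.shape[1:]) if unbatch else out


def dilated_conv3d(x, w, d: int, b=None, stride: int = 1) -> Tensor:
    """Convolution with taps spaced ``d`` voxels apart (receptive field
    (k-1)d + 1 per axis)."""
    if d < 1:
        raise ValueError("dilation must be >= 1")
    return conv3d(x, w, b=b, stride=stride, dilation=d)


def spectral_normalize(w, n_iter: int | None = None,
                       u: np.ndarray | None = None):
    """Rescale a kernel by its largest singular value (power iteration).

    The kernel is reshaped to (out_channels, rest).  Returns ``(w_hat, u)``
    where ``u`` is the persistent left singular vector estimate; pass it back
    in on the next call to warm-start the iteration (5 steps then suffice; a
    cold start iterates until the estimate stabilises).  The singular value
    is treated as a constant in the backward pass.  An all-zero kernel is
    returned unchanged with a warning.
    """
    w = as_tensor(w)
    mat = w.data.reshape(w.shape[0], -1)
    if not np.any(mat):
        warnings.warn("all-zero kernel: spectral normalization skipped")
        return w, u
    warm = u is not None
    if n_iter is None:
        n_iter = 5 if warm else 200
    cur_u = u if warm else np.ones(mat.shape[0]) / np.sqrt(mat.shape[0])
    sigma_prev = None
    for _ in range(n_iter):
        v = mat.T @ cur_u
        v /= np.linalg.norm(v) + 1e-12
        cur_u = mat @ v
        sigma = np.linalg.norm(cur_u)
        cur_u = cur_u / (sigma + 1e-12)
        if sigma_prev is not None and abs(sigma - sigma_prev) < 1e-9 * sigma:
            break
        sigma_prev = sigma
    sigma = float(cur_u @ mat @ v)
    return w * (1.0 / sigma), cur_u


def stat_normalize(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Per-channel standardisation over the spatial voxels, then an affine
    rescale by learnable gamma and beta."""
    x = as_tensor(x)
    x, unbatch = _ensure_batched(x)
    C = x.shape[1]
    axes = (2, 3, 4)
    mu = x.mean(axis=axes, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    norm = xc / (var + eps).sqrt()
    g = as_tensor(gamma).reshape(1, C, 1, 1, 1)
    b = as_tensor(beta).reshape(1, C, 1, 1, 1)
    out = g * norm + b
    return out.reshape(out.shape[1:]) if unbatch else out


def residual_fuse(f_l, f_prev, phi_w, phi_b=None, stride: int = 1) -> Tensor:
    """Residual connection R = F_l + phi(F_prev) with phi a 1x1x1 conv for
    dimensional alignment (stride matches any downsampling in the block)."""
    aligned = conv3d(f_prev, phi_w, b=phi_b, stride=stride, padding=0)
    f_l = as_tensor(f_l)
    if aligned.shape != f_l.shape:
        raise ValueError(
            f"aligned shape {aligned.shape} does not match block output {f_l.shape}"
        )
    return f_l + aligned


def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def channel_attention(x, w, return_weights: bool = False):
    """Scale each channel by a softmax-normalised projection of the global
    average pooled descriptor: alpha = softmax(W g(F))."""
    x = as_tensor(x)
    x, unbatch = _ensure_batched(x)
    N, C = x.shape[:2]
    g = x.mean(axis=(2, 3, 4))  # (N, C)
    w = as_tensor(w)
    logits = g @ w.T  # (N, C)
    alpha = softmax(logits, axis=-1)
    out = x * alpha.reshape(N, C, 1, 1, 1)
    if unbatch:
        out = out.reshape(out.shape[1:])
    return (out, alpha) if return_weights else out


def spatial_attention(x, mask_logits, return_mask: bool = False):
    """Gate features with a 3D sigmoid mask: F'' = F' * sigmoid(logits)."""
    x = as_tensor(x)
    x, unbatch = _ensure_batched(x)
    m = as_tensor(mask_logits)
    if m.ndim == 3:
        m = m.reshape((1, 1) + m.shape)
    elif m.ndim == 4:
        m = m.reshape((m.shape[0], 1) + m.shape[1:])
    mask = m.sigmoid()
    out = x * mask
    if unbatch:
        out = out.reshape(out.shape[1:])
    return (out, mask) if return_mask else out


def graph_propagate(H, A, W, activation: str = "relu") -> Tensor:
    """One step of graph feature propagation: H' = sigma(A H W)."""
    H = as_tensor(H)
    A = as_tensor(A)
    W = as_tensor(W)
    z = A @ H @ W
    if activation == "relu":
        return z.relu()
    if activation in (None, "identity", "linear"):
        return z
    if activation == "tanh":
        return z.tanh()
    raise ValueError(f"unknown activation {activation!r}")


def global_avg_pool(x) -> Tensor:
    """Per-channel spatial mean: (N, C, D, H, W) -> (N, C)."""
    x = as_tensor(x)
    x, unbatch = _ensure_batched(x)
    out = x.mean(axis=(2, 3, 4))
    return out.reshape(out.shape[1:]) if unbatch else out


def entropy_penalty(z) -> Tensor:
    """Shannon entropy (nats) of softmax(z), averaged over the batch.

    Added to the training loss (weight lambda_ent) to encourage compact,
    low-entropy embeddings.
    """
    z = as_tensor(z)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    logp = log_softmax(z, axis=-1)
    p = logp.exp()
    ent = -(p * logp).sum(axis=-1)
    return ent.mean()
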