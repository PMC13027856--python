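"""Temporal (fMRI) branch primitives: linear projection of ROI series,
bidirectional LSTM encoding, attention pooling, functional-connectivity
feature packing, cross-interaction and cross-modality fusion.

Sequence tensors are laid out (N, T, d); functions accept arrays or Tensors.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, concat, stack
from .ops import softmax

__all__ = [
    "temporal_project",
    "init_lstm_params",
    "lstm_forward",
    "bilstm_encode",
    "attention_pool",
    "seq_transform",
    "fc_vectorize",
    "fc_unvectorize",
    "fc_project",
    "cross_interaction",
    "concat_features",
    "cross_modality_fuse",
]


def temporal_project(S, Wp, bp) -> Tensor:
    """Row-wise affine projection H = S Wp + bp of the T x R ROI matrix."""
    S = as_tensor(S)
    Wp = as_tensor(Wp)
    bp = as_tensor(bp)
    if S.shape[-1] != Wp.shape[0]:
        raise ValueError(f"width mismatch: S has R={S.shape[-1]}, Wp {Wp.shape}")
    return S @ Wp + bp.reshape((1,) * (S.ndim - 1) + (-1,))


def init_lstm_params(rng: np.random.Generator, d_in: int, d_h: int) -> dict:
    """Fan-in scaled uniform initialisation of one LSTM direction.

    Gate order along the 4*d_h axis is (input, forget, cell, output).
    """
    s_in = 1.0 / np.sqrt(d_in)
    s_h = 1.0 / np.sqrt(d_h)
    return {
        "W_ih": Tensor(rng.uniform(-s_in, s_in, (d_in, 4 * d_h)), requires_grad=True),
        "W_hh": Tensor(rng.uniform(-s_h, s_h, (d_h, 4 * d_h)), requires_grad=True),
        "b": Tensor(np.zeros(4 * d_h), requires_grad=True),
    }


def _lstm_step(x_t: Tensor, h: Tensor, c: Tensor, p: dict, d_h: int):
    z = x_t @ p["W_ih"] + h @ p["W_hh"] + p["b"].reshape(1, -1)
    i = z[:, 0 * d_h : 1 * d_h].sigmoid()
    f = z[:, 1 * d_h : 2 * d_h].sigmoid()
    g = z[:, 2 * d_h : 3 * d_h].tanh()
    o = z[:, 3 * d_h : 4 * d_h].sigmoid()
    c_new = f * c + i * g
    h_new = o * c_new.tanh()
    return h_new, c_new


def lstm_forward(H, params: dict, reverse: bool = False) -> Tensor:
    """Run one LSTM direction over (N, T, d_in); returns (N, T, d_h).

    Zero initial hidden and cell state.  ``reverse`` runs the recursion
    backwards in time and returns outputs re-aligned to forward time order.
    """
    H = as_tensor(H)
    if H.ndim == 2:  # (T, d) -> single sequence
        H = H.reshape((1,) + H.shape)
    N, T, _ = H.shape
    d_h = params["W_hh"].shape[0]
    h = Tensor(np.zeros((N, d_h)))
    c = Tensor(np.zeros((N, d_h)))
    order = range(T - 1, -1, -1) if reverse else range(T)
    outs: list[Tensor | None] = [None] * T
    for t in order:
        h, c = _lstm_step(H[:, t, :], h, c, params, d_h)
        outs[t] = h
    return stack(outs, axis=1)


def bilstm_encode(H, params_fwd: dict, params_bwd: dict) -> Tensor:
    """Bidirectional LSTM: independent forward and backward parameter sets,
    outputs concatenated per step to width 2*d_h."""
    fwd = lstm_forward(H, params_fwd, reverse=False)
    bwd = lstm_forward(H, params_bwd, reverse=True)
    return concat([fwd, bwd], axis=-1)


def attention_pool(h_seq, w, return_weights: bool = False):
    """Softmax attention over time: alpha_t = softmax_t(w . h_t),
    z_seq = sum_t alpha_t h_t."""
    h_seq = as_tensor(h_seq)
    if h_seq.ndim == 2:
        h_seq = h_seq.reshape((1,) + h_seq.shape)
    w = as_tensor(w).reshape(-1)
    scores = (h_seq * w.reshape(1, 1, -1)).sum(axis=-1)  # (N, T)
    alpha = softmax(scores, axis=-1)
    z = (h_seq * alpha.reshape(alpha.shape + (1,))).sum(axis=1)
    return (z, alpha) if return_weights else z


def seq_transform(z_seq, Wf, bf) -> Tensor:
    """f_seq = ReLU(Wf z_seq + bf)."""
    z_seq = as_tensor(z_seq)
    if z_seq.ndim == 1:
        z_seq = z_seq.reshape(1, -1)
    return (z_seq @ as_tensor(Wf).T + as_tensor(bf).reshape(1, -1)).relu()


def fc_vectorize(z_mat: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Pack a symmetric R x R matrix into its upper triangle (diagonal
    excluded), row-major; length R(R-1)/2."""
    z = np.asarray(z_mat, float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(z, z.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu]


def fc_unvectorize(v: np.ndarray, R: int) -> np.ndarray:
    """Inverse packer: rebuild the symmetric matrix (zero diagonal)."""
    v = np.asarray(v, float)
    if v.size != R * (R - 1) // 2:
        raise ValueError("length does not match R(R-1)/2")
    out = np.zeros((R, R))
    iu = np.triu_indices(R, k=1)
    out[iu] = v
    return out + out.T


def fc_project(f_fc, Wfc, bfc) -> Tensor:
    """Affine map of the packed connectivity vector into the shared latent
    space: f'_fc = Wfc f_fc + bfc."""
    f_fc = as_tensor(f_fc)
    if f_fc.ndim == 1:
        f_fc = f_fc.reshape(1, -1)
    return f_fc @ as_tensor(Wfc).T + as_tensor(bfc).reshape(1, -1)


def cross_interaction(f_seq, f_fc_proj) -> Tensor:
    """Hadamard interaction f_cross = f_seq * f'_fc."""
    a, b = as_tensor(f_seq), as_tensor(f_fc_proj)
    if a.shape != b.shape:
        raise ValueError(f"width mismatch: {a.shape} vs {b.shape}")
    return a * b


def concat_features(f_seq, f_fc, f_cross) -> Tensor:
    """Joint representation [f_seq, f_fc, f_cross] in that order."""
    parts = [as_tensor(f) for f in (f_seq, f_fc, f_cross)]
    parts = [p.reshape(1, -1) if p.ndim == 1 else p for p in parts]
    return concat(parts, axis=-1)


def cross_modality_fuse(z_smri, f_fmri, Ws, bs, Wf, bf) -> Tensor:
    """Fuse the two modality embeddings.

    Both are projected to a common width; the fused vector is
    [proj_s, proj_f, proj_s * proj_f] (three times the common width),
    mirroring the intra-modality interaction pattern.
    """
    if z_smri is None or f_fmri is None:
        raise ValueError("fusion requires both modality embeddings")
    ps = fc_project(z_smri, Ws, bs)
    pf = fc_project(f_fmri, Wf, bf)
    return concat([ps, pf, ps * pf], axis=-1)
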