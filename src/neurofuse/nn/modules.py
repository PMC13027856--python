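"""Model components: the hierarchical multi-view 3D convolutional encoder,
the bidirectional-LSTM temporal encoder with connectivity fusion, the shared
MLP classifier head, and the Adam optimizer.

Weight initialisation is seeded uniform fan-in scaling; forward passes are
deterministic in eval mode (dropout active only during training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat, stack
from . import ops
from . import temporal as tmp

__all__ = [
    "Module",
    "Adam",
    "SmriConfig",
    "FmriConfig",
    "ClassifierHead",
    "SmriEncoder",
    "FmriEncoder",
    "SmriNet",
    "FmriNet",
    "FusedNet",
    "layer_norm",
]


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match parameter count")
        for p, s in zip(params, state):
            p.data = s.copy()


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _uniform(rng, fan_in, shape) -> Tensor:
    s = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-s, s, shape), requires_grad=True)


def layer_norm(x, gain, bias, eps: float = 1e-5) -> Tensor:
    """Per-sample layer normalisation over the feature axis, then affine."""
    x = as_tensor(x)
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    norm = xc / (var + eps).sqrt()
    return as_tensor(gain).reshape(1, -1) * norm + as_tensor(bias).reshape(1, -1)


@dataclass
class SmriConfig:
    """Hierarchical multi-view encoder hyperparameters.

    The default channel plan, alternating kernel sizes and dilations follow
    the full-scale architecture; the ``desk_scale`` preset is a reduced plan
    for CPU-sized experiments.
    """

    channels: tuple[int, ...] = (32, 64, 128, 256)
    kernels: tuple[int, ...] = (3, 5, 3, 5)
    dilations: tuple[int, ...] = (1, 2, 1, 2)
    strides: tuple[int, ...] = (2, 2, 2, 2)
    spectral_norm: bool = True
    channel_attn: bool = True
    spatial_attn: bool = True
    graph_head: bool = False
    n_graph_nodes: int = 8
    lambda_ent: float = 1e-3
    n_planes: int = 3

    @classmethod
    def desk_scale(cls) -> "SmriConfig":
        return cls(channels=(4, 8), kernels=(3, 3), dilations=(1, 1),
                   strides=(2, 2))

    @property
    def embed_dim(self) -> int:
        return self.n_planes * self.channels[-1]


@dataclass
class FmriConfig:
    """Temporal-branch hyperparameters: R ROIs, d_h hidden width, d_f latent
    fusion width; the packed FC vector has R(R-1)/2 entries."""

    n_rois: int = 8
    d_h: int = 128
    d_f: int = 256
    # whether the concatenated representation uses the raw packed FC vector
    # (as printed) or its latent projection
    raw_fc_in_concat: bool = True

    @classmethod
    def desk_scale(cls, n_rois: int = 8) -> "FmriConfig":
        return cls(n_rois=n_rois, d_h=16, d_f=32)

    @property
    def n_fc(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def embed_dim(self) -> int:
        fc_width = self.n_fc if self.raw_fc_in_concat else self.d_f
        return self.d_f + fc_width + self.d_f


class _ConvBlock(Module):
    """conv -> stat-norm -> ReLU with a 1x1x1 residual alignment branch."""

    def __init__(self, rng, cin, cout, k, stride, dilation, spectral_norm):
        self.k, self.stride, self.dilation = k, stride, dilation
        self.spectral_norm = spectral_norm
        fan_in = cin * k**3
        self.w = _uniform(rng, fan_in, (cout, cin, k, k, k))
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.gamma = Tensor(np.ones(cout), requires_grad=True)
        self.beta = Tensor(np.zeros(cout), requires_grad=True)
        self.phi_w = _uniform(rng, cin, (cout, cin, 1, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        w = self.w
        if self.spectral_norm:
            # cold-start converged power iteration: bit-deterministic for a
            # given weight tensor (a persistent warm-start vector would leak
            # state between forward passes)
            w, _ = ops.spectral_normalize(w)
        y = ops.conv3d(x, w, b=self.b, stride=self.stride,
                       dilation=self.dilation, padding="same")
        y = ops.stat_normalize(y, self.gamma, self.beta).relu()
        return ops.residual_fuse(y, x, self.phi_w, stride=self.stride)


class SmriEncoder(Module):
    """Shared-weight hierarchical 3D encoder applied to each plane stack.

    Each plane of the multi-view tensor (N, 3, n, H, W) is treated as a
    single-channel 3D volume, passed through the convolution blocks with
    channel and spatial attention, optionally a graph propagation head, and
    compacted by global average pooling; the plane embeddings are
    concatenated into z of width 3 * C_last.
    """

    def __init__(self, cfg: SmriConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.blocks: list[_ConvBlock] = []
        cin = 1
        for cout, k, d, s in zip(cfg.channels, cfg.kernels, cfg.dilations,
                                 cfg.strides):
            self.blocks.append(
                _ConvBlock(rng, cin, cout, k, s, d, cfg.spectral_norm)
            )
            cin = cout
        C = cfg.channels[-1]
        if cfg.channel_attn:
            self.w_chan = _uniform(rng, C, (C, C))
        if cfg.spatial_attn:
            self.w_spat = _uniform(rng, C, (1, C, 1, 1, 1))
            self.b_spat = Tensor(np.zeros(1), requires_grad=True)
        if cfg.graph_head:
            n = cfg.n_graph_nodes
            # face-adjacency chain over block-parcellated ROIs
            A = np.eye(n, k=1) + np.eye(n, k=-1)
            self.A = Tensor(A)
            self.w_graph = _uniform(rng, C, (C, C))
        self._captured: list[Tensor] = []

    def encode_plane(self, x: Tensor, capture: bool = False) -> Tensor:
        for blk in self.blocks:
            x = blk.forward(x)
        if self.cfg.channel_attn:
            x = ops.channel_attention(x, self.w_chan)
        if self.cfg.spatial_attn:
            logits = ops.conv3d(x, self.w_spat, b=self.b_spat, padding=0)
            x = ops.spatial_attention(x, logits)
        if capture:
            self._captured.append(x)
        if self.cfg.graph_head:
            # node features: average-pool the feature map over n depth slabs
            # (a coarse stand-in parcellation on the downsampled feature grid)
            n = self.cfg.n_graph_nodes
            D = x.shape[2]
            bounds = np.linspace(0, D, n + 1).round().astype(int)
            slabs = []
            for i in range(n):
                lo = min(bounds[i], D - 1)
                hi = max(bounds[i + 1], lo + 1)
                slabs.append(x[:, :, lo:hi, :, :].mean(axis=(2, 3, 4)))
            Hn = stack(slabs, axis=1)  # (N, n, C)
            Hn = ops.graph_propagate(Hn, self.A, self.w_graph)
            return Hn.mean(axis=1)  # (N, C)
        return ops.global_avg_pool(x)

    def forward(self, mvt, capture: bool = False) -> Tensor:
        x = as_tensor(mvt)
        if x.ndim == 4:
            x = x.reshape((1,) + x.shape)
        if x.ndim != 5 or x.shape[1] != self.cfg.n_planes:
            raise ValueError(
                f"expected (N, {self.cfg.n_planes}, n, H, W), got {x.shape}"
            )
        self._captured = []
        zs = []
        for p in range(self.cfg.n_planes):
            plane = x[:, p, :, :, :]
            plane = plane.reshape((plane.shape[0], 1) + plane.shape[1:])
            zs.append(self.encode_plane(plane, capture=capture))
        return concat(zs, axis=-1)


class ClassifierHead(Module):
    """LayerNorm -> dense(256, GELU) -> dropout(0.5) -> linear 2-logit map.

    Softmax is applied externally at evaluation; the logits feed the loss.
    """

    def __init__(self, d_in: int, rng: np.random.Generator,
                 hidden: int = 256, dropout_p: float = 0.5):
        self.dropout_p = dropout_p
        self.ln_gain = Tensor(np.ones(d_in), requires_grad=True)
        self.ln_bias = Tensor(np.zeros(d_in), requires_grad=True)
        self.W1 = _uniform(rng, d_in, (d_in, hidden))
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = _uniform(rng, hidden, (hidden, 2))
        self.b2 = Tensor(np.zeros(2), requires_grad=True)

    def forward(self, f, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        f = as_tensor(f)
        if f.ndim == 1:
            f = f.reshape(1, -1)
        u = layer_norm(f, self.ln_gain, self.ln_bias)
        h = (u @ self.W1 + self.b1.reshape(1, -1)).gelu()
        if training and self.dropout_p > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            mask = (rng.random(h.shape) >= self.dropout_p) / (1 - self.dropout_p)
            h = h * Tensor(mask)
        return h @ self.W2 + self.b2.reshape(1, -1)


class FmriEncoder(Module):
    """ROI-series projection -> Bi-LSTM -> attention pooling, fused with
    packed functional-connectivity features via Hadamard interaction."""

    def __init__(self, cfg: FmriConfig, rng: np.random.Generator):
        self.cfg = cfg
        R, d_h, d_f = cfg.n_rois, cfg.d_h, cfg.d_f
        self.Wp = _uniform(rng, R, (R, d_h))
        self.bp = Tensor(np.zeros(d_h), requires_grad=True)
        self.lstm_fwd = tmp.init_lstm_params(rng, d_h, d_h)
        self.lstm_bwd = tmp.init_lstm_params(rng, d_h, d_h)
        self.w_attn = _uniform(rng, 2 * d_h, (2 * d_h,))
        self.Wf = _uniform(rng, 2 * d_h, (d_f, 2 * d_h))
        self.bf = Tensor(np.zeros(d_f), requires_grad=True)
        self.Wfc = _uniform(rng, cfg.n_fc, (d_f, cfg.n_fc))
        self.bfc = Tensor(np.zeros(d_f), requires_grad=True)

    def forward(self, S, f_fc) -> Tensor:
        """S: (N, T, R) retained-frame ROI series; f_fc: (N, R(R-1)/2)."""
        S = as_tensor(S)
        if S.ndim == 2:
            S = S.reshape((1,) + S.shape)
        f_fc = as_tensor(f_fc)
        if f_fc.ndim == 1:
            f_fc = f_fc.reshape(1, -1)
        H = tmp.temporal_project(S, self.Wp, self.bp)
        h_seq = tmp.bilstm_encode(H, self.lstm_fwd, self.lstm_bwd)
        z_seq = tmp.attention_pool(h_seq, self.w_attn)
        f_seq = tmp.seq_transform(z_seq, self.Wf, self.bf)
        f_fc_proj = tmp.fc_project(f_fc, self.Wfc, self.bfc)
        f_cross = tmp.cross_interaction(f_seq, f_fc_proj)
        fc_part = f_fc if self.cfg.raw_fc_in_concat else f_fc_proj
        return tmp.concat_features(f_seq, fc_part, f_cross)


class SmriNet(Module):
    """Multi-view structural branch: encoder + classifier head."""

    def __init__(self, cfg: SmriConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoder = SmriEncoder(cfg, rng)
        self.head = ClassifierHead(cfg.embed_dim, rng)

    def forward(self, x, training=False, rng=None, capture=False):
        z = self.encoder.forward(x, capture=capture)
        logits = self.head.forward(z, training=training, rng=rng)
        return logits, z


class FmriNet(Module):
    """Temporal functional branch: encoder + classifier head."""

    def __init__(self, cfg: FmriConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoder = FmriEncoder(cfg, rng)
        self.head = ClassifierHead(cfg.embed_dim, rng)

    def forward(self, x, training=False, rng=None, capture=False):
        S, f_fc = x
        z = self.encoder.forward(S, f_fc)
        logits = self.head.forward(z, training=training, rng=rng)
        return logits, z


class FusedNet(Module):
    """Dual-modality model: both encoders, cross-modality interaction
    fusion, and a shared head over the fused vector."""

    def __init__(self, smri_cfg: SmriConfig, fmri_cfg: FmriConfig,
                 rng: np.random.Generator, common_width: int = 256):
        self.smri = SmriEncoder(smri_cfg, rng)
        self.fmri = FmriEncoder(fmri_cfg, rng)
        self.Ws = _uniform(rng, smri_cfg.embed_dim,
                           (common_width, smri_cfg.embed_dim))
        self.bs = Tensor(np.zeros(common_width), requires_grad=True)
        self.Wf = _uniform(rng, fmri_cfg.embed_dim,
                           (common_width, fmri_cfg.embed_dim))
        self.bf = Tensor(np.zeros(common_width), requires_grad=True)
        self.head = ClassifierHead(3 * common_width, rng)

    def forward(self, x, training=False, rng=None, capture=False):
        mvt, S, f_fc = x
        z_s = self.smri.forward(mvt, capture=capture)
        z_f = self.fmri.forward(S, f_fc)
        fused = tmp.cross_modality_fuse(z_s, z_f, self.Ws, self.bs,
                                        self.Wf, self.bf)
        logits = self.head.forward(fused, training=training, rng=rng)
        return logits, fused
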