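"""Grad-CAM saliency for the volumetric branch.

The class-activation map weights each channel of a captured convolutional
feature map by the spatial mean of the target-logit gradient into that
channel, sums, rectifies, and upsamples to the input grid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["grad_cam_map", "grad_cam"]


def grad_cam_map(
    activation: np.ndarray,
    activation_grad: np.ndarray,
    output_shape: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Combine a feature map (C, *spatial) and its gradient into a
    non-negative saliency map, optionally upsampled to ``output_shape``."""
    a = np.asarray(activation, float)
    g = np.asarray(activation_grad, float)
    if a.shape != g.shape:
        raise ValueError("activation and gradient shapes differ")
    spatial_axes = tuple(range(1, a.ndim))
    weights = g.mean(axis=spatial_axes)  # (C,)
    cam = np.tensordot(weights, a, axes=(0, 0))
    cam = np.maximum(cam, 0.0)
    if output_shape is not None and tuple(output_shape) != cam.shape:
        zoom = [o / c for o, c in zip(output_shape, cam.shape)]
        cam = np.maximum(ndimage.zoom(cam, zoom, order=1), 0.0)
    return cam


def grad_cam(net, x, target_class: int = 1, plane: int = 0) -> np.ndarray:
    """Saliency volume for one multi-view input through a structural net.

    ``net`` is an :class:`~neurofuse.nn.modules.SmriNet`; ``x`` one input of
    shape (3, n, H, W) (or a batch of one).  The captured activation is the
    post-attention feature map of the requested plane; the map is upsampled
    to that plane's input volume shape.
    """
    x = np.asarray(x, float)
    if x.ndim == 4:
        x = x[None]
    if x.shape[0] != 1:
        raise ValueError("grad_cam expects a single input")
    net.zero_grad()
    logits, _ = net.forward(x, training=False, capture=True)
    captured = net.encoder._captured
    if not (0 <= plane < len(captured)):
        raise ValueError("requested plane was not captured on the forward path")
    target = logits[:, target_class].sum()
    target.backward()
    cap = captured[plane]
    if cap.grad is None:
        raise ValueError("no gradient reached the captured layer")
    return grad_cam_map(cap.data[0], cap.grad[0], output_shape=x.shape[2:])
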