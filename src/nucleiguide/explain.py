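"""Grad-CAM explanations for the grading network.

Gradient-weighted class activation mapping: the gradient of one class
logit with respect to a chosen stage's post-attention feature map gives
per-channel weights (spatial mean of the gradient); the ReLU of the
weighted channel sum, bilinearly upsampled and max-normalised, highlights
the image regions that push the prediction toward that class.  By default
the map is taken at the deepest stage's post-NGA fused features, for the
predicted class.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize

from .autodiff import Tensor
from .network import ModelConfig, forward

__all__ = ["Heatmap", "grad_cam", "overlay_heatmap"]


@dataclasses.dataclass
class Heatmap:
    """A [0,1] class-evidence map at input resolution."""

    values: np.ndarray  # (H, W), >= 0, max 1 unless identically zero
    target_class: int  # 1-based grade the map explains
    source_stage: int  # 0-based backbone stage hooked


def grad_cam(
    params: dict[str, Tensor],
    config: ModelConfig,
    i_main: np.ndarray,
    i_nuclei: np.ndarray | None,
    target_class: int | None = None,
    stage: int | None = None,
) -> Heatmap:
    """Compute a Grad-CAM heatmap for one image.

    ``i_main``/``i_nuclei``: (3, H, W) or (H, W, 3) arrays in [0, 1].
    ``target_class`` is 1-based; default is the predicted class.
    ``stage`` is the 0-based backbone stage (default: the deepest).
    Regions with no positive contribution yield an all-zero map.
    """
    if stage is None:
        stage = config.n_stages - 1
    if not 0 <= stage < config.n_stages:
        raise ValueError(f"stage {stage} outside 0..{config.n_stages - 1}")

    def to_nchw(x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 3 and x.shape[-1] == 3:
            x = x.transpose(2, 0, 1)
        return x[None]

    xm = to_nchw(i_main)
    xn = None if i_nuclei is None else to_nchw(i_nuclei)
    logits, cache = forward(params, xm, xn, config)
    k = logits.shape[1]
    if target_class is None:
        target_class = int(np.argmax(logits.data[0])) + 1
    if not 1 <= target_class <= k:
        raise ValueError(f"target_class {target_class} outside 1..{k}")

    seed = np.zeros_like(logits.data)
    seed[0, target_class - 1] = 1.0
    feat = cache[f"fused_s{stage}"]
    logits.backward(seed)

    grads = (feat.grad if feat.grad is not None else np.zeros_like(feat.data))[0]
    acts = feat.data[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    size = config.input_size
    cam = resize(cam, (size, size), order=1, mode="edge", anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return Heatmap(values=cam, target_class=target_class, source_stage=stage)


def overlay_heatmap(
    image: np.ndarray, heatmap: Heatmap, alpha: float = 0.4
) -> np.ndarray:
    """Blend a heatmap over an RGB image with a fixed jet palette.

    ``image``: (H, W, 3) in [0, 1].  Returns the blended RGB array.
    """
    import matplotlib.cm as cm

    colors = cm.jet(heatmap.values)[:, :, :3]
    return np.clip((1 - alpha) * np.asarray(image) + alpha * colors, 0, 1)


def nucleus_focus_rate(
    params, config, x_main, x_nuclei, masks, stage: int | None = None
) -> float:
    """Fraction of images whose heatmap mass concentrates on nuclei.

    For each image, compares the mean heatmap value over ground-truth
    nucleus pixels with the mean over background pixels; returns the
    fraction of images where the nuclear mean is strictly larger.
    """
    hits = 0
    n = x_main.shape[0]
    for i in range(n):
        hm = grad_cam(
            params, config,
            x_main[i], None if x_nuclei is None else x_nuclei[i],
            stage=stage,
        )
        m = np.asarray(masks[i]).astype(bool)
        if m.all() or not m.any():
            continue
        if hm.values[m].mean() > hm.values[~m].mean():
            hits += 1
    return hits / n
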