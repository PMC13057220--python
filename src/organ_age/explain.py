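"""Gradient-weighted class-activation maps for the age regressor.

For a chosen residual block, each channel of the block's post-ReLU
activation A_c is weighted by the spatial mean of d(mu)/d(A_c) — the
gradient of the predicted age, not of the predicted uncertainty — and the
ReLU of the weighted sum is upsampled to the input grid and min-max scaled
to [0, 1].  On phantoms the informative region (the age-encoding cavity
wall) is known, so localization is scored quantitatively as the fraction
of top-activation voxels falling inside that region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .age_model import AgeFitResults, _stack_images
from .config import ConfigurationError, DataError


@dataclass
class AttentionMap:
    """Attention values in [0, 1] on the model-input spatial grid."""

    values: np.ndarray
    organ: str = ""
    layer: int = -1

    @property
    def is_null(self) -> bool:
        """True when the gradients vanished and the map is identically 0."""
        return bool(np.all(self.values == 0.0))


def grad_cam(results: AgeFitResults, image, layer: int = -1) -> AttentionMap:
    """Attention map of the age output for one image.

    Parameters
    ----------
    results : trained :class:`~organ_age.age_model.AgeFitResults`.
    image : OrganImage or array matching the trained input shape.
    layer : residual block index (negative indices count from the end);
        the last block is the default.
    """
    net = results.network
    n_blocks = net.n_blocks
    if not -n_blocks <= layer < n_blocks:
        raise ConfigurationError(
            f"block index {layer} out of range for {n_blocks} blocks")
    layer = layer % n_blocks

    x = _stack_images([image])
    if x.ndim - 2 != net.dims or x.shape[1] != net.in_channels:
        raise DataError(f"image shape {x.shape[1:]} does not match the "
                        "trained architecture")
    out = net.forward(x)
    # gradient of mu only; the uncertainty head does not drive the map
    seed_grad = np.zeros_like(out)
    seed_grad[:, 0] = 1.0
    net.net.zero_grad()
    net.backward(seed_grad)

    block = net.blocks[layer]
    activation = block.activation[0]  # (channels, *spatial)
    grad = block.activation_grad[0]
    weights = grad.mean(axis=tuple(range(1, grad.ndim)))  # spatial mean per channel
    cam = np.maximum((weights[:, None] * activation.reshape(len(weights), -1))
                     .sum(axis=0), 0.0).reshape(activation.shape[1:])

    target = x.shape[2:]
    factors = tuple(t / s for t, s in zip(target, cam.shape))
    order = 1 if net.dims == 3 else 0  # trilinear volumes, nearest 2D slices
    cam = ndimage.zoom(cam.astype(np.float64), factors, order=order,
                       mode="nearest", grid_mode=True)
    cam = cam[tuple(slice(0, t) for t in target)]
    peak = cam.max()
    if peak > 0:
        cam = (cam - cam.min()) / (peak - cam.min())
    else:
        cam = np.zeros_like(cam)
    organ = getattr(image, "organ", "")
    return AttentionMap(values=cam, organ=organ, layer=layer)


def localization_score(attention: AttentionMap | np.ndarray,
                       feature_mask: np.ndarray, q: float = 0.9) -> float:
    """Fraction of the top-(1-q) activation voxels inside the feature mask.

    A uniform map scores about the mask's volume fraction (chance level);
    1.0 means every top-activation voxel lies in the known informative
    region.
    """
    values = attention.values if isinstance(attention, AttentionMap) else np.asarray(attention)
    mask = np.asarray(feature_mask).astype(bool)
    if values.shape != mask.shape:
        raise DataError(f"map shape {values.shape} does not match mask "
                        f"shape {mask.shape}")
    if not mask.any():
        raise DataError("feature mask is empty")
    if not 0.0 < q < 1.0:
        raise ConfigurationError("quantile q must be in (0, 1)")
    flat = values.ravel()
    n_top = max(int(round((1.0 - q) * flat.size)), 1)
    top_idx = np.argpartition(flat, flat.size - n_top)[-n_top:]
    return float(mask.ravel()[top_idx].mean())


def cavity_feature_mask(image, phantom=None, dilate: int = 2) -> np.ndarray:
    """Known informative region of a phantom: the dark cavity plus margin.

    Thresholds the in-mask dark core (as in
    :func:`~organ_age.synthetic.measure_cavity_radius`) and dilates it so the
    cavity wall — where the age signal lives — is included.
    """
    from .preprocess import OrganImage

    if not isinstance(image, OrganImage):
        raise DataError("cavity_feature_mask expects an OrganImage")
    vox = image.voxels if not image.has_channels else image.voxels[0]
    inside = image.mask > 0
    vals = vox[inside]
    dark = inside & (vox < vals.min() + 0.5 * (vals.max() - vals.min()))
    if dilate > 0:
        dark = ndimage.binary_dilation(dark, iterations=dilate)
    return dark
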